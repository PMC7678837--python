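"""Bisulfite amplicon sequencing (BSAS): targeted methylation calling.

Reads from a bisulfite-PCR amplicon are compared ungapped against the
amplicon reference with every reference C treated as a wildcard matching
C (methylated) or T (converted); mismatches are counted only at non-C
positions.  Per reference C site, the methylation percentage is the
fraction of accepted reads retaining C.  Fraction comparisons use a
repeated-measures one-way ANOVA (animal as blocking factor) with Tukey's
post-hoc on fraction means.

Only the amplicon (bisulfite-PCR top) strand is modelled; reads are also
tried as reverse complements and tallied.  Alignment is ungapped at
offset 0 with an optional small ±offset scan for ragged ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oxtrap.methylome import site_methylation_fraction
from oxtrap.stats import rm_oneway_anova, tukey_pairwise

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AmpliconRef:
    """An amplicon reference with its C-site offsets by context."""

    name: str
    sequence: str
    chrom: str | None = None
    start: int | None = None
    strand: str = "+"
    cg_offsets: list[int] = field(init=False)
    ch_offsets: list[int] = field(init=False)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        self.cg_offsets, self.ch_offsets = [], []
        seq = self.sequence
        for i, base in enumerate(seq):
            if base != "C":
                continue
            if i + 1 < len(seq) and seq[i + 1] == "G":
                self.cg_offsets.append(i)
            else:
                self.ch_offsets.append(i)  # trailing C: next base unknown -> CH

    @property
    def c_offsets(self) -> list[int]:
        return sorted(self.cg_offsets + self.ch_offsets)


@dataclass
class MapResult:
    accepted: bool
    offset: int = 0
    mismatches: int = 0
    revcomp: bool = False


def _try_align(read: np.ndarray, ref: np.ndarray, c_mask: np.ndarray,
               offset: int, max_mismatch: int) -> int | None:
    """Mismatch count of an ungapped placement, or None if read overruns."""
    L = len(read)
    if offset < 0 or offset + L > len(ref):
        return None
    seg = ref[offset:offset + L]
    cm = c_mask[offset:offset + L]
    informative = (read == seg) | (cm & ((read == b"C") | (read == b"T")))
    mism = int((~informative).sum())
    return mism if mism <= max_mismatch else None


def map_bisulfite_read(
    read: str, ref: AmpliconRef, max_mismatch: int = 2,
    offset_scan: int = 0, try_revcomp: bool = True,
) -> MapResult:
    """Ungapped wildcard-C alignment of one read against the amplicon.

    At reference C positions the read may carry C or T without penalty;
    elsewhere any difference is a mismatch.  Placement is at offset 0 by
    default with an optional ±``offset_scan`` bp scan; the reverse
    complement is tried if the forward orientation is rejected.
    """
    ref_arr = np.frombuffer(ref.sequence.encode(), dtype="S1")
    c_mask = ref_arr == b"C"
    offsets = [0] + [o for k in range(1, offset_scan + 1) for o in (k, -k)]
    for rc in ((False, True) if try_revcomp else (False,)):
        seq = reverse_complement(read) if rc else read
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        if len(arr) > len(ref_arr):
            continue
        for off in offsets:
            mism = _try_align(arr, ref_arr, c_mask, off, max_mismatch)
            if mism is not None:
                return MapResult(True, off, mism, rc)
    return MapResult(False)


def call_amplicon_methylation(
    reads: list[str], ref: AmpliconRef, max_mismatch: int = 2,
    offset_scan: int = 0,
) -> pd.DataFrame:
    """Per-C-site methylation call table over accepted reads.

    Per site, methylated = C calls, unmethylated = T calls; a read base
    that is neither C nor T at a reference-C site is non-informative for
    that site and leaves its denominator.  Raises if no read is accepted,
    reporting the rejection tally.
    """
    ref_arr = np.frombuffer(ref.sequence.encode(), dtype="S1")
    c_offsets = np.asarray(ref.c_offsets, dtype=int)
    meth = np.zeros(len(c_offsets), dtype=int)
    total = np.zeros(len(c_offsets), dtype=int)
    n_rejected = 0
    n_accepted = 0
    for read in reads:
        res = map_bisulfite_read(read, ref, max_mismatch, offset_scan)
        if not res.accepted:
            n_rejected += 1
            continue
        n_accepted += 1
        seq = reverse_complement(read) if res.revcomp else read
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        covered = (c_offsets >= res.offset) & (c_offsets < res.offset + len(arr))
        idx = c_offsets[covered] - res.offset
        calls = arr[idx]
        is_c = calls == b"C"
        is_t = calls == b"T"
        informative = is_c | is_t
        total[covered] += informative
        meth[covered] += is_c
    if n_accepted == 0:
        raise ValueError(f"no reads accepted ({n_rejected} rejected of {len(reads)})")
    context = ["CG" if o in ref.cg_offsets else "CH" for o in c_offsets]
    pct = site_methylation_fraction(meth, total)
    return pd.DataFrame(
        {
            "offset": c_offsets,
            "context": context,
            "meth_count": meth,
            "total_count": total,
            "pct": np.atleast_1d(pct),
        }
    )


def compare_amplicon_fractions(values: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Repeated-measures comparison of a site's methylation across fractions.

    ``values`` is long-form with columns subject, fraction, value (one
    methylation percentage per animal and fraction).  Animals missing a
    fraction are dropped (with a warning from the ANOVA).  Returns the RM
    one-way ANOVA F and p plus Tukey HSD pairwise results on fraction
    means using the RM error term.
    """
    required = {"subject", "fraction", "value"}
    if not required <= set(values.columns):
        raise ValueError(f"values needs columns {sorted(required)}")
    wide = values.pivot_table(index="subject", columns="fraction", values="value")
    complete = wide.dropna()
    if len(complete) < 3:
        raise ValueError("need >= 3 animals with all fractions present")
    F, p, df1, df2, ms_err = rm_oneway_anova(values, "value", "fraction", "subject")
    means = complete.mean(axis=0)
    tukey = tukey_pairwise(means, len(complete), ms_err, df2, alpha)
    return {
        "F": F,
        "p": p,
        "df": (df1, df2),
        "n_subjects": len(complete),
        "means": means,
        "tukey": tukey,
    }
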