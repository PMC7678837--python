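"""Per-site modification calling from paired BS/oxBS cytosine call tables.

A bisulfite (BS) library reads mC + hmC as methylated; a prior oxidation
step (oxBS) converts hmC so that library reads only mC.  Per site, the
methylation percentage of each library is methylated counts over total
counts, and hmC is the BS − oxBS difference clamped at zero.  Genome-wide
levels are unweighted site means per context after a coverage filter, and
spike-in controls of known pure C / mC / hmC status yield conversion
efficiencies.

Symmetric CpG strands are not merged: each strand's cytosine is its own
site, matching per-cytosine call-report granularity.  NA (missing) values
propagate through all arithmetic and never collapse to zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_KEY = ["chrom", "pos", "strand", "context"]


def site_methylation_fraction(meth_count, total_count, min_coverage: int = 1):
    """Percentage methylated calls, 100 × meth/total.

    Scalar or array inputs.  Sites with total_count below ``min_coverage``
    (default 1, i.e. plain arithmetic) yield NaN — a zero-coverage site has
    an undefined level, never 0.
    """
    meth = np.asarray(meth_count, dtype=float)
    total = np.asarray(total_count, dtype=float)
    if np.any(meth > total):
        raise ValueError("meth_count exceeds total_count")
    if np.any(meth < 0) or np.any(total < 0):
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(total >= max(min_coverage, 1), 100.0 * meth / total, np.nan)
    if pct.ndim == 0:
        return float(pct)
    return pct


def estimate_hydroxymethylation(bs_pct, oxbs_pct):
    """hmC percentage: max(0, BS − oxBS), NaN-propagating.

    A negative difference is sampling noise around a true hmC of ~0 and is
    clamped to zero; negative hydroxymethylation is physically meaningless.
    """
    bs = np.asarray(bs_pct, dtype=float)
    ox = np.asarray(oxbs_pct, dtype=float)
    out = np.maximum(0.0, bs - ox)
    out = np.where(np.isnan(bs) | np.isnan(ox), np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def pair_call_tables(
    bs: pd.DataFrame, oxbs: pd.DataFrame, min_coverage: int = 1
) -> pd.DataFrame:
    """Join BS and oxBS call tables on (chrom, pos, strand, context).

    Returns the paired per-site table with columns mC_pct (from oxBS),
    total_mod_pct (from BS), hmC_pct, bs_cov, oxbs_cov.  Unpaired sites are
    excluded and their count logged.
    """
    left = bs.rename(columns={"meth_count": "bs_meth", "total_count": "bs_cov"})
    right = oxbs.rename(columns={"meth_count": "oxbs_meth", "total_count": "oxbs_cov"})
    merged = left.merge(right, on=SITE_KEY, how="inner")
    n_drop = (len(bs) - len(merged)) + (len(oxbs) - len(merged))
    if n_drop:
        logger.info("pair_call_tables: %d unpaired site rows excluded", n_drop)
    merged["total_mod_pct"] = site_methylation_fraction(
        merged["bs_meth"], merged["bs_cov"], min_coverage
    )
    merged["mC_pct"] = site_methylation_fraction(
        merged["oxbs_meth"], merged["oxbs_cov"], min_coverage
    )
    merged["hmC_pct"] = estimate_hydroxymethylation(
        merged["total_mod_pct"], merged["mC_pct"]
    )
    return merged[SITE_KEY + ["mC_pct", "total_mod_pct", "hmC_pct", "bs_cov", "oxbs_cov"]]


def genome_wide_levels(paired: pd.DataFrame, min_coverage: int = 5) -> dict[str, float]:
    """Genome-wide modification levels per context: mCG, hmCG, mCH, hmCH.

    Methylation (mCG, mCH) is the unweighted mean over qualifying sites of
    the per-site oxBS percentage (robust to coverage hotspots, unlike
    read-weighting).  Hydroxymethylation is the BS-level minus oxBS-level
    difference taken at the aggregate — the global BS call level minus the
    global oxBS call level, clamped at 0.  Subtracting the aggregates
    rather than averaging per-site clamped differences keeps the global
    estimate unbiased near zero: per-site clamping inflates a true-zero
    level (e.g. hmCH) by the half-normal mean of the sampling noise.
    Sites must pass the coverage filter in both libraries; contexts with
    no qualifying site yield NaN with a warning.
    """
    ok = (paired["bs_cov"] >= min_coverage) & (paired["oxbs_cov"] >= min_coverage)
    sub = paired[ok]
    out: dict[str, float] = {}
    for ctx in ("CG", "CH"):
        rows = sub[sub["context"] == ctx]
        if len(rows) == 0:
            warnings.warn(f"no {ctx} sites qualify at min_coverage={min_coverage}")
            out[f"m{ctx}"] = float("nan")
            out[f"hm{ctx}"] = float("nan")
            continue
        ox_level = float(rows["mC_pct"].mean())
        bs_level = float(rows["total_mod_pct"].mean())
        out[f"m{ctx}"] = ox_level
        out[f"hm{ctx}"] = max(0.0, bs_level - ox_level)
    return out


@dataclass
class ConversionReport:
    """Bisulfite / oxidation conversion efficiencies from spike-in controls."""

    eff_C: float
    eff_mC: float
    eff_hmC: float
    n_C: int
    n_mC: int
    n_hmC: int


def conversion_efficiency(spikein: pd.DataFrame, truth: pd.DataFrame | None = None) -> ConversionReport:
    """Estimate conversion efficiencies from spike-in call tables.

    ``spikein`` columns: site_id, true_class (C|mC|hmC), library (BS|oxBS),
    meth_count, total_count; if true_class is absent it is merged in from
    ``truth`` (site_id, true_class).

    eff_C  = 1 − methylated rate in BS at true-C sites (conversion of C);
    eff_mC = methylated rate in BS at true-mC sites (retention of mC);
    eff_hmC = 1 − methylated rate in oxBS at true-hmC sites (oxidation +
    conversion of hmC).  A truth class with no covered site gives NaN.
    """
    df = spikein
    if "true_class" not in df.columns:
        if truth is None:
            raise ValueError("spike-in truth classes required")
        df = df.merge(truth, on="site_id")

    def _rate(cls: str, library: str) -> tuple[float, int]:
        rows = df[(df["true_class"] == cls) & (df["library"] == library)]
        total = int(rows["total_count"].sum())
        if total == 0:
            return float("nan"), 0
        return float(rows["meth_count"].sum() / total), total

    rate_C, n_C = _rate("C", "BS")
    rate_mC, n_mC = _rate("mC", "BS")
    rate_hmC, n_hmC = _rate("hmC", "oxBS")
    return ConversionReport(
        eff_C=1.0 - rate_C if not np.isnan(rate_C) else float("nan"),
        eff_mC=rate_mC,
        eff_hmC=1.0 - rate_hmC if not np.isnan(rate_hmC) else float("nan"),
        n_C=n_C,
        n_mC=n_mC,
        n_hmC=n_hmC,
    )
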