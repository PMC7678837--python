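"""Targeted bisulfite amplicon sequencing: calling and fraction comparison.

Reads are aligned ungapped against the amplicon with reference Cs as C/T
wildcards; per-site methylation is the share of accepted reads retaining
C.  Fractions are compared per animal with a repeated-measures one-way
ANOVA and Tukey's post-hoc.
"""

import numpy as np
import pandas as pd

from oxtrap.bsas import AmpliconRef, call_amplicon_methylation, compare_amplicon_fractions
from oxtrap.simulate import simulate_amplicon_reads

REF = ("ATTGACGTTAGGACGGTAAGATTAGGCATTACGATTGGATACTAGGAAGT"
       "TAGCGATTAACGGATTACCGATTAGGGACGATTATTAAGGATACATTAGG")
ref = AmpliconRef("promoter_amp", REF)
print(f"amplicon: {len(REF)} bp, {len(ref.cg_offsets)} CG sites, "
      f"{len(ref.ch_offsets)} CH sites")

rng = np.random.default_rng(4)
truth = {"input": 0.65, "negative": 0.70, "positive": 0.35}
rows = []
for animal in range(1, 7):
    for fraction, level in truth.items():
        probs = {o: float(np.clip(level + rng.normal(0, 0.03), 0, 1))
                 for o in ref.c_offsets}
        reads = simulate_amplicon_reads(REF, probs, 400,
                                        seed=int(rng.integers(2**31)))
        called = call_amplicon_methylation(reads, ref)
        cg_mean = called.loc[called["context"] == "CG", "pct"].mean()
        rows.append((f"a{animal}", fraction, cg_mean))

values = pd.DataFrame(rows, columns=["subject", "fraction", "value"])
print(values.groupby("fraction")["value"].mean().round(1).to_string())
res = compare_amplicon_fractions(values)
print(f"RM one-way ANOVA: F={res['F']:.1f}, p={res['p']:.2e}")
for c in res["tukey"]:
    print(f"  Tukey {c.level_a} vs {c.level_b}: diff={c.diff:+.1f} pp, "
          f"p={c.p:.2e}")
# The positive fraction's ~30 pp promoter hypomethylation is recovered at
# site level and is highly significant against both other fractions.
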