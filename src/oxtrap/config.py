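"""Configuration objects for the synthetic generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

DEFAULT_CELL_TYPES = ("astrocyte", "microglia", "neuron", "oligodendrocyte")

# Rough brain cellularity: neurons dominate, glia split the rest
# (astrocytes 10-20%, microglia 5-10% of cells).
DEFAULT_MIXTURE = (0.15, 0.10, 0.55, 0.20)

DEFAULT_HMCG = {
    "astrocyte": 0.10,
    "microglia": 0.03,  # microglia carry distinctly less hmCG
    "neuron": 0.13,
    "oligodendrocyte": 0.08,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic tissue-mixture experiment.

    The defaults encode the study conditions the analysis is meant to
    recover: a four-cell-type mixture, affinity-purified positive fractions
    at 90% purity, marker genes planted at an 8-fold positive/input
    enrichment, ~70% genome-wide mCG with promoter hypomethylation of a
    cell type's own markers, cell-type-dependent hmCG (lowest in the
    microglia-like type), low mCH with a sparse high-mCH site minority,
    and hmCH identically zero.
    """

    seed: int = 0
    # genome layout
    n_chromosomes: int = 4
    chrom_length_bp: int = 2_200_000
    n_genes: int = 480
    gene_body_range: tuple[int, int] = (2000, 6000)
    gene_gap_range: tuple[int, int] = (500, 3000)
    # cell types and mixture
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES
    mixture_proportions: Sequence[float] = DEFAULT_MIXTURE
    n_markers_per_type: int = 100
    marker_enrichment_fc: float = 8.0
    purity: float = 0.90
    # methylome truth
    baseline_mCG: float = 0.70
    marker_promoter_mCG: float = 0.50
    island_mCG: float = 0.08
    hmCG_by_type: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HMCG)
    )
    mCH_baseline: float = 0.01
    high_mCH_site_rate: float = 0.01
    high_mCH_range: tuple[float, float] = (0.02, 0.60)
    # sequencing model
    coverage_mean: float = 50.0
    conversion_eff_C: float = 1.0
    conversion_eff_mC: float = 1.0
    conversion_eff_hmC: float = 1.0
    # site densities
    promoter_cg_sites: int = 20
    body_cg_sites: int = 10
    n_intergenic_cg: int = 5000
    n_ch_sites: int = 8000
    n_spikein_per_class: int = 60
    spikein_coverage: float = 100.0
    # expression model
    n_rna_genes: int = 4000
    nb_dispersion: float = 0.05
    n_samples_per_group: int = 6
    n_methylome_replicates: int = 4

    def __post_init__(self) -> None:
        if len(self.cell_types) != len(self.mixture_proportions):
            raise ValueError("mixture_proportions must align with cell_types")
        if abs(sum(self.mixture_proportions) - 1.0) > 1e-9:
            raise ValueError("mixture_proportions must sum to 1")
        fracs = {
            "purity": self.purity,
            "baseline_mCG": self.baseline_mCG,
            "marker_promoter_mCG": self.marker_promoter_mCG,
            "island_mCG": self.island_mCG,
            "mCH_baseline": self.mCH_baseline,
            "high_mCH_site_rate": self.high_mCH_site_rate,
            "conversion_eff_C": self.conversion_eff_C,
            "conversion_eff_mC": self.conversion_eff_mC,
            "conversion_eff_hmC": self.conversion_eff_hmC,
            **{f"hmCG_by_type[{ct}]": v for ct, v in self.hmCG_by_type.items()},
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for ct in self.cell_types:
            if ct not in self.hmCG_by_type:
                raise ValueError(f"hmCG_by_type missing entry for {ct!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.marker_enrichment_fc <= 0:
            raise ValueError("marker_enrichment_fc must be positive")
        lo, hi = self.high_mCH_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("high_mCH_range must be an ordered pair in [0, 1]")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (synthetic or real-data mode)."""

    mode: str = "synthetic"
    seed: int = 0
    sim: SimConfig | None = None
    outdir: str | Path = "oxtrap_out"
    # analysis thresholds
    min_coverage: int = 5
    fc_cutoff_de: float = 1.25
    fc_cutoff_marker: float = 5.0
    q_cutoff: float = 0.05
    enrichment_score_cutoff: float = 3.5
    expression_filter: float = 20.0
    bonferroni_m: int | None = None  # None: number of genes tested
    # real-data mode inputs
    paths: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        for name in ("min_coverage", "fc_cutoff_de", "fc_cutoff_marker",
                     "q_cutoff", "enrichment_score_cutoff", "expression_filter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode == "synthetic" and self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        if self.mode == "real":
            required = {"cytosine_bs", "cytosine_oxbs", "genes_bed", "counts", "metadata"}
            missing = required - set(self.paths)
            if missing:
                raise ValueError(
                    f"real mode requires paths for: {', '.join(sorted(missing))}"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outdir"] = str(self.outdir)
        return d
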