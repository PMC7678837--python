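import numpy as np
import pytest

from oxtrap.config import SimConfig


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size configuration for fast structural tests."""
    return SimConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length_bp=600_000,
        n_genes=24,
        n_markers_per_type=4,
        n_intergenic_cg=800,
        n_ch_sites=800,
        n_rna_genes=400,
        n_samples_per_group=3,
        n_methylome_replicates=2,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    from oxtrap.simulate import simulate_annotation

    return simulate_annotation(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_annotation):
    from oxtrap.simulate import simulate_methylome_truth

    return simulate_methylome_truth(small_config, small_annotation)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
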