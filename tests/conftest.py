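import numpy as np
import pytest

from scdmap.simulate import SimConfig, simulate_cohort
from scdmap.worked_example import (
    family_pedigree,
    hes7_domains,
    hes7_synthetic_transcript,
    rflp_synthetic_amplicon,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A miniature cohort configuration for fast unit tests."""
    return SimConfig(
        n_chromosomes=3,
        chrom_length_bp=10_000_000,
        n_markers_per_chrom=80,
        causal_chrom="chr2",
        causal_pos=5_000_000,
        ld_block_length_bp=500_000,
        causal_ibd_core_bp=1_000_000,
        causal_ibd_half_length_bp=2_500_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def hes7_transcript():
    return hes7_synthetic_transcript()


@pytest.fixture(scope="session")
def hes7_domain_annotations():
    return hes7_domains()


@pytest.fixture(scope="session")
def rflp_amplicon():
    return rflp_synthetic_amplicon()


@pytest.fixture(scope="session")
def fig3_pedigree():
    return family_pedigree()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150206)
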