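import numpy as np
import pytest

from rdcnv import SimulationConfig, simulate_cohort
from rdcnv.genome import GenomeModel


@pytest.fixture(scope="session")
def small_cohort():
    """3 samples on 2 Mb with Poisson noise — the workhorse noisy fixture."""
    cfg = SimulationConfig(
        seed=42, n_samples=3, chromosomes=(("chr1", 2_000_000),), events_per_sample=8
    )
    return (cfg,) + simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, flat-GC-bias cohort: every stage should be exact on it."""
    cfg = SimulationConfig(
        seed=7,
        n_samples=3,
        chromosomes=(("chr1", 2_000_000),),
        events_per_sample=8,
        noise="none",
        gc_bias_strength=0.0,
        q0_background=0.0,
        q0_repeat=0.0,
        probe_noise_sd=0.0,
        qpcr_ct_noise_sd=0.0,
    )
    return (cfg,) + simulate_cohort(cfg)


@pytest.fixture(scope="session")
def z_cohort():
    """Cohort with an autosome and a (haploid, female) Z chromosome."""
    cfg = SimulationConfig(
        seed=3,
        n_samples=2,
        chromosomes=(("chr1", 1_000_000), ("chrZ", 500_000)),
        events_per_sample=4,
        noise="none",
        gc_bias_strength=0.0,
        q0_background=0.0,
        q0_repeat=0.0,
    )
    return (cfg,) + simulate_cohort(cfg)


def flat_genome(length=100_000, bin_size=100, name="chr1", gaps=(), gc=0.45):
    """Uniform-GC gapless single-chromosome genome for hand-built signals."""
    n = -(-length // bin_size)
    return GenomeModel(
        chromosomes=[(name, length)],
        bin_size=bin_size,
        gc={name: np.full(n, gc)},
        gaps={name: list(gaps)},
        ploidy={name: 2},
    )
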