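import numpy as np
import pytest

from recessex.simdata import (
    SimConfig,
    TruthTable,
    simulate_population,
    simulate_sequence_genotypes,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def population(default_config):
    """One default-condition cohort shared across tests (read-only)."""
    return simulate_population(default_config)


@pytest.fixture(scope="session")
def genotypes(default_config, population):
    _, truth = population
    return simulate_sequence_genotypes(truth, default_config.mean_coverage)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_founders=60, n_generations=2, n_markers=24,
                     chrom_length_bp=1_200_000, seed=5)


@pytest.fixture(scope="session")
def small_population(small_config):
    return simulate_population(small_config)


def make_truth(diplotypes, seed=0, n_markers=3) -> TruthTable:
    """A hand-built truth table for stages that only need genotype classes."""
    diplo = np.asarray(diplotypes, dtype=np.int8)
    n = len(diplo)
    return TruthTable(
        samples=[f"B{i:03d}" for i in range(n)],
        diplotypes=diplo,
        ancestry=np.zeros((n, 2, n_markers), dtype=np.int32),
        causal=np.stack([diplo >= 1, diplo == 2], axis=1),
        marker_dosages=np.zeros((n, n_markers), dtype=np.int8),
        marker_positions=np.arange(1, n_markers + 1) * 10,
        founder_carrier_haplotype=np.zeros(n_markers, dtype=np.uint8),
        chrom="19",
        focal_pos=15,
        focal_ref="TC",
        focal_alt="T",
        seed=seed,
    )
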