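import numpy as np
import pytest

from sersdx import (CohortPlan, NoiseModel, PeakSpec, ClassSignature,
                    default_grid, simulate_cohort, binary_signatures)

SEED = 1234


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def noiseless_binary():
    """Tiny noise-free cancer/control cohort: spectra equal the band sums."""
    plan = CohortPlan(binary_signatures(), samples_per_class=3,
                      spectra_per_sample=4, noise=NoiseModel.zero(),
                      seed=SEED)
    return simulate_cohort(plan)


@pytest.fixture(scope="session")
def noisy_binary_small():
    """Small default-noise cancer/control cohort for unit tests."""
    plan = CohortPlan(binary_signatures(), samples_per_class=6,
                      spectra_per_sample=8, seed=SEED)
    return simulate_cohort(plan)


def single_peak_signature(center=1080.0, width=10.0, amplitude=1.0,
                          label="non_cancer"):
    return ClassSignature(label, (PeakSpec(center, width, amplitude),))


def rng_for(test_seed: int) -> np.random.Generator:
    return np.random.default_rng(SEED + test_seed)
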