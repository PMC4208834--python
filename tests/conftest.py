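import numpy as np
import pytest

from cortsync.synth import (
    BehaviorSpec,
    CohortConfig,
    CouplingSpec,
    build_forward,
    build_toy_source_space,
    default_parcels,
    simulate_cohort,
    simulate_subject,
)


@pytest.fixture(scope="session")
def src162():
    return build_toy_source_space(162, seed=1)


@pytest.fixture(scope="session")
def parcels162(src162):
    return default_parcels(src162)


@pytest.fixture(scope="session")
def small_forward(src162):
    """Light sensor array for unit tests (34 mag / 34 grad / 32 EEG / 1 EOG)."""
    return build_forward(src162, n_mag=34, n_grad=34, n_eeg=32, seed=1)


@pytest.fixture(scope="session")
def small_subject(src162, parcels162, small_forward):
    """One simulated subject with strong planted coupling, 40 trials."""
    gain, channels = small_forward
    coupling = CouplingSpec(kappa_conflict=5.0, kappa_base=5.0)
    return simulate_subject(
        gain, channels, src162, parcels162, coupling, BehaviorSpec(),
        n_trials=40, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two-subject, 12-trial cohort on a minimal mesh for I/O tests."""
    cfg = CohortConfig(n_subjects=2, n_trials=12, n_per_hemi=42,
                       n_mag=8, n_grad=8, n_eeg=8)
    cohort, truth = simulate_cohort(cfg, seed=5)
    return cohort, truth
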