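import numpy as np
import pytest

import serialdep as sd


@pytest.fixture(scope="session")
def uniform_trials():
    """Eight 17-trial uniform blocks (one scanner session's worth)."""
    return sd.gen_trial_sequence(8, 17, "uniform", seed=11)


@pytest.fixture(scope="session")
def population():
    return sd.PopulationModel()


@pytest.fixture(scope="session")
def adaptation():
    return sd.AdaptationParams(0.3, 1.0)


@pytest.fixture(scope="session")
def noiseless_voxels(uniform_trials):
    """Noiseless, adaptation-free voxel simulation for identity checks."""
    spec = sd.SyntheticVoxelSpec(noise_sd=0.0, adaptation_fraction=0.0)
    return sd.gen_voxel_timeseries(uniform_trials, spec, seed=5)


def brute_force_map(resp, expected_fn, grid_step=0.25):
    """Dense-grid maximum-likelihood oracle, independent of the decoder path.

    ``expected_fn(theta)`` returns the expected-rate vector; the Poisson
    log-likelihood is enumerated on a fine grid and the argmax returned.
    """
    from scipy.special import gammaln

    grid = np.arange(0.0, 180.0, grid_step)
    resp = np.asarray(resp, dtype=float)
    best_theta, best_ll = None, -np.inf
    for theta in grid:
        lam = np.maximum(expected_fn(theta), 1e-12)
        ll = float((resp * np.log(lam) - lam - gammaln(resp + 1.0)).sum())
        if ll > best_ll:
            best_ll, best_theta = ll, theta
    return best_theta
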