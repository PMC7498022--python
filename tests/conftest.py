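import numpy as np
import pytest

import stablevar as sv

# Shared small-scale study conditions: tau = 50, beta = 5 (tau_T = 55),
# sigma_T = 0.3 as in the reference sorting setup, population scaled down
# for test speed.
TAU, BETA, VT = 50.0, 5.0, 0.09


@pytest.fixture(scope="session")
def sigma_w_full():
    """Noise level calibrated once to vW = (1 - 0.25) * vT for r2 = 0.25."""
    return sv.calibrate_sigma(0.75 * VT, tau=TAU, beta=BETA, seed=101)


@pytest.fixture(scope="session")
def sigma_w_all():
    """Noise level calibrated to vW = vT (pure unstable population)."""
    return sv.calibrate_sigma(VT, tau=TAU, beta=BETA, seed=102)


@pytest.fixture(scope="session")
def pop_quarter(sigma_w_full):
    """Stationary population with r2 = 0.25 at test scale."""
    return sv.build_population(
        vT=VT, r2=0.25, tau=TAU, beta=BETA,
        n_subpops=800, n_cells=40_000, seed=103, sigma=sigma_w_full,
    )


@pytest.fixture(scope="session")
def pop_unstable(sigma_w_all):
    """Pure-unstable population (r2 = 0, all subpopulations share alpha)."""
    return sv.build_population(
        vT=VT, r2=0.0, tau=TAU, beta=BETA,
        n_subpops=800, n_cells=40_000, seed=104, sigma=sigma_w_all,
    )


@pytest.fixture(scope="session")
def pop_stable():
    """Pure-stable population (r2 = 1, deterministic within-subpop levels)."""
    return sv.build_population(
        vT=VT, r2=1.0, tau=TAU, beta=BETA,
        n_subpops=800, n_cells=40_000, seed=105,
    )


@pytest.fixture(scope="session")
def t_grid():
    """Snapshot grid to the plateau, 5 * (tau + beta)."""
    return np.linspace(0.0, 5.0 * (TAU + BETA), 12)


@pytest.fixture(scope="session")
def small_ensemble():
    """Fast synthetic two-population ensemble plus its ground truth."""
    design = sv.ExperimentDesign(
        n_cells=8000, n_subpops=300, n_experiments=2,
        quant_noise_sd=0.02, seed=42,
    )
    return sv.generate_ensemble(design)
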