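import numpy as np
import pytest
from hypothesis import settings

from hydrostoma import (
    GROUP_PARAMS,
    MCMCSettings,
    SyntheticDesign,
    fit_level,
    generate_dataset,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def group_params():
    return GROUP_PARAMS


@pytest.fixture(scope="session")
def recovery_experiment():
    """One seed-fixed parameter-recovery run: three high-conductance
    observations with wet-to-moderate daily soil water potentials (the
    identifiable regime), fitted at the observation level."""
    design = SyntheticDesign(
        groups=("SUBS",),
        n_observations_per_group=3,
        n_days_per_observation=3,
        n_leaves=3,
        noise_sd=0.05,
        psi_day_range=(-1.2, -0.1),
        D_max_range=(0.02, 0.07),
        seed=1,
    )
    tables, truth = generate_dataset(design)
    fit = fit_level(tables, "OBS", mcmc=MCMCSettings(n_iter=2000, n_chains=2, seed=1))
    return design, tables, truth, fit


@pytest.fixture(scope="session")
def nested_fits():
    """OBS -> PFT -> GLB staged fits on data whose groups truly differ
    (published group parameters as truth, 20 % within-group spread)."""
    design = SyntheticDesign(
        n_observations_per_group=2,
        n_days_per_observation=2,
        n_leaves=3,
        noise_sd=0.05,
        psi_day_range=(-1.2, -0.1),
        D_max_range=(0.02, 0.07),
        param_jitter_cv=0.2,
        seed=11,
    )
    tables, truth = generate_dataset(design)
    mc = MCMCSettings(n_iter=1500, n_chains=2, seed=11)
    obs_fit = fit_level(tables, "OBS", mcmc=mc)
    pft_fit = fit_level(tables, "PFT", mcmc=mc, psi_fixed=obs_fit.psi_day_estimates,
                        c_lambda_fixed=obs_fit.C_lambda_value)
    glb_fit = fit_level(tables, "GLB", mcmc=mc, psi_fixed=obs_fit.psi_day_estimates,
                        c_lambda_fixed=obs_fit.C_lambda_value)
    return tables, truth, {"GLB": glb_fit, "PFT": pft_fit, "OBS": obs_fit}


@pytest.fixture
def driver_grid():
    """Moderate (psi, D, A_n) lattice spanning open and closed stomata."""
    psi = np.linspace(-4.0, -0.05, 10)
    D = np.linspace(0.0, 0.06, 10)
    A = np.linspace(-2.0, 20.0, 5)
    return psi, D, A
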