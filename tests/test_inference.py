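import math

import numpy as np
import pytest
from scipy import stats

from hydrostoma import (
    GROUP_PARAMS,
    MCMCSettings,
    PriorSpec,
    SyntheticDesign,
    deviance,
    fit_level,
    generate_dataset,
    log_likelihood,
)
from hydrostoma.inference import PARAM_NAMES, _split_rhat, reflected_rw_mcmc
from hydrostoma.units import ObservationTable
import pandas as pd


def _one_record_table(gs=0.3, an=6.5, ci=370.0, vpd=1.0, p=100.0):
    df = pd.DataFrame(
        [{"obs_id": "o1", "date": "2005-07-01", "hour": 12, "leaf": "A",
          "gs_mol": gs, "an_umol": an, "ci_umol": ci, "vpd_kpa": vpd,
          "p_kpa": p, "tleaf_c": 25.0}]
    )
    return ObservationTable(observation_id="o1", pft="SUBS", data=df)


class TestLogLikelihood:
    def test_perfect_fit_unit_peak(self):
        # sigma = 1/sqrt(2*pi) makes the Normal peak density exactly 1
        t = _one_record_table()
        params = {"o1": GROUP_PARAMS["SUBS"]}
        psi = {"o1": {"2005-07-01": -0.5}}
        from hydrostoma.model import predict_table

        pred = predict_table(params["o1"], t, psi["o1"])[0]
        t.data.loc[0, "gs_mol"] = pred
        ll = log_likelihood(params, psi, 1.0 / math.sqrt(2 * math.pi), [t])
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_zero_residual_closed_form(self):
        t = _one_record_table()
        params = {"o1": GROUP_PARAMS["SUBS"]}
        psi = {"o1": {"2005-07-01": -0.5}}
        from hydrostoma.model import predict_table

        t.data.loc[0, "gs_mol"] = predict_table(params["o1"], t, psi["o1"])[0]
        assert log_likelihood(params, psi, 0.1, [t]) == pytest.approx(
            math.log(1 / (0.1 * math.sqrt(2 * math.pi))), abs=1e-12
        )
        assert log_likelihood(params, psi, 0.1, [t]) == pytest.approx(1.3836, abs=1e-4)

    def test_duplication_doubles(self):
        t = _one_record_table()
        params = {"o1": GROUP_PARAMS["SUBS"]}
        psi = {"o1": {"2005-07-01": -0.5}}
        one = log_likelihood(params, psi, 0.2, [t])
        two = log_likelihood(params, psi, 0.2, [t, t])
        assert two == pytest.approx(2 * one)


class TestDeviance:
    @pytest.mark.parametrize("ll,expected", [(0.0, 0.0), (711.5, -1423.0), (-5.0, 10.0)])
    def test_minus_two_loglik(self, ll, expected):
        assert deviance(ll) == expected


class TestSamplerMachinery:
    def test_flat_target_marginals_uniform(self):
        # detailed-balance smoke test: under a flat likelihood the sampler
        # must return the (uniform) prior
        lower, upper = np.array([0.0, -2.0]), np.array([1.0, 3.0])
        # wide reflected proposals decorrelate quickly under a flat target
        draws = reflected_rw_mcmc(lambda x: 0.0, lower, upper, [0.5, 0.0],
                                  n_iter=10_000, seed=4, scales=0.5 * (upper - lower))
        for j in range(2):
            u = (draws[:, j] - lower[j]) / (upper[j] - lower[j])
            assert stats.kstest(u[::10], "uniform").pvalue > 0.01

    def test_split_rhat_agrees_with_arviz(self, recovery_experiment):
        az = pytest.importorskip("arviz")
        *_, fit = recovery_experiment
        for name in ["K_psi[SUBS-01]", "sigma", "C_lambda"]:
            mine = _split_rhat(fit.draws[name])
            ref = float(az.rhat(fit.draws[name], method="split"))
            assert mine == pytest.approx(ref, abs=0.05)


class TestFitLevel:
    def test_draws_respect_prior_bounds(self, recovery_experiment):
        *_, fit = recovery_experiment
        priors = PriorSpec()
        for name, arr in fit.draws.items():
            kind = name.split("[")[0] if "[" in name else name
            kind = {"psi": "psi_day"}.get(kind, kind)
            lo, hi = priors.bounds_of(kind)
            assert arr.min() >= lo - 1e-12 and arr.max() <= hi + 1e-12

    def test_free_parameter_counts(self, nested_fits):
        _, _, fits = nested_fits
        # 6 observations, 12 observation-days, shared tradeoff constant
        assert fits["GLB"].n_free_parameters == 5
        assert fits["PFT"].n_free_parameters == 15
        assert fits["OBS"].n_free_parameters == 6 * 5 + 12 + 1

    def test_deviance_at_mean_below_mean_deviance(self, nested_fits):
        """Jensen direction (positive effective parameter count pD) holds at
        the fixed-psi levels, whose posteriors are well conditioned."""
        _, _, fits = nested_fits
        for lvl in ("GLB", "PFT"):
            f = fits[lvl]
            assert f.deviance_at_mean <= float(f.deviance_trace.mean()) + 1e-6

    def test_observation_level_effective_parameters_negative(self, nested_fits):
        """At the observation level the posterior rides curved soft ridges,
        so the posterior-mean parameters sit off-ridge and pD is negative —
        the same pathology the published observation-level DIC exhibits."""
        _, _, fits = nested_fits
        f = fits["OBS"]
        assert float(f.deviance_trace.mean()) - f.deviance_at_mean < 0

    def test_residual_sd_recovered_with_known_psi(self):
        design = SyntheticDesign(
            groups=("SUBS",), n_observations_per_group=2, n_days_per_observation=2,
            n_leaves=3, noise_sd=0.05, psi_day_range=(-1.2, -0.1), seed=3,
        )
        tables, truth = generate_dataset(design)
        psi_true = {o: info["psi_day"] for o, info in truth["observations"].items()}
        fit = fit_level(tables, "GLB", mcmc=MCMCSettings(n_iter=1500, n_chains=2, seed=3),
                        psi_fixed=psi_true, c_lambda_fixed=truth["C_lambda"])
        assert fit.residual_sd == pytest.approx(design.noise_sd, rel=0.10)

    def test_identical_seeds_identical_chains(self):
        design = SyntheticDesign(groups=("SUBS",), n_observations_per_group=1,
                                 n_days_per_observation=1, n_leaves=1, noise_sd=0.05,
                                 psi_day_range=(-1.0, -0.2), seed=5)
        tables, _ = generate_dataset(design)
        mc = MCMCSettings(n_iter=200, n_chains=2, seed=9)
        f1 = fit_level(tables, "OBS", mcmc=mc)
        f2 = fit_level(tables, "OBS", mcmc=mc)
        for name in f1.draws:
            np.testing.assert_array_equal(f1.draws[name], f2.draws[name])

    def test_staged_levels_require_obs_artifacts(self):
        design = SyntheticDesign(groups=("SUBS",), n_observations_per_group=1,
                                 n_days_per_observation=1, n_leaves=1, seed=5)
        tables, _ = generate_dataset(design)
        with pytest.raises(ValueError, match="psi_fixed"):
            fit_level(tables, "GLB")

    def test_interval_coverage_across_replicates(self):
        """95 % credible intervals cover the truth for >= 80 % of parameters
        across replicate simulations (scaled-down)."""
        hits = total = 0
        for seed in range(20):
            design = SyntheticDesign(
                groups=("SUBS",), n_observations_per_group=1, n_days_per_observation=2,
                n_leaves=3, noise_sd=0.05, psi_day_range=(-1.2, -0.1),
                D_max_range=(0.02, 0.07), seed=100 + seed,
            )
            tables, truth = generate_dataset(design)
            fit = fit_level(tables, "OBS",
                            mcmc=MCMCSettings(n_iter=600, n_chains=2, seed=seed))
            info = truth["observations"]["SUBS-01"]
            for pn in PARAM_NAMES:
                d = fit.draws[f"{pn}[SUBS-01]"].ravel()
                lo, hi = np.quantile(d, [0.025, 0.975])
                hits += lo <= info["params"][pn] <= hi
                total += 1
        assert hits / total >= 0.80
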