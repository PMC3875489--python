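"""Hierarchical Bayesian fitting of the stomatal model.

The model is fitted at three nesting levels:

* ``GLB`` — all observations pooled, one parameter set;
* ``PFT`` — one parameter set per functional group (DCDS/LEGM/SUBS);
* ``OBS`` — one parameter set per observation (species x site).

Soil water potential is rarely measured alongside leaf gas exchange, so it
is treated as latent: one value per observation-day, assumed constant
within the day, estimated jointly with the parameters at the OBS level.
The cavitation tradeoff constant ``C_lambda`` is a single super-parameter
shared by every unit; it too is free only at the OBS level.  GLB and PFT
fits reuse the OBS-level posterior means of the daily potentials and of
``C_lambda`` (the two-pass staging).

The likelihood is i.i.d. Gaussian on measured stomatal conductance around
the model's steady-state prediction, with one residual SD ``sigma`` per
analysis level.  Priors are independent uniforms on physiologically
meaningful ranges; sampling is Metropolis-within-Gibbs with reflected
Gaussian random-walk proposals (reflection at the prior bounds keeps the
proposal symmetric, so plain Metropolis acceptance applies), with proposal
scales adapted during burn-in toward a 0.2-0.5 acceptance rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import SolverError
from .model import solve_gs
from .params import C_0_DEFAULT, StomatalParams

__all__ = [
    "PriorSpec",
    "MCMCSettings",
    "FitResult",
    "log_likelihood",
    "deviance",
    "fit_level",
    "reflected_rw_mcmc",
    "predict_at_posterior_mean",
]

PARAM_NAMES = ("K_psi", "g_p", "K_i", "pi_0", "xi")

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform prior bounds per parameter kind."""

    K_psi: tuple[float, float] = (0.01, 1.5)       # mol m-2 s-1 MPa-1
    g_p: tuple[float, float] = (0.0005, 0.08)      # mol m-2 s-1 MPa-1
    K_i: tuple[float, float] = (20.0, 400.0)       # umol m-2 s-1
    pi_0: tuple[float, float] = (0.5, 2.0)         # MPa
    xi: tuple[float, float] = (0.0, 250.0)
    C_lambda: tuple[float, float] = (0.1, 10.0)    # m2 s mol-1
    psi_day: tuple[float, float] = (-8.0, -0.01)   # MPa
    sigma: tuple[float, float] = (0.001, 1.0)      # mol m-2 s-1

    def __post_init__(self) -> None:
        for name in ("K_psi", "g_p", "K_i", "pi_0", "xi", "C_lambda", "psi_day", "sigma"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"prior bounds for {name} must satisfy lower < upper")

    def bounds_of(self, kind: str) -> tuple[float, float]:
        return getattr(self, kind)


@dataclass(frozen=True)
class MCMCSettings:
    n_iter: int = 5000
    n_chains: int = 2
    seed: int = 0
    adapt_interval: int = 25
    target_accept: float = 0.3
    n_ridge_moves: int = 3   # repetitions of the joint degeneracy moves per sweep


@dataclass
class FitResult:
    """Posterior summaries and draws for one analysis level."""

    level: str
    draws: dict[str, np.ndarray]            # name -> (n_chains, n_kept)
    deviance_trace: np.ndarray              # (n_chains, n_kept)
    posterior_mean: dict[str, float]
    posterior_sd: dict[str, float]
    psi_day_estimates: dict[str, dict[str, float]]   # obs -> day -> MPa
    C_lambda_value: float
    residual_sd: float
    n_free_parameters: int
    deviance_at_mean: float
    acceptance_rates: dict[str, float]
    rhat: dict[str, float]
    unit_of_obs: dict[str, str]
    seed: int

    def params_of_unit(self, unit: str, C_0: float = C_0_DEFAULT) -> StomatalParams:
        """Posterior-mean parameter set for one unit."""
        return StomatalParams(
            K_psi=self.posterior_mean[f"K_psi[{unit}]"],
            g_p=self.posterior_mean[f"g_p[{unit}]"],
            C_lambda=self.C_lambda_value,
            pi_0=self.posterior_mean[f"pi_0[{unit}]"],
            K_i=self.posterior_mean[f"K_i[{unit}]"],
            xi=self.posterior_mean[f"xi[{unit}]"],
            C_0=C_0,
        )

    @property
    def units(self) -> list[str]:
        return sorted(set(self.unit_of_obs.values()))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "level": self.level,
            "seed": self.seed,
            "posterior_mean": self.posterior_mean,
            "posterior_sd": self.posterior_sd,
            "psi_day_estimates": self.psi_day_estimates,
            "C_lambda_value": self.C_lambda_value,
            "residual_sd": self.residual_sd,
            "n_free_parameters": self.n_free_parameters,
            "mean_deviance": float(self.deviance_trace.mean()),
            "deviance_at_mean": self.deviance_at_mean,
            "acceptance_rates": self.acceptance_rates,
            "rhat": self.rhat,
            "unit_of_obs": self.unit_of_obs,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def draws_to_csv(self, path: str | Path) -> None:
        names = sorted(self.draws)
        flat = {n: self.draws[n].reshape(-1) for n in names}
        n_chains, n_kept = self.deviance_trace.shape
        flat["chain"] = np.repeat(np.arange(n_chains), n_kept)
        flat["deviance"] = self.deviance_trace.reshape(-1)
        pd.DataFrame(flat).to_csv(path, index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# likelihood

def _gaussian_loglik(n: int, sse: float, sigma: float) -> float:
    return -0.5 * n * (_LOG2PI + 2.0 * math.log(sigma)) - sse / (2.0 * sigma * sigma)


def _resolve_params(params_by_unit: dict, table) -> StomatalParams:
    if table.observation_id in params_by_unit:
        return params_by_unit[table.observation_id]
    if table.pft in params_by_unit:
        return params_by_unit[table.pft]
    if len(params_by_unit) == 1:
        return next(iter(params_by_unit.values()))
    raise KeyError(f"no parameter set for observation {table.observation_id!r}")


def log_likelihood(params_by_unit, psi_days, sigma: float, tables) -> float:
    """Gaussian log-likelihood of measured g_s given parameters and daily psi.

    ``params_by_unit`` maps unit labels (observation ids, group labels, or a
    single global entry) to StomatalParams; ``psi_days`` maps observation id
    -> day -> soil water potential (MPa).
    """
    total = 0.0
    for t in tables:
        p = _resolve_params(params_by_unit, t)
        df = t.data
        psi = df["date"].astype(str).map(psi_days[t.observation_id]).to_numpy(float)
        D = (df["vpd_kpa"] / df["p_kpa"]).to_numpy(float)
        pred = solve_gs(p, psi, D, df["an_umol"].to_numpy(float), df["ci_umol"].to_numpy(float))
        resid = df["gs_mol"].to_numpy(float) - pred
        total += _gaussian_loglik(len(df), float(resid @ resid), sigma)
    return total


def deviance(log_likelihood_value: float) -> float:
    """Deviance D = -2 log L (may be negative when densities exceed 1)."""
    return -2.0 * log_likelihood_value


# ---------------------------------------------------------------------------
# sampler machinery

def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a proposal back into [lo, hi] (symmetric proposal kernel)."""
    span = hi - lo
    y = (x - lo) % (2.0 * span)
    return lo + (span - abs(y - span))


def reflected_rw_mcmc(logpdf, lower, upper, x0, n_iter: int, seed: int, scales=None):
    """Generic Metropolis-within-Gibbs over a box: one reflected Gaussian
    random-walk update per coordinate per iteration.

    Returns draws of shape (n_iter, ndim).  Used directly by the structured
    fit below and available for sanity checks against known targets.
    """
    rng = np.random.default_rng(seed)
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    x = np.array(x0, float)
    ndim = x.size
    scales = np.asarray(scales if scales is not None else 0.1 * (upper - lower), float)
    lp = logpdf(x)
    out = np.empty((n_iter, ndim))
    for it in range(n_iter):
        for j in range(ndim):
            prop = x.copy()
            prop[j] = _reflect(x[j] + rng.normal(0.0, scales[j]), lower[j], upper[j])
            lp_prop = logpdf(prop)
            if lp_prop - lp > math.log(rng.uniform()):
                x, lp = prop, lp_prop
        out[it] = x
    return out


class _Adaptive:
    """Per-coordinate proposal scale with burn-in adaptation."""

    def __init__(self, scale: float, lo: float, hi: float, target: float):
        self.scale = scale
        self.min = 1e-6 * (hi - lo)
        self.max = 2.0 * (hi - lo)
        self.target = target
        self.tries = 0
        self.accepts = 0
        self.total_tries = 0
        self.total_accepts = 0

    def record(self, accepted: bool) -> None:
        self.tries += 1
        self.total_tries += 1
        if accepted:
            self.accepts += 1
            self.total_accepts += 1

    def adapt(self) -> None:
        if self.tries == 0:
            return
        rate = self.accepts / self.tries
        self.scale = float(np.clip(self.scale * math.exp(1.2 * (rate - self.target)),
                                   self.min, self.max))
        self.tries = 0
        self.accepts = 0

    @property
    def rate(self) -> float:
        return self.total_accepts / max(self.total_tries, 1)


class _ObsData:
    """Per-observation record arrays, sorted by day for sliced psi updates."""

    def __init__(self, table):
        df = table.data.sort_values(["date", "hour", "leaf"], kind="mergesort")
        self.obs_id = table.observation_id
        self.pft = table.pft
        self.gs = df["gs_mol"].to_numpy(float)
        self.an = df["an_umol"].to_numpy(float)
        self.ci = df["ci_umol"].to_numpy(float)
        self.D = (df["vpd_kpa"] / df["p_kpa"]).to_numpy(float)
        self.days = sorted(df["date"].astype(str).unique())
        codes = df["date"].astype(str).map({d: i for i, d in enumerate(self.days)}).to_numpy()
        self.day_slices = [np.flatnonzero(codes == i) for i in range(len(self.days))]
        self.n = len(df)


def _predict_obs(od: _ObsData, theta: np.ndarray, c_lambda: float, psi_per_record) -> np.ndarray:
    p = StomatalParams(
        K_psi=theta[0], g_p=theta[1], C_lambda=c_lambda,
        pi_0=theta[3], K_i=theta[2], xi=theta[4],
    )
    return solve_gs(p, psi_per_record, od.D, od.an, od.ci)


def _ls_fit_unit(
    obs_list,
    priors: PriorSpec,
    c_lambda: float,
    psi_by_obs: dict | None,
    x0: np.ndarray | None = None,
):
    """Bounded least-squares fit of one unit's 5 parameters (plus its
    observations' daily psi when ``psi_by_obs`` is None).

    Returns ``(x_opt, rss)`` with layout [K_psi, g_p, K_i, pi_0, xi,
    psi_day...] (psi in observation order, days sorted within each).
    """
    free_psi = psi_by_obs is None
    lo = [priors.bounds_of(pn)[0] for pn in PARAM_NAMES]
    hi = [priors.bounds_of(pn)[1] for pn in PARAM_NAMES]
    n_psi = sum(len(od.days) for od in obs_list) if free_psi else 0
    if free_psi:
        lo += [priors.psi_day[0]] * n_psi
        hi += [priors.psi_day[1]] * n_psi
    lo, hi = np.array(lo), np.array(hi)
    if x0 is None:
        x0 = 0.5 * (lo + hi)

    counts = [[len(s) for s in od.day_slices] for od in obs_list]

    def resid(x):
        out = []
        p = StomatalParams(K_psi=x[0], g_p=x[1], C_lambda=c_lambda,
                           pi_0=x[3], K_i=x[2], xi=x[4])
        k = 5
        for od, cnt in zip(obs_list, counts):
            if free_psi:
                psi_days = x[k : k + len(od.days)]
                k += len(od.days)
            else:
                psi_days = np.array([psi_by_obs[od.obs_id][d] for d in od.days])
            psi_rec = np.repeat(psi_days, cnt)
            out.append(od.gs - solve_gs(p, psi_rec, od.D, od.an, od.ci))
        return np.concatenate(out)

    sol = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                        method="trf", xtol=1e-10, max_nfev=400)
    return sol.x, float(sol.cost * 2.0)


def _map_start(obs, units, unit_of, obs_of_unit, priors, free_psi,
               psi_fixed, c_lambda_fixed):
    """Deterministic warm start: per-unit bounded least squares, with a
    coarse profile over the shared cavitation constant at the OBS level."""
    if free_psi:
        c_grid = np.geomspace(max(priors.C_lambda[0], 0.3),
                              min(priors.C_lambda[1], 8.0), 5)
    else:
        c_grid = np.array([c_lambda_fixed])
    best = None
    x_warm: dict[str, np.ndarray | None] = {u: None for u in units}
    for c_lam in c_grid:
        total_rss, xs = 0.0, {}
        for u in units:
            x, rss = _ls_fit_unit(obs_of_unit[u], priors, c_lam,
                                  None if free_psi else psi_fixed, x0=x_warm[u])
            xs[u] = x
            total_rss += rss
        if best is None or total_rss < best[0]:
            best = (total_rss, float(c_lam), xs)
        x_warm = xs
    total_rss, c_lam, xs = best
    theta = {u: xs[u][:5].copy() for u in units}
    psi = {}
    if free_psi:
        for u in units:
            k = 5
            for od in obs_of_unit[u]:
                psi[od.obs_id] = xs[u][k : k + len(od.days)].copy()
                k += len(od.days)
    n_total = sum(od.n for od in obs)
    sigma = float(np.clip(math.sqrt(total_rss / n_total), *_shrink(priors.sigma)))
    return theta, c_lam, psi, sigma


def _shrink(bounds, eps_frac=1e-3):
    lo, hi = bounds
    eps = eps_frac * (hi - lo)
    return lo + eps, hi - eps


def fit_level(
    tables,
    level: str,
    priors: PriorSpec | None = None,
    mcmc: MCMCSettings | None = None,
    psi_fixed: dict[str, dict[str, float]] | None = None,
    c_lambda_fixed: float | None = None,
    init: str = "map",
) -> FitResult:
    """Fit the stomatal model at one hierarchy level by Metropolis-within-Gibbs.

    ``level`` is ``"OBS"``, ``"PFT"`` or ``"GLB"``.  For OBS the daily soil
    water potentials and the shared ``C_lambda`` are free; for PFT/GLB both
    must be supplied (``psi_fixed``: obs -> day -> MPa, and
    ``c_lambda_fixed``), normally taken from a prior OBS fit.  Chains are run
    independently; the first half of each chain is discarded as burn-in,
    during which proposal scales adapt.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCSettings()
    if level not in ("OBS", "PFT", "GLB"):
        raise ValueError(f"unknown level {level!r}")
    free_psi = level == "OBS"
    if not free_psi and (psi_fixed is None or c_lambda_fixed is None):
        raise ValueError(f"{level} fit requires psi_fixed and c_lambda_fixed from an OBS fit")

    obs = [_ObsData(t) for t in tables]
    if level == "OBS":
        unit_of = {od.obs_id: od.obs_id for od in obs}
    elif level == "PFT":
        for od in obs:
            if od.pft not in ("DCDS", "LEGM", "SUBS"):
                raise ValueError(f"observation {od.obs_id} lacks a functional group label")
        unit_of = {od.obs_id: od.pft for od in obs}
    else:
        unit_of = {od.obs_id: "GLB" for od in obs}
    units = sorted(set(unit_of.values()))
    obs_of_unit = {u: [od for od in obs if unit_of[od.obs_id] == u] for u in units}
    n_total = sum(od.n for od in obs)
    n_days_total = sum(len(od.days) for od in obs)
    n_free = len(units) * 5 + (n_days_total + 1 if free_psi else 0)

    kept = mcmc.n_iter - mcmc.n_iter // 2
    names = [f"{pn}[{u}]" for u in units for pn in PARAM_NAMES]
    if free_psi:
        names.append("C_lambda")
        names += [f"psi[{od.obs_id}:{d}]" for od in obs for d in od.days]
    names.append("sigma")
    all_draws = {n: np.empty((mcmc.n_chains, kept)) for n in names}
    dev_trace = np.empty((mcmc.n_chains, kept))
    acc_rates: dict[str, float] = {}

    # Warm start shared by all chains: a bounded least-squares (MAP-style)
    # fit locates the high-likelihood region that short burn-ins cannot
    # reach from a random prior draw; chains are jittered around it.
    map_start = None
    if init == "map":
        map_start = _map_start(obs, units, unit_of, obs_of_unit, priors,
                               free_psi, psi_fixed, c_lambda_fixed)
    elif init != "prior":
        raise ValueError(f"unknown init {init!r}")

    for chain in range(mcmc.n_chains):
        rng = np.random.default_rng([mcmc.seed, chain])

        # -- initialization (retry on non-finite likelihood)
        for _attempt in range(100):
            if map_start is not None and _attempt == 0:
                theta0, c_lam0, psi0, sigma0 = map_start

                def jit(x, bounds, frac=0.05):
                    lo, hi = bounds
                    return np.clip(x + rng.normal(0, frac * (hi - lo), size=np.shape(x)),
                                   *_shrink(bounds))

                theta = {
                    u: np.array([
                        jit(theta0[u][j], priors.bounds_of(pn))
                        for j, pn in enumerate(PARAM_NAMES)
                    ])
                    for u in units
                }
                c_lam = (float(jit(c_lam0, priors.C_lambda, 0.02))
                         if free_psi else float(c_lambda_fixed))
                if free_psi:
                    psi = {oid: np.asarray(jit(v, priors.psi_day, 0.02))
                           for oid, v in psi0.items()}
                else:
                    psi = {
                        od.obs_id: np.array([psi_fixed[od.obs_id][d] for d in od.days])
                        for od in obs
                    }
                sigma = float(jit(sigma0, priors.sigma, 0.02))
            else:
                theta = {
                    u: np.array([rng.uniform(*priors.bounds_of(pn)) for pn in PARAM_NAMES])
                    for u in units
                }
                c_lam = rng.uniform(*priors.C_lambda) if free_psi else float(c_lambda_fixed)
                if free_psi:
                    psi = {od.obs_id: rng.uniform(*priors.psi_day, size=len(od.days))
                           for od in obs}
                else:
                    psi = {
                        od.obs_id: np.array([psi_fixed[od.obs_id][d] for d in od.days])
                        for od in obs
                    }
                sigma = rng.uniform(*priors.sigma)
            pred, sse = {}, {}
            for od in obs:
                psi_rec = np.repeat(psi[od.obs_id], [len(s) for s in od.day_slices])
                pred[od.obs_id] = _predict_obs(od, theta[unit_of[od.obs_id]], c_lam, psi_rec)
                r = od.gs - pred[od.obs_id]
                sse[od.obs_id] = float(r @ r)
            sse_total = sum(sse.values())
            ll = _gaussian_loglik(n_total, sse_total, sigma)
            if math.isfinite(ll):
                break
        else:
            raise SolverError("could not find a finite-likelihood starting point")

        # -- adaptive scales per scalar coordinate
        ad: dict = {}
        for u in units:
            for j, pn in enumerate(PARAM_NAMES):
                lo, hi = priors.bounds_of(pn)
                ad[("t", u, j)] = _Adaptive(0.1 * (hi - lo), lo, hi, mcmc.target_accept)
        if free_psi:
            lo, hi = priors.C_lambda
            ad[("c",)] = _Adaptive(0.1 * (hi - lo), lo, hi, mcmc.target_accept)
            lo, hi = priors.psi_day
            for od in obs:
                for d in range(len(od.days)):
                    ad[("p", od.obs_id, d)] = _Adaptive(0.05 * (hi - lo), lo, hi,
                                                        mcmc.target_accept)
            for od in obs:
                ad[("r1", od.obs_id)] = _Adaptive(0.1, -1.0, 1.0, mcmc.target_accept)
                ad[("r3", od.obs_id)] = _Adaptive(0.05, -0.5, 0.5, mcmc.target_accept)
            ad[("r2",)] = _Adaptive(0.3, *priors.C_lambda, mcmc.target_accept)
        lo, hi = priors.sigma
        ad[("s",)] = _Adaptive(0.1 * (hi - lo), lo, hi, mcmc.target_accept)

        burn = mcmc.n_iter // 2
        keep_i = 0
        for it in range(mcmc.n_iter):
            inv2s2 = 1.0 / (2.0 * sigma * sigma)

            # unit-level parameters
            for u in units:
                for j, pn in enumerate(PARAM_NAMES):
                    key = ("t", u, j)
                    lo, hi = priors.bounds_of(pn)
                    prop = theta[u].copy()
                    prop[j] = _reflect(theta[u][j] + rng.normal(0, ad[key].scale), lo, hi)
                    new_pred, new_sse, d_sse = {}, {}, 0.0
                    for od in obs_of_unit[u]:
                        psi_rec = np.repeat(psi[od.obs_id],
                                            [len(s) for s in od.day_slices])
                        pp = _predict_obs(od, prop, c_lam, psi_rec)
                        r = od.gs - pp
                        new_pred[od.obs_id] = pp
                        new_sse[od.obs_id] = float(r @ r)
                        d_sse += new_sse[od.obs_id] - sse[od.obs_id]
                    accept = -d_sse * inv2s2 > math.log(rng.uniform())
                    if accept:
                        theta[u] = prop
                        pred.update(new_pred)
                        sse.update(new_sse)
                        sse_total += d_sse
                    ad[key].record(accept)

            # shared cavitation constant (OBS level only)
            if free_psi:
                key = ("c",)
                lo, hi = priors.C_lambda
                c_prop = _reflect(c_lam + rng.normal(0, ad[key].scale), lo, hi)
                new_pred, new_sse, d_sse = {}, {}, 0.0
                for od in obs:
                    psi_rec = np.repeat(psi[od.obs_id], [len(s) for s in od.day_slices])
                    pp = _predict_obs(od, theta[unit_of[od.obs_id]], c_prop, psi_rec)
                    r = od.gs - pp
                    new_pred[od.obs_id] = pp
                    new_sse[od.obs_id] = float(r @ r)
                    d_sse += new_sse[od.obs_id] - sse[od.obs_id]
                accept = -d_sse * inv2s2 > math.log(rng.uniform())
                if accept:
                    c_lam = c_prop
                    pred, sse = {**pred, **new_pred}, {**sse, **new_sse}
                    sse_total += d_sse
                ad[key].record(accept)

                # latent daily soil water potentials
                lo, hi = priors.psi_day
                for od in obs:
                    th = theta[unit_of[od.obs_id]]
                    for d, idx in enumerate(od.day_slices):
                        key = ("p", od.obs_id, d)
                        psi_prop = _reflect(psi[od.obs_id][d] + rng.normal(0, ad[key].scale),
                                            lo, hi)
                        p_obj = StomatalParams(
                            K_psi=th[0], g_p=th[1], C_lambda=c_lam,
                            pi_0=th[3], K_i=th[2], xi=th[4],
                        )
                        pp = solve_gs(p_obj, psi_prop, od.D[idx], od.an[idx], od.ci[idx])
                        r = od.gs[idx] - pp
                        old_r = od.gs[idx] - pred[od.obs_id][idx]
                        d_sse = float(r @ r) - float(old_r @ old_r)
                        accept = -d_sse * inv2s2 > math.log(rng.uniform())
                        if accept:
                            psi[od.obs_id][d] = psi_prop
                            pred[od.obs_id][idx] = pp
                            sse[od.obs_id] += d_sse
                            sse_total += d_sse
                        ad[key].record(accept)

            # Joint "ridge" moves along the model's known soft degeneracies.
            # Per-coordinate updates mix poorly across these valleys: (i) a
            # uniform shift of an observation's daily psi compensated by its
            # baseline osmotic pressure, (ii) a joint rescaling of K_psi
            # against (pi_0, psi_day, g_p) that preserves the products the
            # wet-regime likelihood constrains, and (iii) the slope/intercept
            # trade between C_lambda and the g_p's in 1/K = 1/g_p +
            # C_lambda*|psi_x|.
            for _ridge_rep in range(mcmc.n_ridge_moves if free_psi else 0):
                for od in obs:
                    u = unit_of[od.obs_id]
                    th = theta[u]
                    cnt = [len(s) for s in od.day_slices]

                    # (i) translation: psi_d + delta, pi_0 - delta/mean-adjustment
                    key = ("r1", od.obs_id)
                    delta = rng.normal(0, ad[key].scale)
                    A = np.maximum(od.an, 0.0)
                    ci = np.where(np.isnan(od.ci), 370.0, od.ci)
                    m_bar = float(np.mean(1.0 + th[4] * A / (th[2] + A) * 370.0 / ci))
                    psi_prop = psi[od.obs_id] + delta
                    pi0_prop = th[3] - delta / m_bar
                    lo_p, hi_p = priors.psi_day
                    lo_0, hi_0 = priors.pi_0
                    if (np.all(psi_prop >= lo_p) and np.all(psi_prop <= hi_p)
                            and lo_0 <= pi0_prop <= hi_0):
                        prop = th.copy()
                        prop[3] = pi0_prop
                        pp = _predict_obs(od, prop, c_lam, np.repeat(psi_prop, cnt))
                        r = od.gs - pp
                        d_sse = float(r @ r) - sse[od.obs_id]
                        accept = -d_sse * inv2s2 > math.log(rng.uniform())
                        if accept:
                            theta[u] = prop
                            psi[od.obs_id] = psi_prop
                            pred[od.obs_id] = pp
                            sse[od.obs_id] += d_sse
                            sse_total += d_sse
                        ad[key].record(accept)
                        th = theta[u]
                    else:
                        ad[key].record(False)

                    # (ii) scale trade: K_psi*e^eps vs (pi_0, psi_d)*e^-eps, g_p*e^eps
                    key = ("r3", od.obs_id)
                    eps = rng.normal(0, ad[key].scale)
                    f = math.exp(eps)
                    prop = th.copy()
                    prop[0] *= f        # K_psi
                    prop[1] *= f        # g_p
                    prop[3] /= f        # pi_0
                    psi_prop = psi[od.obs_id] / f
                    n_d = len(od.days)
                    in_bounds = (
                        priors.K_psi[0] <= prop[0] <= priors.K_psi[1]
                        and priors.g_p[0] <= prop[1] <= priors.g_p[1]
                        and priors.pi_0[0] <= prop[3] <= priors.pi_0[1]
                        and np.all(psi_prop >= priors.psi_day[0])
                        and np.all(psi_prop <= priors.psi_day[1])
                    )
                    if in_bounds:
                        pp = _predict_obs(od, prop, c_lam, np.repeat(psi_prop, cnt))
                        r = od.gs - pp
                        d_sse = float(r @ r) - sse[od.obs_id]
                        # log-Jacobian of the multiplicative map: +eps (K_psi)
                        # +eps (g_p) -eps (pi_0) -n_d*eps (psi days)
                        log_j = eps * (2 - 1 - n_d)
                        accept = (-d_sse * inv2s2 + log_j) > math.log(rng.uniform())
                        if accept:
                            theta[u] = prop
                            psi[od.obs_id] = psi_prop
                            pred[od.obs_id] = pp
                            sse[od.obs_id] += d_sse
                            sse_total += d_sse
                        ad[key].record(accept)
                    else:
                        ad[key].record(False)

                # (iii) C_lambda vs g_p slope/intercept trade at reference tension
                key = ("r2",)
                delta = rng.normal(0, ad[key].scale)
                r_ref = 1.5  # MPa, typical operating xylem tension
                c_prop = c_lam + delta
                gp_prop = {}
                log_j = 0.0
                ok = priors.C_lambda[0] <= c_prop <= priors.C_lambda[1]
                if ok:
                    for u in units:
                        gp = theta[u][1]
                        denom = 1.0 - delta * r_ref * gp
                        if denom <= 0:
                            ok = False
                            break
                        gp_new = gp / denom
                        if not priors.g_p[0] <= gp_new <= priors.g_p[1]:
                            ok = False
                            break
                        gp_prop[u] = gp_new
                        log_j += 2.0 * math.log(gp_new / gp)
                if ok:
                    new_pred, new_sse, d_sse = {}, {}, 0.0
                    for od in obs:
                        prop = theta[unit_of[od.obs_id]].copy()
                        prop[1] = gp_prop[unit_of[od.obs_id]]
                        cnt = [len(s) for s in od.day_slices]
                        pp = _predict_obs(od, prop, c_prop, np.repeat(psi[od.obs_id], cnt))
                        r = od.gs - pp
                        new_pred[od.obs_id] = pp
                        new_sse[od.obs_id] = float(r @ r)
                        d_sse += new_sse[od.obs_id] - sse[od.obs_id]
                    accept = (-d_sse * inv2s2 + log_j) > math.log(rng.uniform())
                    if accept:
                        c_lam = c_prop
                        for u in units:
                            theta[u][1] = gp_prop[u]
                        pred.update(new_pred)
                        sse.update(new_sse)
                        sse_total += d_sse
                    ad[key].record(accept)
                else:
                    ad[key].record(False)

            # residual SD
            key = ("s",)
            lo, hi = priors.sigma
            s_prop = _reflect(sigma + rng.normal(0, ad[key].scale), lo, hi)
            d_ll = (_gaussian_loglik(n_total, sse_total, s_prop)
                    - _gaussian_loglik(n_total, sse_total, sigma))
            accept = d_ll > math.log(rng.uniform())
            if accept:
                sigma = s_prop
            ad[key].record(accept)

            if it < burn and (it + 1) % mcmc.adapt_interval == 0:
                for a in ad.values():
                    a.adapt()

            if it >= burn:
                for u in units:
                    for j, pn in enumerate(PARAM_NAMES):
                        all_draws[f"{pn}[{u}]"][chain, keep_i] = theta[u][j]
                if free_psi:
                    all_draws["C_lambda"][chain, keep_i] = c_lam
                    for od in obs:
                        for d, day in enumerate(od.days):
                            all_draws[f"psi[{od.obs_id}:{day}]"][chain, keep_i] = \
                                psi[od.obs_id][d]
                all_draws["sigma"][chain, keep_i] = sigma
                dev_trace[chain, keep_i] = deviance(
                    _gaussian_loglik(n_total, sse_total, sigma)
                )
                keep_i += 1

        for k, a in ad.items():
            acc_rates[str(k)] = a.rate

    # -- summaries
    post_mean = {n: float(all_draws[n].mean()) for n in names}
    post_sd = {n: float(all_draws[n].std(ddof=1)) for n in names}
    rhat = {n: _split_rhat(all_draws[n]) for n in names}

    if free_psi:
        psi_est = {
            od.obs_id: {d: post_mean[f"psi[{od.obs_id}:{d}]"] for d in od.days} for od in obs
        }
        c_lambda_value = post_mean["C_lambda"]
    else:
        psi_est = {od.obs_id: {d: psi_fixed[od.obs_id][d] for d in od.days} for od in obs}
        c_lambda_value = float(c_lambda_fixed)

    # deviance at the posterior-mean parameters (for DIC)
    mean_params = {}
    for u in units:
        mean_params[u] = StomatalParams(
            K_psi=post_mean[f"K_psi[{u}]"], g_p=post_mean[f"g_p[{u}]"],
            C_lambda=c_lambda_value, pi_0=post_mean[f"pi_0[{u}]"],
            K_i=post_mean[f"K_i[{u}]"], xi=post_mean[f"xi[{u}]"],
        )
    sse_mean = 0.0
    for od in obs:
        psi_rec = np.repeat(
            np.array([psi_est[od.obs_id][d] for d in od.days]),
            [len(s) for s in od.day_slices],
        )
        r = od.gs - solve_gs(mean_params[unit_of[od.obs_id]], psi_rec, od.D, od.an, od.ci)
        sse_mean += float(r @ r)
    dev_at_mean = deviance(_gaussian_loglik(n_total, sse_mean, post_mean["sigma"]))

    return FitResult(
        level=level,
        draws=all_draws,
        deviance_trace=dev_trace,
        posterior_mean=post_mean,
        posterior_sd=post_sd,
        psi_day_estimates=psi_est,
        C_lambda_value=c_lambda_value,
        residual_sd=post_mean["sigma"],
        n_free_parameters=n_free,
        deviance_at_mean=dev_at_mean,
        acceptance_rates=acc_rates,
        rhat=rhat,
        unit_of_obs=dict(unit_of),
        seed=mcmc.seed,
    )


def _split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman-Rubin)."""
    n_chains, n = draws.shape
    half = n // 2
    if half < 2:
        return float("nan")
    chains = np.vstack([draws[:, :half], draws[:, half : 2 * half]])
    m, k = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = k * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (k - 1) / k * w + b / k
    return float(math.sqrt(var_plus / w))


def predict_at_posterior_mean(fit: FitResult, tables):
    """(measured, predicted) g_s arrays over all records at the posterior mean."""
    meas, preds = [], []
    for t in tables:
        unit = fit.unit_of_obs[t.observation_id]
        p = fit.params_of_unit(unit)
        df = t.data
        psi = df["date"].astype(str).map(fit.psi_day_estimates[t.observation_id]).to_numpy(float)
        D = (df["vpd_kpa"] / df["p_kpa"]).to_numpy(float)
        preds.append(solve_gs(p, psi, D, df["an_umol"].to_numpy(float),
                              df["ci_umol"].to_numpy(float)))
        meas.append(df["gs_mol"].to_numpy(float))
    return np.concatenate(meas), np.concatenate(preds)
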