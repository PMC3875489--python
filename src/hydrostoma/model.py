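"""The forward stomatal model.

Steady-state stomatal conductance emerges from three coupled pieces:

1. **Osmotic adjustment.**  Guard-cell osmotic pressure rises with net
   photosynthesis ``A_n`` following a Michaelis-Menten term scaled by the
   intercellular CO2 ratio::

       pi = pi_0 * (1 + xi * A_n / (K_i + A_n) * C_0 / C_i),   A_n >= 0

   (the adjustment term is floored at zero for nocturnal/respiring leaves).

2. **Cavitation-limited hydraulics.**  Soil-to-leaf hydraulic conductance
   declines hyperbolically with xylem tension, with the loss rate
   proportional to the maximum conductance (the efficiency-safety
   tradeoff)::

       K(psi_x) = g_p / (1 + C_lambda * g_p * |psi_x|)

3. **Turgor-proportional conductance and mass balance.**  Stomatal
   conductance is proportional to guard-cell turgor, and leaf transpiration
   must equal soil-to-leaf water flow::

       g_s = K_psi * max(pi + psi_x, 0)
       g_s * D = K(psi_x) * (psi_soil - psi_x)

Substituting (1)-(2) into the mass balance gives a quadratic in the xylem
water potential ``psi_x``; the unique physically admissible root lies in
``[-pi, psi_soil]``.  Both the closed-form root and a bracketing bisection
(Brent) fallback are provided and agree to solver tolerance.  When the soil
is drier than the osmotic pressure can offset (``psi_soil <= -pi``) the
stomata are closed: ``g_s = 0`` and ``psi_x = psi_soil``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, SolverError
from .params import StomatalParams

__all__ = [
    "LeafEnvironment",
    "ModelState",
    "osmotic_pressure",
    "hydraulic_conductance",
    "solve_leaf",
    "solve_gs",
    "transpiration",
    "predict_table",
]


@dataclass(frozen=True)
class LeafEnvironment:
    """Boundary conditions for one leaf solution."""

    psi_soil: float          # MPa, <= 0
    D: float                 # scaled VPD, dimensionless, >= 0
    A_n: float               # umol CO2 m-2 s-1
    C_i: float | None = None  # umol mol-1; defaults to params.C_0

    def __post_init__(self) -> None:
        if self.psi_soil > 0:
            raise DomainError("soil water potential must be <= 0")
        if self.D < 0:
            raise DomainError("scaled VPD must be >= 0")


@dataclass(frozen=True)
class ModelState:
    """Solved steady state for one leaf."""

    psi_x: float   # xylem water potential, MPa
    pi: float      # guard-cell osmotic pressure, MPa
    turgor: float  # pi + psi_x, MPa
    K: float       # realized soil-to-leaf conductance, mol m-2 s-1 MPa-1
    g_s: float     # stomatal conductance, mol H2O m-2 s-1
    E: float       # transpiration, mol H2O m-2 s-1


def osmotic_pressure(params: StomatalParams, A_n, C_i=None):
    """Guard-cell osmotic pressure (MPa); accepts scalars or arrays."""
    A_n = np.asarray(A_n, dtype=float)
    if np.any(params.K_i + A_n <= 0):
        raise DomainError("K_i + A_n must be positive")
    C_i = np.asarray(params.C_0 if C_i is None else C_i, dtype=float)
    C_i = np.where(np.isnan(C_i), params.C_0, C_i)
    A = np.maximum(A_n, 0.0)
    pi = params.pi_0 * (1.0 + params.xi * A / (params.K_i + A) * params.C_0 / C_i)
    return pi if pi.ndim else float(pi)


def hydraulic_conductance(params: StomatalParams, psi_x):
    """Soil-to-leaf hydraulic conductance at xylem potential psi_x (<= 0)."""
    psi_x = np.asarray(psi_x, dtype=float)
    if np.any(psi_x > 0):
        raise DomainError("xylem water potential must be <= 0")
    K = params.g_p / (1.0 + params.C_lambda * params.g_p * np.abs(psi_x))
    return K if K.ndim else float(K)


def _mass_balance_residual(psi_x, params, psi_soil, D, pi):
    gs = params.K_psi * max(pi + psi_x, 0.0)
    K = params.g_p / (1.0 + params.C_lambda * params.g_p * abs(psi_x))
    return gs * D - K * (psi_soil - psi_x)


def _solve_psix_closed(params: StomatalParams, psi_soil: float, D: float, pi: float) -> float:
    """Closed-form root of the mass-balance quadratic, selected in [-pi, psi_soil]."""
    kd = params.K_psi * D
    lam = params.C_lambda * params.g_p
    a = -kd * lam
    b = kd * (1.0 - lam * pi) + params.g_p
    c = kd * pi - params.g_p * psi_soil
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise SolverError(
            f"negative discriminant (psi={psi_soil}, D={D}, pi={pi}, params={params})"
        )
    sq = np.sqrt(disc)
    # Citardauq-stable pair: q/a and c/q avoid cancellation when |a| is tiny
    # (weak cavitation), where (-b + sq)/(2a) loses all precision.
    q = -0.5 * (b + np.copysign(sq, b))
    roots = [q / a, c / q] if q != 0 else [-b / (2.0 * a)]
    tol = 1e-9 * max(1.0, pi, abs(psi_soil))
    inside = [r for r in roots if -pi - tol <= r <= psi_soil + tol]
    if not inside:
        raise SolverError(
            f"no quadratic root in [-pi, psi_soil] (psi={psi_soil}, D={D}, pi={pi})"
        )
    if len(inside) == 2 and abs(inside[0] - inside[1]) > tol:
        warnings.warn("both quadratic roots admissible; taking the larger-turgor root")
        return max(inside)
    return float(np.clip(inside[0], -pi, psi_soil))


def _solve_psix_bisect(
    params: StomatalParams, psi_soil: float, D: float, pi: float, xtol: float = 1e-12
) -> float:
    """Bracketing (Brent) root of the mass balance on [-pi, psi_soil]."""
    lo, hi = -pi, psi_soil
    f_lo = _mass_balance_residual(lo, params, psi_soil, D, pi)
    f_hi = _mass_balance_residual(hi, params, psi_soil, D, pi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise SolverError(
            f"mass balance not bracketed on [-pi, psi_soil] (psi={psi_soil}, D={D}, pi={pi})"
        )
    return float(brentq(_mass_balance_residual, lo, hi, args=(params, psi_soil, D, pi), xtol=xtol))


def solve_leaf(
    params: StomatalParams, env: LeafEnvironment, method: str = "closed", xtol: float = 1e-12
) -> ModelState:
    """Solve the coupled turgor / mass-balance system for one leaf.

    ``method`` is ``"closed"`` (quadratic root) or ``"bisect"`` (Brent
    bracketing on ``[-pi, psi_soil]``); both give the same state to solver
    tolerance.
    """
    pi = osmotic_pressure(params, env.A_n, env.C_i)
    psi = env.psi_soil

    if psi <= -pi:
        # soil drier than osmotic offset: stomata closed, no flow, no gradient
        return ModelState(
            psi_x=psi, pi=pi, turgor=max(pi + psi, 0.0),
            K=hydraulic_conductance(params, psi), g_s=0.0, E=0.0,
        )
    if env.D == 0.0:
        gs = params.K_psi * max(pi + psi, 0.0)
        return ModelState(
            psi_x=psi, pi=pi, turgor=pi + psi,
            K=hydraulic_conductance(params, psi), g_s=gs, E=0.0,
        )

    if method == "closed":
        psi_x = _solve_psix_closed(params, psi, env.D, pi)
    elif method == "bisect":
        psi_x = _solve_psix_bisect(params, psi, env.D, pi, xtol=xtol)
    else:
        raise ValueError(f"unknown method {method!r}")

    gs = params.K_psi * max(pi + psi_x, 0.0)
    K = hydraulic_conductance(params, psi_x)
    return ModelState(psi_x=psi_x, pi=pi, turgor=pi + psi_x, K=K, g_s=gs, E=gs * env.D)


def solve_gs(params: StomatalParams, psi_soil, D, A_n, C_i=None):
    """Vectorized stomatal conductance over aligned arrays of drivers.

    Broadcasts ``psi_soil``, ``D``, ``A_n`` (and optional ``C_i``) and returns
    an array of g_s (mol m-2 s-1).  Same closed-form solution as
    :func:`solve_leaf`, evaluated without Python-level loops.
    """
    psi, D, A_n = np.broadcast_arrays(
        np.asarray(psi_soil, float), np.asarray(D, float), np.asarray(A_n, float)
    )
    if np.any(psi > 0):
        raise DomainError("soil water potential must be <= 0")
    if np.any(D < 0):
        raise DomainError("scaled VPD must be >= 0")
    if C_i is None:
        C_i = np.full_like(psi, params.C_0)
    else:
        C_i = np.broadcast_to(np.asarray(C_i, float), psi.shape).copy()
        C_i[np.isnan(C_i)] = params.C_0
    pi = params.pi_0 * (
        1.0 + params.xi * np.maximum(A_n, 0.0) / (params.K_i + np.maximum(A_n, 0.0))
        * params.C_0 / C_i
    )

    kd = params.K_psi * D
    lam = params.C_lambda * params.g_p
    a = -kd * lam
    b = kd * (1.0 - lam * pi) + params.g_p
    c = kd * pi - params.g_p * psi
    open_mask = psi > -pi
    quad = open_mask & (D > 0)

    psi_x = np.where(open_mask, psi, psi)  # default: psi (closed or D=0 cases)
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = b * b - 4.0 * a * c
        sq = np.sqrt(np.maximum(disc, 0.0))
        # stable root pair (q/a, c/q); the admissible root is the smaller one
        q = -0.5 * (b + np.copysign(sq, b))
        safe_a = np.where(quad, a, 1.0)
        safe_q = np.where(q != 0, q, 1.0)
        root = np.minimum(q / safe_a, c / safe_q)
    psi_x = np.where(quad, np.clip(root, -pi, psi), psi_x)

    gs = np.where(open_mask, params.K_psi * np.maximum(pi + psi_x, 0.0), 0.0)
    return gs


def transpiration(state_or_gs, D: float | None = None):
    """Transpiration E = g_s * D (mol H2O m-2 s-1)."""
    if isinstance(state_or_gs, ModelState):
        if D is None:
            raise ValueError("D required when passing a ModelState")
        return state_or_gs.g_s * D
    return np.asarray(state_or_gs) * np.asarray(D)


def predict_table(params: StomatalParams, table, psi_by_day: dict) -> np.ndarray:
    """Predicted g_s for every record of an ObservationTable.

    ``psi_by_day`` maps each calendar day (as str) to its soil water
    potential (MPa).  Returns an array aligned with ``table.data`` rows.
    """
    df = table.data
    psi = df["date"].astype(str).map(psi_by_day).to_numpy(dtype=float)
    if np.any(np.isnan(psi)):
        missing = sorted(set(df["date"].astype(str)) - set(psi_by_day))
        raise KeyError(f"missing soil water potential for days {missing}")
    D = (df["vpd_kpa"] / df["p_kpa"]).to_numpy(dtype=float)
    return solve_gs(params, psi, D, df["an_umol"].to_numpy(dtype=float),
                    df["ci_umol"].to_numpy(dtype=float))
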