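"""Forward-model behavioral analysis.

Response surfaces of stomatal conductance over soil water potential and
scaled vapor pressure deficit, stomatal closure points, ensemble (across
observations) response curves, and xylem vulnerability summaries.  All
outputs are numeric (grids as arrays/CSV); plotting is left to the caller.

The "favorable corner" convention used for benchmark numbers is soil water
potential of -0.033 MPa (approximately field capacity) and scaled VPD of
0.0035 (about 91 % relative humidity at 30 degC at sea level), with net
assimilation fixed at 6.5 umol m-2 s-1 (the cross-group mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import LeafEnvironment, hydraulic_conductance, osmotic_pressure, solve_gs, solve_leaf
from .params import StomatalParams

__all__ = [
    "PSI_FAVORABLE",
    "D_FAVORABLE",
    "D_HIGH_DEMAND",
    "AN_REFERENCE",
    "BehaviorGrid",
    "response_surface",
    "closure_potential",
    "ensemble_curves",
    "vulnerability_curve",
    "behavior_benchmarks",
]

PSI_FAVORABLE = -0.033   # MPa, approximately field capacity
D_FAVORABLE = 0.0035     # scaled VPD under near-saturated air
D_HIGH_DEMAND = 0.05     # scaled VPD under strong evaporative demand
AN_REFERENCE = 6.5       # umol CO2 m-2 s-1, reference net assimilation


@dataclass
class BehaviorGrid:
    """g_s evaluated over a (psi_soil x D) lattice at fixed assimilation."""

    psi_axis: np.ndarray      # MPa, values <= -0.001
    D_axis: np.ndarray
    A_n_fixed: float
    g_s_matrix: np.ndarray    # shape (len(psi_axis), len(D_axis))
    params_label: str = ""

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.g_s_matrix, index=self.psi_axis, columns=self.D_axis).to_csv(
            path, index_label="psi_MPa", float_format="%.8g"
        )


def response_surface(
    params: StomatalParams, psi_axis, D_axis, A_n: float = AN_REFERENCE, label: str = ""
) -> BehaviorGrid:
    """Stomatal conductance over a grid of soil water potential and scaled VPD."""
    psi_axis = np.asarray(psi_axis, float)
    D_axis = np.asarray(D_axis, float)
    if psi_axis.size == 0 or D_axis.size == 0:
        raise ValueError("axes must be non-empty")
    if np.any(psi_axis > -0.001):
        raise ValueError("psi axis values must be <= -0.001 MPa")
    gs = solve_gs(params, psi_axis[:, None], D_axis[None, :], A_n)
    return BehaviorGrid(psi_axis=psi_axis, D_axis=D_axis, A_n_fixed=A_n,
                        g_s_matrix=gs, params_label=label)


def closure_potential(
    params: StomatalParams, A_n: float = AN_REFERENCE, method: str = "analytic"
) -> float:
    """Soil water potential (MPa) at which stomata close, independent of D.

    Conductance vanishes exactly when the soil can no longer sustain
    positive turgor, i.e. at psi_soil = -pi(A_n).  ``method="bisect"``
    recovers the same point numerically from the forward response at small
    D, as a cross-check.
    """
    pi = osmotic_pressure(params, A_n)
    if method == "analytic":
        return -float(pi)
    if method == "bisect":
        f = lambda psi: solve_leaf(params, LeafEnvironment(psi, 1e-4, A_n)).g_s - 1e-12
        return float(brentq(f, -pi - 1.0, -1e-6, xtol=1e-10))
    raise ValueError(f"unknown method {method!r}")


def ensemble_curves(
    param_sets,
    axis,
    sweep: str = "psi",
    fixed: float | None = None,
    A_n: float = AN_REFERENCE,
) -> pd.DataFrame:
    """Mean +/- SD stomatal conductance across parameter sets along a sweep.

    ``sweep="psi"`` sweeps soil water potential with D fixed (default 0.03);
    ``sweep="D"`` sweeps scaled VPD with psi fixed (default -1.0 MPa).
    Returns a DataFrame with columns ``axis``, ``mean``, ``sd``.
    """
    param_sets = list(param_sets)
    if len(param_sets) < 2:
        raise ValueError("need at least 2 parameter sets for an ensemble")
    axis = np.asarray(axis, float)
    if sweep == "psi":
        D = 0.03 if fixed is None else fixed
        curves = np.stack([solve_gs(p, axis, D, A_n) for p in param_sets])
    elif sweep == "D":
        psi = -1.0 if fixed is None else fixed
        curves = np.stack([solve_gs(p, psi, axis, A_n) for p in param_sets])
    else:
        raise ValueError(f"unknown sweep {sweep!r}")
    return pd.DataFrame(
        {"axis": axis, "mean": curves.mean(axis=0), "sd": curves.std(axis=0, ddof=1)}
    )


def vulnerability_curve(param_sets, psi_x_axis):
    """Mean soil-to-leaf conductance vs xylem potential, and its half-loss point.

    Returns ``(curve, half_loss)`` where ``curve`` is a DataFrame with the
    pointwise mean and SD of K(psi_x) across parameter sets, and
    ``half_loss`` is the xylem potential (MPa) at which the *mean* curve
    falls to half its value at psi_x = 0, found by bracketing bisection.
    """
    param_sets = list(param_sets)
    if not param_sets:
        raise ValueError("need at least one parameter set")
    psi_x_axis = np.asarray(psi_x_axis, float)
    curves = np.stack([hydraulic_conductance(p, psi_x_axis) for p in param_sets])
    curve = pd.DataFrame(
        {
            "psi_x": psi_x_axis,
            "mean": curves.mean(axis=0),
            "sd": curves.std(axis=0, ddof=1) if len(param_sets) > 1 else np.zeros_like(psi_x_axis),
        }
    )

    mean_k = lambda psi: float(np.mean([hydraulic_conductance(p, psi) for p in param_sets]))
    k0 = mean_k(0.0)
    target = lambda psi: mean_k(psi) - 0.5 * k0
    lo = -1.0
    while target(lo) > 0:
        lo *= 2.0
        if lo < -1e6:
            raise RuntimeError("half-loss point beyond -1e6 MPa")
    half_loss = float(brentq(target, lo, 0.0, xtol=1e-10))
    return curve, half_loss


def behavior_benchmarks(
    group_params: dict[str, StomatalParams], A_n: float = AN_REFERENCE
) -> dict[str, float]:
    """The eight benchmark numbers of the forward model.

    Favorable-corner conductance for SUBS/LEGM/DCDS/GLB, the SUBS
    conductance under high evaporative demand, and the closure soil water
    potentials of the three functional groups.
    """
    corner = {
        g: solve_leaf(group_params[g], LeafEnvironment(PSI_FAVORABLE, D_FAVORABLE, A_n)).g_s
        for g in ("SUBS", "LEGM", "DCDS", "GLB")
    }
    return {
        "gs_favorable_SUBS": corner["SUBS"],
        "gs_favorable_LEGM": corner["LEGM"],
        "gs_favorable_DCDS": corner["DCDS"],
        "gs_favorable_GLB": corner["GLB"],
        "gs_high_demand_SUBS": solve_leaf(
            group_params["SUBS"], LeafEnvironment(PSI_FAVORABLE, D_HIGH_DEMAND, A_n)
        ).g_s,
        "closure_psi_SUBS": closure_potential(group_params["SUBS"], A_n),
        "closure_psi_DCDS": closure_potential(group_params["DCDS"], A_n),
        "closure_psi_LEGM": closure_potential(group_params["LEGM"], A_n),
    }
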