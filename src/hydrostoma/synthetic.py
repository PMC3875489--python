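"""Synthetic diurnal gas-exchange data with the structure the fit assumes.

The generator emulates a field campaign: for each observation (a species at
a site) a handful of diurnal courses are measured on separate days.  Within
a day the evaporative demand and photosynthesis follow a sine of solar
time, soil water potential is constant (one latent value per day), and the
measured stomatal conductance is the model's steady state plus i.i.d.
Gaussian instrument noise truncated at zero.

Defaults mirror the shrub study design this package targets: three
functional groups (DCDS, LEGM, SUBS) with published group parameters as
the truth, measurement hours 07:00-18:00, three leaves per hour, and daily
soil water potentials drawn uniformly from [-3, -0.1] MPa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import GROUP_PARAMS, C_0_DEFAULT, StomatalParams
from .model import solve_gs
from .units import CANONICAL_COLUMNS, ObservationTable, write_harmonized_csv

__all__ = ["SyntheticDesign", "diurnal_drivers", "generate_dataset", "write_dataset"]

_GROUP_ORDER = ["DCDS", "LEGM", "SUBS"]


@dataclass
class SyntheticDesign:
    """Design of one synthetic campaign."""

    n_observations_per_group: int = 2
    n_days_per_observation: int = 2
    hours: tuple[int, ...] = tuple(range(7, 19))
    n_leaves: int = 3
    groups: tuple[str, ...] = tuple(_GROUP_ORDER)
    true_params: dict[str, StomatalParams] = field(
        default_factory=lambda: dict(GROUP_PARAMS)
    )  # per group; per-observation jitter optional below
    psi_day_range: tuple[float, float] = (-3.0, -0.1)
    noise_sd: float = 0.1      # mol m-2 s-1
    # day-to-day weather: each day draws its own midday peaks uniformly
    D_max_range: tuple[float, float] = (0.015, 0.06)   # midday scaled VPD
    A_max_range: tuple[float, float] = (6.0, 16.0)     # midday A_n, umol m-2 s-1
    P_kpa: float = 88.0        # site air pressure (~1100 m elevation)
    param_jitter_cv: float = 0.0  # lognormal CV for per-observation spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.psi_day_range
        if not (-8.0 <= lo < hi <= -0.01):
            raise ValueError("psi_day_range must lie within [-8, -0.01]")


def diurnal_drivers(hours, D_max: float, A_max: float, C_0: float = C_0_DEFAULT):
    """Per-hour (D, A_n, C_i) following a sine of solar time.

    D(h) = D_max*sin(pi*(h-6)/12) clipped at 0.001; A_n likewise clipped at
    0; C_i dips below ambient in proportion to assimilation,
    C_i(h) = C_0*(1 - 0.25*A_n/A_max).
    """
    h = np.asarray(hours, dtype=float)
    s = np.sin(np.pi * (h - 6.0) / 12.0)
    D = np.maximum(D_max * s, 0.001)
    A_n = np.maximum(A_max * s, 0.0)
    C_i = C_0 * (1.0 - 0.25 * A_n / A_max)
    return D, A_n, C_i


def _jittered(params: StomatalParams, cv: float, rng: np.random.Generator) -> StomatalParams:
    if cv <= 0:
        return params
    sd = np.sqrt(np.log1p(cv * cv))
    draw = lambda x: float(x * rng.lognormal(-0.5 * sd * sd, sd))  # mean-preserving
    return StomatalParams(
        K_psi=float(np.clip(draw(params.K_psi), 0.01, 1.5)),
        g_p=draw(params.g_p),
        C_lambda=params.C_lambda,   # shared tradeoff constant, never jittered
        pi_0=float(np.clip(draw(params.pi_0), 0.05, 3.0)),
        K_i=draw(params.K_i),
        xi=draw(params.xi),
        C_0=params.C_0,
    )


def generate_dataset(design: SyntheticDesign):
    """Draw one synthetic campaign.

    Returns ``(tables, truth)`` where ``tables`` is a list of
    ObservationTable and ``truth`` records every true parameter and every
    latent daily soil water potential, for recovery tests.  Reproducible
    under ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    lo, hi = design.psi_day_range
    tables: list[ObservationTable] = []
    truth: dict = {
        "seed": design.seed,
        "noise_sd": design.noise_sd,
        "C_lambda": None,
        "observations": {},
    }

    for group in design.groups:
        base = design.true_params[group]
        truth["C_lambda"] = base.C_lambda
        for k in range(design.n_observations_per_group):
            obs_id = f"{group}-{k + 1:02d}"
            p = _jittered(base, design.param_jitter_cv, rng)
            psi_days = rng.uniform(lo, hi, size=design.n_days_per_observation)
            rows = []
            for d, psi_d in enumerate(psi_days):
                date = f"2005-07-{d + 1:02d}"
                D_h, A_h, Ci_h = diurnal_drivers(
                    design.hours,
                    rng.uniform(*design.D_max_range),
                    rng.uniform(*design.A_max_range),
                )
                for h_idx, hour in enumerate(design.hours):
                    gs_true = float(
                        solve_gs(p, psi_d, D_h[h_idx], A_h[h_idx], Ci_h[h_idx])
                    )
                    for leaf in range(design.n_leaves):
                        gs_obs = max(0.0, gs_true + rng.normal(0.0, design.noise_sd))
                        rows.append(
                            {
                                "obs_id": obs_id,
                                "date": date,
                                "hour": int(hour),
                                "leaf": f"L{leaf + 1}",
                                "gs_mol": gs_obs,
                                "an_umol": float(A_h[h_idx]),
                                "ci_umol": float(Ci_h[h_idx]),
                                "vpd_kpa": float(D_h[h_idx] * design.P_kpa),
                                "p_kpa": design.P_kpa,
                                "tleaf_c": 25.0,
                            }
                        )
            df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
            tables.append(
                ObservationTable(observation_id=obs_id, species=f"synthetic {group}", pft=group, data=df)
            )
            truth["observations"][obs_id] = {
                "pft": group,
                "params": {
                    "K_psi": p.K_psi, "g_p": p.g_p, "C_lambda": p.C_lambda,
                    "pi_0": p.pi_0, "K_i": p.K_i, "xi": p.xi, "C_0": p.C_0,
                },
                "psi_day": {
                    f"2005-07-{d + 1:02d}": float(psi) for d, psi in enumerate(psi_days)
                },
            }
    return tables, truth


def write_dataset(tables, truth, outdir: str | Path) -> Path:
    """Write CSVs + YAML manifest + truth JSON; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for t in tables:
        fname = f"{t.observation_id}.csv"
        write_harmonized_csv(t, outdir / fname)
        entries.append(
            {"observation_id": t.observation_id, "species": t.species, "pft": t.pft, "file": fname}
        )
    manifest = outdir / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"observations": entries}, sort_keys=False))
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return manifest
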