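"""Model parameter containers and published parameter fixtures.

The six free parameters of the stomatal model, for one analysis unit
(a single observation, a plant functional group, or the pooled global fit):

==========  =============================  ===========================
name        meaning                        units
==========  =============================  ===========================
K_psi       apparent guard-cell            mol H2O m-2 s-1 MPa-1
            compliance (gs per unit
            turgor pressure)
g_p         maximum soil-to-leaf           mol H2O m-2 s-1 MPa-1
            hydraulic conductance
C_lambda    cavitation tradeoff constant   m2 s mol-1
            (lambda = C_lambda * g_p)
pi_0        baseline guard-cell osmotic    MPa
            pressure
K_i         half-saturation of the         umol CO2 m-2 s-1
            photosynthesis-driven
            osmotic adjustment
xi          osmotic-adjustment gain        dimensionless
==========  =============================  ===========================

plus the fixed reference CO2 mole fraction ``C_0`` (umol mol-1).

All conductances are stored in mol m-2 s-1 (MPa-1); published tables often
print g_p in mmol m-2 s-1 MPa-1 and are converted on construction of the
fixtures below.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "StomatalParams",
    "GROUP_PARAMS",
    "C_LAMBDA_DEFAULT",
    "C_0_DEFAULT",
    "observation_params_table",
    "observation_params",
]

C_0_DEFAULT = 370.0
"""Reference CO2 mole fraction (umol mol-1), a period-typical ambient value."""

C_LAMBDA_DEFAULT = 3.13
"""Published posterior mean of the cavitation tradeoff constant (m2 s mol-1),
shared across species and analysis levels."""


@dataclass(frozen=True)
class StomatalParams:
    """Parameter set for one analysis unit. Conductances in mol m-2 s-1 (MPa-1)."""

    K_psi: float
    g_p: float
    C_lambda: float
    pi_0: float
    K_i: float
    xi: float
    C_0: float = C_0_DEFAULT

    def __post_init__(self) -> None:
        if not 0.01 <= self.K_psi <= 1.5:
            raise ValueError(f"K_psi={self.K_psi} outside [0.01, 1.5]")
        if self.g_p <= 0:
            raise ValueError("g_p must be positive")
        if self.C_lambda <= 0:
            raise ValueError("C_lambda must be positive")
        if not 0 < self.pi_0 <= 3:
            raise ValueError(f"pi_0={self.pi_0} outside (0, 3]")
        if self.K_i <= 0:
            raise ValueError("K_i must be positive")
        if self.xi < 0:
            raise ValueError("xi must be non-negative")
        if self.C_0 <= 0:
            raise ValueError("C_0 must be positive")

    @property
    def lam(self) -> float:
        """Effective cavitation slope lambda = C_lambda * g_p (MPa-1)."""
        return self.C_lambda * self.g_p

    def with_(self, **kwargs) -> "StomatalParams":
        return replace(self, **kwargs)


def _group(K_psi: float, g_p_mmol: float, K_i: float, pi_0: float, xi: float) -> StomatalParams:
    return StomatalParams(
        K_psi=K_psi,
        g_p=g_p_mmol * 1e-3,
        C_lambda=C_LAMBDA_DEFAULT,
        pi_0=pi_0,
        K_i=K_i,
        xi=xi,
    )


# Published posterior means at the global (GLB) and functional-group levels.
# Functional groups: DCDS = deciduous non-legume shrubs, LEGM = deciduous
# legume shrubs, SUBS = Artemisia subshrubs.  g_p given in mmol m-2 s-1 MPa-1.
GROUP_PARAMS: dict[str, StomatalParams] = {
    "GLB": _group(0.38, 3.60, 202.6, 1.76, 25.5),
    "DCDS": _group(0.16, 2.57, 198.8, 1.91, 23.8),
    "LEGM": _group(0.70, 2.05, 284.0, 1.94, 34.1),
    "SUBS": _group(1.42, 5.66, 319.8, 1.87, 9.9),
}

# Published per-observation posterior means (43 species-by-site observations).
# Columns: observation index, functional group, K_psi (mol m-2 s-1 MPa-1),
# g_p (mmol m-2 s-1 MPa-1), K_i (umol m-2 s-1), pi_0 (MPa), xi (-).
_OBS_ROWS = [
    (1, "DCDS", 0.088, 33.11, 295.4, 0.95, 149.6),
    (2, "DCDS", 0.552, 28.10, 326.8, 1.30, 9.8),
    (3, "DCDS", 0.380, 20.08, 324.1, 1.02, 99.0),
    (4, "LEGM", 0.454, 18.14, 330.1, 1.02, 79.8),
    (5, "DCDS", 0.297, 26.79, 329.7, 1.02, 69.1),
    (6, "LEGM", 0.591, 10.95, 330.1, 1.54, 2.9),
    (7, "LEGM", 0.639, 17.16, 333.9, 1.04, 12.0),
    (8, "LEGM", 0.734, 10.57, 329.9, 1.20, 11.9),
    (9, "SUBS", 0.228, 25.90, 345.8, 1.41, 26.0),
    (10, "SUBS", 0.508, 22.16, 338.7, 1.09, 27.4),
    (11, "SUBS", 1.084, 11.64, 345.1, 1.51, 2.9),
    (12, "LEGM", 0.927, 1.94, 362.5, 1.39, 88.7),
    (13, "SUBS", 1.461, 5.06, 369.7, 1.95, 15.7),
    (14, "DCDS", 1.034, 2.77, 302.1, 1.39, 45.8),
    (15, "SUBS", 0.986, 1.47, 227.2, 1.16, 135.1),
    (16, "LEGM", 0.576, 9.83, 41.4, 0.94, 5.6),
    (17, "LEGM", 1.034, 1.66, 67.7, 1.26, 38.3),
    (18, "DCDS", 0.460, 19.17, 308.3, 1.12, 36.5),
    (19, "LEGM", 1.307, 3.90, 219.8, 1.74, 34.2),
    (20, "DCDS", 0.526, 6.42, 45.3, 1.04, 49.3),
    (21, "SUBS", 0.282, 30.17, 316.3, 1.54, 8.8),
    (22, "DCDS", 0.263, 20.60, 304.4, 1.06, 191.7),
    (23, "LEGM", 1.407, 2.82, 26.5, 1.35, 3.6),
    (24, "SUBS", 1.482, 8.28, 331.1, 1.98, 1.7),
    (25, "DCDS", 0.322, 20.99, 305.4, 0.71, 149.0),
    (26, "DCDS", 0.345, 19.93, 311.0, 0.76, 151.9),
    (27, "DCDS", 0.311, 22.57, 308.1, 0.77, 148.7),
    (28, "DCDS", 0.180, 27.62, 313.2, 0.85, 140.8),
    (29, "SUBS", 0.311, 22.94, 314.0, 0.82, 152.0),
    (30, "LEGM", 0.262, 25.18, 305.6, 0.78, 162.8),
    (31, "DCDS", 1.090, 0.87, 27.4, 1.43, 10.6),
    (32, "LEGM", 0.845, 1.71, 319.5, 1.55, 113.5),
    (33, "LEGM", 0.246, 23.21, 271.1, 1.21, 130.4),
    (34, "LEGM", 0.565, 26.70, 325.6, 1.31, 33.9),
    (35, "SUBS", 0.599, 8.05, 303.0, 1.17, 158.1),
    (36, "LEGM", 0.551, 38.58, 320.1, 1.38, 30.9),
    (37, "LEGM", 0.452, 50.90, 341.6, 1.69, 51.5),
    (38, "SUBS", 0.807, 55.83, 314.9, 1.86, 7.4),
    (39, "LEGM", 0.236, 18.59, 298.9, 1.15, 205.1),
    (40, "LEGM", 0.636, 5.95, 323.0, 1.43, 87.9),
    (41, "LEGM", 0.157, 23.07, 317.9, 1.27, 150.3),
    (42, "DCDS", 0.745, 2.56, 325.9, 1.50, 119.3),
    (43, "DCDS", 0.407, 12.50, 309.5, 1.32, 150.7),
]


def observation_params_table() -> pd.DataFrame:
    """Per-observation published parameter estimates as a DataFrame.

    g_p is reported in mmol m-2 s-1 MPa-1 (the display convention);
    use :func:`observation_params` for model-ready parameter objects.
    """
    return pd.DataFrame(
        _OBS_ROWS, columns=["observation", "pft", "K_psi", "g_p_mmol", "K_i", "pi_0", "xi"]
    ).set_index("observation")


def observation_params(pft: str | None = None) -> dict[int, StomatalParams]:
    """Model-ready per-observation parameter sets, optionally one functional group."""
    out: dict[int, StomatalParams] = {}
    for obs, grp, k_psi, gp_mmol, k_i, pi_0, xi in _OBS_ROWS:
        if pft is not None and grp != pft:
            continue
        out[obs] = StomatalParams(
            K_psi=k_psi,
            g_p=gp_mmol * 1e-3,
            C_lambda=C_LAMBDA_DEFAULT,
            pi_0=pi_0,
            K_i=k_i,
            xi=xi,
        )
    return out


def pft_of_observation() -> dict[int, str]:
    """Functional-group label per observation index."""
    return {row[0]: row[1] for row in _OBS_ROWS}
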