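"""Reading, unit harmonization and leaf-hour averaging of gas-exchange tables.

Diurnal leaf gas-exchange measurements come from several generations of
portable instruments (LI-6400, LI-6200, LI-6000, CI-301PS) that report
stomatal conductance either as a molar conductance (mol or mmol m-2 s-1),
a velocity conductance (m s-1), or a resistance (s cm-1 or m2 s mol-1).
Everything is harmonized here to the LI-6400 convention:

* conductance ``gs_mol``      mol H2O m-2 s-1
* photosynthesis ``an_umol``  umol CO2 m-2 s-1
* intercellular CO2 ``ci_umol``  umol mol-1 (may be missing)
* vapor pressure deficit ``vpd_kpa``  kPa (leaf surface)
* air pressure ``p_kpa``      kPa
* leaf temperature ``tleaf_c``  degC (may be missing)

Velocity/molar interconversion uses the ideal gas law,
``g_mol = g_vel * P / (R * T_K)`` with R = 8.314 J mol-1 K-1.

To avoid pseudo-replication from repeated measurements on the same leaf,
records are averaged per (date, hour, leaf) before any fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, EmptyInputError, FormatError, UnitError

__all__ = [
    "LeafRecord",
    "ObservationTable",
    "LICOR_6400_DIALECT",
    "CANONICAL_COLUMNS",
    "convert_units",
    "scaled_vpd",
    "relative_humidity_from_D",
    "saturation_vapor_pressure",
    "read_gas_exchange_table",
    "average_by_leaf_hour",
    "write_harmonized_csv",
    "load_manifest",
]

logger = logging.getLogger(__name__)

R_GAS = 8.314  # J mol-1 K-1

CANONICAL_COLUMNS = [
    "obs_id", "date", "hour", "leaf",
    "gs_mol", "an_umol", "ci_umol", "vpd_kpa", "p_kpa", "tleaf_c",
]

#: Default column mapping for LI-6400 style files.  Keys are canonical field
#: names, values are the instrument's column headers.  ``gs_unit`` /
#: ``vpd_unit`` / ``p_unit`` select the input units (canonical if omitted).
LICOR_6400_DIALECT: dict[str, str] = {
    "gs": "Cond",
    "an": "Photo",
    "ci": "Ci",
    "vpd": "VpdL",
    "p": "Press",
    "tleaf": "Tleaf",
    "date": "Date",
    "hour": "HHMMSS",
    "leaf": "Leaf",
}

_MANDATORY = ["gs", "an", "vpd", "p", "date", "hour", "leaf"]


@dataclass(frozen=True)
class LeafRecord:
    """One leaf-hour gas-exchange measurement in harmonized units."""

    observation_id: str
    date: str
    hour: int
    leaf_id: str
    g_s: float      # mol H2O m-2 s-1
    A_n: float      # umol CO2 m-2 s-1
    VPD: float      # kPa
    P: float        # kPa
    C_i: float | None = None   # umol mol-1
    T_leaf: float | None = None  # degC

    def is_valid(self) -> bool:
        return record_is_valid(self.g_s, self.A_n, self.VPD, self.P)


def record_is_valid(g_s, A_n, VPD, P) -> bool:
    """Sanity bounds every retained record must satisfy."""
    if not np.isfinite(g_s) or not np.isfinite(A_n) or not np.isfinite(VPD) or not np.isfinite(P):
        return False
    return (
        g_s >= 0
        and -5 <= A_n <= 60
        and VPD >= 0
        and 50 <= P <= 110
        and 0 <= VPD / P <= 0.2
    )


@dataclass
class ObservationTable:
    """All harmonized records for one observation (one species at one site)."""

    observation_id: str
    species: str = ""
    pft: str = ""
    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CANONICAL_COLUMNS))

    def __post_init__(self) -> None:
        if self.pft and self.pft not in ("DCDS", "LEGM", "SUBS"):
            raise ValueError(f"unknown functional group {self.pft!r}")
        if len(self.data) and (self.data["obs_id"] != self.observation_id).any():
            raise ValueError("all records must share the table's observation_id")

    @property
    def days(self) -> list[str]:
        """Distinct calendar days present, sorted."""
        return sorted(self.data["date"].astype(str).unique())

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# unit conversion

# conductance-family tags; "to molar" factors are value -> mol m-2 s-1,
# possibly temperature/pressure dependent.
_COND_TAGS = {"mol m-2 s-1", "mmol m-2 s-1", "m s-1", "s cm-1", "m2 s mol-1"}
_PRESS_TAGS = {"kPa", "hPa", "mbar"}


def _to_molar(value: float, tag: str, T: float, P: float) -> float:
    molar_per_velocity = P * 1000.0 / (R_GAS * (T + 273.15))  # (mol m-2 s-1) per (m s-1)
    if tag == "mol m-2 s-1":
        return value
    if tag == "mmol m-2 s-1":
        return value * 1e-3
    if tag == "m s-1":
        return value * molar_per_velocity
    if tag == "s cm-1":           # resistance: r s/cm -> velocity 0.01/r m/s
        return (0.01 / value) * molar_per_velocity
    if tag == "m2 s mol-1":       # molar resistance
        return 1.0 / value
    raise UnitError(f"unsupported conductance unit {tag!r}")


def _from_molar(value: float, tag: str, T: float, P: float) -> float:
    molar_per_velocity = P * 1000.0 / (R_GAS * (T + 273.15))
    if tag == "mol m-2 s-1":
        return value
    if tag == "mmol m-2 s-1":
        return value * 1e3
    if tag == "m s-1":
        return value / molar_per_velocity
    if tag == "s cm-1":
        return 0.01 * molar_per_velocity / value
    if tag == "m2 s mol-1":
        return 1.0 / value
    raise UnitError(f"unsupported conductance unit {tag!r}")


def convert_units(value, from_unit: str, to_unit: str, T: float = 25.0, P: float = 101.325):
    """Convert between supported gas-exchange units.

    Conductance/resistance family: ``mol m-2 s-1``, ``mmol m-2 s-1``,
    ``m s-1`` (velocity conductance), ``s cm-1`` (resistance),
    ``m2 s mol-1`` (molar resistance).  Pressure family: ``kPa``, ``hPa``,
    ``mbar``.  ``T`` (degC) and ``P`` (kPa) enter only the molar/velocity
    conversions.
    """
    if from_unit == to_unit:
        return value
    if from_unit in _COND_TAGS and to_unit in _COND_TAGS:
        return _from_molar(_to_molar(value, from_unit, T, P), to_unit, T, P)
    if from_unit in _PRESS_TAGS and to_unit in _PRESS_TAGS:
        factor = {"kPa": 1.0, "hPa": 0.1, "mbar": 0.1}
        return value * factor[from_unit] / factor[to_unit]
    raise UnitError(f"unsupported unit pair {from_unit!r} -> {to_unit!r}")


def scaled_vpd(VPD, P):
    """Dimensionless vapor pressure deficit D = VPD / P (both kPa)."""
    if np.any(np.asarray(P) <= 0):
        raise DomainError("air pressure must be positive")
    if np.any(np.asarray(VPD) < 0):
        raise DomainError("VPD must be non-negative")
    return VPD / P


def saturation_vapor_pressure(T):
    """Saturation vapor pressure over water (kPa), Tetens formula, T in degC."""
    T = np.asarray(T, dtype=float)
    return 0.61078 * np.exp(17.27 * T / (T + 237.3))


def relative_humidity_from_D(D, T, P=101.325):
    """Relative humidity (fraction) implied by scaled VPD ``D`` at T (degC), P (kPa).

    RH = 1 - D*P/e_sat(T); negative results (demand exceeding saturation)
    are clamped to 0 with a warning.
    """
    if np.any((np.asarray(T) < -10) | (np.asarray(T) > 60)):
        raise DomainError("temperature outside [-10, 60] degC")
    rh = 1.0 - np.asarray(D) * np.asarray(P) / saturation_vapor_pressure(T)
    if np.any(rh < 0):
        warnings.warn("relative humidity clamped to 0 (D exceeds saturation deficit)")
        rh = np.clip(rh, 0.0, None)
    return rh if rh.ndim else float(rh)


# ---------------------------------------------------------------------------
# reading / averaging

def _hour_of(v) -> int:
    """Hour from either an integer/float hour or a Licor HHMMSS stamp."""
    if isinstance(v, str):
        v = v.strip()
        if ":" in v:
            return int(v.split(":")[0])
        v = float(v)
    v = float(v)
    if v >= 100:  # HHMMSS numeric stamp
        return int(v // 10000)
    return int(v)


def read_gas_exchange_table(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    observation_id: str | None = None,
    species: str = "",
    pft: str = "",
) -> ObservationTable:
    """Read one observation's CSV and harmonize it to canonical units.

    ``dialect`` maps canonical field names (gs, an, ci, vpd, p, tleaf, date,
    hour, leaf) to the file's column headers and may carry ``gs_unit``,
    ``vpd_unit``, ``p_unit`` tags for non-canonical input units.  Rows
    violating the record sanity bounds are dropped with a logged count.
    """
    path = Path(path)
    dialect = {**LICOR_6400_DIALECT, **(dialect or {})}
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)

    for key in _MANDATORY:
        if dialect.get(key) not in raw.columns:
            raise FormatError(
                f"{path.name}: mandatory column {dialect.get(key)!r} (field {key!r}) not found"
            )

    p_unit = dialect.get("p_unit", "kPa")
    vpd_unit = dialect.get("vpd_unit", "kPa")
    gs_unit = dialect.get("gs_unit", "mol m-2 s-1")

    p_kpa = raw[dialect["p"]].astype(float).map(lambda v: convert_units(v, p_unit, "kPa"))
    vpd_kpa = raw[dialect["vpd"]].astype(float).map(lambda v: convert_units(v, vpd_unit, "kPa"))
    tleaf = (
        raw[dialect["tleaf"]].astype(float)
        if dialect.get("tleaf") in raw.columns
        else pd.Series(np.nan, index=raw.index)
    )
    t_for_gas = tleaf.fillna(25.0)
    gs_mol = pd.Series(
        [
            convert_units(v, gs_unit, "mol m-2 s-1", T=t, P=p)
            for v, t, p in zip(raw[dialect["gs"]].astype(float), t_for_gas, p_kpa)
        ],
        index=raw.index,
    )
    ci = (
        raw[dialect["ci"]].astype(float)
        if dialect.get("ci") in raw.columns
        else pd.Series(np.nan, index=raw.index)
    )

    obs_id = observation_id or path.stem
    df = pd.DataFrame(
        {
            "obs_id": obs_id,
            "date": raw[dialect["date"]].astype(str),
            "hour": raw[dialect["hour"]].map(_hour_of),
            "leaf": raw[dialect["leaf"]].astype(str),
            "gs_mol": gs_mol,
            "an_umol": raw[dialect["an"]].astype(float),
            "ci_umol": ci,
            "vpd_kpa": vpd_kpa,
            "p_kpa": p_kpa,
            "tleaf_c": tleaf,
        }
    )

    ok = df.apply(
        lambda r: record_is_valid(r["gs_mol"], r["an_umol"], r["vpd_kpa"], r["p_kpa"]), axis=1
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d of %d records failing sanity bounds", obs_id, n_dropped, len(df))
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise EmptyInputError(f"{path.name}: no valid records after filtering")
    return ObservationTable(observation_id=obs_id, species=species, pft=pft, data=df)


def average_by_leaf_hour(table: ObservationTable) -> ObservationTable:
    """Average replicate records per (date, hour, leaf); idempotent."""
    if len(table) == 0:
        raise EmptyInputError("cannot average an empty table")
    df = table.data
    grouped = (
        df.groupby(["date", "hour", "leaf"], as_index=False, sort=True)
        .agg({c: "mean" for c in ["gs_mol", "an_umol", "ci_umol", "vpd_kpa", "p_kpa", "tleaf_c"]})
    )
    grouped.insert(0, "obs_id", table.observation_id)
    return ObservationTable(
        observation_id=table.observation_id,
        species=table.species,
        pft=table.pft,
        data=grouped[CANONICAL_COLUMNS],
    )


def write_harmonized_csv(table: ObservationTable, path: str | Path) -> None:
    """Write a table in the canonical column layout (deterministic formatting)."""
    table.data[CANONICAL_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def load_manifest(path: str | Path) -> list[ObservationTable]:
    """Load a YAML manifest listing observations and their harmonized CSVs.

    Each manifest entry: ``{observation_id, species, pft, file}`` with ``file``
    relative to the manifest's directory.  Files must already be in canonical
    units (as written by :func:`write_harmonized_csv` or the generator).
    """
    path = Path(path)
    entries = yaml.safe_load(path.read_text())
    tables = []
    for e in entries["observations"]:
        df = pd.read_csv(path.parent / e["file"], dtype={"date": str, "leaf": str})
        tables.append(
            ObservationTable(
                observation_id=str(e["observation_id"]),
                species=e.get("species", ""),
                pft=e.get("pft", ""),
                data=df[CANONICAL_COLUMNS],
            )
        )
    return tables
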