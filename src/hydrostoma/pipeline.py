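"""Staged analysis pipeline tying the modules together.

Stages (each a plain function, also exposed as CLI subcommands):

``simulate``  write a synthetic campaign (CSVs + manifest + truth record);
``ingest``    harmonize raw instrument tables into the canonical layout;
``fit``       fit one hierarchy level (OBS must run before PFT/GLB, which
              reuse its latent-psi and C_lambda posterior means);
``compare``   deviance/DIC/chi-square comparison across fitted levels;
``behave``    response grids and the benchmark numbers of the forward model.

Every artifact embeds the configuration hash and the seed so reruns are
attributable; identical configurations yield identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior as bh
from .comparison import chi2_deviance_test, dic
from .errors import StagingError
from .inference import FitResult, MCMCSettings, PriorSpec, fit_level
from .params import GROUP_PARAMS, C_0_DEFAULT, StomatalParams
from .synthetic import SyntheticDesign, generate_dataset, write_dataset
from .units import average_by_leaf_hour, load_manifest, read_gas_exchange_table, write_harmonized_csv

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_ingest",
    "run_fit",
    "run_compare",
    "run_behave",
]


@dataclass
class PipelineConfig:
    outdir: str = "hydrostoma_out"
    seed: int = 0
    n_iter: int = 5000
    n_chains: int = 2
    priors: PriorSpec = field(default_factory=PriorSpec)
    A_n_reference: float = bh.AN_REFERENCE
    psi_favorable: float = bh.PSI_FAVORABLE
    D_favorable: float = bh.D_FAVORABLE
    C_0: float = C_0_DEFAULT

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        priors = PriorSpec(**{k: tuple(v) for k, v in raw.pop("priors", {}).items()})
        return cls(priors=priors, **raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def mcmc(self) -> MCMCSettings:
        return MCMCSettings(n_iter=self.n_iter, n_chains=self.n_chains, seed=self.seed)


def _stamp(config: PipelineConfig) -> dict:
    return {"config_hash": config.digest(), "seed": config.seed}


def run_simulate(config: PipelineConfig, design: SyntheticDesign | None = None) -> Path:
    """Generate and write a synthetic campaign under ``outdir/data``."""
    design = design or SyntheticDesign(seed=config.seed)
    tables, truth = generate_dataset(design)
    datadir = Path(config.outdir) / "data"
    manifest = write_dataset(tables, truth, datadir)
    (datadir / "stamp.json").write_text(json.dumps(_stamp(config), indent=1))
    logger.info("simulate: %d observations, %d records total",
                len(tables), sum(len(t) for t in tables))
    return manifest


def run_ingest(
    config: PipelineConfig, files: list, dialect: dict | None = None, pft_map: dict | None = None
) -> Path:
    """Harmonize raw instrument CSVs and write a canonical dataset."""
    datadir = Path(config.outdir) / "data"
    datadir.mkdir(parents=True, exist_ok=True)
    entries = []
    for f in files:
        table = read_gas_exchange_table(f, dialect=dialect)
        table.pft = (pft_map or {}).get(table.observation_id, "")
        table = average_by_leaf_hour(table)
        fname = f"{table.observation_id}.csv"
        write_harmonized_csv(table, datadir / fname)
        entries.append(
            {
                "observation_id": table.observation_id,
                "species": table.species,
                "pft": table.pft,
                "file": fname,
            }
        )
        logger.info("ingest: %s -> %d leaf-hour records", table.observation_id, len(table))
    manifest = datadir / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"observations": entries}, sort_keys=False))
    (datadir / "stamp.json").write_text(json.dumps(_stamp(config), indent=1))
    return manifest


def run_fit(config: PipelineConfig, level: str) -> FitResult:
    """Fit one hierarchy level; PFT/GLB require a prior OBS fit on disk."""
    outdir = Path(config.outdir)
    tables = [average_by_leaf_hour(t) for t in load_manifest(outdir / "data" / "manifest.yaml")]
    fitdir = outdir / "fits"
    fitdir.mkdir(parents=True, exist_ok=True)

    psi_fixed = None
    c_lambda_fixed = None
    if level in ("PFT", "GLB"):
        obs_json = fitdir / "OBS.json"
        if not obs_json.exists():
            raise StagingError(
                f"{level} fit requires a prior OBS fit (missing {obs_json}); run fit OBS first"
            )
        obs_fit = json.loads(obs_json.read_text())
        psi_fixed = obs_fit["psi_day_estimates"]
        c_lambda_fixed = obs_fit["C_lambda_value"]

    fit = fit_level(
        tables, level, priors=config.priors, mcmc=config.mcmc(),
        psi_fixed=psi_fixed, c_lambda_fixed=c_lambda_fixed,
    )
    fit.to_json(fitdir / f"{level}.json")
    fit.draws_to_csv(fitdir / f"{level}_draws.csv")
    payload = json.loads((fitdir / f"{level}.json").read_text())
    payload.update(_stamp(config))
    (fitdir / f"{level}.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    logger.info("fit %s: %d free parameters, mean deviance %.1f, sigma %.3f",
                level, fit.n_free_parameters, float(fit.deviance_trace.mean()), fit.residual_sd)
    return fit


def run_compare(config: PipelineConfig) -> dict:
    """Build the cross-level comparison report from fitted-level artifacts."""
    fitdir = Path(config.outdir) / "fits"
    levels = [lvl for lvl in ("GLB", "PFT", "OBS") if (fitdir / f"{lvl}.json").exists()]
    if len(levels) < 2:
        raise StagingError("compare requires at least two fitted levels on disk")
    rows, tests = {}, {}
    fits = {lvl: json.loads((fitdir / f"{lvl}.json").read_text()) for lvl in levels}
    for lvl, f in fits.items():
        rows[lvl] = {
            "deviance": f["mean_deviance"],
            "dic": dic([f["mean_deviance"]], f["deviance_at_mean"]),
            "n_parameters": f["n_free_parameters"],
            "residual_sd": f["residual_sd"],
        }
    for simple, complex_ in zip(levels[:-1], levels[1:]):
        c = chi2_deviance_test(
            rows[simple]["deviance"], rows[complex_]["deviance"],
            rows[simple]["n_parameters"], rows[complex_]["n_parameters"],
        )
        tests[f"{complex_}_vs_{simple}"] = {"chi2": c.chi2_stat, "df": c.df, "p_value": c.p_value}
    report = {"levels": rows, "tests": tests, **_stamp(config)}
    (fitdir / "comparison.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _params_from_fit_json(path: Path) -> dict[str, StomatalParams]:
    f = json.loads(path.read_text())
    pm, c_lam = f["posterior_mean"], f["C_lambda_value"]
    units = sorted({n.split("[", 1)[1][:-1] for n in pm if n.startswith("K_psi[")})
    return {
        u: StomatalParams(
            K_psi=pm[f"K_psi[{u}]"], g_p=pm[f"g_p[{u}]"], C_lambda=c_lam,
            pi_0=pm[f"pi_0[{u}]"], K_i=pm[f"K_i[{u}]"], xi=pm[f"xi[{u}]"],
        )
        for u in units
    }


def run_behave(config: PipelineConfig, params_source: str = "fixtures") -> dict:
    """Evaluate response grids and benchmark numbers.

    ``params_source`` is ``"fixtures"`` (the published group estimates) or
    the path of a fit-result JSON whose posterior means are used instead.
    """
    outdir = Path(config.outdir) / "behavior"
    outdir.mkdir(parents=True, exist_ok=True)
    if params_source == "fixtures":
        group_params = dict(GROUP_PARAMS)
    else:
        group_params = _params_from_fit_json(Path(params_source))

    psi_axis = -np.geomspace(0.033, 5.0, 60)
    D_axis = np.linspace(config.D_favorable, 0.05, 40)
    for label, p in group_params.items():
        grid = bh.response_surface(p, psi_axis, D_axis, config.A_n_reference, label=label)
        grid.to_csv(outdir / f"surface_{label}.csv")

    if set(("SUBS", "LEGM", "DCDS", "GLB")) <= set(group_params):
        report = {
            k: float(v)
            for k, v in bh.behavior_benchmarks(group_params, config.A_n_reference).items()
        }
    else:  # benchmark set needs all four canonical units; report corners per unit
        report = {
            f"gs_favorable_{u}": float(
                bh.response_surface(
                    p, [config.psi_favorable], [config.D_favorable], config.A_n_reference
                ).g_s_matrix[0, 0]
            )
            for u, p in group_params.items()
        }
    report = {**report, **_stamp(config)}
    (outdir / "benchmarks.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
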