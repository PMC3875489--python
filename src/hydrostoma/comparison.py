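"""Deviance-based comparison of the hierarchy levels, DIC, and fit diagnostics.

Nested fits (GLB within PFT within OBS) are compared by the difference in
deviance, referred to a chi-square distribution with degrees of freedom
equal to the difference in free-parameter counts.  The deviance information
criterion DIC = mean posterior deviance + pD, with the effective parameter
count pD = mean deviance - deviance at the posterior mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "LevelComparison",
    "chi2_deviance_test",
    "dic",
    "pred_obs_correlation",
    "group_psi_ttest",
    "comparison_table",
]


@dataclass(frozen=True)
class LevelComparison:
    dev_simple: float
    dev_complex: float
    k_simple: int
    k_complex: int
    chi2_stat: float
    df: int
    p_value: float


def chi2_deviance_test(
    dev_simple: float, dev_complex: float, k_simple: int, k_complex: int
) -> LevelComparison:
    """Chi-square test of a nested-model deviance drop.

    ``chi2_stat = dev_simple - dev_complex`` on ``df = k_complex - k_simple``
    degrees of freedom (upper-tail p).  A negative statistic (the richer
    model fitting worse) is reported with p = 1 and a warning.
    """
    if k_complex <= k_simple:
        raise ValueError("complex model must have more parameters than the simple one")
    stat = dev_simple - dev_complex
    df = k_complex - k_simple
    if stat < 0:
        warnings.warn("complex model fits worse than the simple one (negative deviance drop)")
        p = 1.0
    else:
        p = float(stats.chi2.sf(stat, df))
    return LevelComparison(dev_simple, dev_complex, k_simple, k_complex, stat, df, p)


def dic(deviance_trace, deviance_at_mean: float) -> float:
    """Deviance information criterion from a posterior deviance trace.

    pD = mean(trace) - deviance_at_mean; DIC = mean(trace) + pD.
    """
    trace = np.asarray(deviance_trace, float).ravel()
    if trace.size == 0:
        raise ValueError("deviance trace is empty")
    dbar = float(trace.mean())
    return dbar + (dbar - deviance_at_mean)


def pred_obs_correlation(predicted, measured) -> float:
    """Pearson correlation between predicted and measured stomatal conductance."""
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    if predicted.shape != measured.shape or predicted.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.std(predicted) == 0 or np.std(measured) == 0:
        raise DomainError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(predicted, measured).statistic)


def group_psi_ttest(psi_group_a, psi_group_b) -> float:
    """Welch two-sample t-test p-value for a difference in group-mean soil
    water potential."""
    a = np.asarray(psi_group_a, float)
    b = np.asarray(psi_group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 1.0
        raise DomainError("degenerate zero-variance groups with different means")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def comparison_table(fits: dict) -> dict:
    """Summary rows across fitted levels plus pairwise nested tests.

    ``fits`` maps level name (subset of GLB/PFT/OBS, in coarse-to-fine
    order) to FitResult.  Returns a JSON-serializable dict; render with
    :func:`format_comparison_table` for a plain-text view.
    """
    order = [lvl for lvl in ("GLB", "PFT", "OBS") if lvl in fits]
    rows = {}
    for lvl in order:
        f = fits[lvl]
        rows[lvl] = {
            "deviance": float(f.deviance_trace.mean()),
            "dic": dic(f.deviance_trace, f.deviance_at_mean),
            "n_parameters": f.n_free_parameters,
            "residual_sd": f.residual_sd,
        }
    tests = {}
    for simple, complex_ in zip(order[:-1], order[1:]):
        cmp_ = chi2_deviance_test(
            rows[simple]["deviance"], rows[complex_]["deviance"],
            fits[simple].n_free_parameters, fits[complex_].n_free_parameters,
        )
        tests[f"{complex_}_vs_{simple}"] = {
            "chi2": cmp_.chi2_stat, "df": cmp_.df, "p_value": cmp_.p_value,
        }
    return {"levels": rows, "tests": tests}


def format_comparison_table(report: dict) -> str:
    """Plain-text rendering of :func:`comparison_table` output."""
    lines = [f"{'Level':<6}{'Deviance':>12}{'DIC':>12}{'k':>6}{'sigma':>10}"]
    for lvl, r in report["levels"].items():
        lines.append(
            f"{lvl:<6}{r['deviance']:>12.1f}{r['dic']:>12.1f}"
            f"{r['n_parameters']:>6d}{r['residual_sd']:>10.3f}"
        )
    for name, t in report.get("tests", {}).items():
        lines.append(f"{name}: chi2={t['chi2']:.1f} df={t['df']} p={t['p_value']:.2g}")
    return "\n".join(lines)
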