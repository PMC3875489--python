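"""Three-level hierarchical analysis and deviance-based model comparison.

Simulates a small campaign in which the three functional groups truly
differ (published group parameters as truth, 20% within-group spread),
runs the two-pass staging -- observation-level fit first, then group and
pooled fits reusing its latent-psi and C_lambda posterior means -- and
prints the cross-level comparison table.
"""

from hydrostoma import MCMCSettings, SyntheticDesign, fit_level, generate_dataset
from hydrostoma.comparison import comparison_table, format_comparison_table

design = SyntheticDesign(
    n_observations_per_group=2, n_days_per_observation=2, n_leaves=3,
    noise_sd=0.05, psi_day_range=(-1.2, -0.1), D_max_range=(0.02, 0.07),
    param_jitter_cv=0.2, seed=11,
)
tables, _ = generate_dataset(design)
mc = MCMCSettings(n_iter=1500, n_chains=2, seed=11)

obs = fit_level(tables, "OBS", mcmc=mc)
pft = fit_level(tables, "PFT", mcmc=mc, psi_fixed=obs.psi_day_estimates,
                c_lambda_fixed=obs.C_lambda_value)
glb = fit_level(tables, "GLB", mcmc=mc, psi_fixed=obs.psi_day_estimates,
                c_lambda_fixed=obs.C_lambda_value)

report = comparison_table({"GLB": glb, "PFT": pft, "OBS": obs})
print(format_comparison_table(report))
print("\nDeviance falls as granularity grows; each chi-square test compares "
      "the deviance drop against the added parameter count, so small p-values "
      "mean the finer grouping is a real improvement, not just extra knobs.")
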