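# Methods

## Model

The steady-state leaf model couples three mechanisms.

**Turgor-proportional conductance.** Stomatal aperture, and hence
conductance, responds linearly to guard-cell turgor `pi + psi_x`, with
apparent compliance `K_psi` absorbing both the mechanical compliance of a
single stoma and stomatal density. Negative turgor means closed stomata
(`g_s = 0`), not negative conductance.

**Photosynthesis-driven osmotic adjustment.** Guard-cell osmotic pressure
is `pi = pi_0 * (1 + xi * A_n/(K_i + A_n) * C_0/C_i)`. The Michaelis term
saturates in `A_n`; since fitted `K_i` (tens to hundreds of µmol m⁻² s⁻¹)
far exceeds field assimilation rates (< 20), the effective sensitivity is
the ratio `xi/K_i` and the two parameters are individually soft — only
mildly constrained by the data. The CO₂ ratio `C_0/C_i` amplifies
adjustment when intercellular CO₂ is drawn down; when `C_i` is missing the
model substitutes `C_0` (370 µmol mol⁻¹, a period-typical ambient value),
which makes the factor exactly neutral. For respiring leaves (`A_n < 0`)
the adjustment term is floored at zero rather than extrapolated to
"negative adjustment".

**Cavitation with an efficiency–safety tradeoff.** Soil-to-leaf
conductance declines hyperbolically with xylem tension,
`K = g_p/(1 + C_lambda*g_p*|psi_x|)`: in reciprocal form `1/K = 1/g_p +
C_lambda*|psi_x|`, a line whose intercept is the observation's maximum
conductance and whose slope `C_lambda` is one constant for all species.
Because the slope multiplies `g_p` inside the loss term, high-conductance
xylem loses a larger *fraction* of its capacity at the same tension — wide
vessels conduct more and cavitate sooner. The tension at half loss is
`−1/(C_lambda*g_p)`.

**Solution.** Mass balance `g_s*D = K(psi_x)*(psi − psi_x)` with the two
relations above is a quadratic in `psi_x`. The admissible root lies in
`[−pi, psi]` and is unique (the quadratic is concave with opposite signs at
the ends); it is evaluated with the Citardauq-stable root pair `q/a`, `c/q`
because the leading coefficient vanishes as cavitation becomes negligible
and the textbook formula loses all precision there. A Brent bracketing
solver on the same interval serves as an independent cross-check (agreement
to 1e−8 MPa is asserted in tests, default bisection tolerance 1e−12,
configurable). When `psi <= −pi` the stomata are closed and no gradient
develops (`psi_x = psi`); when `D = 0` there is no flow and again
`psi_x = psi`.

## Parameters

| name | meaning | units | group-level range |
|---|---|---|---|
| `K_psi` | guard-cell apparent compliance | mol m⁻² s⁻¹ MPa⁻¹ | 0.16–1.42 |
| `g_p` | maximum soil-to-leaf conductance | mol m⁻² s⁻¹ MPa⁻¹ | 0.002–0.0057 |
| `C_lambda` | cavitation tradeoff constant (shared) | m² s mol⁻¹ | 3.13 |
| `pi_0` | baseline osmotic pressure | MPa | 1.76–1.94 |
| `K_i` | osmotic-adjustment half-saturation | µmol m⁻² s⁻¹ | 199–320 |
| `xi` | osmotic-adjustment gain | – | 9.9–34.1 |

Conductances are kept in mol m⁻² s⁻¹ internally; published tables print
`g_p` in mmol and the fixtures convert on construction, which avoids the
mmol/mol confusion such tables invite.

## Inference

Three nesting levels: pooled (GLB), functional group (PFT: deciduous
non-legume shrubs, legume shrubs, *Artemisia* subshrubs), and observation
(OBS, species × site). The likelihood is i.i.d. Gaussian on measured `g_s`
with one residual SD `sigma` per level; priors are independent uniforms on
physiologically meaningful ranges (`K_psi` ∈ [0.01, 1.5] mol m⁻² s⁻¹ MPa⁻¹,
`g_p` ∈ [0.0005, 0.08], `K_i` ∈ [20, 400], `pi_0` ∈ [0.5, 2], `xi` ∈
[0, 250], `C_lambda` ∈ [0.1, 10], daily `psi` ∈ [−8, −0.01] MPa, `sigma` ∈
[0.001, 1]). Daily soil water potentials are latent (constant within a
day) and, like the shared `C_lambda`, are free only at the OBS level; PFT
and GLB fits consume the OBS posterior means of both — a two-pass staging
enforced by the pipeline. `sigma` is sampled but not counted among the
free parameters, so the counts are 5 per unit, plus days + 1 at OBS (e.g.
296 for a 43-observation, 80-day campaign).

The sampler is Metropolis-within-Gibbs: each scalar gets a reflected
Gaussian random-walk proposal (reflection at the prior bounds keeps the
kernel symmetric), with scales adapted every 25 sweeps during burn-in
toward ~30 % acceptance; the first half of each chain (≥ 2 chains) is
burn-in. Two design elements proved essential:

* **Warm start.** Chains start from a bounded least-squares fit (per-unit
  trust-region fits profiled over a coarse `C_lambda` grid), jittered per
  chain. Random prior draws leave 1000-sweep burn-ins stranded far from
  the mass of the posterior.
* **Ridge moves.** The wet-regime likelihood constrains mainly the
  products `K_psi*(pi + psi_d)` and the pair (intercept, slope) of `1/K`;
  per-coordinate updates therefore crawl along three soft valleys. Each
  sweep adds joint Metropolis-Hastings moves: a per-observation
  translation (daily `psi` up, `pi_0` down by the mean adjustment factor),
  a per-observation multiplicative rescaling of `K_psi` against
  (`pi_0`, daily `psi`, `g_p`) with the exact log-Jacobian, and a global
  `C_lambda`–`g_p` slope/intercept exchange at a reference tension of
  1.5 MPa, also Jacobian-corrected. Without them, split-R̂ sits at 3–4 on
  desk-scale problems; with them, typical fits reach R̂ ≲ 1.5 in 2000
  sweeps.

Convergence is summarized by split-R̂ (in-package, cross-checked against
arviz in the suite). Model comparison uses deviance `D = −2 log L`
(negative when most densities exceed 1, as here where `g_s` residuals are
small), chi-square tests on deviance differences with df equal to the
parameter-count difference, Spiegelhalter DIC with
`pD = mean(D) − D(posterior mean)`, Pearson predicted-vs-measured
correlation, and a Welch t-test for group-mean latent potentials.

## Synthetic data generator

The generator emulates a field campaign: per observation, several diurnal
courses on separate days; within a day, scaled VPD and assimilation follow
a half-sine of solar time and intercellular CO₂ dips below ambient in
proportion to assimilation; soil water potential is one latent value per
day, drawn uniformly (default [−3, −0.1] MPa); measured conductance is the
model's steady state plus Gaussian noise truncated at zero (default SD
0.1 mol m⁻² s⁻¹). Each day draws its own midday peaks (scaled VPD
0.015–0.06, assimilation 6–16 µmol m⁻² s⁻¹) — day-to-day weather variation
is both realistic and what breaks the translation degeneracy between the
latent potentials and the osmotic parameters; with identical drivers every
day the absolute scale of the system is informed only by the
cavitation nonlinearity, whose magnitude is of order `C_lambda*E` (a few
percent except on wet, high-demand days). Default true parameters are the
published group estimates, optionally spread per observation by a
mean-preserving lognormal (20 % CV).

What the generator does **not** emulate: weather-driven soil-moisture
dynamics (days are exchangeable), instrument drift, heteroscedastic or
autocorrelated noise, energy-balance feedbacks on leaf temperature, and
radiation–photosynthesis coupling beyond the sine proxy. Passing recovery
tests therefore demonstrate that the estimator is consistent with its own
assumptions at realistic noise, not that field data meet those assumptions.

**Recovery experiment design.** The suite's seed-fixed recovery run uses
three observations with the subshrub truth (3 days × 36 records each,
noise 0.05) and daily potentials in [−1.2, −0.1] MPa. Both choices are
identifiability-driven and made a priori: high-conductance units transpire
most, so the cavitation signal that pins the absolute parameter scale is
strongest; and days at or beyond closure contribute no information about
their own potential (any drier value fits identically). At this reduced
scale the shared `C_lambda` keeps a broad posterior (the pooling across 43
observations that pins it in a full campaign is absent), which the ridge
moves integrate over honestly.

## Numerical choices

* Saturation vapor pressure: Tetens (Monteith form),
  `0.61078*exp(17.27*T/(T+237.3))` kPa — standard in micrometeorology;
  `D = 0.0035` at 30 °C and sea level then corresponds to 91.6 % relative
  humidity.
* Velocity/molar conductance conversions use the ideal gas law at the
  record's own temperature and pressure; resistance units invert first.
  All conversions are involutive to 10 significant digits.
* Record sanity bounds (`g_s ≥ 0`, `A_n` ∈ [−5, 60], `VPD ≥ 0`, `P` ∈
  [50, 110] kPa, `D ≤ 0.2`) drop rows with a logged count; leaf-hour
  averaging is mandatory before fitting to avoid pseudo-replication.
* Quadratic root selection: the in-interval root; if roundoff ever put
  both roots inside, the larger-turgor root wins with a warning.
* Chain seeds derive from `(seed, chain-index)` via numpy's SeedSequence,
  so runs are exactly reproducible and chains independent.

## Known limitations

* **Observation-level DIC is unstable.** The OBS posterior rides curved
  soft ridges; the posterior-mean parameter vector can sit off-ridge, so
  `pD` can be strongly negative and DIC meaningless at that level (the
  suite asserts this behavior; the group- and pooled-level DICs are well
  behaved). Deviance differences, which never evaluate at the mean,
  remain usable across all levels.
* **Weak identifiability at small scale.** With few observations,
  `C_lambda` (and through it each `g_p`) retains substantial posterior
  spread; `xi` and `K_i` are individually soft everywhere (only their
  ratio matters at field assimilation rates). Credible intervals report
  this honestly; point estimates of soft parameters should not be
  over-interpreted.
* **Vulnerability-curve group summaries depend on the averaging
  convention.** The package averages `K(psi_x)` curves across observations
  and halves the mean curve; published group half-loss figures are close
  for the subshrub and legume groups (−12.1 and −13.8 MPa here) but the
  convention behind the deciduous-shrub figure is not recoverable, so
  half-loss points are reported, not asserted.
* Steady state only: no stomatal kinetics, boundary-layer conductance,
  leaf energy balance, or hydraulic capacitance.
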