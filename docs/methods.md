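# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of the package.

## Intake accounting

Diets are defined by protein:carbohydrate mass parts and a combined
concentration in g/L; the nutrient densities split `concentration/1000`
mg/µL proportionally to the parts, so protein and carbohydrate densities
always sum to the total density (mass balance). Tube-length drops are
converted to volumes by a linear calibration; the default convention
anchors a full tube to the 100 µL dispensed, i.e. slope = 100/L₀ µL/mm and
zero intercept. Slope and intercept are configurable because the exact
standard curve of any given lab is an empirical artefact of its tubes and
graph paper. Evaporation is corrected by subtracting the mean volume loss
of the control tubes of the same diet over the same interval, and the
corrected volume is floored at zero: negative intake is physically
impossible, and raw negative readings are measurement noise. Micronutrients
and dye are identical across diets and ignored in the accounting.

## Response-surface model

For each line × sex dataset the trait and the per-day intakes are
z-standardized (mean 0, sd 1 with the n−1 denominator), and the
second-order surface

    z(trait) = β_P zP + β_C zC + γ_PP zP² + γ_CC zC² + γ_PC zP·zC
               + u_replicate + ε

is fitted by maximum likelihood (statsmodels MixedLM, random intercept per
replicate population). ML rather than REML is used so that per-term
likelihood-ratio χ² tests (full model vs the model with the term removed,
df 1) are valid for fixed effects. Raw polynomial terms of the standardized
intakes are used, not orthogonal polynomials, following the
response-surface tradition in evolutionary nutritional ecology. When the
replicate variance estimates at its boundary (zero) or the mixed-model
Hessian is singular, the fit falls back to ordinary least squares with
replicate as fixed dummies — the same fixed-effects structure — and the
results object records which estimator produced it. Per-day intake is
total intake divided by days lived; DEP is defined as LEP/lifespan, so
DEP × LS = LEP holds by construction.

The total-consumption model is `sqrt(P+C per day) ~ line*sex +
concentration + ratio` with a random intercept on line × replicate; main
effects are tested by LR χ² from the additive model and the interaction
against the additive model (marginality-respecting drops). The P:C ratio
covariate is the numeric mass ratio p/c.

**Replicate nesting.** Replicate populations are nested within selection
line: replicate 1 of the control line and replicate 1 of the selected line
are unrelated populations. Every model that pools lines therefore groups
its random intercept on the line × replicate combination. (In null
simulations, grouping on the bare replicate label inflated the regulation
interaction test from 5% to ~8%.)

## Sequential landscape comparison

Two arms (two lines, two sexes, or one group scored for two traits) are
stacked with a dummy g. Six nested fixed-effects models are built on
z-standardized intakes (pooled scale):

1. `zP + zC`               4. model 3 + `zP²·g + zC²·g`
2. model 1 + `zP·g + zC·g` 5. model 4 + `zP·zC`
3. model 2 + `zP² + zC²`   6. model 5 + `zP·zC·g`

with replicate as a shared 4-level fixed covariate. The linear, quadratic
and correlational blocks are partial F-tests on (1 vs 2), (3 vs 4),
(5 vs 6): F = ((SSr−SSc)/DF1)/(SSc/DF2) with DF2 = n − p of the larger
model. Residual sums of squares come from the fixed-effects fits because
residual SS is not well defined under a mixed model, and the printed
comparison tables in this literature are consistent with classical partial
F-tests. Significant blocks trigger univariate follow-ups: each nutrient's
group interaction is tested alone by an LR χ² (df 1).

**Group main effect and degrees of freedom.** By default every model also
carries the group main effect, so that a mean difference between arms is
absorbed there rather than leaking into the interaction blocks; with 600
stacked flies the three blocks then have DF2 = 591, 587, 585. The
historical parameterization in this literature omits the main effect and
yields DF2 = 592, 588, 586; it is available as `group_main_effect=False`.
Null simulations (identical surfaces, 2000 seeds) show the default is
calibrated at the nominal 5% for all three blocks, while the
no-main-effect variant inflates the linear block whenever arm means differ
by chance.

**Response standardization scope.** For two-group comparisons of one trait
the response is z-scored over the pooled set (`response_scope="pooled"`);
the partial F-statistic is invariant to a common affine rescaling, so this
choice does not perturb calibration. When two differently scaled traits
are compared (lifespan in days vs eggs/day), each trait must be z-scored
on its own (`response_scope="arm"`, the automatic choice in trait mode).
Fixing each arm's sample variance to 1 makes the quadratic block mildly
conservative (≈2.5% observed at a nominal 5%); this is inherent to
comparing traits on per-trait z-scales and is the direction of error that
does not produce false positives.

## Thin-plate-spline landscapes

Landscapes are fitted to untransformed trait values over raw mg/day
intakes (the data scale a reader sees), deliberately different from the
standardized scale of the parametric models. The thin-plate smoothing
spline minimises `Σ(yᵢ − f(xᵢ))² + nλ J(f)` with the r²log r kernel;
coordinates are standardized internally for conditioning. The solver
reduces the penalised system to the penalty's range space by QR and
eigendecomposes it once, after which the GCV score
`n·RSS(λ)/tr(I−A(λ))²` is evaluated over a 61-point log-spaced grid
(10⁻⁹…10³ on the standardized scale) and the minimiser taken;
`smoothing=<value>` overrides. Affine surfaces lie in the penalty null
space and are reproduced exactly at any λ. The roughness `cᵀKc` is
strictly decreasing in λ (checked as a property test).

Predictions are reported on a grid (default 100×100 over the intake
bounding box) masked to the convex hull of the observed intakes —
landscapes are not extrapolated beyond where animals actually ate. The
optimum is the masked-grid argmax, ties broken toward lower protein then
lower carbohydrate, refined by Nelder–Mead on the spline (rejecting steps
outside the hull, xatol 10⁻⁴). A flat landscape (relative range ≤ 10⁻¹²)
warns and returns the intake centroid.

The optimum region is a case-resampling bootstrap: flies are resampled
with replacement B ≥ 200 times, the spline refitted at the original λ
(floored at 10⁻⁷ so duplicated rows keep the system well posed), and the
grid argmax recorded; the region is the smallest set of grid cells by
bootstrap-count rank covering the central (1−α) mass, always including the
point optimum's cell. More than 10% refit failures raises. This replaces
package-specific confidence-region constructions with a documented,
assumption-light bootstrap of the argmax.

## Dietary-choice analysis

"Feeding at random" assigns half the total consumed volume to each tube of
the pair ("equal amounts" is read as equal volumes — the foods are liquids
dispensed and measured volumetrically); expected P and C follow from each
diet's densities, and `expected_P + expected_C = V/2·(c_A+c_B)/1000`
exactly. Observed minus expected intake is tested against zero per
nutrient by a two-sided one-sample t-test (the per-nutrient choice is a
design decision; an all-zero difference vector returns t = 0, p = 1).
Preference is classified from the sign of significant differences. The
regulated intake point is the mean cumulative (P, C) over all flies of a
group across all diet pairs, reported as a 1:x ratio at one decimal; a
zero mean protein intake flags an infinite ratio. Group comparisons fit
`C ~ P × group` with a line × replicate random intercept by ML and report
LR χ² (df 1) for the covariate, the factor (both from the additive model)
and the interaction (full vs additive); a significant interaction means
the defended blend differs.

## Synthetic-data generator

The generator reproduces the two experimental designs exactly: the
no-choice design (15 diets × 2 lines × 4 replicates × 2 sexes × 5 flies =
1200) and the choice design (4 diet pairs × [4 control + 3 selected]
replicates × 2 sexes × 5 flies = 280, a fixed 16-day window read every 4
days, no deaths before day 16). A fixed seed gives byte-identical tables.

No-choice intake: each fly draws one daily feeding volume, lognormal
(mean-one parameterization, σ = 0.35) around a diet-specific mean of
55 µL/day at 180 g/L scaled by `(180/conc)^0.45` — compensatory feeding on
dilute diets — times line and sex factors (selected line 1.15, males 1.10)
that emulate the reported consumption differences. Realized intakes thus
spread along each diet's rail. Lifespan is gamma-distributed (sd 8 days)
around the true surface value at the fly's per-day intake, floored at 2
days and recorded in whole days; female egg counts are negative binomial
(dispersion 8) per 6-day dish with daily mean from the DEP surface, so
LEP emerges as DEP × lifespan; 2% of flies are flagged as non-natural
deaths; replicate effects are additive normal shifts. Default true
surfaces are concave, carbohydrate-dominant quadratics with peaks at the
reported per-trait optima (e.g. control females: 0.21 mg/day protein, 24.2
mg/day carbohydrate for lifespan); the selected line's DEP surface is
protein-linear with no interior peak.

Choice intake: tube volumes are the exact solution of the 2×2 mixing
system taking expected cumulative intake to the group's target point (the
reported mean intakes per line and sex); unreachable targets project onto
the pair's reachable cone by non-negative least squares and are logged.
Interval volumes add mean-one lognormal noise (σ = 0.25), and replicate
shifts perturb the carbohydrate target.

**What passing tests do and do not show.** The generator shares the real
experiments' design structure, rail geometry, positive/overdispersed trait
distributions and replicate structure, but its surfaces are exactly
quadratic, its noise is exactly gamma/negative-binomial/lognormal, and
flies neither age in their feeding rate nor interact. Recovery and
calibration results therefore validate the estimators under the stated
model, not the biology of any particular dataset; published coefficient
tables and optima depend on unreleased raw data and are matched only in
sign structure and design constants, never numerically.

## Numerical choices and degenerate inputs

- z-standardization uses the n−1 denominator; constant or singleton groups
  raise an error naming the group.
- Surface fits require ≥10 rows, ≥2 replicates, and a design-matrix
  condition number below 10¹⁰ (all flies on one rail is rejected).
- LR statistics are floored at 0; mixed-model refits that lose the
  pinned estimator fall back to a consistent OLS pair for that term.
- The comparison's model matrices are rank-checked; unbalanced designs
  that cannot estimate an interaction raise rather than silently drop it.
- The partial-F routine rejects SSc > SSr (misordered models) and
  SSc ≤ 0.
- Landscape fits require ≥20 points spanning ≥3 rails and a 2-D intake
  cloud (second singular value bounded away from 0).

## Known limitations

- The quadratic-surface and landscape stages assume per-day intake is
  constant over life; time-varying feeding is out of scope.
- The sequential comparison treats replicate labels as a shared 4-level
  factor in the fixed-effects models (as the printed degrees of freedom in
  this literature imply); a fully nested replicate parameterization is
  available only through the mixed-model stages.
- The bootstrap optimum region fixes λ at the original GCV choice;
  re-selecting λ per replicate would widen regions slightly at a ~60×
  runtime cost.
- The default generator does not emulate a positive quadratic protein
  effect (a trough) for control-female lifespan; concave defaults keep
  the optimum-recovery oracle well defined.
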