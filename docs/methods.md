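# Methods

This note documents the models and procedures implemented in
`savanna_carbon`, the assumptions behind them, the design of the
synthetic-data generator, and the numerical choices that matter.

## Carbon accounting

### Aboveground woody carbon

The inventory records one row per woody individual with growth form
(`adult_tree`, `subadult`, `gulliver`, `shrub`), size parameters, and
per-agent biomass-loss fractions. Two allometric models convert size to
aboveground biomass:

* **Adult trees** (basal stem diameter ≥ 5 cm): `AGB = a·(ρ·D²·H)^b`,
  with ρ the species' specific wood density (oven-dry mass over fresh
  volume, g/cm³), D the largest stem's diameter at breast height (cm;
  taped circumferences are converted by D = c/π at ingest) and H the
  height (m). Defaults a = 0.0673, b = 0.976 are the widely used
  pantropical moist-forest coefficients; they are configuration, not
  constants.
* **Shrub-like forms**: `AGB = c·CA^d·H^e` with crown area CA from two
  perpendicular crown diameters treated as an ellipse. Published
  coefficients for the cited crown-area models differ between floras and
  are not reproduced here; the shipped defaults (c = 0.65, d = 0.96,
  e = 0.89) are synthetic placeholders of realistic magnitude and must be
  replaced for real inventories. Subadults use the shrub model by
  default (configurable); they share the shrub compartments and the fixed
  shrub RS ratio.

AGB converts to carbon with species-wise wood carbon fractions
(validated to (0.3, 0.6)). The allometric estimate of a measured
(damaged) individual is its *actual* AGC; the recorded per-agent loss
fractions are interpreted as fractions of pre-disturbance biomass, so the
pre-disturbance stock is recovered by division:
`AGC_pre = AGC_actual/(1 − Σ losses)`. The total loss is capped at 0.99
to keep the extrapolation finite on degenerate input.

### Belowground woody carbon

Root:shoot ratios: `RS = 1.89208·D^(−0.43491)` for adult trees (strictly
decreasing in stem size; it crosses the fixed shrub value once, near
D ≈ 0.74 cm, i.e. all real trees sit below it), and RS = 2.16 for
shrub-like forms. BGC is computed from carbon, not biomass, which assumes
equal root and shoot carbon fractions. The damage rule: for losses ≤ 30%
roots are assumed intact (`BGC = RS·AGC_pre`, the boundary belongs to
this branch); for losses > 30% (gullivers) BGC is the mean of
`RS·AGC_pre` and `RS·AGC_actual`, i.e. the midpoint of the no-dieback and
full-proportional-dieback bounds. The documented discontinuity at the
threshold is intentional; BGC always lies within those bounds.

### Per-hectare scaling and compartments

Each individual contributes `(kg C/1000)·(10000/subplot area)` t/ha
through the expansion factor of the subplot its growth form was recorded
on (100 m² for small individuals, intermediate areas for other forms, the
whole plot for adults). Stocks are summed per plot into tree AGC, tree
BGC, shrub AGC and shrub BGC; with topsoil and subsoil SOC these form the
six compartments, and AGC + BGC + SOC = C_total. Plots whose largest-stem
DBH exceeds 60 cm (strictly) are flagged as carrying a methuselah — an
old-growth tree that has escaped the fire, browser and woodcutting traps
— and the flag enters the driver models as a binary predictor.

### Soil organic carbon

Layer stocks follow `SOC = conc·bd·depth/10` per depth class
(thicknesses 10/10/10/20/20/30 cm, totalling 100 cm); topsoil is the
0–30 cm sum and subsoil the 30–100 cm sum. Hand-auger cores that stop at
50 cm get their 50–70 and 70–100 cm *stocks* (not concentrations — the
stock is the aggregated quantity) imputed as the arithmetic mean of the
corresponding stocks on neighbouring plots. "Neighbouring" is implemented
as all plots sharing land-use and vegetation type (no distance rule is
defined); imputed plots are flagged in the output. Plot SOC is the
cover-weighted mean over the sampled patch types (under tree canopy,
between trees, bare soil); covers of unsampled types are renormalised
away. No equivalent-soil-mass or carbonate correction is applied (the
target soils are carbonate-free sands), and auger diameter does not enter
beyond the measured bulk density.

## Disturbance-regime scoring

Each agent (browsing, fire, woodcutting) is rated 0–5 in 0.5 steps per
layer (overstorey > 3 m, understorey ≤ 3 m) and recency class (> 2 y,
≤ 2 y). Agent intensity is the sum of the four components (0–20);
browsing is kept separate per layer (0–10 each) because overstorey
browsing is predominantly elephant impact while understorey browsing
aggregates all other browsers. Herbivore species density indices (0–10)
are summed within guilds (13 wild grazers/mixed feeders, 3 domestic, 1
mega-browser, 2 other browsers; the membership table ships with the
package). Scores are ordinal but treated as quasi-numerical downstream —
a deliberate modelling choice, with sums of on-grid ratings staying on
the 0.5 grid. Damage shares per agent and land use are computed from
living individuals' loss fractions only; the plot-level ratings
additionally encode dead individuals and are carried as a separate,
unreconciled channel.

## Driver models

The additive-model engine (`gamm.py`) implements:

* **Basis**: low-rank thin-plate regression splines per predictor
  (radial basis r³/12 at the observed covariate values, eigen-truncated
  to k = 9 components; knots are subsampled only above 2000 unique
  values). The thin-plate constraint removes the polynomial span from the
  wiggly part; the constant is dropped for identifiability, leaving k−2
  penalized coefficients plus one unpenalized linear coefficient. Basis
  columns are standardized to unit RMS so the penalty and X'X live on
  comparable scales.
* **Double penalty**: each smooth carries its wiggliness penalty plus a
  second penalty on the null space of the first (the linear direction,
  plus any degenerate directions left by eigen-truncation). This lets
  REML shrink an uninformative smooth to ~0 effective degrees of freedom.
* **Tensor interactions**: products of the constrained marginal bases
  (k = 5 per margin), which exclude the marginal main effects from the
  interaction space; one penalty per margin plus a joint null-space
  penalty. The two shipped interactions are fire × overstorey browsing
  and fire × understorey browsing (configurable).
* **Random term**: the grouping factor (vegetation type) enters both as
  an unpenalized parametric contrast and as a ridge-penalized random
  intercept; the penalty resolves the apparent confounding.
* **Smoothness selection**: Gaussian/identity REML with the error
  variance profiled out; the criterion
  `(n−M_p)[log(2π D_p/(n−M_p)) + 1] + log|X'X+S| − log|S|₊` is minimized
  over log smoothing parameters by L-BFGS-B (bounds ±12/+22, a small
  ridge of 1e-10 stabilizes the Cholesky factor). Non-convergence is
  surfaced as a warning and recorded on the fit. Per-term edf is the
  trace of `(X'X+S)⁻¹X'X` restricted to the term's coefficients; smooth
  p-values are approximate Wald tests at rank ⌈edf⌉ and should be read as
  descriptive.

On identical data this engine reproduces R mgcv (`gam(..., select=TRUE,
method="REML")`) per-term edf and deviance explained to within a few
percent, including the occasional chance retention of a null predictor.

**Predictor selection** uses a greedy pairwise Spearman filter
(|ρ| < 0.75; from the worst pair, the member with the higher mean
absolute correlation is dropped — the threshold is specified, the
algorithm is a package choice) and a standardized PCA for descriptive
overviews. **Group comparisons** use Games-Howell (pair SE from the
unpooled variances, Welch–Satterthwaite df, studentized-range reference
with k groups; at k = 2 it reduces exactly to the two-sided Welch t) and
Bartlett's variance test; damage shares use one-way ANOVA with Tukey HSD
and a compact letter display. **Relative predictor importance** is
hierarchical partitioning: the Shapley value of each predictor's gain in
deviance explained over all 2^p predictor subsets (exhaustive up to
p = 10; terms not being partitioned form a base model present in every
subset fit; tensors enter only when both margins are present). Negative
averages are floored at zero with a warning; raw shares sum exactly to
the full model's gain over the base model.

## Synthetic-data generator

The generator emulates the study design end-to-end: 2 vegetation types ×
land-use types L/M/H/R/A with 10/10/10/6/6 plots each (84 plots), 1000 m²
plots (agricultural plots get variable field-sized areas). One latent
disturbance intensity per plot drives both the per-individual losses and
the plot ratings — the two channels the field protocol records
separately; their joint distribution is a package choice since only the
marginals are constrained.

* **Losses**: per individual, a Beta-distributed total loss (mean rising
  with latent disturbance, concentration 4, capped at 0.95) split across
  the five agents by a Dirichlet draw whose mean equals the land-use
  agent mix. The default mix is anchored to the damage-share gradients of
  the study design: elephant share 31% (L) → 78% (H), 7% (A);
  woodcutting 2% (L) → 58% (A); fire maximal at L (61%) falling to 14%
  (H). Expected damage shares therefore equal the mix by construction.
* **Stand structure**: lognormal DBH per vegetation type with height
  from a power law of DBH (a standard forestry assumption), denser and
  taller in woodland savanna. Expected plot AGC follows programmed
  additive partial effects of the realised scores — a symmetric unimodal
  bump in overstorey browsing (amplitude 2.8 t/ha, peak at 4.0 on the
  0–10 scale, width 2.2), linear decline in understorey browsing, a
  depletion curve in woodcutting, a unimodal wild-grazer effect, linear
  soil-N and CEC effects, and exactly zero effect of fire intensity and
  domestic-grazer density (the designated null predictors). Baselines
  (6.0/9.7 t/ha) are set so realized reference-plot means match the
  study's stated L-plot means (7.1/10.9 t/ha). Individual counts are
  Poisson with expectation calibrated so the allometric pipeline
  reproduces the programmed expectation; the resulting integer-count and
  size noise (≈ 2 t/ha per plot) is the realistic sampling error of plot
  inventories. Rare methuselah trees (65–75 cm DBH) occur mainly at the
  high-disturbance ends of both pathways, where the study located its
  outlier plots.
* **Soil**: per-plot surface concentration calibrated (through the
  depth-decay profile, bulk densities near 1.45/1.74 g/cm³ and the
  cover-weighted patch multipliers) to per-land-use SOC totals that rise
  under anthropogenic use; concentrations decay with depth; ~20% of cores
  are 50-cm hand-auger cores requiring imputation. Sand content is drawn
  near 93 ± 4%.
* **Reproducibility**: a seed is mandatory; one RNG stream per table is
  spawned from it, so adding a table never perturbs the others, and a
  fixed seed yields byte-identical CSVs. The programmed truth (partial
  effect parameters, the numeric peak location, per-plot expected stocks)
  is returned as a `GroundTruth` record that the pipeline never reads.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial structure and autocorrelation between
plots; temporal dynamics and fire spread; measurement error in ratings
and size parameters; multi-stemmed adults (one stem per tree); dead
standing biomass; interactions between disturbance agents in the
response (the programmed truth is additive, so the tensor terms should —
and do — shrink to zero on generated data); and any vegetation-type ×
disturbance interaction, which keeps the additive Gaussian model
well-specified. Because the truth is additive while the real study's
relative declines are closer to multiplicative, the generated
percent-changes along the pathways are qualitatively right (steeper
toward agriculture than toward high elephant density) but shallower than
the field estimates.

## Numerical choices and degenerate inputs

Loss fractions outside [0,1] or sums above 1 are rejected; zero subplot
areas, non-positive design counts, off-grid ratings, unknown growth forms
or guilds, constant predictors, and missing un-imputed depth classes all
fail fast with diagnostics. Zero total damage makes agent shares
undefined (reported missing, not zero); zero AGC makes the
belowground:aboveground ratio undefined (NaN). The Monte-Carlo
Games-Howell calibration precomputes studentized-range critical values on
a 160-point log-spaced df grid and interpolates — the interpolation error
is far below the Monte-Carlo error at 10⁴ replicates.

## Problem sizes

The shipped tests and the acceptance script use the study-scale
configurations throughout: the 84-plot design for pipeline checks, a 5×
replicate (n = 420) for smooth recovery (20 replicates for the shrinkage
rate), 10⁴ Monte-Carlo replicates for the familywise-error calibration,
10⁵ random individuals for the BGC bound check, and 10³ cores for the SOC
oracle. Hierarchical partitioning is exercised exhaustively at p = 3
(2³ subsets) against an independent orderings-based oracle.

## Known limitations

The smooth p-values are approximate (Wald at integer rank) and
intentionally secondary to edf-based shrinkage; the compact letter
display is a greedy heuristic (adequate for plot annotation, not a
partition-optimal display); the engine supports the Gaussian/identity
family only — the family the driver analysis specifies; and REML
shrinkage selection retains, in a minority of replicates, ~1–2 edf of
chance structure on a truly null predictor at n = 420 (the reference
implementation reproduces this behaviour on identical data).
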