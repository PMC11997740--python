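# savanna-carbon

Whole-ecosystem carbon accounting for disturbance-prone savannas, with a
nonlinear driver analysis. The package implements the full chain from a
woody-plant inventory and soil cores to per-plot carbon stocks in six
compartments, disturbance-regime scores, and penalized additive mixed
models of carbon drivers — and ships a synthetic-data generator that
emulates an 84-plot land-use-gradient study so every stage is testable
without field data.

## Who this is for

Ecosystem ecologists and carbon-accounting practitioners working in
savannas and other dryland systems, where standard forest inventory
protocols break down: woody plants are damaged by elephants, fire,
browsing and woodcutting; shrub-like and stunted growth forms carry a
non-trivial share of carbon; root systems are disproportionately large;
and soil carbon varies strongly between vegetation patch types.

## The accounting model

**Aboveground carbon (AGC).** Individuals are measured per growth form.
Adult trees use a pantropical allometry

    AGB [kg] = a · (ρ · D² · H)^b            (default a = 0.0673, b = 0.976)

with specific wood density ρ (g/cm³), breast-height diameter D (cm) and
height H (m); shrub-like forms (shrubs, gullivers, subadults) use a
crown-area × height power law `AGB = c · CA^d · H^e` (coefficients are
configuration — replace the defaults with a locally calibrated set). AGB
converts to carbon by species-wise wood carbon fractions. Per-agent
biomass-loss fractions (elephant, other browsers, woodcutting, fire,
other) recorded on every individual allow extrapolating pre-disturbance
carbon: `AGC_pre = AGC_actual / (1 − loss)`.

**Belowground carbon (BGC).** Root:shoot ratios are size-dependent for
adult trees,

    RS = 1.89208 · D^(−0.43491)

and fixed at RS = 2.16 for shrub-like forms. Undamaged and slightly
damaged individuals (loss ≤ 30%) get `BGC = RS · AGC_pre`; heavily
damaged gullivers (loss > 30%) get the mean of the pre-disturbance
maximum and post-disturbance minimum, `(RS·AGC_pre + RS·AGC_actual)/2`,
approximating partial root dieback.

**Soil organic carbon (SOC).** Per core and depth class
(0–10/10–20/20–30/30–50/50–70/70–100 cm),

    SOC [t/ha] = C [g/kg] · bulk density [g/cm³] · depth [cm] / 10,

summed into topsoil (0–30 cm) and subsoil (30–100 cm), with missing deep
classes of 50-cm hand-auger cores imputed from plots of the same land-use
and vegetation type, and patch-type cores (under tree / between trees /
bare) weighted by their relative ground cover.

Per plot this yields six compartments — tree AGC, tree BGC, shrub AGC,
shrub BGC, topsoil SOC, subsoil SOC — plus the pools AGC, BGC, SOC and
whole-ecosystem `C_total`.

**Driver analysis.** Plot-level disturbance-regime scores (0–20 per agent
from 0–5 ratings by layer and recency; browsing kept separate per layer,
0–10 each) and herbivore-guild densities enter penalized additive mixed
models (thin-plate regression splines, *double penalty* so that
uninformative smooths shrink to ~0 effective degrees of freedom, REML
smoothness selection, tensor-product fire × browsing interactions,
vegetation type as parametric + random intercept, Gaussian/identity).
Predictor relevance is summarised by hierarchical partitioning of
explained deviance; land-use group contrasts use the Games-Howell test.

## Worked example

One damaged adult tree (D = 22 cm, H = 8 m, ρ = 0.60, carbon fraction
0.47, 25% elephant + 15% fire biomass loss):

```python
import savanna_carbon as sc

ind = sc.WoodyIndividual(
    plot_id="demo", species="Burkea africana", growth_form="adult_tree",
    height=8.0, dbh=22.0, loss_fractions={"elephant": 0.25, "fire": 0.15},
    subplot_area=1000.0,
)
traits = sc.SpeciesTraits("Burkea africana", swd=0.60, carbon_fraction=0.47)
rec = sc.individual_carbon(ind, traits)
```

prints (via the record's fields):

```
actual AGC   61.0 kg C     # allometry on the measured (damaged) size
pre-dist AGC 101.7 kg C    # 61.0 / (1 - 0.40)
RS ratio     0.493         # 1.89208 * 22^-0.43491
BGC          40.1 kg C     # loss > 30%: 0.493 * (101.7 + 61.0) / 2
```

A full simulated study (84 plots, two vegetation types, land-use gradient
L/M/H/R/A):

```python
res = sc.run_pipeline(sc.RunConfig(seed=1, fit_models=True))
res.compartments.groupby(["vegetation_type", "land_use"])[
    ["AGC", "BGC", "SOC", "C_total"]].mean().round(1)
```

```
                           AGC  BGC   SOC  C_total
vegetation_type land_use
scrub           A          1.8  2.4  39.8     43.9
                H          4.9  4.1  33.2     42.2
                L          7.7  7.0  28.3     43.0
                M          7.0  6.8  32.4     46.2
                R          6.4  6.0  36.9     49.3
woodland        A          6.5  6.6  40.9     54.0
                H          8.8  7.5  30.8     47.0
                L         11.5  7.6  26.3     45.4
                M         11.2  8.2  26.6     46.0
                R          8.0  7.0  32.2     47.2
```

Woody carbon is highest at the low-disturbance reference (L) and declines
toward both pathway endpoints (high elephant density H; agriculture A),
while SOC runs the other way — higher under anthropogenic use. The fitted
AGC driver model for this run explains 69.7% of deviance (adjusted
R² = 0.658), retains woodcutting and wild-grazer smooths, and shrinks the
no-effect predictors toward zero edf (`res.gamm_summaries`).

A CLI mirrors the library: `savanna-carbon simulate|carbon|soc|
compare-groups|fit-gamm|partition|report`.

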