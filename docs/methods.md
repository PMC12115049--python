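# Methods

## Scope and data model

The package analyzes paired soil–plant surveys: a soil table and a
plant table share `sample_id`, each carrying one concentration column
(mg/kg dry weight) per metal — by default the seven-metal panel Cr,
Cu, Zn, Cd, Pb, Hg, As. Coordinates are planar kilometres in a
projected frame; distances enter the analysis only as random-forest
features, so no geodesy is performed. Reference values (regional
geochemical background B, plant standard limits, Hakanson toxicity
coefficients T, risk-screening values) travel in a YAML `ReferenceSet`
and every metal present in a table must have an entry there.

## Pollution indices

Single-factor index P = C/B; Nemerow composite
NIPI = sqrt((P_ave² + P_max²)/2), where P_ave and P_max are formed
from the survey mean and maximum concentration of each metal;
Hakanson single-metal risk E_r = T·P, and RI as the sum of E_r values.
`aggregate_ri` is axis-agnostic: summing across metals gives a
sample's composite risk; summing a metal's per-sample E_r over the
survey gives the per-metal risk total reported by `index_report`.

Classification schemes are configurable ordered threshold→label maps.
Defaults are the standard ones: Nemerow classes Safe (≤ 0.7), Alert
(0.7–1], Light (1–2], Moderate (2–3], Heavy (> 3) with right-closed
intervals; Hakanson E_r classes at 40/80/160/320 and RI classes at
150/300/600 with right-open intervals. Toxicity coefficients default
to the canonical Hakanson values (Cd 30, Hg 40, As 10, Pb 5, Cu 5,
Cr 2, Zn 1); alternative mappings can be supplied through the
`ReferenceSet`.

## Soil–plant transfer

BCF = C_plant/C_soil on matched pairs (whole above-ground tissue vs
paired 0–20 cm topsoil; no root/shoot partitioning). The species mean
is the arithmetic mean of per-sample BCFs; the cross-species mean is
the **unweighted mean of species means**, not the pooled per-sample
mean — the two differ when group sizes differ, and published
cross-species values follow the former convention. Pairs with zero
soil concentration are excluded with a warning.

Correlation matrices are Pearson r between every plant-metal and
soil-metal column, computed per species over that species' pairs only
(minimum 3); zero-variance columns yield missing entries with a
warning. Group differences use a Kruskal–Wallis omnibus test per
metal across species, followed (when p < 0.05) by pairwise
Mann–Whitney tests with Bonferroni adjustment; both raw and adjusted
p-values are reported because adjustment conventions vary between
studies. Comparisons against reference values use the one-sample
Wilcoxon signed-rank test. Rank-based tests were chosen as robust
defaults for the small per-species groups (n ≈ 6–14) typical of such
surveys.

## APCS-MLR receptor model

Standardization Z = (C − mean)/sd (sample sd) forces the PCA onto the
correlation matrix. Components are ordered by descending eigenvalue,
sign-flipped so each component's largest-magnitude loading is
positive, and retained by the Kaiser criterion (eigenvalue > 1); the
retained count q is data-driven, never forced. Loadings are
eigenvectors scaled by sqrt(eigenvalue), so the full loading matrix
reconstructs the correlation matrix exactly and the eigenvalue trace
equals the number of metals — both asserted in tests. No factor
rotation is applied by default; the loadings are raw principal
components.

Unit-variance component scores AZ = Z·S use score coefficients
S = loadings/eigenvalue. The absolute score subtracts the score of an
artificial sample whose concentrations are all zero
(Z0 = −mean/sd): APCS = AZ − A0, which makes the APCS of a true
all-zero sample exactly the zero vector and anchors scores at a
physically meaningful origin. Per metal, OLS of concentration on the
APCS columns yields an intercept b0, slopes b_j, and R²; the design
is rejected when its condition number exceeds 1e8.

The contribution accounting (the model's output quantity) follows the
standard Thurston-style convention: the mean contribution of
component j to metal i is b_ij · mean(APCS_j), the unidentified
contribution is b0_i, and percent shares normalize absolute values so
each metal's row sums to 100. Absolute values guard against the sign
indeterminacy of regression-based apportionment; shares therefore
measure attribution magnitude, not signed flux.

## Random-forest apportionment

Features encode source influence rather than raw distance:
exp(−d/λ) with d the Euclidean distance to a source point or the
nearest point of a source polyline, λ = 10 km by default. Forests use
500 trees, sqrt(p) features per split, bootstrap with OOB scoring,
and a 70/30 train/test split stratified by species (default seed 42);
all of these are configuration keys. Metrics: R² = 1 − SS_res/SS_tot,
RMSE, MAE, and RPD = sd(obs, n−1)/RMSE on each split (a perfect fit
reports RPD = inf). Importance shares are impurity-based feature
importances normalized to 100%; a fully uninformative forest falls
back to equal shares.

## Synthetic survey generator

The generator is the statistical stand-in for the study's unreleased
raw data; it defines the conditions under which the pipeline's
recovery properties are demonstrated. Soil concentrations are a
geogenic background draw plus distance-decaying source terms under
mean-one multiplicative log-normal noise; plant concentrations apply
species-specific transfer factors plus an optional additive
atmospheric deposition term (used for Hg, whose above-ground content
is partly decoupled from soil), again under log-normal noise.
Log-normal noise (default sd 0.2 on the log scale for both media) was
chosen because trace-metal concentrations are strictly positive and
right-skewed. Ground-truth shares are defined on the noise-free
mixture — the estimand the apportionment methods target — and the
background counts as its own geogenic share.

The default `kalamaili-like` preset emulates a 36-sample arid-steppe
survey: four shrub species with counts 9/7/6/14, a 36 × 36 km domain,
two factories (points, decay 8 km) loading Cr/Cu/Zn/Cd/As and Hg on
one of them, and three traffic corridors (polylines, decay 6 km)
loading Pb — one highway carrying most of it — plus minor Zn/Cu on
the railway. Design choices that matter and why:

- **Counts 9/7/6/14.** The emulated survey reports species counts
  9/7/6/12 alongside a 36-sample total; those counts sum to 34, so
  the preset absorbs the discrepancy in the largest group.
- **Source geography.** Factories sit on the west side (an
  x-varying intensity field) and the traffic corridors run east–west
  across the north (y-varying fields). On a bounded domain two
  proximity fields can never be fully independent, but this
  arrangement keeps the factory and road families close to
  uncorrelated under uniform sampling, which is what makes a
  36-sample survey informative about two source families at all.
- **Emission profiles.** Road emissions are Pb-dominated (with minor
  railway Zn/Cu) rather than spread across many metals: a road factor
  shared with the factory metals would be inseparable from the
  industrial factor at this sample size. Magnitudes and background
  means were set so that simulated survey means and coefficients of
  variation track the emulated study's soil summary table for most
  metals; soil Pb ends more variable than that table reports because
  a resolvable Pb gradient is a precondition for recovering the
  traffic source.
- **Transfer factors.** Species-specific values reproduce the
  published per-species BCFs for Cr, Cd (and approximately Hg), and
  the published cross-species means otherwise. Pb transfer is
  species-uniform (0.125, the published cross-species mean): strongly
  species-patterned Pb uptake is statistically confounded with the
  Cr/Cd species pattern and would route Pb onto the species
  component of the PCA, an identifiability artifact rather than a
  property of the methods.

What the generator does **not** emulate: geochemical speciation, soil
pH/organic-matter covariates, spatially correlated background fields,
temporal dynamics, censored values below detection limits. Passing
recovery tests therefore show that the estimators are correct and
well-behaved under a clean mixture-plus-noise model, not that any
particular real survey is this well identified.

## Recovery diagnostics

Receptor-model components are anonymous; to compare them against the
generator's ground truth, each retained component is mapped to the
source family (factory vs road) whose true noise-free intensity field
its scores track best, requiring |r| ≥ 0.3 and a 0.1 margin over the
runner-up — components failing both (species-uptake or noise
components, or general components mixing families) stay unassigned.
Family shares sum the contribution percentages of the components
assigned to each family. On the default preset over seeds 0–19, the
pipeline attributes Cd to the factory family in 20/20 seeds and Pb to
the road family in 17/20, the forest ranks the true dominant Pb
source first in 19/20, and at least six of seven metals achieve
regression R² > 0.5 in 17/20 — the acceptance suite asserts these at
the 80% (and 18/20 for the forest) level. Problem sizes throughout
are the survey's own: 36 samples, 7 metals, 5 sources, 20 seeds.

## Numerical notes

- Degenerate inputs fail loudly: zero-variance metals in
  standardization, constant targets in forest fits, constant observed
  vectors in evaluation, empty risk vectors, non-positive reference
  values.
- Correlation-matrix eigenvalues are clipped at zero when numerically
  negative; rank deficiency triggers a warning, not an error.
- Kruskal–Wallis on all-identical pooled values is reported as p = 1
  (no evidence of difference) rather than an error.
- All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; soil and plant stages draw from
  distinct child streams so either can be regenerated independently.
- The RPD of a perfect prediction is reported as `inf` rather than
  capped; consumers should treat non-finite RPD as "error-free fit".

## Known limitations

The contribution accounting's absolute values mean shares cannot
distinguish a source that adds metal from one whose coefficient is
negative through collinearity. Kaiser retention on seven metals can
fluctuate between q = 1 and q = 3 near eigenvalue 1, which is the
main failure mode of family recovery at n = 36. The random-forest
split protocol (70/30, species-stratified) is one reasonable choice
among several; OOB R² is reported alongside to expose sensitivity.
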