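# metalsource

Heavy-metal pollution assessment and source apportionment for paired
soil–plant surveys, aimed at environmental scientists working on trace
metals in arid and semi-arid ecosystems: given a soil table and a
plant table paired by sampling site (seven metals: Cr, Cu, Zn, Cd, Pb,
Hg, As), the package computes the standard pollution indices, the
soil→plant transfer statistics, and two complementary source
apportionments — a Thurston-style APCS-MLR receptor model and a
random-forest regression on source-proximity features. A synthetic
survey generator with known source structure makes every stage
testable end to end.

## The statistics at its core

**Pollution indices.** The single-factor index compares a measured
concentration with a regional geochemical background,
*P<sub>i</sub> = C<sub>i</sub>/B<sub>i</sub>*. The Nemerow composite
index blends the survey average and maximum while weighting the worst
pollutant,

> NIPI = √((P²<sub>ave</sub> + P²<sub>max</sub>) / 2),

and the Hakanson potential ecological risk scales the single-factor
index by a per-metal toxicity coefficient,
*E<sub>r</sub> = T<sub>r</sub> · P<sub>i</sub>*, with
RI = Σ E<sub>r</sub> as the composite risk score
(T<sub>r</sub>: Cd 30, Hg 40, As 10, Pb 5, Cu 5, Cr 2, Zn 1).

**Soil–plant transfer.** The bioconcentration factor
BCF = C<sub>p</sub>/C<sub>s</sub> (plant over paired soil
concentration) marks actively accumulating species when > 1; species
summaries average per-sample BCFs within species and then across
species. Pearson correlation matrices between plant-metal and
soil-metal columns, per species, plus Kruskal–Wallis /
Mann–Whitney group tests complete the transfer picture.

**APCS-MLR.** Metals are standardized, a PCA of the correlation
matrix is truncated by the Kaiser criterion (eigenvalue > 1), and
component scores are re-anchored by subtracting the score of an
artificial all-zero-concentration sample (absolute principal component
scores). Each metal is then regressed on the APCS columns; slope ×
mean score gives each component's mean contribution, the intercept an
"unidentified" contribution, and absolute values normalize these into
percent shares per metal.

**Random forest.** Each metal is regressed on one proximity feature
per candidate source, exp(−d/λ) with d the distance to the source
point or polyline; impurity importances, normalized to percent, read
as source influence. Fits are scored by R², RMSE, MAE and the
residual prediction deviation RPD = sd(obs)/RMSE on a held-out split.

## Worked example

Simulate a 36-sample survey with two factories and three traffic
corridors, then run the full pipeline:

```sh
metalsource simulate --seed 3 --out demo
metalsource run --soil demo/soil.csv --plants demo/plants.csv \
    --refs demo/refs.yaml --sources demo/sources.csv --seed 3 --out out
```

The indices stage prints, per metal, the Nemerow index with its class
and the per-metal ecological risk total (sum of per-sample
E<sub>r</sub>):

```
          p_ave     p_max      nipi       nipi_level    mean_er           ri      risk_level
Cr     0.884925  2.056706  1.583214  Light Pollution   1.769849    63.714580        Low Risk
Cd     0.987774  2.345550  1.799626  Light Pollution  29.633233  1066.796388  Very High Risk
Hg     0.436869  1.276081  0.953739            Alert  17.474763   629.091475  Very High Risk
```

Cd and Hg dominate the ecological risk despite moderate Nemerow
values — their toxicity coefficients (30, 40) amplify even mild
enrichment. The BCF stage reports cross-species means

```
Cr    3.309149
Hg    1.147479
Cd    0.930670
Pb    0.123324
```

(Cr and Hg accumulate, BCF > 1; Pb barely transfers), and the
APCS-MLR stage attributes each metal to the retained components:

```
             PC1        PC2  unidentified  regression_r2
Cd     75.519985  18.818192      5.661823       0.778004
Pb     10.024417  74.479353     15.496230       0.666960
```

Here PC1 is the industrial component (it carries Cr, Cu, Zn, Cd, As)
and PC2 the traffic component (Pb, Hg): the simulated factories drive
Cd while the simulated highway drives Pb, which is exactly the planted
ground truth recorded in `demo/truth.json`.

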