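# heni

Dietary human-health impact characterization for food life cycle assessment
(LCA).

Environmental LCA expresses human-health damage in disability-adjusted life
years (DALYs), but the largest health effect of a food is usually eating it.
`heni` quantifies that dietary effect in the same damage-level unit, so
nutrition and environment can be compared and summed on one scale. It is
aimed at LCA practitioners, nutrition modelers, and anyone scoring recipes
or food products for combined health impact.

## The model

For a food delivering amounts *d<sub>r</sub>* (grams per functional unit —
serving, 100 g, or kcal) of each dietary risk component *r* (fruit, calcium,
fiber by source, PUFA, sodium, trans fat, processed meat, …), each amount is
multiplied by a **Dietary Risk Factor** *DRF<sub>r</sub>* (μDALY per gram
consumed; negative = beneficial) and summed:

```
impact [μDALY/FU] = Σ_r d_r · DRF_r
HENI   [min/FU]   = −0.526 × impact
```

The **Health Nutrient Index (HENI)** converts μDALY to minutes of healthy
life gained (positive) or lost per functional unit, using the ≈0.526 million
minutes in a year.

DRFs themselves come from an epidemiological comparative-risk chain, also
implemented here: log-linear relative-risk dose-response curves clamped to
RR = 1 inside the theoretical minimum-risk exposure level (TMREL), a
population attributable fraction PAF = (E[RR] − 1)/E[RR] against the TMREL
counterfactual, and a marginal finite difference of attributable burden
(PAF × DALY/person-year pool) per gram of daily intake. Non-marginal diet
scenarios combine attributable fractions multiplicatively,
1 − Π(1 − PAF<sub>i</sub>), within each disease outcome.

## Worked example

The package bundles a three-ingredient strawberry yogurt (corn syrup,
strawberries, plain low-fat yogurt; one 170 g serving, 127.4 kcal):

```bash
heni demo-yogurt
```

```
strawberry yogurt: 170.0 g, 127.4 kcal per serving
component        d_r [g]     DRF  min (calc)  min (publ)
--------------------------------------------------------
fruit_fiber        0.120   -0.18       -0.01       -0.01
calcium            0.280   -5.15       -0.76       -0.77
pufa               0.080   -0.61       -0.03       -0.02
fruit              5.950   -0.19       -0.59       -0.59
sodium             0.114   13.90        0.83        0.83
trans_fat          0.030    4.44        0.07        0.07
--------------------------------------------------------
total impact -0.93 μDALY/serving → HENI +0.5 min of healthy life gained
beneficial +1.39 min, detrimental −0.90 min
```

Reading: each row multiplies the per-serving amount by its DRF and scales
to minutes (μDALY sign kept, so negative = beneficial). One serving nets
−0.9251 μDALY, i.e. about half a minute of healthy life gained — calcium
and fruit benefits minus ~0.9 min lost mainly to sodium. The `min (publ)`
column shows the published breakdown for comparison; calcium differs by
0.01 min because the published amount is rounded to 0.28 g.

Scoring your own recipe from CSV (component columns in g per 100 g of
ingredient):

```bash
heni score --recipe recipe.csv --drf drf.csv --fu serving --out result.json
heni derive-drf --rr rr.json --intake intake.json --burden burden.csv
heni diet-delta --epi epi.json --scenario scenario.json
```

The result JSON reports per-component μDALY, both minute sign conventions,
uncharacterized components, and run provenance (version, seed, config hash).

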