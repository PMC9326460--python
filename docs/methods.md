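# Methods

## Scope and model

`heni` characterizes the dietary human-health impact of foods per functional
unit (FU: one serving, 100 g, or 1 kcal) and expresses it at damage level in
μDALY, alongside a minute-scale Health Nutrient Index (HENI). The chain has
four stages, each a module:

1. **composition** — ingredient masses and per-gram contents aggregate into
   risk-component inventory flows d_r (g/FU), with declarative
   double-counting exclusions and functional-unit conversion.
2. **characterization** — d_r × DRF_r products, their sum, the minute
   conversion, beneficial/detrimental decomposition, and damage-level
   combination with environmental human-health impacts.
3. **epi_drf** — derivation of marginal DRFs from relative-risk curves,
   TMRELs, intake distributions, and burden rates.
4. **diet_scenarios** — non-marginal diet shifts via multiplicative
   combination of attributable fractions.

The io_cli module supplies readers/writers, the command-line interface, the
packaged strawberry-yogurt worked example, and a seeded synthetic generator.

## Key constants and conventions

* **0.526 minutes per μDALY.** A year holds 525,960 ≈ 0.526 million minutes;
  1 μDALY = 10⁻⁶ year ≈ 0.526 min. Some published descriptions of the
  minute conversion say "seconds", which is dimensionally inconsistent with
  the accompanying numbers (a year has ~31.6 M seconds); the package follows
  the numbers and documents the constant as minutes.
* **Sign conventions.** The canonical internal quantity is μDALY, positive =
  damage. `heni_minutes` applies the leading minus, so positive minutes =
  healthy life gained. Published per-component breakdown tables keep the
  μDALY sign after the ×0.526 scaling; results expose both as
  `per_component_minutes` (gained sign) and
  `per_component_minutes_udaly_sign`, always labeled.
* **All amounts in grams.** SSB amounts are beverage grams (provisional;
  composition sources differ). Fibers are split by source (fruit, vegetable,
  legume, whole-grain, other), each its own component with its own DRF.
* **Exclusion rules** are data, not code: (ingredient-category, component)
  pairs. The default set carries one rule — calcium is not counted for
  fluid-milk ingredients, whose benefit the milk component already captures.
  Yogurt is categorized as `yogurt`, not `fluid_milk`, so its calcium counts.

## Epidemiological derivation

No closed formula for combining relative risks, exposures, and burden rates
is prescribed by the framework this package serves, so the standard
comparative-risk-assessment construction is adopted and stated explicitly:

* **RR curves** are log-linear between knots (relative risks are
  ratio-scale; this is the usual convention for monotone dose-response
  segments), constant beyond the outermost knots, and clamped to RR = 1
  inside the TMREL range [low, high] g/day.
* **PAF** = (E[RR] − 1)/E[RR], with the TMREL counterfactual at RR = 1.
  E[RR] is integrated exactly over the intake distribution: point masses
  evaluate the curve; histograms are piecewise-uniform densities integrated
  by adaptive quadrature split at curve breakpoints (so refining a bin into
  halves leaves the PAF unchanged to ≤1e-12); lognormals integrate
  RR(x)·pdf(x) up to the last breakpoint with the constant-RR tail handled
  analytically.
* **Marginal DRF** = [AB(+δ) − AB(−δ)] / (2δ·365) × 10⁶ μDALY per g, where
  AB = PAF × Σ burden rates (DALY/person-year) and the distribution is
  rigidly translated by ±δ g/day. The 1/365 day→year annualization and the
  DALY→μDALY scaling are explicit so the contract is auditable; whether the
  source method annualizes identically is not recoverable from the material
  this package is built against, so the convention is declared, not
  inferred. Default δ = 1 g/day with a convergence companion at δ/2
  (central differences converge as O(δ²) on smooth curves). Shifts that
  would push intakes negative are clamped at zero and flagged.
* **Stratified DRFs** (by age group and sex) aggregate as a
  population-weighted mean with caller-supplied weights summing to 1.
* This module is validated against closed-form and Monte Carlo oracles. It
  is *not* expected to reproduce the packaged DRF table: those values derive
  from population-scale epidemiological source data that are not bundled;
  they ship as a static fixture consumed by the characterization stage.

## Diet scenarios

For substantial (non-marginal) dietary changes, attributable fractions of
risk factors sharing a disease outcome combine multiplicatively,
1 − Π(1 − PAF_i); outcome-level attributable burdens then add. Burden
entries naming the same outcome must carry identical pooled rates — one
burden pool per outcome — which is this package's declared bookkeeping
convention (the granularity at which whole-diet applications distribute
overlapping outcomes is not specified by the source framework). Distribution
shifting is a rigid translation of mean intake, chosen for transparency over
re-estimating distribution shape. For a single component and small shift δ,
the scenario delta converges to marginal_drf × δ × 365/10⁶; the residual
shrinks linearly in δ because the scenario applies a one-sided shift while
the marginal DRF is a central derivative.

`active_range_report` returns the probability mass outside the TMREL — the
population share for which marginal changes actually alter risk. Marginal
scores should always be read alongside it.

## Worked example and its rounding

The packaged strawberry yogurt (170 g serving: 10 g corn syrup, 6 g
strawberries, 154 g plain low-fat yogurt) stores per-ingredient mass
fractions back-computed from the published per-serving amounts, so the
resolved totals equal the published row exactly: fruit fiber 0.12, calcium
0.28, PUFA 0.08, fruit 5.95, sodium 0.114, trans fat 0.030 g/serving.
Scoring gives −0.9251 μDALY/serving → +0.487 min gained (prints 0.5), with
−0.90 min detrimental (sodium + trans fat). Two cells of the published
breakdown differ from recomputation by 0.01 min (calcium −0.77 printed vs
−0.76 recomputed, PUFA −0.02 vs −0.03): the published calcium input was
≈0.283 g before rounding to the printed 0.28 the fixture stores. The
published "1.5 min gained" for the beneficial side recomputes to ≈1.39 from
the breakdown cells and is treated as source-internal rounding, not a check.

## Synthetic generator

`generate_synthetic(seed, n_ingredients=3, n_components=4)` draws ingredient
masses U(5, 200) g and energies U(1, 300) kcal per serving; each ingredient
carries each candidate component with probability 0.6 at content
U(0, 0.05) g/g; DRFs are U(−6, 15) μDALY/g, spanning the strongest published
beneficial (≈−5.15, calcium) and detrimental (≈+13.9, sodium) factors. The
expected impact is computed by an independent plain summation kept separate
from the pipeline, which is what the determinism and oracle tests compare
against. The generator emulates composition arithmetic only — it does not
emulate correlated nutrient co-occurrence, measurement error, or realistic
category structure, so passing tests certify the arithmetic and plumbing,
not nutritional realism of any particular recipe.

## Numerical choices

* Quadrature: `scipy.integrate.quad`, epsabs 1e-13 / epsrel 1e-12, split at
  knot and TMREL breakpoints; lognormal tails beyond the last breakpoint are
  analytic (constant RR × survival mass).
* Functional-unit conversions route through the serving basis so any pair of
  bases composes and round-trips to ≤1e-12 relative; zero serving mass or
  energy for the requested basis is rejected, not propagated.
* Totals are exact floating-point sums — no renormalization.
* Histogram edges clamped at zero during shifting are kept strictly
  increasing by 1e-12 spacers; the clamped flag reports the event.
* Display rounding is two decimals for minutes, full precision internally.

## Problem sizes

The bundled example is desk-scale (3 ingredients, 6 components; scoring is
microseconds). Property suites run 1,000 generator seeds for the
linearity/permutation checks and 10⁶-sample Monte Carlo oracles for E[RR];
the whole suite completes in a few seconds on one CPU.

## Known limitations

* Epidemiological resolution is coarse: e.g. all fruit grams are equally
  beneficial; substitution effects between foods (eating more of one food
  means less of another) are out of scope.
* DRF values change with epidemiological revisions; the packaged table is a
  fixed worked-example snapshot, not a maintained database.
* Morbidity/mortality splits, uncertainty intervals on epidemiological
  inputs, and midpoint-to-damage conversion of environmental categories are
  not modeled; uncharacterized nutrients are surfaced for midpoint-level
  reporting rather than forced into DALYs.
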