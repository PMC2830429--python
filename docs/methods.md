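# Methods

## Model structure and assumptions

`eacsim` implements a deterministic annual-cycle Markov cohort model of
esophageal adenocarcinoma (EAC) natural history in white men. A closed
cohort enters at exact age 20, entirely in the Normal state, and moves
through the ordered states

Normal → GERD symptoms → Barrett's esophagus (short- or long-segment) →
undetected cancer → detected cancer → death,

with a direct Normal→BE path (a substantial share of BE patients never
report reflux symptoms). Assumptions, chosen for parsimony:

* **No regression.** Probability mass only moves forward in the state
  order; the one-year transition matrix is upper-triangular.
* **BE segment split.** Incident BE divides 1:3 into long-segment (LSBE)
  and short-segment (SSBE) disease; SSBE progresses to cancer at half the
  LSBE rate (a surface-area rationale). Both constants are structural and
  the parameter container rejects other values.
* **Mortality.** Pre-cancer states die at the age-specific all-cause
  probability q(a); both cancer states die at cancer-specific rates. A
  switch (`undetected_all_cause`) lets the undetected state keep all-cause
  mortality instead — the clinically ambiguous alternative — but the
  default follows the source description literally (cancer-specific
  mortality from cancer onset).
* **Competing risks, death first.** Within a cycle the death probability is
  applied first; the annual disease probabilities are then distributed
  among survivors, rescaled proportionally if they would sum above one.
  This makes every row stochastic by construction and is order-explicit.
* **Cycle length one year, no half-cycle correction** — matching the
  granularity at which the transition probabilities are defined.
* **Deterministic expected-fraction propagation** rather than individual
  microsimulation: all reported outputs are population rates, for which
  expectations suffice, and a noise-free likelihood-free calibration is
  orders of magnitude faster.

Two numerically identical propagation paths exist: a transparent
matrix-per-cycle single-cohort reference (`simulate_cohort`) and a
vectorized calendar-year × age grid sweep over all overlapping cohorts
(`PopulationEngine`), used inside calibration where the model is evaluated
tens of thousands of times (~2–3 ms per evaluation for six age groups). A
test asserts their equality to 1e-13 and a matrix-power oracle checks the
constant-rate case to 1e-10 over 60 cycles.

## Parameters

| parameter | meaning | units | default / range |
| --- | --- | --- | --- |
| `p_normal_gerd[g]` | Normal→GERD annual probability per 10-y age group | /yr | calibrated, bounds [0, 0.30] |
| `p_normal_be[g]` | Normal→BE annual probability | /yr | calibrated, [0, 0.005] |
| `p_gerd_be[g]` | GERD→BE annual probability | /yr | calibrated, [0, 0.01] |
| `r_lsbe_ca[g]` | LSBE→undetected-cancer hazard at the 1973 anchor | /yr | calibrated, [0, 0.01] |
| `secular_slope` | per-year increment of the BE→cancer multiplier | /yr | calibrated, [0, 0.25] |
| `mean_sojourn_years` | mean undetected→detected sojourn time | yr | calibrated, [4, 9] |

The secular multiplier is m(y) = max(0, 1 + slope·(y − 1973)); the
detection probability is 1 − exp(−1/T) under an exponential waiting-time
convention (only a mean sojourn time is reported in the literature).

Age dependence is piecewise-constant over the six 10-year groups 20–29 …
70–79 for all four calibrated transitions, including the BE→cancer base
rate. Making that rate age-dependent is a deliberate design choice: with an
age-constant rate, model incidence is forced to be proportional to the BE
prevalence age profile (the undetected pool has only a ~2-year memory), and
the observed incidence gradient across age (0→9.3 per 100,000) is about
three times steeper than the BE prevalence gradient — structurally
unreachable. Cohorts simulated past the oldest group reuse the last group's
rates; reported outputs cover ages 20–79 only.

The calibration bounds above are literature-informed: the BE-inflow
probabilities are capped so lifetime BE prevalence cannot exceed roughly
the top of the published population range (~25%), and the Normal→GERD cap
allows the observed ~20% symptom prevalence to be reached within a few
years of entry. Generous-looking caps are not harmless here: with twelve
BE-inflow coordinates, bounds an order of magnitude above data-compatible
values leave the feasible region in a vanishing corner of the search cube.

## Demographic inputs

All demographic inputs are config-overridable CSVs with strict readers
(unknown columns are rejected loudly). The defaults are synthetic
stand-ins so the full pipeline runs with no external data:

* **Life table** — Gompertz–Makeham, q(a) = 1 − exp(−(A + B·e^{θa})) with
  A = 5·10⁻⁴, B = 3·10⁻⁵, θ = 0.09 /yr: plausible adult male mortality
  (q ≈ 0.002 at 40, 0.017 at 70).
* **Cancer mortality** — 0.35 /yr in both cancer states (EAC survival is
  poor; the sources report no value, so this is an explicit fixture).
* **Population counts** — stationary 1,000,000 men per single year of age,
  making absolute case counts deterministic and interpretable. Absolute
  prevented-case numbers therefore refer to this synthetic population;
  percent reductions are scale-free.
* **Standard weights** — equal weights over the six age groups for
  age-adjusted incidence (the original standard population is not named).
  For *overall* adult prevalence figures the documented default is the
  stationary-demography age distribution (survival-from-20 summed within
  groups), exposed as `stationary_age_group_weights`; census weights can be
  substituted.

## Calibration targets and the synthetic generator

Targets are (endpoint, year, age-group, value) cells with a
calibration/validation role split. GERD and BE prevalence are assumed
constant over calendar time and may carry the year sentinel `ALL`, which
expands to every year of the scoring role (so a constant prevalence carries
per-year weight, mirroring the per-year incidence cells). The built-in
fixture carries the representative-year (1986) age-specific values; a
full-period incidence series can be loaded from CSV.

`generate_synthetic_targets` emulates the statistical structure of the real
calibration data from a known ground-truth parameter set: constant
age-specific prevalences and an incidence series rising linearly through
the secular multiplier, with optional multiplicative mean-one lognormal
observation noise (rates are positive and registry sampling error scales
roughly with the rate). With zero noise and a single target year the truth
scores an exact GOF of zero. What the generator does *not* emulate:
registry-size Poisson noise with age-dependent variance, secular drift in
the prevalence endpoints, cohort (period) effects in mortality, or
reporting/coding artifacts — so passing recovery tests demonstrate the
machinery's self-consistency, not robustness to real-data misspecification.

## Goodness of fit and the search

Fit per endpoint is Pearson-style chi-squared, Σᵢ (Oᵢ − Mᵢ)²/max(Oᵢ, ε)
with ε = 0.5 in the endpoint's own units; the floor exists because the
youngest age group's incidence target is printed as 0.0, where the Pearson
denominator is undefined. Endpoint weights default to 1 and are exposed.

The search is simulated annealing: uniform random start within bounds,
single-coordinate uniform proposals of width 0.1× the bound width reflected
at the bounds, Metropolis acceptance, geometric cooling ×0.95. The starting
temperature (`AUTO`) is the median absolute score difference among 50
random bound-uniform pairs, so initial acceptance is near 50% on any score
scale. Cooling stages default to one per `n_iterations/250` evaluations,
which keeps the whole run on the same ~6-orders-of-magnitude annealing
profile at any budget; a fixed stage length would leave small runs
effectively unannealed. Temperature 0 reduces the algorithm to stochastic
hill descent. Every evaluation (accepted or not) is recorded; identical
seed, bounds and configuration reproduce the evaluation sequence exactly.

### Three-phase procedure

The three endpoints are fitted sequentially (Forward order GERD → BE → EAC
incidence, or Reverse), one full SA budget per phase, with two design
choices where the published description is open:

* **Cumulative phase objectives.** Phase 2 scores GERD+BE and phase 3 all
  three endpoints. With single-endpoint phases the previously fitted
  endpoints drift while later ones are fitted and the final combined
  ranking is inconsistent with the last phase's search; cumulative
  objectives roughly halved the final combined GOF and its seed-to-seed
  variance on the representative-year targets.
* **Endpoint-scoped bound narrowing.** After phases 1 and 2, the min–max
  envelope of the 10% best-scoring sets narrows the bounds of the
  parameters that phase calibrates (phase 1: Normal→GERD; phase 2: the two
  BE-inflow probabilities). Parameters the phase endpoint cannot identify
  keep their bounds: in a converged annealing chain their values freeze at
  arbitrary points, and narrowing all parameters to that envelope
  (the literal alternative) pins later phases to those arbitrary values —
  in experiments it inflated the final combined GOF by three orders of
  magnitude.

After phase 3, all of its evaluations are re-ranked on the combined GOF
and the best `final_fraction` (1%; 1,000 of 10⁵ at full scale) form the
parameter ensemble, ascending by combined score with ties broken by
evaluation order.

### Validation

Hold-out years are scored with the same GOF divided by the number of years
in each period ("adjusted" GOF), averaged over the ensemble; the model
validates when the hold-out value is strictly below 1.5× the calibration
value. The strict inequality resolves the boundary case. Note the ratio is
ill-conditioned when both scores are near zero (perfect fits), which only
occurs on noise-free synthetic data.

## Chemoprevention counterfactual

A five-year cumulative rate reduction R₅ converts to a constant annual
reduction r = 1 − (1 − R₅)^{1/5} (12.945% for the 50% base case), which
multiplies both BE→cancer hazards for every eligible person-year: age ≥ 40
and calendar year ≥ 1960 by default, full adherence, no cessation, and no
modeling of aspirin harms or cardiac benefits. The counterfactual re-runs
every ensemble member with and without the intervention over the reporting
window (earlier entry cohorts provide the pre-window run-in), converts
incidence to absolute cases through the population counts, and reports
per-period prevented cases as ensemble means with min–max ranges. Cumulative
range columns are running sums of the per-period range columns (a bound on,
not the distribution of, member-wise cumulative extremes). The
population-level percent reduction is always below the annual hazard
reduction because pre-existing undetected cancers and pre-eligibility
person-time are unaffected.

## Problem sizes used in the tests

The shipped test suite exercises calibration at reduced scale, chosen to
keep the full suite in single-digit minutes on one CPU while preserving the
procedure's structure: parameter recovery uses 3 age groups, 10 calendar
years and 5,000 SA evaluations per phase over 5 seeds; the
representative-year calibration uses the full 6 groups with 10,000
evaluations per phase (the same size `scripts/acceptance.py` runs). The
full-scale configuration (10⁵ evaluations per phase, 1973–2000 calibration
with 2001–2005 hold-out) is reachable through the same interfaces.

## Known limitations

* **The ensemble understates along-ridge parameter uncertainty.** The
  pre-cancer block is under-identified: six prevalence constraints face
  nine pre-cancer parameters, leaving a ~3-dimensional trade-off manifold
  (e.g. more direct Normal→BE inflow against less GERD-mediated inflow) on
  which the GOF is flat. An ensemble defined as the best 1% of annealing
  evaluations concentrates near the single manifold point the chain
  converged to, so its min–max envelope is a local, not global, uncertainty
  interval — it can exclude the generating truth of a synthetic experiment
  even when the fit is essentially perfect. Ensemble spread and deep
  convergence pull in opposite directions under a best-fraction-by-score
  selection rule; sampling-based calibration (e.g. ABC-style acceptance
  regions) would be the structural fix and is out of scope.
* **Entry at age 20 flattens the youngest GERD cell.** Everyone enters
  symptom-free at 20, so prevalence among 20–29-year-olds is structurally
  below a target that reflects onset earlier in life; with no regression,
  fitting 17.6% at 20–29 would force ≳30% at 30–39. The chi-squared
  optimum under-fits the youngest GERD cell (~10% vs 17.6%) and fits the
  rest, which also pulls the weighted overall GERD prevalence slightly
  below the published overall figure.
* **Overall BE prevalence.** The published age-specific BE curve
  (1.7…5.8%) aggregates to ~3.6–3.7% under any plausible adult age
  weighting; the separately published overall figure of 4.2% reflects the
  age distribution of the source endoscopy studies rather than the adult
  population, and the model — which fits the age-specific curve —
  reproduces the former, not the latter.
* Women, non-white populations, dysplasia states, cancer staging, costs and
  quality-of-life are outside the model's scope by design.
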