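# Methods

This note records the modelling conventions, curation decisions and
numerical choices behind `nutrimpact`, and what the synthetic test
harness does and does not demonstrate.

## The model

The engine belongs to the LiST family of deterministic lives-saved
models: changes in intervention coverage drive health outcomes either
directly (cause-specific mortality, disease incidence, birth outcomes)
or by shifting risk-factor distributions (stunting, wasting,
breastfeeding practices).  Each intervention–outcome pair applies its
effect only to the *affected fraction* — the population slice that can
plausibly benefit, such as the zinc-deficient share of 12–59-month-olds
or the food-insecure share of pregnant women.

**Mortality pathway.**  Baseline cause-specific deaths are assumed to
already include the protection conferred by baseline coverage `c0`.
Deaths averted by a single intervention are therefore
`D·e·a·(c1−c0)/(1−e·a·c0)`: the denominator recovers the
no-intervention envelope before applying the new coverage `c1`.
Interventions sharing a `(cause, age band)` cell combine by residual
multiplication, `D·[1 − Π(1−rᵢc1ᵢ)/(1−rᵢc0ᵢ)]` with `rᵢ = eᵢaᵢ`,
which is commutative, collapses to the single-intervention formula for
one component, and can never exceed the envelope.  The combined total
is attributed to interventions in proportion to their single-
intervention impacts.  Birth outcomes (SGA, preterm, stillbirth,
neural-tube-defect stillbirth) use the same algebra with the envelope
`live_births × outcome prevalence`; they are adverse events averted,
not deaths, and are kept in a separate `birth` band.

**Distribution pathway.**  Odds-ratio pairs act on ordered category
distributions stored as severe-side cumulative probabilities.  The
canonical OR direction is "odds of the adverse outcome *without* the
intervention relative to with it" (values > 1 mean benefit); the
covered slice has its cumulative odds multiplied by the reciprocal of
the canonical OR, applied uniformly at every cut point (a
proportional-odds assumption).  At the population level each cut moves
by `p' = p + a·(c1−c0)·(shifted(p) − p)` — the covered-and-affected
slice shifts, the baseline-covered slice is netted out, and the rest
stays put.  This is a first-order rebasing: it does not attempt to
invert the baseline mixture to recover the never-covered distribution,
which would require knowing how coverage and outcome co-vary.  Multiple
pairs acting on the same distribution contribute additive deltas from
the common baseline, keeping the combination order-independent; a
guard (floor 1e-12, monotone repair of 1e-15) protects the cumulative
ordering against pathological stacked shifts.

**Severity-specific effects.**  Evidence exists that SQ-LNS reduces
severe wasting/stunting more than moderate; the engine nevertheless
applies a single OR at all cuts for the combined categories, which is
the convention currently in use.  The four z-score categories use cuts
at −3, −2, −1 SD.

**What is deliberately not modelled.**  No demographic projection:
population, births and cause envelopes are per-year inputs held fixed
across scenario years, so multi-year results isolate the coverage
signal.  No anthropometry→mortality or breastfeeding→mortality
cascade: those relative-risk tables live elsewhere in the model family
and are not parameterised here; `run_scenario` exposes a
`mortality_rr_hook` so a user can close the loop with their own table.
No acute-malnutrition treatment, and no maternal-anaemia→mortality
linkage.  Coverage decreases are permitted and yield negative
"averted" values, flagged in the result's warnings.  Negative point
efficacies (sources with RR > 1) are preserved in the registry but
clamped to zero with a logged warning inside the engine: absent an
explicit harm model, a beneficial-intent intervention never adds
deaths.

## The parameter registry

The bundled `pairs.tsv` holds 45 effect rows grouped into 34 pairs by
`pair_id`; grouping choices are part of the curation:

* delivery-channel variants (infant and young child feeding education:
  health system / home–community / combined ORs) sit under one pair per
  practice outcome;
* target-group variants (iron fortification vs maternal anaemia for
  women of reproductive age and for pregnant women) are one pair;
* odds-ratio orientation variants (complementary-food provision quotes
  an OR both "with" and "without" the intervention) are one pair — the
  engine uses the "without" (canonical) variant and stores the other;
* sub-outcome variants (folic acid vs neural-tube-defect mortality,
  quoted separately for stillbirths and neonatal deaths) are one pair.

This yields the published accounting: 34 pairs, 25 of them pre-existing
and 9 new, from 14 interventions (6 women-facing, 8 child-facing).
Source anomalies are preserved verbatim rather than repaired: the
zinc-fortification/pneumonia-mortality row prints 0.49 with CI
(−0.28, 0.20), whose upper bound excludes the point (plausibly a typo
for the 0.80 of the supplementation analogue); it loads with
`ci_anomaly` set.  Rows quoting ORs without CIs load with null bounds.
Some breastfeeding-education ORs are printed in the benefit direction
("odds of the practice with the intervention"); for a binary split
this equals the adverse-outcome odds ratio without the intervention, so
those rows are stored with the canonical orientation tag.

The exclusion table codes the *first* reason stated for each of the 19
excluded pairs (e.g. the stop-smoking row codes as `unable_to_model`
even though insignificance is also mentioned), which is what makes the
count of seven insignificance exclusions reproducible.  A `section`
column records which panel (women vs infants/children) a row came
from.

The neonatal vitamin A supplementation intervention carries two
mortality pairs applied to infants under six months; the registry
assigns the 0-month band to the neonatal pair and the 1–5-month band to
the second pair so the bands never double-count.  Its affected fraction
is maternal (the share of pregnant women who are vitamin A deficient),
one of the cases where an infant-facing intervention legitimately uses
a maternal indicator.

## Evidence grading

The grade is a pure function of (design mix, five criterion ratings,
upgrade flags): RCT-only reviews start high, mixed start moderate,
non-RCT-only start low; serious/very-serious limitations subtract 1/2
levels each, summed then floored at very-low; upgrades (one level per
documented reason, capped at high) apply only when nothing was
downgraded.  The numeric cut-offs that turn I², study counts and event
counts into ratings are *not* fixed by the checklist itself, so they
live in a user-editable `RatingRules` (defaults: inconsistency serious
above I² 50%, very serious above 75%; imprecision serious below 3
studies, very serious below 100 events) and are advisory only — the
grade never reads them implicitly.

## Meta-analysis

Fixed-effect pooling is inverse-variance; random effects use the
DerSimonian–Laird moment estimator
`τ² = max(0, (Q − df)/(S₁ − S₂/S₁))` with fixed-effect weights in Q.
All 95% intervals use the normal quantile 1.959964 — no t-distribution
and no Hartung–Knapp adjustment, matching the conventions of the legacy
review software behind the source estimates.  The same quantile
converts supplied CIs to standard errors at load (recorded on the study
record).  Q is set identically to zero for a single study so I² cannot
be driven to 100% by floating-point noise.  Subgroup analysis pools
independently within the three complementary-food strata.  A
cross-check against `statsmodels.stats.meta_analysis.combine_effects`
lives in the test suite; the implementation itself is self-contained.

## Affected fractions

Resolution walks `indicator → fallback chain` and returns the first
available value; `all` is unconditionally 1.  Food-insecurity
indicators chain FIES → $1.90/day poverty (the published fallback
rule).  Food *security* is the complement `1 − food insecurity`,
derived on the fly when no direct value is stored.  Zinc deficiency is
expected to be supplied from national food-supply adequacy data (the
usual proxy in the absence of plasma-zinc surveys), but any value in
[0, 1] is accepted.  The "infants with diarrhoea" fractions are
profile inputs, not computed internally.  The fallback applies per
lookup, not per country-year.

## Synthetic data

The generators exist so every module is testable without external
data.  Profiles draw magnitudes loosely typical of LMIC settings:
live births 50–500k/year, under-five mortality 30–100 per 1000 births
with diarrhoea 5–20% and pneumonia 10–20% of under-five deaths,
deficiency prevalences in documented ranges, Dirichlet-drawn
stunting/wasting/breastfeeding distributions, and baseline coverages of
5–40%.  FIES is omitted with a configurable probability to exercise
the poverty fallback.  Trial sets draw per-study true effects
`true_md + N(0, τ²)` plus sampling noise with SEs from arm sizes
(default 300–700/arm, z-score SD 1.1); the default landscape gives
SQ-LNS a true mean difference of +0.14 z-scores and the other food
types zero, with mild heterogeneity (τ² = 0.002).  Every artifact is a
deterministic function of `(seed, purpose tag, index)`.

These ranges are arbitrary beyond plausibility.  Passing tests
demonstrate internal correctness — formula agreement with enumeration
oracles, calibration of the pooling machinery under its own assumptions
(normal effects, known SEs), conservation and monotonicity of the
engine — not that any real country's burden or any real trial
portfolio is reproduced.  In particular the generators omit
urban/rural structure, secular trends, coverage–outcome correlation
and survey measurement error.

## Problem sizes and numerical choices

The test suite checks DL calibration on 500 simulated meta-analyses
(k = 10, true MD 0.15, τ² = 0.01: observed |bias| < 0.02, coverage
within [90%, 98%]), subgroup detection on 200 seeded replicates
(tau² = 0, ~500/arm, k = 12: only the SQ-LNS CI excludes zero in ≥ 90%),
and engine properties across 1000 seeded profiles with a 2ⁿ
coverage-cell enumeration oracle on three-intervention instances.  The
grading rule space (3 × 3⁵ × 4 = 2916 combinations) is enumerated
exhaustively against an independently coded rule table.

Numerical conventions: odds-ratio 1 and zero coverage change are exact
identities (short-circuited, not just approximate); distribution
cumulatives are kept strictly inside (0, 1); downgrades are summed
before flooring; attribution shares sum to the combined total to
1e-9.  Incidence trajectories are reported per target group, so two
interventions with overlapping but unequal target bands (e.g. vitamin A
at 6–59 months, zinc at 12–59 months) produce separate trajectories
rather than a merged one.

## Known limitations

* The registry's pair grouping is a curation choice; other defensible
  groupings change pair-level counts (not intervention counts).
* The rebasing of distribution shifts is first-order in coverage, as
  described above; it is exact when baseline coverage is zero.
* Multi-channel ORs combine by log-OR weighted average over the
  scenario's channel mix — a modelling convenience, since ORs compose
  multiplicatively, not an estimate of a joint-delivery effect.
* The evidence-grading cut-offs are defaults, not the checklist's
  verbatim thresholds; treat graded outputs as reproducible
  book-keeping, not as authoritative re-grades.
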