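# nutrimpact

An open, testable engine for the nutrition module of a LiST-style
lives-saved model.  Policy analysts use models of this family to ask:
*if coverage of proven maternal and child nutrition interventions were
scaled up in a low- or middle-income country, how many deaths would be
averted, and how would risk factors such as stunting, wasting and
breastfeeding practices shift?*

`nutrimpact` packages three things:

1. **A parameter registry** — machine-readable transcriptions of the 34
   nutrition intervention–outcome pairs currently modelled (14
   interventions: six for women of reproductive age and pregnant women,
   eight for infants and children), each carrying its efficacy or odds
   ratio, the affected-fraction rule naming the population slice that
   can benefit, and an evidence-quality grade — plus the 19 reviewed-
   but-excluded pairs with coded exclusion reasons.
2. **Evidence-processing utilities** — a modified-GRADE quality score
   (design-based starting level, five downgrade criteria, conditional
   upgrades), relative-risk → efficacy conversion (efficacy = 1 − RR),
   and inverse-variance fixed-effect and DerSimonian–Laird
   random-effects meta-analysis of mean differences with food-type
   subgroup analysis (local unfortified food / fortified non-LNS food /
   small-quantity lipid-based nutrient supplements).
3. **A deterministic impact engine** — coverage scale-up scenarios are
   turned into deaths averted per intervention × cause × age band ×
   year and into shifted prevalence distributions, with residual
   multiplication combining interventions that act on the same cause so
   the joint impact never exceeds the cause-specific death envelope.

## The model in brief

For an intervention with efficacy $e$ (= 1 − RR), affected fraction
$a$, and coverage moving from $c_0$ to $c_1$, deaths averted out of a
cause envelope $D$ (which already reflects baseline coverage) are

$$\Delta = D\,\frac{e\,a\,(c_1 - c_0)}{1 - e\,a\,c_0}.$$

Interventions $i$ sharing a cause and age band combine residually,
$\Delta_{\text{comb}} = D\,[1 - \prod_i (1 - r_i c_{1i})/(1 - r_i c_{0i})]$
with $r_i = e_i a_i$, attributed proportionally to single-intervention
impacts.  Outcomes that are ordered distributions (stunting/wasting
z-score categories, breastfeeding practices) move by odds ratios: the
covered-and-affected slice has its odds of sitting at or beyond each
severity cut multiplied by the reciprocal of the canonical OR.

Affected fractions resolve against a country profile (deficiency
prevalences, food insecurity, disease burden); food-insecurity
indicators use the Food Insecurity Experience Scale (FIES) prevalence
and fall back to the <$1.90/day poverty head-count when FIES is
missing.

## Worked example

```python
import nutrimpact as ni

registry = ni.load_bundled_registry()
profile = ni.generate_country_profile(ni.GeneratorParams(seed=1))
scenario = ni.generate_scenario(1, registry, range(2025, 2031),
                                baseline_coverage=profile.baseline_coverage)
result = ni.run_scenario(profile, registry, scenario)

print(f"pairs: {len(registry)}, interventions: {len(registry.distinct_interventions())}")
print(f"under-five + maternal deaths averted in 2030: "
      f"{sum(v for (c, b, y), v in result.combined_deaths_averted.items() if y == 2030 and b != 'birth'):,.1f}")
print(f"adverse birth outcomes averted in 2030: "
      f"{sum(v for (c, b, y), v in result.combined_deaths_averted.items() if y == 2030 and b == 'birth'):,.1f}")

trials = ni.generate_trial_set(ni.GeneratorParams(seed=1))
for food_type, est in ni.subgroup_pool(trials).items():
    print(f"{food_type.value:>18}: MD {est.md:+.3f} ({est.ci_low:+.3f}, {est.ci_high:+.3f})"
          f"{'  *' if est.significant else ''}")
```

prints

```
pairs: 34, interventions: 14
under-five + maternal deaths averted in 2030: 235.6
adverse birth outcomes averted in 2030: 9,453.8
 local_unfortified: MD +0.028 (-0.016, +0.073)
 fortified_non_lns: MD +0.002 (-0.056, +0.060)
            sq_lns: MD +0.162 (+0.105, +0.220)  *
```

The scenario ramps every intervention linearly from its baseline
coverage to a seeded target by 2030; deaths averted are summed over
causes and age bands, with birth outcomes (small-for-gestational-age,
preterm, stillbirth) reported as adverse events averted.  The subgroup
pooling reproduces the structure of the complementary-food re-analysis:
on a synthetic trial landscape where only SQ-LNS carries a real benefit
(true mean difference +0.14 z-scores), only the SQ-LNS subgroup's 95%
CI excludes zero (`*`).

A command-line interface mirrors the library:

```bash
nutrimpact registry stats                 # bookkeeping count table
nutrimpact convert --rr 0.59 --ci 0.52 0.68
nutrimpact meta pool trials.tsv --subgroup
nutrimpact run --profile p.yaml --scenario s.yaml --out out/
nutrimpact synth profile --seed 3 --out p.yaml
```

## Layout

| Path | Contents |
| --- | --- |
| `src/nutrimpact/registry.py` | pair/exclusion tables, loading, validation, counting |
| `src/nutrimpact/grading.py` | modified-GRADE quality scoring |
| `src/nutrimpact/conversion.py` | RR↔efficacy, odds-ratio arithmetic on distributions |
| `src/nutrimpact/meta.py` | fixed-effect and DL pooling, subgroup analysis |
| `src/nutrimpact/affected_fractions.py` | country profiles, fraction resolution, correlation |
| `src/nutrimpact/impact.py` | the scenario engine |
| `src/nutrimpact/synthetic.py` | seeded profile/trial/scenario generators |
| `src/nutrimpact/data/` | bundled pair and exclusion tables (TSV) |
| `docs/methods.md` | modelling assumptions, conventions, and limitations |

See `docs/methods.md` for the full account of modelling conventions,
curation choices in the bundled tables, and known limitations.
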