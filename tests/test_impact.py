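"""Impact engine: closed forms, combination rules, scenario properties."""

import dataclasses

import pytest
from _oracles import residual_product_averted

from nutrimpact.conversion import OrderedDistribution, apply_or_to_prevalence
from nutrimpact.impact import (
    ImpactConfigError,
    Scenario,
    combined_reduction,
    deaths_averted_single,
    run_scenario,
    shift_outcome_prevalence,
)
from nutrimpact.registry import (
    Metric,
    PairRegistry,
    load_pair_registry,
)
from nutrimpact.synthetic import GeneratorParams, generate_country_profile, generate_scenario


class TestDeathsAvertedSingle:
    def test_no_coverage_change_averts_nothing(self):
        assert deaths_averted_single(1000, 0.5, 0.8, 0.3, 0.3) == 0.0
        assert deaths_averted_single(1000, 0.5, 0.0, 0.0, 0.9) == 0.0
        assert deaths_averted_single(1000, 0.0, 1.0, 0.0, 1.0) == 0.0

    def test_perfect_intervention_empties_the_envelope(self):
        assert deaths_averted_single(1000, 1.0 - 1e-12, 1.0, 0.0, 1.0) == pytest.approx(
            1000.0
        )

    def test_baseline_coverage_renormalisation_closed_form(self):
        # 1000 x 0.5*0.4*0.5 / (1 - 0.5*0.4*0.1) = 100/0.98
        value = deaths_averted_single(1000, 0.5, 0.4, 0.1, 0.6)
        assert value == pytest.approx(1000 * 0.1 / 0.98, rel=1e-12)
        assert value == pytest.approx(102.040816326, rel=1e-9)

    def test_negative_efficacy_clamps_to_zero(self, caplog):
        with caplog.at_level("WARNING", logger="nutrimpact.impact"):
            value = deaths_averted_single(1000, -0.25, 0.5, 0.1, 0.9)
        assert value == 0.0
        assert any("clamped" in rec.message for rec in caplog.records)

    def test_coverage_decrease_goes_negative(self):
        assert deaths_averted_single(1000, 0.5, 1.0, 0.6, 0.2) < 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            deaths_averted_single(-5, 0.5, 0.5, 0.0, 1.0)
        with pytest.raises(ValueError):
            deaths_averted_single(100, 1.0, 0.5, 0.0, 1.0)
        with pytest.raises(ValueError):
            deaths_averted_single(100, 0.5, 1.2, 0.0, 1.0)


class TestCombinedReduction:
    def test_single_component_is_the_plain_product(self):
        assert combined_reduction([(0.5, 0.4, 0.6)]) == pytest.approx(0.5 * 0.4 * 0.6)

    def test_two_half_reductions_compose_to_three_quarters(self):
        assert combined_reduction([(0.5, 1.0, 1.0), (0.5, 1.0, 1.0)]) == pytest.approx(0.75)

    def test_commutative(self):
        comps = [(0.3, 0.8, 0.5), (0.6, 0.2, 0.9), (0.1, 1.0, 0.4)]
        assert combined_reduction(comps) == pytest.approx(
            combined_reduction(list(reversed(comps)))
        )

    def test_bounds(self):
        comps = [(0.3, 0.8, 0.5), (0.6, 0.2, 0.9), (0.1, 1.0, 0.4)]
        singles = [e * af * c for e, af, c in comps]
        combined = combined_reduction(comps)
        assert combined >= max(singles)
        assert combined <= min(1.0, sum(singles))


class TestShiftOutcomePrevalence:
    def test_or_one_and_no_coverage_change_are_identities(self):
        dist = OrderedDistribution(("a", "b", "c", "d"), (0.1, 0.3, 0.6))
        assert shift_outcome_prevalence(dist, 1.0, 0.7, 0.1, 0.8) == dist
        assert shift_outcome_prevalence(dist, 1.92, 0.7, 0.4, 0.4) == dist
        assert shift_outcome_prevalence(0.3, 1.0, 0.7, 0.1, 0.8) == pytest.approx(0.3)

    def test_full_population_limit_equals_plain_distribution_shift(self):
        from nutrimpact.conversion import shift_category_distribution

        dist = OrderedDistribution(("a", "b", "c", "d"), (0.1, 0.3, 0.6))
        full = shift_outcome_prevalence(dist, 2.0, 1.0, 0.0, 1.0)
        plain = shift_category_distribution(dist, 0.5)  # reciprocal of canonical OR 2
        assert full.cumulative == pytest.approx(plain.cumulative)

    def test_partial_coverage_mixture_closed_form(self):
        # covered-and-affected slice af*c1 = 0.2 shifts; 0.8 stays at baseline
        shifted = shift_outcome_prevalence(0.3, 2.0, 0.5, 0.0, 0.4)
        expected = 0.2 * apply_or_to_prevalence(0.3, 0.5) + 0.8 * 0.3
        assert shifted == pytest.approx(expected)
        assert shifted == pytest.approx(0.2752941176, rel=1e-9)

    def test_beneficial_or_reduces_severe_side(self):
        dist = OrderedDistribution(("a", "b", "c", "d"), (0.1, 0.3, 0.6))
        shifted = shift_outcome_prevalence(dist, 1.92, 0.6, 0.1, 0.7)
        assert all(s < b for s, b in zip(shifted.cumulative, dist.cumulative))


# ---------------------------------------------------------------------------
# scenario-level behaviour


def _mini_pairs_tsv(tmp_path, rows):
    from nutrimpact.registry import PAIR_COLUMNS

    lines = ["\t".join(PAIR_COLUMNS)]
    lines += ["\t".join(r) for r in rows]
    path = tmp_path / "mini_pairs.tsv"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _mini_row(pair_id, intervention, point, af_indicator, target="children_6_59mo"):
    return [
        pair_id, intervention, intervention.replace("_", " "), "mort_diarrhoea",
        "cause_specific_mortality", target, "efficacy", "", str(point), "", "", "",
        af_indicator, target, "", "moderate", "0", "0", "0", "0", "test",
    ]


@pytest.fixture
def mini_registry(tmp_path):
    rows = [
        _mini_row("a__mort", "intervention_a", 0.5, "vitamin_a_deficiency_6_59"),
        _mini_row("b__mort", "intervention_b", 0.3, "with_diarrhoea_6_59"),
        _mini_row("c__mort", "intervention_c", 0.2, "all"),
    ]
    return load_pair_registry(_mini_pairs_tsv(tmp_path, rows))


def _flat_scenario(registry, year, coverage):
    return Scenario(
        years=(year,),
        coverage={i: {year: coverage[i]} for i in coverage},
    )


class TestRunScenario:
    def test_null_scenario_yields_zero_impact(self, profile, registry):
        from nutrimpact.registry import Channel

        scenario = Scenario(
            years=(2025,),
            coverage={
                i: {2025: profile.baseline_coverage.get(i, 0.0)}
                for i in registry.distinct_interventions()
            },
            channel_mix={
                "iycf_education": {
                    Channel.HEALTH_SYSTEM: 0.4,
                    Channel.HOME_COMMUNITY: 0.4,
                    Channel.COMBINED: 0.2,
                },
            },
        )
        result = run_scenario(profile, registry, scenario)
        assert result.total_deaths_averted() == pytest.approx(0.0, abs=1e-9)
        for value in result.combined_deaths_averted.values():
            assert value == pytest.approx(0.0, abs=1e-9)

    def test_single_intervention_matches_closed_form(self, profile, mini_registry):
        profile.baseline_coverage["intervention_a"] = 0.1
        scenario = _flat_scenario(mini_registry, 2025, {"intervention_a": 0.6})
        result = run_scenario(profile, mini_registry, scenario)
        af = profile.indicators["vitamin_a_deficiency_6_59"]
        for band in ("6_11mo", "12_23mo", "24_59mo"):
            expected = deaths_averted_single(
                profile.deaths["diarrhoea"][band], 0.5, af, 0.1, 0.6
            )
            assert result.combined_deaths_averted[("diarrhoea", band, 2025)] == (
                pytest.approx(expected)
            )
            assert result.deaths_averted[
                ("intervention_a", "diarrhoea", band, 2025)
            ] == pytest.approx(expected)

    def test_combined_bounded_by_singles(self, profile, mini_registry):
        for i in ("intervention_a", "intervention_b", "intervention_c"):
            profile.baseline_coverage[i] = 0.1
        scenario = _flat_scenario(
            mini_registry, 2025,
            {"intervention_a": 0.7, "intervention_b": 0.5, "intervention_c": 0.9},
        )
        result = run_scenario(profile, mini_registry, scenario)
        for band in ("6_11mo", "12_23mo", "24_59mo"):
            singles = [
                result.deaths_averted[(i, "diarrhoea", band, 2025)]
                for i in ("intervention_a", "intervention_b", "intervention_c")
            ]
            combined = result.combined_deaths_averted[("diarrhoea", band, 2025)]
            assert combined >= max(singles) - 1e-9
            assert combined <= sum(singles) + 1e-9
            assert combined <= profile.deaths["diarrhoea"][band]
            shares = result.attribution[("diarrhoea", band, 2025)]
            assert sum(shares.values()) == pytest.approx(combined, abs=1e-9)

    def test_agrees_with_enumeration_oracle(self, profile, mini_registry):
        baselines = {"intervention_a": 0.05, "intervention_b": 0.2, "intervention_c": 0.15}
        targets = {"intervention_a": 0.65, "intervention_b": 0.8, "intervention_c": 0.4}
        profile.baseline_coverage.update(baselines)
        scenario = _flat_scenario(mini_registry, 2025, targets)
        result = run_scenario(profile, mini_registry, scenario)
        af_by_intervention = {
            "intervention_a": profile.indicators["vitamin_a_deficiency_6_59"],
            "intervention_b": profile.indicators["with_diarrhoea_6_59"],
            "intervention_c": 1.0,
        }
        effs = {"intervention_a": 0.5, "intervention_b": 0.3, "intervention_c": 0.2}
        order = sorted(effs)
        for band in ("6_11mo", "12_23mo", "24_59mo"):
            expected = residual_product_averted(
                profile.deaths["diarrhoea"][band],
                [(effs[i], af_by_intervention[i]) for i in order],
                [baselines[i] for i in order],
                [targets[i] for i in order],
            )
            assert result.combined_deaths_averted[("diarrhoea", band, 2025)] == (
                pytest.approx(expected, rel=1e-12)
            )

    def test_null_field_registry_produces_zero_impact(self, profile, registry):
        """Zero efficacies and unit odds ratios avert nothing anywhere."""
        neutral_pairs = []
        for pair in registry:
            variants = []
            for v in pair.variants:
                if v.effect.metric is Metric.EFFICACY:
                    effect = dataclasses.replace(
                        v.effect, point=0.0, ci_low=None, ci_high=None
                    )
                else:
                    effect = dataclasses.replace(
                        v.effect, point=1.0, ci_low=None, ci_high=None
                    )
                variants.append(dataclasses.replace(v, effect=effect))
            neutral_pairs.append(dataclasses.replace(pair, variants=variants))
        neutral = PairRegistry(pairs=neutral_pairs)
        scenario = generate_scenario(
            3, neutral, range(2025, 2028), baseline_coverage=profile.baseline_coverage
        )
        result = run_scenario(profile, neutral, scenario)
        assert result.total_deaths_averted() == pytest.approx(0.0, abs=1e-9)
        for (outcome, band, _year), value in result.prevalence_trajectories.items():
            baseline = _baseline_value(profile, outcome, band)
            if isinstance(value, dict):
                assert sum(value.values()) == pytest.approx(1.0, abs=1e-9)
            elif baseline is not None:
                assert value == pytest.approx(baseline, abs=1e-9)

    def test_coverage_monotonicity(self, profile, mini_registry):
        profile.baseline_coverage.update(
            {"intervention_a": 0.1, "intervention_b": 0.1, "intervention_c": 0.1}
        )
        base_cov = {"intervention_a": 0.5, "intervention_b": 0.5, "intervention_c": 0.5}
        base = run_scenario(
            profile, mini_registry, _flat_scenario(mini_registry, 2025, base_cov)
        ).total_deaths_averted()
        bumped_cov = dict(base_cov, intervention_b=0.8)
        bumped = run_scenario(
            profile, mini_registry, _flat_scenario(mini_registry, 2025, bumped_cov)
        ).total_deaths_averted()
        assert bumped >= base

    def test_unknown_intervention_is_config_error(self, profile, mini_registry):
        scenario = _flat_scenario(mini_registry, 2025, {"made_up": 0.5})
        with pytest.raises(ImpactConfigError, match="made_up"):
            run_scenario(profile, mini_registry, scenario)

    def test_coverage_decrease_is_flagged(self, profile, mini_registry):
        profile.baseline_coverage["intervention_a"] = 0.6
        scenario = _flat_scenario(mini_registry, 2025, {"intervention_a": 0.2})
        result = run_scenario(profile, mini_registry, scenario)
        assert result.total_deaths_averted() < 0.0
        assert any("decreases" in w for w in result.warnings)

    def test_multi_channel_pair_requires_channel_mix(self, profile, registry):
        scenario = Scenario(years=(2025,), coverage={"iycf_education": {2025: 0.8}})
        with pytest.raises(ImpactConfigError, match="channel mix"):
            run_scenario(profile, registry, scenario)


def _baseline_value(profile, outcome, band):
    from nutrimpact.impact import OUTCOME_CATALOG

    info = OUTCOME_CATALOG[outcome]
    if info.kind == "rate":
        return profile.incidence.get(info.key)
    if info.kind == "prevalence":
        return profile.indicators.get(info.key)
    if info.kind == "birth":
        return profile.birth_outcomes.get(info.key)
    if info.kind == "practice_prevalence":
        return profile.indicators.get(info.key)
    return None


class TestScenarioValidation:
    def test_years_must_be_contiguous(self):
        with pytest.raises(ImpactConfigError, match="contiguous"):
            Scenario(years=(2025, 2027), coverage={}).validate()

    def test_coverage_bounds_enforced(self):
        with pytest.raises(ImpactConfigError, match="outside"):
            Scenario(years=(2025,), coverage={"x": {2025: 1.2}}).validate()

    def test_missing_year_detected(self):
        with pytest.raises(ImpactConfigError, match="missing year"):
            Scenario(years=(2025, 2026), coverage={"x": {2025: 0.5}}).validate()
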