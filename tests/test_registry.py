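"""Registry loading, bookkeeping counts, round-tripping, and validation."""

import pytest

from nutrimpact import registry as reg_mod
from nutrimpact.registry import (
    EFFICACY_CLASSES,
    ODDS_RATIO_CLASSES,
    ExclusionReason,
    IntegrityError,
    Metric,
    ParseError,
    Population,
    SchemaError,
    bundled_exclusions_path,
    bundled_pairs_path,
    count_pairs,
    distinct_interventions,
    load_exclusion_table,
    load_pair_registry,
    write_registry,
)

WOMEN = frozenset({Population.WRA, Population.PW})


class TestBundledBookkeeping:
    """The bundled tables reproduce the published review accounting."""

    def test_pair_and_intervention_tallies(self, registry):
        assert count_pairs(registry) == 34
        assert count_pairs(registry, lambda p: p.is_new) == 9
        assert (
            count_pairs(
                registry,
                lambda p: p.is_new and p.intervention_id == "zinc_fortification",
            )
            == 5
        )
        assert len(distinct_interventions(registry)) == 14
        assert len(distinct_interventions(registry, lambda p: not p.is_new)) == 12
        assert (
            len(distinct_interventions(registry, lambda p: bool(p.target_groups & WOMEN)))
            == 6
        )
        assert (
            len(
                distinct_interventions(
                    registry, lambda p: not (p.target_groups & WOMEN)
                )
            )
            == 8
        )

    def test_exclusion_tallies(self, registry, exclusions):
        assert len(exclusions) == 19
        insignificant = [
            r
            for r in exclusions
            if r.primary_reason is ExclusionReason.NO_SIGNIFICANT_EFFECT
        ]
        assert len(insignificant) == 7
        assert sum(1 for r in exclusions if r.section == "infants_children") == 11
        # all newly reviewed pairs = the added ones plus the excluded ones
        assert count_pairs(registry, lambda p: p.is_new) + len(exclusions) == 28

    def test_metric_outcome_class_partition(self, registry):
        for pair in registry:
            for effect in pair.effects:
                if effect.metric is Metric.EFFICACY:
                    assert pair.outcome_class in EFFICACY_CLASSES
                else:
                    assert pair.outcome_class in ODDS_RATIO_CLASSES

    def test_ci_anomaly_row_preserved_verbatim(self, registry):
        pair = registry.get("zinc_fort__pneumonia_mortality")
        assert pair.ci_anomaly
        effect = pair.effects[0]
        assert effect.point == pytest.approx(0.49)
        assert effect.ci_low == pytest.approx(-0.28)
        assert effect.ci_high == pytest.approx(0.20)

    def test_missing_cis_load_as_none(self, registry):
        wasting = registry.get("provision_cf__wasting")
        assert {e.point for e in wasting.effects} == {1.5, 1.64}
        assert all(e.ci_low is None and e.ci_high is None for e in wasting.effects)

    def test_affected_fraction_fallback_chains(self, registry):
        bep = registry.get("bep__sga")
        assert bep.affected_fraction.fallback_chain == ("fies", "poverty_190")
        mmn = registry.get("mmn__sga")
        assert mmn.affected_fraction.indicator_id == "all"
        assert mmn.affected_fraction.fallback_chain == ()


class TestRoundTrip:
    def test_write_reproduces_source_byte_for_byte(self, registry, tmp_path):
        out = tmp_path / "pairs.tsv"
        write_registry(registry, out)
        assert out.read_text(encoding="utf-8") == bundled_pairs_path().read_text(
            encoding="utf-8"
        )

    def test_reload_of_written_registry_is_equal(self, registry, tmp_path):
        out = tmp_path / "pairs.tsv"
        write_registry(registry, out)
        reloaded = load_pair_registry(out)
        assert [p.pair_id for p in reloaded] == [p.pair_id for p in registry]
        assert [p.variants for p in reloaded] == [p.variants for p in registry]


class TestValidationErrors:
    def _lines(self):
        return bundled_pairs_path().read_text(encoding="utf-8").splitlines()

    def test_duplicate_row_is_integrity_error(self, tmp_path):
        lines = self._lines()
        lines.append(lines[1])  # repeat the first data row verbatim
        bad = tmp_path / "dup.tsv"
        bad.write_text("\n".join(lines) + "\n", encoding="utf-8")
        with pytest.raises(IntegrityError, match="iron_fortification__anaemia_maternal"):
            load_pair_registry(bad)

    def test_missing_column_is_schema_error(self, tmp_path):
        lines = self._lines()
        header = lines[0].split("\t")
        idx = header.index("quality")
        stripped = [
            "\t".join(f for i, f in enumerate(line.split("\t")) if i != idx)
            for line in lines
        ]
        bad = tmp_path / "noquality.tsv"
        bad.write_text("\n".join(stripped) + "\n", encoding="utf-8")
        with pytest.raises(SchemaError, match="quality"):
            load_pair_registry(bad)

    def test_unknown_enum_token_reports_row_number(self, tmp_path):
        lines = self._lines()
        fields = lines[3].split("\t")
        fields[lines[0].split("\t").index("quality")] = "excellent"
        lines[3] = "\t".join(fields)
        bad = tmp_path / "badenum.tsv"
        bad.write_text("\n".join(lines) + "\n", encoding="utf-8")
        with pytest.raises(ParseError, match="row 4") as err:
            load_pair_registry(bad)
        assert "excellent" in str(err.value)

    def test_point_outside_ci_rejected_unless_flagged(self, tmp_path):
        lines = self._lines()
        header = lines[0].split("\t")
        fields = lines[1].split("\t")
        fields[header.index("point")] = "0.9"  # outside (0.24, 0.44)
        lines[1] = "\t".join(fields)
        bad = tmp_path / "badci.tsv"
        bad.write_text("\n".join(lines) + "\n", encoding="utf-8")
        with pytest.raises(ParseError, match="ci_anomaly"):
            load_pair_registry(bad)

    @pytest.mark.parametrize("table", ["pairs", "exclusions"])
    def test_empty_file_with_header_loads_empty(self, tmp_path, table):
        if table == "pairs":
            src, loader = bundled_pairs_path(), load_pair_registry
        else:
            src, loader = bundled_exclusions_path(), load_exclusion_table
        empty = tmp_path / f"{table}.tsv"
        empty.write_text(
            src.read_text(encoding="utf-8").splitlines()[0] + "\n", encoding="utf-8"
        )
        assert len(loader(empty)) == 0

    def test_unknown_exclusion_reason_is_parse_error(self, tmp_path):
        lines = bundled_exclusions_path().read_text(encoding="utf-8").splitlines()
        lines[2] = lines[2].replace("no_significant_effect", "not_a_reason")
        bad = tmp_path / "exc.tsv"
        bad.write_text("\n".join(lines) + "\n", encoding="utf-8")
        with pytest.raises(ParseError, match="not_a_reason"):
            load_exclusion_table(bad)

    def test_filter_matching_nothing_counts_zero(self, registry):
        assert count_pairs(registry, lambda p: p.intervention_id == "nonexistent") == 0


def test_channel_variants_only_on_feeding_education_pairs(registry):
    for pair in registry:
        if pair.is_multi_channel:
            assert pair.intervention_id == "iycf_education"
            assert pair.outcome_class is reg_mod.OutcomeClass.PRACTICE_DISTRIBUTION
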