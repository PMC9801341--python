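"""Parameter registry for nutrition intervention-outcome pairs.

The registry is the model's parameter book: one record per intervention-
outcome (I-O) pair, carrying the pair's effect estimate(s), the rule for
resolving its affected fraction (the population slice that can actually
benefit, e.g. the zinc-deficient fraction of 12-59-month-olds), an ordinal
evidence-quality grade, and review-status flags.  A companion table lists
the I-O pairs that were reviewed but excluded, with a single primary
reason code per record.

Effects come in two metrics.  Mortality, disease-incidence, birth-outcome
and maternal-anaemia pairs carry an *efficacy* (1 - relative risk, the
proportional reduction among covered, affected individuals).  Outcomes
expressed as prevalence distributions (stunting and wasting z-score
categories, breastfeeding practices) carry an *odds ratio* instead.

File dialect
------------
Tab-delimited UTF-8 text with one header row, ``.`` decimal separator and
the empty string for missing values.  ``pairs.tsv`` holds one row per
*effect variant*; rows sharing a ``pair_id`` form one pair.  Variants are
used where the source tabulates several estimates under a single
conceptual pair:

* delivery-channel variants (infant and young child feeding education,
  one odds ratio per channel: health system / home-community / combined);
* target-group variants (iron fortification against maternal anaemia has
  one efficacy for women of reproductive age and one for pregnant women);
* odds-ratio orientation variants (the complementary-food provision rows
  quote the odds ratio both "with" and "without" the intervention);
* sub-outcome variants (folic acid against neural-tube-defect mortality
  is quoted separately for stillbirths and neonatal deaths).

The grouping is a curation choice of the bundled fixture, made so that
pair-level bookkeeping matches the published accounting (34 pairs, 14
interventions).  Loading preserves the raw rows verbatim, so a registry
round-trips byte-for-byte through :func:`write_registry`.

Known source anomalies are preserved, not repaired: the zinc-fortification
pneumonia-mortality row prints an efficacy of 0.49 with a 95% CI of
(-0.28, 0.20) whose upper bound excludes the point estimate.  That row
loads with ``ci_anomaly`` set rather than failing validation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Callable, Iterator, Optional, Union

__all__ = [
    "Metric",
    "Channel",
    "OrOrientation",
    "OutcomeClass",
    "Population",
    "Quality",
    "ExclusionReason",
    "EffectSpec",
    "AffectedFractionSpec",
    "PairVariant",
    "InterventionOutcomePair",
    "ExclusionRecord",
    "PairRegistry",
    "RegistryError",
    "SchemaError",
    "IntegrityError",
    "ParseError",
    "load_pair_registry",
    "load_exclusion_table",
    "load_bundled_registry",
    "load_bundled_exclusions",
    "bundled_pairs_path",
    "bundled_exclusions_path",
    "count_pairs",
    "distinct_interventions",
    "write_registry",
]


class RegistryError(Exception):
    """Base class for registry loading/validation failures."""


class SchemaError(RegistryError):
    """The file header does not match the documented column schema."""


class IntegrityError(RegistryError):
    """Cross-record constraint violated (e.g. duplicated pair rows)."""


class ParseError(RegistryError):
    """A field value could not be parsed; carries the 1-based row number."""

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class Metric(str, Enum):
    EFFICACY = "efficacy"
    ODDS_RATIO = "odds_ratio"


class Channel(str, Enum):
    HEALTH_SYSTEM = "health_system"
    HOME_COMMUNITY = "home_community"
    COMBINED = "combined"
    ANY = "any"


class OrOrientation(str, Enum):
    """Which arm the quoted odds ratio puts in the numerator.

    ``ODDS_WITHOUT_INTERVENTION`` is the canonical model direction: the
    odds of the adverse outcome without the intervention relative to with
    it, so values above 1 mean the intervention is beneficial.
    """

    ODDS_WITHOUT_INTERVENTION = "odds_without_intervention"
    ODDS_WITH_INTERVENTION = "odds_with_intervention"


class OutcomeClass(str, Enum):
    CAUSE_SPECIFIC_MORTALITY = "cause_specific_mortality"
    DISEASE_INCIDENCE = "disease_incidence"
    BIRTH_OUTCOME = "birth_outcome"
    MATERNAL_ANAEMIA = "maternal_anaemia"
    PRACTICE_DISTRIBUTION = "practice_distribution"
    ANTHROPOMETRY_DISTRIBUTION = "anthropometry_distribution"


#: Outcome classes that carry efficacy-metric effects.
EFFICACY_CLASSES = frozenset(
    {
        OutcomeClass.CAUSE_SPECIFIC_MORTALITY,
        OutcomeClass.DISEASE_INCIDENCE,
        OutcomeClass.BIRTH_OUTCOME,
        OutcomeClass.MATERNAL_ANAEMIA,
    }
)

#: Outcome classes that carry odds-ratio effects (distribution outcomes).
ODDS_RATIO_CLASSES = frozenset(
    {OutcomeClass.PRACTICE_DISTRIBUTION, OutcomeClass.ANTHROPOMETRY_DISTRIBUTION}
)


class Population(str, Enum):
    WRA = "WRA"
    PW = "PW"
    NEONATES_LT1MO = "neonates_lt1mo"
    INFANTS_LT6MO = "infants_lt6mo"
    INFANTS_1_6MO = "infants_1_6mo"
    CHILDREN_6_23MO = "children_6_23mo"
    CHILDREN_6_59MO = "children_6_59mo"
    CHILDREN_12_59MO = "children_12_59mo"


#: Affected-fraction populations acceptable for a given target group.  An
#: infant target group may use a maternal (PW) indicator: e.g. neonatal
#: vitamin A supplementation is applied to infants born to vitamin
#: A-deficient mothers.
_AF_COMPATIBLE = {
    Population.WRA: {Population.WRA},
    Population.PW: {Population.PW},
    Population.NEONATES_LT1MO: {Population.NEONATES_LT1MO, Population.PW},
    Population.INFANTS_LT6MO: {Population.INFANTS_LT6MO, Population.PW},
    Population.INFANTS_1_6MO: {Population.INFANTS_1_6MO, Population.PW},
    Population.CHILDREN_6_23MO: {Population.CHILDREN_6_23MO},
    Population.CHILDREN_6_59MO: {Population.CHILDREN_6_59MO},
    Population.CHILDREN_12_59MO: {Population.CHILDREN_12_59MO},
}


class Quality(str, Enum):
    VERY_LOW = "very_low"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"

    @property
    def ordinal(self) -> int:
        return ("very_low", "low", "moderate", "high").index(self.value)


class ExclusionReason(str, Enum):
    NO_SIGNIFICANT_EFFECT = "no_significant_effect"
    UNABLE_TO_MODEL = "unable_to_model"
    NO_SYSTEMATIC_REVIEW = "no_systematic_review"
    SMALL_SAMPLE = "small_sample"
    DOUBLE_COUNTED_ELSEWHERE = "double_counted_elsewhere"
    NO_OUTCOME_PROPORTION_DATA = "no_outcome_proportion_data"
    NO_STANDARD_DEFINITION = "no_standard_definition"
    NO_MORTALITY_LINK = "no_mortality_link"
    NO_DIRECT_ESTIMATE = "no_direct_estimate"


@dataclass(frozen=True)
class EffectSpec:
    """A single effect estimate.

    ``point`` is an efficacy (1 - RR, must be < 1) or an odds ratio
    (must be > 0) depending on ``metric``.  CI bounds are optional and may
    legitimately disagree with the point estimate on anomalous source rows;
    ordering is enforced at registry load, not here.
    """

    metric: Metric
    point: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    or_orientation: Optional[OrOrientation] = None
    channel: Optional[Channel] = None

    def __post_init__(self) -> None:
        if self.metric is Metric.EFFICACY:
            if not self.point < 1:
                raise ValueError(f"efficacy must be < 1, got {self.point}")
            if self.or_orientation is not None:
                raise ValueError("or_orientation is only valid for odds-ratio effects")
        else:
            if not self.point > 0:
                raise ValueError(f"odds ratio must be > 0, got {self.point}")
            if self.or_orientation is None:
                raise ValueError("odds-ratio effects require an or_orientation")


@dataclass(frozen=True)
class AffectedFractionSpec:
    """Rule for resolving the benefiting population fraction.

    ``indicator_id`` names a proportion in the country profile ("all"
    resolves to 1.0 unconditionally).  ``fallback_chain`` lists indicator
    ids tried in order when the primary one is absent; it is only used for
    food-insecurity indicators, encoding the FIES -> $1.90/day-poverty
    fallback.
    """

    indicator_id: str
    population: Population
    fallback_chain: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.fallback_chain and not self.indicator_id.startswith("food_insecurity"):
            raise ValueError(
                "fallback_chain is only valid for food-insecurity indicators, "
                f"got {self.indicator_id!r}"
            )


@dataclass(frozen=True)
class PairVariant:
    """One fixture row: an effect with its own target group and fraction."""

    outcome_id: str
    target_group: Population
    effect: EffectSpec
    affected_fraction: AffectedFractionSpec
    source: str = ""
    raw: dict = field(default_factory=dict, compare=False, repr=False)


@dataclass
class InterventionOutcomePair:
    """One registry record, possibly grouping several effect variants."""

    pair_id: str
    intervention_id: str
    intervention_name: str
    outcome_class: OutcomeClass
    quality: Quality
    is_new: bool
    efficacy_updated: bool
    af_updated: bool
    ci_anomaly: bool
    variants: list[PairVariant]

    # -- convenience accessors -------------------------------------------
    @property
    def outcome_id(self) -> str:
        return self.variants[0].outcome_id

    @property
    def target_group(self) -> Population:
        return self.variants[0].target_group

    @property
    def target_groups(self) -> frozenset[Population]:
        return frozenset(v.target_group for v in self.variants)

    @property
    def effects(self) -> list[EffectSpec]:
        return [v.effect for v in self.variants]

    @property
    def affected_fraction(self) -> AffectedFractionSpec:
        return self.variants[0].affected_fraction

    @property
    def metric(self) -> Metric:
        return self.variants[0].effect.metric

    @property
    def source(self) -> str:
        return self.variants[0].source

    @property
    def is_multi_channel(self) -> bool:
        return any(v.effect.channel is not None for v in self.variants)


@dataclass(frozen=True)
class ExclusionRecord:
    intervention_name: str
    outcome_name: str
    primary_reason: ExclusionReason
    quality: Optional[Quality]  # None when no systematic review was available
    source: str
    section: str  # "wra_pw" or "infants_children"


PAIR_COLUMNS = [
    "pair_id",
    "intervention_id",
    "intervention_name",
    "outcome_id",
    "outcome_class",
    "target_group",
    "metric",
    "channel",
    "point",
    "ci_low",
    "ci_high",
    "or_orientation",
    "af_indicator",
    "af_population",
    "af_fallback",
    "quality",
    "is_new",
    "efficacy_updated",
    "af_updated",
    "ci_anomaly",
    "source",
]

EXCLUSION_COLUMNS = [
    "intervention_name",
    "outcome_name",
    "primary_reason",
    "quality",
    "source",
    "section",
]

Predicate = Optional[Callable[[InterventionOutcomePair], bool]]


@dataclass
class PairRegistry:
    """An ordered, validated collection of intervention-outcome pairs."""

    pairs: list[InterventionOutcomePair]
    path: Optional[Path] = None
    _rows: list[dict] = field(default_factory=list, repr=False, compare=False)

    def __iter__(self) -> Iterator[InterventionOutcomePair]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, pair_id: str) -> InterventionOutcomePair:
        for p in self.pairs:
            if p.pair_id == pair_id:
                return p
        raise KeyError(pair_id)

    def count(self, predicate: Predicate = None) -> int:
        if predicate is None:
            return len(self.pairs)
        return sum(1 for p in self.pairs if predicate(p))

    def distinct_interventions(self, predicate: Predicate = None) -> frozenset[str]:
        return frozenset(
            p.intervention_id for p in self.pairs if predicate is None or predicate(p)
        )

    def write(self, path: Union[str, Path]) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(PAIR_COLUMNS)
            for row in self._rows:
                writer.writerow([row[c] for c in PAIR_COLUMNS])


# ---------------------------------------------------------------------------
# parsing helpers


def _check_header(header: Optional[list[str]], expected: list[str], path: Path) -> None:
    if header is None:
        raise SchemaError(f"{path}: file is empty, expected header {expected}")
    missing = [c for c in expected if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column {missing[0]!r}")
    extra = [c for c in header if c not in expected]
    if extra:
        raise SchemaError(f"{path}: unexpected column {extra[0]!r}")


def _enum(cls, token: str, rownum: int, column: str):
    try:
        return cls(token)
    except ValueError:
        raise ParseError(f"unknown {column} token {token!r}", row=rownum) from None


def _opt_float(token: str, rownum: int, column: str) -> Optional[float]:
    if token == "":
        return None
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"bad number {token!r} in column {column}", row=rownum) from None


def _flag(token: str, rownum: int, column: str) -> bool:
    if token not in ("0", "1"):
        raise ParseError(f"flag column {column} must be 0/1, got {token!r}", row=rownum)
    return token == "1"


def _parse_pair_row(row: dict, rownum: int) -> PairVariant:
    metric = _enum(Metric, row["metric"], rownum, "metric")
    outcome_class = _enum(OutcomeClass, row["outcome_class"], rownum, "outcome_class")
    target_group = _enum(Population, row["target_group"], rownum, "target_group")
    quality = _enum(Quality, row["quality"], rownum, "quality")  # noqa: F841  (validated)
    channel = (
        _enum(Channel, row["channel"], rownum, "channel") if row["channel"] else None
    )
    orientation = (
        _enum(OrOrientation, row["or_orientation"], rownum, "or_orientation")
        if row["or_orientation"]
        else None
    )
    point = _opt_float(row["point"], rownum, "point")
    if point is None:
        raise ParseError("point estimate is required", row=rownum)
    ci_low = _opt_float(row["ci_low"], rownum, "ci_low")
    ci_high = _opt_float(row["ci_high"], rownum, "ci_high")
    ci_anomaly = _flag(row["ci_anomaly"], rownum, "ci_anomaly")

    if metric is Metric.EFFICACY and outcome_class not in EFFICACY_CLASSES:
        raise ParseError(
            f"efficacy metric is invalid for outcome class {outcome_class.value}",
            row=rownum,
        )
    if metric is Metric.ODDS_RATIO and outcome_class not in ODDS_RATIO_CLASSES:
        raise ParseError(
            f"odds-ratio metric is invalid for outcome class {outcome_class.value}",
            row=rownum,
        )
    if channel is not None and outcome_class is not OutcomeClass.PRACTICE_DISTRIBUTION:
        raise ParseError(
            "delivery channel is only valid for practice-distribution pairs",
            row=rownum,
        )
    try:
        effect = EffectSpec(
            metric=metric,
            point=point,
            ci_low=ci_low,
            ci_high=ci_high,
            or_orientation=orientation,
            channel=channel,
        )
    except ValueError as exc:
        raise ParseError(str(exc), row=rownum) from None
    if (
        not ci_anomaly
        and ci_low is not None
        and ci_high is not None
        and not (ci_low <= point <= ci_high)
    ):
        raise ParseError(
            f"point {point} outside CI ({ci_low}, {ci_high}) and not flagged ci_anomaly",
            row=rownum,
        )

    af_population = _enum(Population, row["af_population"], rownum, "af_population")
    fallback = tuple(t for t in row["af_fallback"].split(",") if t)
    try:
        af = AffectedFractionSpec(
            indicator_id=row["af_indicator"],
            population=af_population,
            fallback_chain=fallback,
        )
    except ValueError as exc:
        raise ParseError(str(exc), row=rownum) from None
    if af.indicator_id == "all" and fallback:
        raise ParseError("indicator 'all' cannot carry a fallback chain", row=rownum)
    if af_population not in _AF_COMPATIBLE[target_group]:
        raise ParseError(
            f"affected-fraction population {af_population.value} is inconsistent "
            f"with target group {target_group.value}",
            row=rownum,
        )

    return PairVariant(
        outcome_id=row["outcome_id"],
        target_group=target_group,
        effect=effect,
        affected_fraction=af,
        source=row["source"],
        raw=dict(row),
    )


def load_pair_registry(path: Union[str, Path]) -> PairRegistry:
    """Load and validate a tab-delimited intervention-outcome pair table.

    Rows sharing a ``pair_id`` are grouped into a single pair; pair-level
    fields (intervention, outcome class, quality) must agree across the
    group, while status flags are OR-ed (a pair counts as updated if any
    of its variants was updated).
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"registry file not found: {path}")
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        _check_header(header, PAIR_COLUMNS, path)
        raw_rows = []
        for i, fields in enumerate(reader, start=2):
            if not fields or all(f == "" for f in fields):
                continue
            if len(fields) != len(PAIR_COLUMNS):
                raise ParseError(
                    f"expected {len(PAIR_COLUMNS)} fields, got {len(fields)}", row=i
                )
            raw_rows.append((i, dict(zip(PAIR_COLUMNS, fields))))

    pairs: dict[str, InterventionOutcomePair] = {}
    order: list[str] = []
    seen_variants: set[tuple] = set()
    for rownum, row in raw_rows:
        variant = _parse_pair_row(row, rownum)
        pid = row["pair_id"]
        key = (
            pid,
            variant.outcome_id,
            variant.target_group,
            variant.effect.channel,
            variant.effect.or_orientation,
        )
        if key in seen_variants:
            raise IntegrityError(f"duplicate row for pair_id {pid!r}")
        seen_variants.add(key)

        quality = _enum(Quality, row["quality"], rownum, "quality")
        outcome_class = _enum(OutcomeClass, row["outcome_class"], rownum, "outcome_class")
        flags = {
            name: _flag(row[name], rownum, name)
            for name in ("is_new", "efficacy_updated", "af_updated", "ci_anomaly")
        }
        if pid not in pairs:
            pairs[pid] = InterventionOutcomePair(
                pair_id=pid,
                intervention_id=row["intervention_id"],
                intervention_name=row["intervention_name"],
                outcome_class=outcome_class,
                quality=quality,
                is_new=flags["is_new"],
                efficacy_updated=flags["efficacy_updated"],
                af_updated=flags["af_updated"],
                ci_anomaly=flags["ci_anomaly"],
                variants=[variant],
            )
            order.append(pid)
        else:
            pair = pairs[pid]
            for attr, col in (
                ("intervention_id", "intervention_id"),
                ("intervention_name", "intervention_name"),
            ):
                if getattr(pair, attr) != row[col]:
                    raise IntegrityError(
                        f"pair {pid!r}: conflicting {col} across variant rows"
                    )
            if pair.outcome_class is not outcome_class:
                raise IntegrityError(
                    f"pair {pid!r}: conflicting outcome_class across variant rows"
                )
            if pair.quality is not quality:
                raise IntegrityError(
                    f"pair {pid!r}: conflicting quality across variant rows"
                )
            pair.is_new = pair.is_new or flags["is_new"]
            pair.efficacy_updated = pair.efficacy_updated or flags["efficacy_updated"]
            pair.af_updated = pair.af_updated or flags["af_updated"]
            pair.ci_anomaly = pair.ci_anomaly or flags["ci_anomaly"]
            pair.variants.append(variant)

    for pair in pairs.values():
        metrics = {v.effect.metric for v in pair.variants}
        if len(metrics) != 1:
            raise IntegrityError(f"pair {pair.pair_id!r}: mixed effect metrics")

    return PairRegistry(
        pairs=[pairs[pid] for pid in order],
        path=path,
        _rows=[row for _, row in raw_rows],
    )


def load_exclusion_table(path: Union[str, Path]) -> list[ExclusionRecord]:
    """Load the reviewed-but-excluded pair table."""
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"exclusion file not found: {path}")
    records = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        _check_header(header, EXCLUSION_COLUMNS, path)
        for i, fields in enumerate(reader, start=2):
            if not fields or all(f == "" for f in fields):
                continue
            if len(fields) != len(EXCLUSION_COLUMNS):
                raise ParseError(
                    f"expected {len(EXCLUSION_COLUMNS)} fields, got {len(fields)}", row=i
                )
            row = dict(zip(EXCLUSION_COLUMNS, fields))
            reason = _enum(ExclusionReason, row["primary_reason"], i, "primary_reason")
            quality = (
                None
                if row["quality"] in ("", "NA")
                else _enum(Quality, row["quality"], i, "quality")
            )
            if row["section"] not in ("wra_pw", "infants_children"):
                raise ParseError(f"unknown section {row['section']!r}", row=i)
            records.append(
                ExclusionRecord(
                    intervention_name=row["intervention_name"],
                    outcome_name=row["outcome_name"],
                    primary_reason=reason,
                    quality=quality,
                    source=row["source"],
                    section=row["section"],
                )
            )
    return records


# ---------------------------------------------------------------------------
# module-level operation wrappers and bundled fixtures


def count_pairs(registry: PairRegistry, predicate: Predicate = None) -> int:
    return registry.count(predicate)


def distinct_interventions(
    registry: PairRegistry, predicate: Predicate = None
) -> frozenset[str]:
    return registry.distinct_interventions(predicate)


def write_registry(registry: PairRegistry, path: Union[str, Path]) -> None:
    registry.write(path)


def bundled_pairs_path() -> Path:
    return Path(str(resources.files(__package__) / "data" / "pairs.tsv"))


def bundled_exclusions_path() -> Path:
    return Path(str(resources.files(__package__) / "data" / "exclusions.tsv"))


def load_bundled_registry() -> PairRegistry:
    return load_pair_registry(bundled_pairs_path())


def load_bundled_exclusions() -> list[ExclusionRecord]:
    return load_exclusion_table(bundled_exclusions_path())
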