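"""Deterministic impact engine: coverage scale-up -> deaths averted.

The model assumes the baseline cause-specific death envelope already
reflects baseline intervention coverage.  For one intervention with
efficacy e, affected fraction af and coverage moving from c0 to c1, the
deaths averted out of a cause envelope D are

    D . e.af.(c1 - c0) / (1 - e.af.c0)

the denominator back-calculates the no-intervention envelope before
applying the new coverage.  Interventions sharing a cause and age band
are combined by residual multiplication so the joint impact can never
exceed the envelope:

    averted = D . [1 - prod_i (1 - r_i.c1_i) / (1 - r_i.c0_i)],  r_i = e_i.af_i

with the combined total attributed to interventions in proportion to
their single-intervention impacts.

Outcomes held as prevalence distributions (stunting/wasting z-score
categories, breastfeeding practices) move by odds ratios instead: the
covered-and-affected slice of the population has the odds at every
severity cut point multiplied by the canonical OR's reciprocal, and the
population-level cumulative at each cut moves by

    p' = p + af.(c1 - c0).(shifted(p) - p)

Scalar prevalences and rates (disease incidence, maternal anaemia, birth
outcome prevalences) scale multiplicatively by (1 - r.c1)/(1 - r.c0).

Negative point efficacies (possible when the source RR exceeded 1) are
clamped to zero with a logged warning: the engine never adds deaths from
a beneficial-intent intervention.  Coverage *decreases* are allowed and
produce negative "averted" values, flagged in the result's warnings.

The stunting/wasting -> mortality and breastfeeding -> mortality
linkages are deliberately not built in (their relative-risk parameters
live elsewhere in the wider model family); ``mortality_rr_hook`` on
:func:`run_scenario` accepts a user-supplied table should one want to
close that loop.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import yaml

from .affected_fractions import (
    BF_CATEGORIES,
    CountryProfile,
    resolve_affected_fraction,
)
from .conversion import OrderedDistribution, apply_or_to_prevalence, orient_odds_ratio
from .registry import (
    Channel,
    Metric,
    OrOrientation,
    PairRegistry,
    PairVariant,
    Population,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "ImpactResult",
    "OutcomeInfo",
    "OUTCOME_CATALOG",
    "ImpactConfigError",
    "deaths_averted_single",
    "combined_reduction",
    "shift_outcome_prevalence",
    "run_scenario",
    "load_scenario",
]


class ImpactConfigError(ValueError):
    """Scenario/registry/profile combination is not runnable."""


#: Age bands spanned by each target population (child bands only).
TARGET_BANDS = {
    Population.NEONATES_LT1MO: ("0mo",),
    Population.INFANTS_LT6MO: ("0mo", "1_5mo"),
    Population.INFANTS_1_6MO: ("1_5mo",),
    Population.CHILDREN_6_23MO: ("6_11mo", "12_23mo"),
    Population.CHILDREN_6_59MO: ("6_11mo", "12_23mo", "24_59mo"),
    Population.CHILDREN_12_59MO: ("12_23mo", "24_59mo"),
}


@dataclass(frozen=True)
class OutcomeInfo:
    """How the engine treats one outcome id.

    kind:
      ``mortality``  — averted counts against profile.deaths[cause];
      ``birth``      — averted counts against live_births x prevalence,
                       plus a prevalence trajectory;
      ``rate``       — multiplicative shift of profile.incidence[key];
      ``prevalence`` — multiplicative shift of profile.indicators[key];
      ``practice``   — OR shift of a breastfeeding-practice distribution;
      ``practice_prevalence`` — OR shift of a scalar practice indicator;
      ``anthropometry`` — OR shift of stunting/wasting distributions.
    """

    kind: str
    cause: Optional[str] = None
    key: Optional[str] = None
    bands: Optional[tuple[str, ...]] = None  # None: derive from target group


OUTCOME_CATALOG: dict[str, OutcomeInfo] = {
    "mort_diarrhoea": OutcomeInfo(kind="mortality", cause="diarrhoea"),
    "mort_pneumonia": OutcomeInfo(kind="mortality", cause="pneumonia"),
    "ntd_neonatal_mortality": OutcomeInfo(
        kind="mortality", cause="neural_tube_defects", bands=("0mo",)
    ),
    "mort_hypertensive_maternal": OutcomeInfo(
        kind="mortality", cause="hypertensive_disorder", bands=("maternal",)
    ),
    "ntd_stillbirth": OutcomeInfo(kind="birth", cause="ntd_stillbirth", key="ntd_stillbirth"),
    "stillbirth": OutcomeInfo(kind="birth", cause="stillbirth", key="stillbirth"),
    "sga": OutcomeInfo(kind="birth", cause="sga", key="sga"),
    "preterm": OutcomeInfo(kind="birth", cause="preterm", key="preterm"),
    "inc_diarrhoea": OutcomeInfo(kind="rate", key="inc_diarrhoea"),
    "inc_pneumonia": OutcomeInfo(kind="rate", key="inc_pneumonia"),
    "anaemia_maternal": OutcomeInfo(kind="prevalence", key="maternal_anaemia", bands=("PW",)),
    "stunting": OutcomeInfo(kind="anthropometry", key="stunting"),
    "wasting": OutcomeInfo(kind="anthropometry", key="wasting"),
    "bf_early_initiation": OutcomeInfo(
        kind="practice_prevalence", key="early_initiation_bf", bands=("0mo",)
    ),
    "bf_exclusive_lt1mo": OutcomeInfo(kind="practice", key="0mo", bands=("0mo",)),
    "bf_exclusive_1_5mo": OutcomeInfo(kind="practice", key="1_5mo", bands=("1_5mo",)),
    "bf_continued_6_23mo": OutcomeInfo(kind="practice", key="6_23mo", bands=("6_23mo",)),
}


@dataclass
class Scenario:
    """Coverage trajectories per intervention per year."""

    years: tuple[int, ...]
    coverage: dict[str, dict[int, float]]
    channel_mix: dict[str, dict[Channel, float]] = field(default_factory=dict)

    def validate(self) -> "Scenario":
        years = tuple(self.years)
        if not years:
            raise ImpactConfigError("scenario has no years")
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise ImpactConfigError("scenario years must be contiguous")
        for intervention, series in self.coverage.items():
            for year in years:
                if year not in series:
                    raise ImpactConfigError(
                        f"coverage for {intervention!r} missing year {year}"
                    )
                c = series[year]
                if not 0.0 <= c <= 1.0:
                    raise ImpactConfigError(
                        f"coverage {intervention!r}@{year} = {c} outside [0, 1]"
                    )
        for intervention, mix in self.channel_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ImpactConfigError(
                    f"channel mix for {intervention!r} sums to {total}, expected 1"
                )
            if any(w < 0 for w in mix.values()):
                raise ImpactConfigError(f"negative channel weight for {intervention!r}")
        return self

    def to_dict(self) -> dict:
        return {
            "years": list(self.years),
            "coverage": {
                i: {int(y): float(c) for y, c in series.items()}
                for i, series in self.coverage.items()
            },
            "channel_mix": {
                i: {ch.value: float(w) for ch, w in mix.items()}
                for i, mix in self.channel_mix.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "Scenario":
        return cls(
            years=tuple(int(y) for y in doc["years"]),
            coverage={
                i: {int(y): float(c) for y, c in series.items()}
                for i, series in doc.get("coverage", {}).items()
            },
            channel_mix={
                i: {Channel(ch): float(w) for ch, w in mix.items()}
                for i, mix in doc.get("channel_mix", {}).items()
            },
        ).validate()

    def save(self, path: Union[str, Path]) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_scenario(path: Union[str, Path]) -> Scenario:
    with Path(path).open(encoding="utf-8") as fh:
        return Scenario.from_dict(yaml.safe_load(fh))


@dataclass
class ImpactResult:
    """Deaths averted and prevalence trajectories from one scenario run."""

    deaths_averted: dict[tuple[str, str, str, int], float] = field(default_factory=dict)
    combined_deaths_averted: dict[tuple[str, str, int], float] = field(default_factory=dict)
    prevalence_trajectories: dict[tuple[str, str, int], object] = field(default_factory=dict)
    attribution: dict[tuple[str, str, int], dict[str, float]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def total_deaths_averted(self, year: Optional[int] = None) -> float:
        return sum(
            v
            for (cause, band, y), v in self.combined_deaths_averted.items()
            if year is None or y == year
        )


# ---------------------------------------------------------------------------
# elementary operations


def deaths_averted_single(
    cause_deaths: float, efficacy: float, af: float, c0: float, c1: float
) -> float:
    """Deaths averted by one intervention against one cause envelope."""
    if cause_deaths < 0:
        raise ValueError("cause_deaths must be non-negative")
    if not efficacy < 1:
        raise ValueError(f"efficacy must be < 1, got {efficacy}")
    for name, v in (("af", af), ("c0", c0), ("c1", c1)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    e = efficacy
    if e < 0:
        logger.warning("negative efficacy %.3f clamped to 0 for impact", e)
        e = 0.0
    denom = 1.0 - e * af * c0
    if denom <= 0.0:
        raise ValueError("e*af*c0 >= 1: baseline coverage would erase the envelope")
    return cause_deaths * e * af * (c1 - c0) / denom


def combined_reduction(components: Sequence[tuple[float, float, float]]) -> float:
    """1 - prod(1 - e.af.c) over (efficacy, af, coverage) components.

    Commutative residual multiplication; bounded below by the largest
    single reduction and above by min(1, sum of single reductions).
    """
    residual = 1.0
    for efficacy, af, c in components:
        if not efficacy < 1:
            raise ValueError(f"efficacy must be < 1, got {efficacy}")
        e = max(efficacy, 0.0)
        for name, v in (("af", af), ("coverage", c)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        residual *= 1.0 - e * af * c
    return 1.0 - residual


def _shift_cut(p: float, applied_or: float, af: float, c0: float, c1: float) -> float:
    """Population-level move of one cumulative cut point.

    Only the covered-and-affected slice is shifted; the change from the
    baseline-coverage slice is netted out:
    p' = p + af.(c1 - c0).(apply_or(p, OR) - p).
    """
    return p + af * (c1 - c0) * (apply_or_to_prevalence(p, applied_or) - p)


def shift_outcome_prevalence(
    baseline: Union[OrderedDistribution, float],
    canonical_or: float,
    af: float,
    c0: float,
    c1: float,
):
    """Shift a prevalence or ordered distribution for one odds-ratio pair.

    ``canonical_or`` is in the model direction (odds of the adverse
    outcome without the intervention over with it; > 1 means benefit), so
    the covered slice's adverse-side odds are multiplied by its
    reciprocal.  OR = 1 or c1 = c0 returns the baseline unchanged.
    """
    if not canonical_or > 0:
        raise ValueError("odds ratio must be positive")
    applied = 1.0 / canonical_or
    if isinstance(baseline, OrderedDistribution):
        shifted = tuple(_shift_cut(p, applied, af, c0, c1) for p in baseline.cumulative)
        return OrderedDistribution(cut_labels=baseline.cut_labels, cumulative=shifted)
    return _shift_cut(float(baseline), applied, af, c0, c1)


# ---------------------------------------------------------------------------
# scenario engine


def _canonical_or(
    pair_variants: Sequence[PairVariant],
    intervention_id: str,
    channel_mix: dict[str, dict[Channel, float]],
) -> float:
    """Canonical OR for an odds-ratio pair, mixing channels if needed.

    Multi-channel pairs combine their per-channel ORs on the log scale,
    weighted by the scenario's channel mix (renormalised over the channels
    the pair actually has).  Pairs quoting both orientations use the
    already-canonical "without intervention" variant.
    """
    channelled = [v for v in pair_variants if v.effect.channel is not None]
    if channelled:
        mix = channel_mix.get(intervention_id)
        if mix is None:
            raise ImpactConfigError(
                f"multi-channel pair for {intervention_id!r} requires a channel mix"
            )
        available = {v.effect.channel: v for v in channelled}
        weights = {ch: w for ch, w in mix.items() if ch in available}
        total = sum(weights.values())
        if total <= 0:
            raise ImpactConfigError(
                f"channel mix for {intervention_id!r} has no weight on available "
                f"channels {sorted(c.value for c in available)}"
            )
        log_or = sum(
            (w / total)
            * math.log(
                orient_odds_ratio(
                    available[ch].effect.point, available[ch].effect.or_orientation
                )
            )
            for ch, w in weights.items()
        )
        return math.exp(log_or)

    canonical = [
        v
        for v in pair_variants
        if v.effect.or_orientation is OrOrientation.ODDS_WITHOUT_INTERVENTION
    ]
    chosen = canonical[0] if canonical else pair_variants[0]
    return orient_odds_ratio(chosen.effect.point, chosen.effect.or_orientation)


def _bands_for(info: OutcomeInfo, variant: PairVariant) -> tuple[str, ...]:
    if info.bands is not None:
        return info.bands
    bands = TARGET_BANDS.get(variant.target_group)
    if bands is None:
        raise ImpactConfigError(
            f"cannot derive age bands for target group {variant.target_group.value}"
        )
    return bands


def _scale(r: float, c0: float, c1: float) -> float:
    """Multiplicative survival-style factor (1 - r.c1)/(1 - r.c0)."""
    return (1.0 - r * c1) / (1.0 - r * c0)


def run_scenario(
    profile: CountryProfile,
    registry: PairRegistry,
    scenario: Scenario,
    *,
    mortality_rr_hook: Optional[Callable] = None,
) -> ImpactResult:
    """Run a coverage scale-up scenario against a country profile.

    Deterministic: the result is a pure function of its inputs.  The
    baseline year's coverages come from ``profile.baseline_coverage``
    (missing interventions default to zero).  Interventions present in
    the scenario but absent from the registry are an error.

    ``mortality_rr_hook``, if given, is called with the result after the
    direct pathways are computed; it may append additional entries (e.g.
    an anthropometry -> mortality linkage with user-supplied relative
    risks).  No such linkage is applied by default.
    """
    scenario.validate()
    known = registry.distinct_interventions()
    unknown = set(scenario.coverage) - set(known)
    if unknown:
        raise ImpactConfigError(f"scenario interventions not in registry: {sorted(unknown)}")

    result = ImpactResult()
    warned_negative: set[str] = set()

    for year in scenario.years:
        # (cause, band) -> intervention -> [(single_averted, ratio_factor)]
        mort: dict[tuple[str, str], dict[str, list[tuple[float, float]]]] = defaultdict(
            lambda: defaultdict(list)
        )
        envelopes: dict[tuple[str, str], float] = {}
        # (outcome_id, band) -> list of (canonical_or, af, c0, c1)
        dist_contribs: dict[tuple[str, str], list[tuple[float, float, float, float]]] = (
            defaultdict(list)
        )
        # (outcome_id, band/key) -> list of scale factors
        scalar_contribs: dict[tuple[str, str], list[float]] = defaultdict(list)

        for pair in registry:
            if pair.intervention_id not in scenario.coverage:
                continue
            c0 = profile.baseline_coverage.get(pair.intervention_id, 0.0)
            c1 = scenario.coverage[pair.intervention_id][year]
            if c1 < c0 and pair.pair_id not in warned_negative:
                result.warnings.append(
                    f"{pair.pair_id}: coverage decreases ({c0:.3f} -> {c1:.3f}); "
                    "negative averted values denote deaths added"
                )
                warned_negative.add(pair.pair_id)

            if pair.metric is Metric.EFFICACY:
                for variant in pair.variants:
                    info = OUTCOME_CATALOG.get(variant.outcome_id)
                    if info is None:
                        raise ImpactConfigError(
                            f"unknown outcome id {variant.outcome_id!r} in pair "
                            f"{pair.pair_id!r}"
                        )
                    af = resolve_affected_fraction(variant.affected_fraction, profile)
                    e = variant.effect.point
                    if e < 0:
                        if pair.pair_id not in warned_negative:
                            logger.warning(
                                "pair %s: negative efficacy %.3f clamped to 0",
                                pair.pair_id,
                                e,
                            )
                            warned_negative.add(pair.pair_id)
                        e = 0.0
                    r = e * af
                    if info.kind == "mortality":
                        for band in _bands_for(info, variant):
                            deaths = profile.deaths.get(info.cause, {}).get(band)
                            if deaths is None:
                                continue
                            key = (info.cause, band)
                            envelopes[key] = deaths
                            single = deaths_averted_single(deaths, e, af, c0, c1)
                            mort[key][pair.intervention_id].append(
                                (single, _scale(r, c0, c1))
                            )
                    elif info.kind == "birth":
                        prevalence = profile.birth_outcomes.get(info.key)
                        if prevalence is None:
                            result.warnings.append(
                                f"{pair.pair_id}: no baseline prevalence for "
                                f"{info.key}; outcome skipped"
                            )
                            continue
                        events = profile.live_births * prevalence
                        key = (info.cause, "birth")
                        envelopes[key] = events
                        single = deaths_averted_single(events, e, af, c0, c1)
                        mort[key][pair.intervention_id].append(
                            (single, _scale(r, c0, c1))
                        )
                        scalar_contribs[(variant.outcome_id, "birth")].append(
                            _scale(r, c0, c1)
                        )
                    elif info.kind == "rate":
                        if info.key in profile.incidence:
                            band = variant.target_group.value
                            scalar_contribs[(variant.outcome_id, band)].append(
                                _scale(r, c0, c1)
                            )
                    elif info.kind == "prevalence":
                        if info.key in profile.indicators:
                            scalar_contribs[(variant.outcome_id, info.bands[0])].append(
                                _scale(r, c0, c1)
                            )
                    else:  # pragma: no cover - fixture carries no such pair
                        raise ImpactConfigError(
                            f"efficacy metric unsupported for outcome kind {info.kind}"
                        )
            else:  # odds-ratio pair
                variant = pair.variants[0]
                info = OUTCOME_CATALOG.get(variant.outcome_id)
                if info is None:
                    raise ImpactConfigError(
                        f"unknown outcome id {variant.outcome_id!r} in pair "
                        f"{pair.pair_id!r}"
                    )
                canonical = _canonical_or(
                    pair.variants, pair.intervention_id, scenario.channel_mix
                )
                af = resolve_affected_fraction(variant.affected_fraction, profile)
                if info.kind == "anthropometry":
                    for band in _bands_for(info, variant):
                        if band in profile.distributions.get(info.key, {}):
                            dist_contribs[(variant.outcome_id, band)].append(
                                (canonical, af, c0, c1)
                            )
                elif info.kind == "practice":
                    if info.key in profile.bf_practices:
                        dist_contribs[(variant.outcome_id, info.key)].append(
                            (canonical, af, c0, c1)
                        )
                elif info.kind == "practice_prevalence":
                    if info.key in profile.indicators:
                        dist_contribs[(variant.outcome_id, info.bands[0])].append(
                            (canonical, af, c0, c1)
                        )
                else:
                    raise ImpactConfigError(
                        f"odds-ratio metric unsupported for outcome kind {info.kind}"
                    )

        # ---- combine mortality-style outcomes per (cause, band) --------
        for key, by_intervention in mort.items():
            cause, band = key
            envelope = envelopes[key]
            residual = 1.0
            singles: dict[str, float] = {}
            for intervention, entries in by_intervention.items():
                single_total = 0.0
                for single, factor in entries:
                    single_total += single
                    residual *= factor
                singles[intervention] = single_total
                result.deaths_averted[(intervention, cause, band, year)] = single_total
            combined = envelope * (1.0 - residual)
            result.combined_deaths_averted[(cause, band, year)] = combined
            total_single = sum(singles.values())
            if total_single != 0.0:
                shares = {
                    i: combined * s / total_single for i, s in singles.items()
                }
            else:
                shares = {i: 0.0 for i in singles}
            result.attribution[(cause, band, year)] = shares

        # ---- scalar prevalence/rate outcomes ----------------------------
        for (outcome_id, band), factors in scalar_contribs.items():
            info = OUTCOME_CATALOG[outcome_id]
            if info.kind == "rate":
                base = profile.incidence[info.key]
            elif info.kind == "prevalence":
                base = profile.indicators[info.key]
            else:  # birth prevalence trajectory
                base = profile.birth_outcomes[info.key]
            value = base
            for f in factors:
                value *= f
            result.prevalence_trajectories[(outcome_id, band, year)] = value

        # ---- distribution / OR outcomes ---------------------------------
        for (outcome_id, band), contribs in dist_contribs.items():
            info = OUTCOME_CATALOG[outcome_id]
            if info.kind == "anthropometry":
                baseline = profile.distributions[info.key][band]
                cuts = list(baseline.cumulative)
                new_cuts = []
                for p in cuts:
                    delta = sum(
                        af * (c1 - c0) * (apply_or_to_prevalence(p, 1.0 / canonical) - p)
                        for canonical, af, c0, c1 in contribs
                    )
                    new_cuts.append(min(max(p + delta, 1e-12), 1.0 - 1e-12))
                # cumulative ordering is preserved for any one contribution;
                # guard against pathological stacked shifts
                for i in range(1, len(new_cuts)):
                    new_cuts[i] = max(new_cuts[i], new_cuts[i - 1] + 1e-15)
                shifted = OrderedDistribution(
                    cut_labels=baseline.cut_labels, cumulative=tuple(new_cuts)
                )
                result.prevalence_trajectories[(outcome_id, band, year)] = dict(
                    zip(shifted.cut_labels, shifted.category_probabilities())
                )
            elif info.kind == "practice":
                categories = BF_CATEGORIES[info.key]
                probs = [profile.bf_practices[info.key][c] for c in categories]
                # adverse-side cumulatives: worst practice first
                worst_first = probs[::-1]
                cuts = []
                acc = 0.0
                for p in worst_first[:-1]:
                    acc += p
                    cuts.append(acc)
                new_cuts = []
                for p in cuts:
                    delta = sum(
                        af * (c1 - c0) * (apply_or_to_prevalence(p, 1.0 / canonical) - p)
                        for canonical, af, c0, c1 in contribs
                    )
                    new_cuts.append(min(max(p + delta, 1e-12), 1.0 - 1e-12))
                for i in range(1, len(new_cuts)):
                    new_cuts[i] = max(new_cuts[i], new_cuts[i - 1] + 1e-15)
                new_worst = [new_cuts[0]]
                for a, b in zip(new_cuts, new_cuts[1:]):
                    new_worst.append(b - a)
                new_worst.append(1.0 - new_cuts[-1])
                result.prevalence_trajectories[(outcome_id, info.key, year)] = dict(
                    zip(categories, new_worst[::-1])
                )
            else:  # practice_prevalence: scalar proportion of a good practice
                p_good = profile.indicators[info.key]
                p_bad = 1.0 - p_good
                delta = sum(
                    af * (c1 - c0) * (apply_or_to_prevalence(p_bad, 1.0 / canonical) - p_bad)
                    for canonical, af, c0, c1 in contribs
                )
                new_bad = min(max(p_bad + delta, 0.0), 1.0)
                result.prevalence_trajectories[(outcome_id, band, year)] = 1.0 - new_bad

    if mortality_rr_hook is not None:
        mortality_rr_hook(result)
    return result
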