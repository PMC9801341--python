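"""Modified-GRADE evidence-quality scoring for intervention-outcome pairs.

The grade is an ordinal level (very low / low / moderate / high) assigned
to the body of evidence behind one intervention-outcome pair:

1. The starting level depends on study design: reviews of RCTs only start
   high, mixed RCT/non-RCT reviews start moderate, and non-RCT-only
   reviews start low.
2. The level is downgraded one step per *serious* and two steps per *very
   serious* limitation across five criteria: indirectness, risk of bias,
   inconsistency, imprecision, and publication bias.  Downgrades are
   summed and the result is floored at very low.
3. Only when no downgrade was applied, the level may be upgraded one step
   per documented reason (a large effect, a dose-response relationship),
   capped at high.

The grade is a pure function of the design mix, the five criterion
ratings, and the upgrade flags; the quantitative metadata carried on an
:class:`EvidenceProfile` (I-squared, study and event counts) are advisory.
:class:`RatingRules` offers default numeric cut-offs for turning that
metadata into inconsistency/imprecision ratings, but the thresholds are
deliberately user-editable: the checklist criteria are fixed while the
operational cut-offs are a reviewer's choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = [
    "Level",
    "DesignMix",
    "Rating",
    "UpgradeFlag",
    "CRITERIA",
    "EvidenceProfile",
    "QualityAssessment",
    "RatingRules",
    "initial_level",
    "apply_downgrades",
    "apply_upgrades",
    "grade_evidence",
    "load_evidence_profiles",
]


class Level(IntEnum):
    VERY_LOW = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()


class DesignMix(str, Enum):
    RCT_ONLY = "rct_only"
    MIXED = "mixed"
    NON_RCT_ONLY = "non_rct_only"


class Rating(str, Enum):
    NONE = "none"
    SERIOUS = "serious"
    VERY_SERIOUS = "very_serious"


class UpgradeFlag(str, Enum):
    LARGE_EFFECT = "large_effect"
    DOSE_RESPONSE = "dose_response"


CRITERIA = (
    "indirectness",
    "risk_of_bias",
    "inconsistency",
    "imprecision",
    "publication_bias",
)

_START = {
    DesignMix.RCT_ONLY: Level.HIGH,
    DesignMix.MIXED: Level.MODERATE,
    DesignMix.NON_RCT_ONLY: Level.LOW,
}

_STEPS = {Rating.NONE: 0, Rating.SERIOUS: 1, Rating.VERY_SERIOUS: 2}


@dataclass(frozen=True)
class EvidenceProfile:
    """The inputs to a grade for one intervention-outcome pair."""

    design_mix: DesignMix
    criterion_ratings: dict[str, Rating]
    upgrade_flags: frozenset[UpgradeFlag] = frozenset()
    i_squared: Optional[float] = None
    n_studies: Optional[int] = None
    n_events: Optional[int] = None

    def __post_init__(self) -> None:
        missing = [c for c in CRITERIA if c not in self.criterion_ratings]
        if missing:
            raise ValueError(f"criterion_ratings missing {missing}")
        unknown = [c for c in self.criterion_ratings if c not in CRITERIA]
        if unknown:
            raise ValueError(f"unknown criteria {unknown}")
        if self.i_squared is not None and not 0 <= self.i_squared <= 100:
            raise ValueError("i_squared must be a percentage in [0, 100]")


@dataclass(frozen=True)
class QualityAssessment:
    start_level: Level
    total_downgrade: int
    total_upgrade: int
    final_level: Level
    trace: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        expected = Level(
            min(3, max(0, self.start_level - self.total_downgrade + self.total_upgrade))
        )
        if self.final_level is not expected:
            raise ValueError("final_level inconsistent with start/downgrade/upgrade")
        if self.total_upgrade > 0 and self.total_downgrade > 0:
            raise ValueError("upgrades are only permitted when nothing was downgraded")


def initial_level(design_mix: DesignMix) -> Level:
    """Starting grade implied by the review's study-design mix."""
    return _START[DesignMix(design_mix)]


def apply_downgrades(
    level: Level, criterion_ratings: dict[str, Rating]
) -> tuple[Level, int, tuple[tuple[str, str, int], ...]]:
    """Subtract 1/2 steps per serious/very-serious criterion, floored at 0.

    Downgrades are summed across criteria before flooring (equivalent to
    stepwise flooring under clamping; stated for determinism).  The trace
    records one ``(criterion, rating, delta)`` entry per criterion in the
    canonical criterion order, so the result is independent of input
    ordering.
    """
    trace = []
    total = 0
    for criterion in CRITERIA:
        rating = Rating(criterion_ratings.get(criterion, Rating.NONE))
        delta = _STEPS[rating]
        total += delta
        trace.append((criterion, rating.value, -delta))
    return Level(max(0, int(level) - total)), total, tuple(trace)


def apply_upgrades(
    level: Level, upgrade_flags: frozenset[UpgradeFlag], total_downgrade: int
) -> tuple[Level, int]:
    """Raise one level per distinct upgrade reason, only if never downgraded.

    Capped at high; at most two reasons (large effect, dose-response) exist.
    """
    if total_downgrade > 0:
        return level, 0
    n = len({UpgradeFlag(f) for f in upgrade_flags})
    return Level(min(3, int(level) + n)), n


def grade_evidence(profile: EvidenceProfile) -> QualityAssessment:
    """Full grade: start level -> downgrades -> (conditional) upgrades."""
    start = initial_level(profile.design_mix)
    downgraded, total_down, trace = apply_downgrades(start, profile.criterion_ratings)
    final, total_up = apply_upgrades(downgraded, profile.upgrade_flags, total_down)
    up_trace = tuple(
        (flag.value, "upgrade", 1)
        for flag in sorted(profile.upgrade_flags, key=lambda f: f.value)
        if total_up > 0
    )
    return QualityAssessment(
        start_level=start,
        total_downgrade=total_down,
        total_upgrade=total_up,
        final_level=final,
        trace=trace + up_trace,
    )


@dataclass(frozen=True)
class RatingRules:
    """Default numeric cut-offs for rating inconsistency and imprecision.

    These operationalise two of the five criteria from quantitative review
    metadata.  The defaults (inconsistency serious above 50% I-squared,
    very serious above 75%; imprecision serious below 3 studies, very
    serious below 100 events) follow common meta-analytic practice; they
    are exposed as plain fields so a reviewer can substitute their own.
    """

    i2_serious: float = 50.0
    i2_very_serious: float = 75.0
    min_studies: int = 3
    min_events: int = 100

    def rate_inconsistency(self, i_squared: Optional[float]) -> Rating:
        if i_squared is None:
            return Rating.NONE
        if i_squared > self.i2_very_serious:
            return Rating.VERY_SERIOUS
        if i_squared > self.i2_serious:
            return Rating.SERIOUS
        return Rating.NONE

    def rate_imprecision(
        self, n_studies: Optional[int] = None, n_events: Optional[int] = None
    ) -> Rating:
        if n_events is not None and n_events < self.min_events:
            return Rating.VERY_SERIOUS
        if n_studies is not None and n_studies < self.min_studies:
            return Rating.SERIOUS
        return Rating.NONE


def load_evidence_profiles(path: Union[str, Path]) -> dict[str, EvidenceProfile]:
    """Read a YAML mapping of pair_id -> evidence profile.

    Each entry gives ``design_mix``, per-criterion ratings (missing
    criteria default to ``none``), and optional ``upgrades`` list plus
    advisory metadata.
    """
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    profiles = {}
    for pair_id, spec in doc.items():
        ratings = {
            c: Rating(spec.get(c, "none")) for c in CRITERIA
        }
        profiles[pair_id] = EvidenceProfile(
            design_mix=DesignMix(spec["design_mix"]),
            criterion_ratings=ratings,
            upgrade_flags=frozenset(UpgradeFlag(u) for u in spec.get("upgrades", [])),
            i_squared=spec.get("i_squared"),
            n_studies=spec.get("n_studies"),
            n_events=spec.get("n_events"),
        )
    return profiles
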