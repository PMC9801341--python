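"""Effect-size conversions and odds-ratio arithmetic on distributions.

Two effect metrics drive the model.  *Efficacy* is 1 - relative risk: the
proportional reduction of an adverse outcome among covered, affected
individuals.  *Odds ratios* are used for outcomes that are prevalence
distributions (stunting/wasting z-score categories, breastfeeding
practices): the intervention changes the odds of sitting at or beyond
each severity cut point, applied uniformly at every cut (a
proportional-odds assumption).

Risk-ratio CIs map to efficacy CIs with a bound swap (1 - upper, 1 -
lower), so coverage ordering is preserved; efficacies can legitimately be
negative when the underlying RR exceeds 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .registry import EffectSpec, Metric, OrOrientation

__all__ = [
    "RiskRatioEstimate",
    "OrderedDistribution",
    "rr_to_efficacy",
    "efficacy_to_rr",
    "orient_odds_ratio",
    "apply_or_to_prevalence",
    "shift_category_distribution",
]

#: Default z-score cut points for stunting/wasting category distributions,
#: most severe first: z < -3, -3 <= z < -2, -2 <= z < -1, z >= -1.
ZSCORE_CUT_LABELS = ("z<-3", "-3<=z<-2", "-2<=z<-1", "z>=-1")


@dataclass(frozen=True)
class RiskRatioEstimate:
    """A relative risk with an optional 95% CI."""

    rr: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.rr > 0:
            raise ValueError(f"relative risk must be positive, got {self.rr}")
        for name in ("ci_low", "ci_high"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.rr <= self.ci_high:
                raise ValueError(
                    f"rr {self.rr} outside CI ({self.ci_low}, {self.ci_high})"
                )


@dataclass(frozen=True)
class OrderedDistribution:
    """An ordered-category distribution stored as severe-side cumulatives.

    ``cumulative[i]`` is the probability of being at or beyond cut point
    ``i`` on the severe side (e.g. P(z < -3), P(z < -2), P(z < -1) for a
    four-category z-score distribution).  Cumulatives must be strictly
    increasing within (0, 1); the implied category probabilities are
    non-negative and sum to one by construction.
    """

    cut_labels: tuple[str, ...]
    cumulative: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cut_labels) != len(self.cumulative) + 1:
            raise ValueError(
                "need one category label per cut point plus one for the mildest "
                f"category: {len(self.cut_labels)} labels, {len(self.cumulative)} cuts"
            )
        prev = 0.0
        for c in self.cumulative:
            if not 0.0 < c < 1.0:
                raise ValueError(f"cumulative probability {c} outside (0, 1)")
            if c <= prev:
                raise ValueError("cumulative probabilities must be strictly increasing")
            prev = c

    @classmethod
    def from_categories(
        cls, labels: Sequence[str], probabilities: Sequence[float], *, tol: float = 1e-9
    ) -> "OrderedDistribution":
        """Build from per-category probabilities, most severe first."""
        total = sum(probabilities)
        if abs(total - 1.0) > max(tol, 1e-9):
            raise ValueError(f"category probabilities sum to {total}, expected 1")
        cumulative = []
        acc = 0.0
        for p in probabilities[:-1]:
            acc += p
            cumulative.append(acc)
        return cls(cut_labels=tuple(labels), cumulative=tuple(cumulative))

    def category_probabilities(self) -> tuple[float, ...]:
        probs = [self.cumulative[0]]
        for a, b in zip(self.cumulative, self.cumulative[1:]):
            probs.append(b - a)
        probs.append(1.0 - self.cumulative[-1])
        return tuple(probs)


def rr_to_efficacy(est: RiskRatioEstimate) -> EffectSpec:
    """Convert a relative risk to an efficacy (1 - RR) effect.

    CI bounds swap: the efficacy lower bound is 1 minus the RR upper
    bound.  Negative efficacy (RR > 1, harm direction) is representable.
    """
    return EffectSpec(
        metric=Metric.EFFICACY,
        point=1.0 - est.rr,
        ci_low=None if est.ci_high is None else 1.0 - est.ci_high,
        ci_high=None if est.ci_low is None else 1.0 - est.ci_low,
    )


def efficacy_to_rr(eff: EffectSpec) -> RiskRatioEstimate:
    """Exact inverse of :func:`rr_to_efficacy`."""
    if eff.metric is not Metric.EFFICACY:
        raise TypeError(f"expected an efficacy effect, got metric {eff.metric.value}")
    return RiskRatioEstimate(
        rr=1.0 - eff.point,
        ci_low=None if eff.ci_high is None else 1.0 - eff.ci_high,
        ci_high=None if eff.ci_low is None else 1.0 - eff.ci_low,
    )


def orient_odds_ratio(or_value: float, orientation: OrOrientation) -> float:
    """Express an odds ratio in the canonical model direction.

    Canonical means "odds of the adverse outcome without the intervention
    relative to with it", so values above 1 indicate benefit.  An OR
    quoted the other way round (adverse odds with the intervention in the
    numerator) is inverted.
    """
    if not or_value > 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    orientation = OrOrientation(orientation)
    if orientation is OrOrientation.ODDS_WITHOUT_INTERVENTION:
        return or_value
    return 1.0 / or_value


def apply_or_to_prevalence(p: float, or_value: float) -> float:
    """Multiply the odds of a prevalence by ``or_value``.

    p' = OR.p/(1-p) / (1 + OR.p/(1-p)).  The endpoints 0 and 1 are fixed
    points; the transform is strictly increasing in both arguments.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {p}")
    if not or_value > 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    if p == 0.0 or p == 1.0 or or_value == 1.0:
        return p
    odds = or_value * p / (1.0 - p)
    return odds / (1.0 + odds)


def shift_category_distribution(
    dist: OrderedDistribution, or_value: float
) -> OrderedDistribution:
    """Apply one odds ratio at every severity cut point.

    An OR below 1 reduces the odds of sitting at or beyond each severe-side
    cut, shifting mass towards the mild end.  Strict monotonicity of the
    cumulatives is preserved because the odds transform is strictly
    monotone in p.
    """
    shifted = tuple(apply_or_to_prevalence(c, or_value) for c in dist.cumulative)
    return OrderedDistribution(cut_labels=dist.cut_labels, cumulative=shifted)
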