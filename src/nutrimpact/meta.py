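"""Inverse-variance meta-analysis of mean differences.

Implements fixed-effect pooling and DerSimonian-Laird (DL) random-effects
pooling of study-level mean differences (z-score units for the
complementary-food analyses), with the usual heterogeneity statistics:

* Cochran's Q around the fixed-effect mean, with df = k - 1;
* the DL moment estimator tau^2 = max(0, (Q - df) / (S1 - S2/S1)) where
  S1 and S2 are the sums of fixed-effect weights and squared weights;
* I^2 = max(0, (Q - df)/Q) x 100 (zero when Q = 0).

Random-effects weights are 1/(se_i^2 + tau^2); when tau^2 = 0 the DL pool
equals the fixed pool, and the DL confidence interval is never narrower
than the fixed one.  95% intervals use the normal quantile 1.959964 (no
t or Hartung-Knapp adjustment), matching the conventions of standard
systematic-review software.  Subgroup pooling simply runs DL within each
food-type stratum independently: local unfortified food, industrially
fortified (non-LNS) food, and small-quantity lipid-based nutrient
supplements (SQ-LNS).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

__all__ = [
    "Z95",
    "FoodType",
    "StudyEstimate",
    "PooledEstimate",
    "fixed_pool",
    "dl_pool",
    "subgroup_pool",
    "load_trials",
]

#: Two-sided 95% normal quantile used for every confidence interval here.
Z95 = 1.959964


class FoodType(str, Enum):
    LOCAL_UNFORTIFIED = "local_unfortified"
    FORTIFIED_NON_LNS = "fortified_non_lns"
    SQ_LNS = "sq_lns"


@dataclass(frozen=True)
class StudyEstimate:
    """One trial's mean difference and standard error."""

    study_id: str
    md: float
    se: float
    n_int: Optional[int] = None
    n_ctl: Optional[int] = None
    food_type: Optional[FoodType] = None
    outcome: Optional[str] = None
    se_from_ci: bool = False

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"standard error must be positive, got {self.se}")

    @classmethod
    def from_ci(
        cls,
        study_id: str,
        md: float,
        ci_low: float,
        ci_high: float,
        **kwargs,
    ) -> "StudyEstimate":
        """Recover the SE from a 95% CI assuming normality."""
        if ci_high <= ci_low:
            raise ValueError("ci_high must exceed ci_low")
        se = (ci_high - ci_low) / (2.0 * Z95)
        return cls(study_id=study_id, md=md, se=se, se_from_ci=True, **kwargs)


@dataclass(frozen=True)
class PooledEstimate:
    md: float
    se: float
    ci_low: float
    ci_high: float
    q: float
    df: int
    tau2: float
    i2: float
    k: int
    model: str

    def __post_init__(self) -> None:
        if not self.ci_low <= self.md <= self.ci_high:
            raise ValueError("pooled estimate outside its own CI")

    @property
    def significant(self) -> bool:
        """True when the 95% CI excludes zero."""
        return self.ci_low > 0.0 or self.ci_high < 0.0


def _heterogeneity(studies: Sequence[StudyEstimate]) -> tuple[float, int, float, float, float]:
    """Return (Q, df, S1, S2, fixed-effect mean)."""
    weights = [1.0 / (s.se * s.se) for s in studies]
    s1 = sum(weights)
    s2 = sum(w * w for w in weights)
    mean = sum(w * s.md for w, s in zip(weights, studies)) / s1
    # Q is identically zero for k = 1; avoid float noise driving I2 to 100
    q = 0.0 if len(studies) == 1 else sum(
        w * (s.md - mean) ** 2 for w, s in zip(weights, studies)
    )
    return q, len(studies) - 1, s1, s2, mean


def _i2(q: float, df: int) -> float:
    if q <= 0.0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def fixed_pool(studies: Sequence[StudyEstimate]) -> PooledEstimate:
    """Inverse-variance fixed-effect pool."""
    if not studies:
        raise ValueError("cannot pool an empty study list")
    q, df, s1, _s2, mean = _heterogeneity(studies)
    se = 1.0 / math.sqrt(s1)
    return PooledEstimate(
        md=mean,
        se=se,
        ci_low=mean - Z95 * se,
        ci_high=mean + Z95 * se,
        q=q,
        df=df,
        tau2=0.0,
        i2=_i2(q, df),
        k=len(studies),
        model="fixed",
    )


def dl_pool(studies: Sequence[StudyEstimate]) -> PooledEstimate:
    """DerSimonian-Laird random-effects pool."""
    if not studies:
        raise ValueError("cannot pool an empty study list")
    q, df, s1, s2, _mean = _heterogeneity(studies)
    denom = s1 - s2 / s1
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    weights = [1.0 / (s.se * s.se + tau2) for s in studies]
    total = sum(weights)
    mean = sum(w * s.md for w, s in zip(weights, studies)) / total
    se = 1.0 / math.sqrt(total)
    return PooledEstimate(
        md=mean,
        se=se,
        ci_low=mean - Z95 * se,
        ci_high=mean + Z95 * se,
        q=q,
        df=df,
        tau2=tau2,
        i2=_i2(q, df),
        k=len(studies),
        model="dl",
    )


def subgroup_pool(
    studies: Sequence[StudyEstimate],
    by: Callable[[StudyEstimate], Optional[FoodType]] = lambda s: s.food_type,
) -> dict[FoodType, PooledEstimate]:
    """Independent DL pools within each food-type subgroup.

    Subgroups with no studies are omitted; an unlabelled study is an error.
    """
    groups: dict[FoodType, list[StudyEstimate]] = {}
    for s in studies:
        label = by(s)
        if label is None:
            raise ValueError(f"study {s.study_id!r} has no subgroup label")
        groups.setdefault(FoodType(label), []).append(s)
    return {ft: dl_pool(members) for ft, members in groups.items()}


TRIAL_COLUMNS = [
    "study_id",
    "food_type",
    "outcome",
    "md",
    "ci_low",
    "ci_high",
    "n_int",
    "n_ctl",
]


def load_trials(path: Union[str, Path]) -> list[StudyEstimate]:
    """Read a tab-delimited trial table (CIs are converted to SEs)."""
    path = Path(path)
    studies = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in TRIAL_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing column {missing[0]!r}")
        for row in reader:
            studies.append(
                StudyEstimate.from_ci(
                    study_id=row["study_id"],
                    md=float(row["md"]),
                    ci_low=float(row["ci_low"]),
                    ci_high=float(row["ci_high"]),
                    n_int=int(row["n_int"]) if row["n_int"] else None,
                    n_ctl=int(row["n_ctl"]) if row["n_ctl"] else None,
                    food_type=FoodType(row["food_type"]) if row["food_type"] else None,
                    outcome=row["outcome"] or None,
                )
            )
    return studies
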