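"""Country profiles and affected-fraction resolution.

A :class:`CountryProfile` is the state a scenario acts on: population by
age band, cause-specific deaths, indicator prevalences (micronutrient
deficiencies, food insecurity, poverty), baseline stunting/wasting and
breastfeeding-practice distributions, disease incidence rates, birth-
outcome prevalences, and baseline intervention coverages.

The affected fraction of an intervention-outcome pair is the proportion
of its target population that can actually benefit (the deficient, the
food-insecure, the ill).  Resolution walks the pair's indicator id and
fallback chain against the profile.  Two special rules:

* Food insecurity prefers the Food Insecurity Experience Scale (FIES)
  prevalence and falls back to the share of the population living below
  $1.90/day when FIES is unavailable for the country (the two indicators
  are strongly correlated across countries, which is what justifies the
  substitution).
* Food *security* indicators are the complement: 1 minus the resolved
  food-insecurity value, when no direct value is stored.

Age bands follow the under-five convention: 0 months, 1-5, 6-11, 12-23
and 24-59 months, plus women of reproductive age (WRA), pregnant women
(PW) and a maternal band for maternal deaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from scipy import stats

from .conversion import OrderedDistribution, ZSCORE_CUT_LABELS
from .registry import AffectedFractionSpec

__all__ = [
    "AGE_BANDS",
    "FOOD_INSECURITY_CHAIN",
    "CountryProfile",
    "ProfileError",
    "ResolutionError",
    "load_profile",
    "resolve_affected_fraction",
    "pearson_correlation",
]

AGE_BANDS = ("0mo", "1_5mo", "6_11mo", "12_23mo", "24_59mo")

#: Default lookup chain for food-insecurity indicators: FIES prevalence
#: first, $1.90/day poverty head-count as the fallback.
FOOD_INSECURITY_CHAIN = ("fies", "poverty_190")

#: Breastfeeding practice categories by age band (best practice first).
BF_CATEGORIES = {
    "0mo": ("exclusive", "predominant", "partial", "none"),
    "1_5mo": ("exclusive", "predominant", "partial", "none"),
    "6_23mo": ("any", "none"),
}


class ProfileError(ValueError):
    """The country profile fails validation."""


class ResolutionError(KeyError):
    """No indicator in the affected-fraction chain could be resolved."""


@dataclass
class CountryProfile:
    name: str
    population: dict[str, float]
    live_births: float
    deaths: dict[str, dict[str, float]]  # cause -> age band -> deaths/year
    indicators: dict[str, float]
    incidence: dict[str, float] = field(default_factory=dict)
    birth_outcomes: dict[str, float] = field(default_factory=dict)
    distributions: dict[str, dict[str, OrderedDistribution]] = field(default_factory=dict)
    bf_practices: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline_coverage: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "CountryProfile":
        problems = []
        for band, count in self.population.items():
            if count < 0:
                problems.append(f"population[{band}] is negative")
        if self.live_births < 0:
            problems.append("live_births is negative")
        for cause, by_band in self.deaths.items():
            for band, d in by_band.items():
                if d < 0:
                    problems.append(f"deaths[{cause}][{band}] is negative")
        for key, value in {**self.indicators, **self.birth_outcomes}.items():
            if not 0.0 <= value <= 1.0:
                problems.append(f"proportion {key} = {value} outside [0, 1]")
        for key, value in self.baseline_coverage.items():
            if not 0.0 <= value <= 1.0:
                problems.append(f"baseline coverage {key} = {value} outside [0, 1]")
        if "fies" not in self.indicators and "poverty_190" not in self.indicators:
            problems.append(
                "indicator poverty_190 is required whenever fies is absent "
                "(food-insecurity fallback would be unresolvable)"
            )
        for band, cats in self.bf_practices.items():
            expected = BF_CATEGORIES.get(band)
            if expected is not None and set(cats) != set(expected):
                problems.append(f"bf_practices[{band}] categories != {expected}")
            if abs(sum(cats.values()) - 1.0) > 1e-6:
                problems.append(f"bf_practices[{band}] does not sum to 1")
        if problems:
            raise ProfileError(f"profile {self.name!r}: " + "; ".join(problems))
        return self

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "population": dict(self.population),
            "live_births": self.live_births,
            "deaths": {c: dict(b) for c, b in self.deaths.items()},
            "indicators": dict(self.indicators),
            "incidence": dict(self.incidence),
            "birth_outcomes": dict(self.birth_outcomes),
            "distributions": {
                outcome: {
                    band: {
                        "labels": list(dist.cut_labels),
                        "cumulative": list(dist.cumulative),
                    }
                    for band, dist in by_band.items()
                }
                for outcome, by_band in self.distributions.items()
            },
            "bf_practices": {b: dict(c) for b, c in self.bf_practices.items()},
            "baseline_coverage": dict(self.baseline_coverage),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "CountryProfile":
        distributions = {
            outcome: {
                band: OrderedDistribution(
                    cut_labels=tuple(spec.get("labels", ZSCORE_CUT_LABELS)),
                    cumulative=tuple(spec["cumulative"]),
                )
                for band, spec in by_band.items()
            }
            for outcome, by_band in doc.get("distributions", {}).items()
        }
        return cls(
            name=doc["name"],
            population={k: float(v) for k, v in doc.get("population", {}).items()},
            live_births=float(doc.get("live_births", 0.0)),
            deaths={
                c: {b: float(v) for b, v in by_band.items()}
                for c, by_band in doc.get("deaths", {}).items()
            },
            indicators={k: float(v) for k, v in doc.get("indicators", {}).items()},
            incidence={k: float(v) for k, v in doc.get("incidence", {}).items()},
            birth_outcomes={
                k: float(v) for k, v in doc.get("birth_outcomes", {}).items()
            },
            distributions=distributions,
            bf_practices={
                b: {k: float(v) for k, v in cats.items()}
                for b, cats in doc.get("bf_practices", {}).items()
            },
            baseline_coverage={
                k: float(v) for k, v in doc.get("baseline_coverage", {}).items()
            },
        )

    def save(self, path: Union[str, Path]) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_profile(path: Union[str, Path]) -> CountryProfile:
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return CountryProfile.from_dict(doc).validate()


def _lookup_chain(chain: Sequence[str], profile: CountryProfile) -> Optional[tuple[float, str]]:
    for indicator in chain:
        if indicator in profile.indicators:
            return profile.indicators[indicator], indicator
    return None


def resolve_affected_fraction(
    spec: AffectedFractionSpec,
    profile: CountryProfile,
    *,
    with_provenance: bool = False,
):
    """Resolve one affected-fraction spec against a profile.

    Returns the fraction in [0, 1]; with ``with_provenance`` the name of
    the indicator that supplied it is returned alongside ("all" for the
    unconditional rule, "1-<indicator>" for derived food security).
    Resolution uses the first available indicator in the chain; later
    fallbacks never override an earlier hit.
    """
    if spec.indicator_id == "all":
        return (1.0, "all") if with_provenance else 1.0

    chain = (spec.indicator_id, *spec.fallback_chain)
    hit = _lookup_chain(chain, profile)
    if hit is None and spec.indicator_id.startswith("food_security"):
        counterpart = spec.indicator_id.replace("food_security", "food_insecurity", 1)
        sub = _lookup_chain((counterpart, *FOOD_INSECURITY_CHAIN), profile)
        if sub is not None:
            value, via = 1.0 - sub[0], f"1-{sub[1]}"
            return (value, via) if with_provenance else value
    if hit is None:
        raise ResolutionError(
            f"no indicator available for affected fraction (tried {', '.join(chain)})"
        )
    value, via = hit
    return (value, via) if with_provenance else value


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation with explicit degeneracy guards."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
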