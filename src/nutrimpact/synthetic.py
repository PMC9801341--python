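"""Seeded generators for country profiles, trial sets, and scenarios.

Everything downstream of the parameter registry needs country state and
trial data that real deployments pull from surveys, vital statistics and
systematic reviews.  These generators produce validated stand-ins with
magnitudes loosely matching low- and middle-income settings (e.g.
under-five mortality 30-100 per 1000 live births with diarrhoea at
5-20% of under-five deaths), purely so the machinery can be exercised
and tested end to end; no generated profile resembles any real country.

Determinism: every generator call derives an independent random stream
from ``(seed, purpose-tag, index)`` via :class:`numpy.random.SeedSequence`,
so the same inputs always reproduce byte-identical artifacts and adding
a new generator never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .affected_fractions import AGE_BANDS, CountryProfile
from .conversion import OrderedDistribution, ZSCORE_CUT_LABELS
from .impact import Scenario
from .meta import FoodType, StudyEstimate
from .registry import Channel, PairRegistry

__all__ = [
    "GeneratorParams",
    "TrialParams",
    "generate_country_profile",
    "generate_trial_set",
    "generate_scenario",
]


def _rng(seed: int, tag: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode()), int(index)])
    )


#: Plausible ranges for deficiency/insecurity indicators (proportions).
DEFAULT_DEFICIENCY_RANGES: dict[str, tuple[float, float]] = {
    "iron_deficiency_wra": (0.15, 0.50),
    "iron_deficiency_pw": (0.20, 0.60),
    "folate_insufficiency_wra": (0.10, 0.40),
    "calcium_deficiency_pw": (0.30, 0.80),
    "vitamin_a_deficiency_pw": (0.10, 0.40),
    "vitamin_a_deficiency_6_59": (0.10, 0.50),
    "zinc_deficiency_12_59": (0.10, 0.50),
    "maternal_anaemia": (0.20, 0.60),
    "fies": (0.10, 0.60),
    "poverty_190": (0.05, 0.50),
    "with_diarrhoea_lt1mo": (0.01, 0.05),
    "with_diarrhoea_6_59": (0.10, 0.40),
    "early_initiation_bf": (0.30, 0.70),
}


@dataclass(frozen=True)
class TrialParams:
    """Conditions for the complementary-food trial generator.

    One mean-difference trial set per food-type subgroup.  Defaults model
    the study landscape the subgroup re-analysis addresses: only SQ-LNS
    carries a real benefit on the z-score outcome (true mean difference
    0.14 SD), other food types are null; arm sizes of a few hundred
    children; mild between-study heterogeneity; z-score SD 1.1.
    """

    k_per_subgroup: int = 12
    true_md: dict = field(
        default_factory=lambda: {
            FoodType.LOCAL_UNFORTIFIED: 0.0,
            FoodType.FORTIFIED_NON_LNS: 0.0,
            FoodType.SQ_LNS: 0.14,
        }
    )
    tau2: float = 0.002
    n_range: tuple[int, int] = (300, 700)
    outcome_sd: float = 1.1
    outcome: str = "haz_md"


@dataclass(frozen=True)
class GeneratorParams:
    seed: int
    n_countries: int = 1
    mortality_scale: float = 1.0
    deficiency_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_DEFICIENCY_RANGES)
    )
    fies_missing_prob: float = 0.3
    trial_params: TrialParams = field(default_factory=TrialParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fies_missing_prob <= 1.0:
            raise ValueError("fies_missing_prob must be a probability")
        for key, (lo, hi) in self.deficiency_ranges.items():
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError(f"bad range for {key}: ({lo}, {hi})")


def _dirichlet_categories(
    rng: np.random.Generator, mean: Sequence[float], concentration: float = 60.0
) -> tuple[float, ...]:
    draw = rng.dirichlet(np.asarray(mean) * concentration)
    # keep strictly interior so cumulative cut points stay in (0, 1)
    draw = np.clip(draw, 1e-4, None)
    draw = draw / draw.sum()
    return tuple(float(x) for x in draw)


def _zscore_distribution(
    rng: np.random.Generator, mean_categories: Sequence[float]
) -> OrderedDistribution:
    cats = _dirichlet_categories(rng, mean_categories)
    return OrderedDistribution.from_categories(ZSCORE_CUT_LABELS, cats)


def generate_country_profile(params: GeneratorParams, index: int = 0) -> CountryProfile:
    """Generate one validated synthetic country profile."""
    rng = _rng(params.seed, "country_profile", index)

    live_births = float(rng.uniform(50_000, 500_000))
    population = {
        "0mo": live_births / 12.0,
        "1_5mo": live_births * 5.0 / 12.0,
        "6_11mo": live_births * 0.49,
        "12_23mo": live_births * 0.96,
        "24_59mo": live_births * 2.8,
        "WRA": live_births * rng.uniform(18.0, 26.0),
        "PW": live_births * rng.uniform(1.0, 1.4),
    }

    u5mr = rng.uniform(30.0, 100.0) * params.mortality_scale  # per 1000 births
    total_u5_deaths = live_births * u5mr / 1000.0
    frac_diarrhoea = rng.uniform(0.05, 0.20)
    frac_pneumonia = rng.uniform(0.10, 0.20)
    frac_ntd = rng.uniform(0.005, 0.02)
    frac_other = 1.0 - frac_diarrhoea - frac_pneumonia - frac_ntd
    age_split = rng.dirichlet([8.0, 3.0, 3.0, 3.0, 3.0])  # heavy neonatal share

    def _by_band(total: float) -> dict[str, float]:
        return {band: float(total * w) for band, w in zip(AGE_BANDS, age_split)}

    deaths = {
        "diarrhoea": _by_band(total_u5_deaths * frac_diarrhoea),
        "pneumonia": _by_band(total_u5_deaths * frac_pneumonia),
        "neural_tube_defects": {"0mo": float(total_u5_deaths * frac_ntd)},
        "other": _by_band(total_u5_deaths * frac_other),
        "hypertensive_disorder": {
            "maternal": float(live_births * rng.uniform(50, 400) / 100_000 * 0.15)
        },
    }

    indicators = {}
    for key, (lo, hi) in params.deficiency_ranges.items():
        indicators[key] = float(rng.uniform(lo, hi))
    if rng.random() < params.fies_missing_prob:
        indicators.pop("fies", None)

    incidence = {
        "inc_diarrhoea": float(rng.uniform(1.0, 4.0)),  # episodes/child-year
        "inc_pneumonia": float(rng.uniform(0.1, 0.5)),
    }
    birth_outcomes = {
        "sga": float(rng.uniform(0.10, 0.30)),
        "preterm": float(rng.uniform(0.08, 0.15)),
        "stillbirth": float(rng.uniform(0.01, 0.03)),
        "ntd_stillbirth": float(rng.uniform(0.0005, 0.002)),
    }

    distributions = {
        "stunting": {
            band: _zscore_distribution(rng, [0.08, 0.15, 0.25, 0.52])
            for band in AGE_BANDS
        },
        "wasting": {
            band: _zscore_distribution(rng, [0.02, 0.06, 0.18, 0.74])
            for band in AGE_BANDS
        },
    }

    bf_practices = {
        "0mo": dict(
            zip(
                ("exclusive", "predominant", "partial", "none"),
                _dirichlet_categories(rng, [0.50, 0.18, 0.22, 0.10]),
            )
        ),
        "1_5mo": dict(
            zip(
                ("exclusive", "predominant", "partial", "none"),
                _dirichlet_categories(rng, [0.35, 0.20, 0.30, 0.15]),
            )
        ),
        "6_23mo": dict(
            zip(("any", "none"), _dirichlet_categories(rng, [0.80, 0.20]))
        ),
    }

    baseline_coverage = {
        intervention: float(rng.uniform(0.05, 0.40))
        for intervention in sorted(_DEFAULT_INTERVENTIONS)
    }

    profile = CountryProfile(
        name=f"synthetic-{params.seed}-{index:03d}",
        population=population,
        live_births=live_births,
        deaths=deaths,
        indicators=indicators,
        incidence=incidence,
        birth_outcomes=birth_outcomes,
        distributions=distributions,
        bf_practices=bf_practices,
        baseline_coverage=baseline_coverage,
    )
    return profile.validate()


_DEFAULT_INTERVENTIONS = (
    "iron_fortification",
    "folic_acid",
    "balanced_energy_protein",
    "multiple_micronutrient_supplementation",
    "calcium_supplementation",
    "iron_supplementation",
    "iycf_education",
    "complementary_feeding_education",
    "provision_fortified_complementary_food",
    "zinc_supplementation",
    "vitamin_a_supplementation",
    "zinc_treatment_diarrhoea",
    "neonatal_vitamin_a_supplementation",
    "zinc_fortification",
)


def generate_trial_set(params: GeneratorParams, index: int = 0) -> list[StudyEstimate]:
    """Generate complementary-food trials, one batch per food-type subgroup.

    Study-level true effects are ``true_md + N(0, tau2)``; observed mean
    differences add sampling noise ``N(0, se^2)`` with the SE derived
    from the drawn arm sizes and the outcome SD.
    """
    rng = _rng(params.seed, "trial_set", index)
    tp = params.trial_params
    studies = []
    for food_type in FoodType:
        true_md = float(tp.true_md.get(food_type, 0.0))
        for j in range(tp.k_per_subgroup):
            n_int = int(rng.integers(tp.n_range[0], tp.n_range[1] + 1))
            n_ctl = int(rng.integers(tp.n_range[0], tp.n_range[1] + 1))
            se = tp.outcome_sd * np.sqrt(1.0 / n_int + 1.0 / n_ctl)
            theta = true_md + rng.normal(0.0, np.sqrt(tp.tau2))
            md = float(theta + rng.normal(0.0, se))
            studies.append(
                StudyEstimate(
                    study_id=f"{food_type.value}_{j:02d}",
                    md=md,
                    se=float(se),
                    n_int=n_int,
                    n_ctl=n_ctl,
                    food_type=food_type,
                    outcome=tp.outcome,
                )
            )
    return studies


def generate_scenario(
    seed: int,
    registry: PairRegistry,
    years: Sequence[int],
    baseline_coverage: Optional[dict[str, float]] = None,
    index: int = 0,
) -> Scenario:
    """Linear coverage scale-up to a seeded target per intervention.

    Starts at the supplied baseline coverage (default: a seeded draw in
    [0.05, 0.30]) and ramps linearly to a target in [0.5, 0.9] by the
    final year, clamped to [0, 1].  Channel mixes are generated for every
    multi-channel intervention.
    """
    rng = _rng(seed, "scenario", index)
    years = tuple(int(y) for y in years)
    baseline_coverage = baseline_coverage or {}
    coverage = {}
    for intervention in sorted(registry.distinct_interventions()):
        start = float(baseline_coverage.get(intervention, rng.uniform(0.05, 0.30)))
        target = float(rng.uniform(0.5, 0.9))
        if len(years) == 1:
            series = {years[0]: min(max(target, 0.0), 1.0)}
        else:
            step = (target - start) / (len(years) - 1)
            series = {
                y: min(max(start + i * step, 0.0), 1.0) for i, y in enumerate(years)
            }
        coverage[intervention] = series

    channel_mix = {}
    multi_channel = {
        p.intervention_id for p in registry if p.is_multi_channel
    }
    for intervention in sorted(multi_channel):
        weights = rng.dirichlet([4.0, 4.0, 2.0])
        channel_mix[intervention] = {
            Channel.HEALTH_SYSTEM: float(weights[0]),
            Channel.HOME_COMMUNITY: float(weights[1]),
            Channel.COMBINED: float(weights[2]),
        }
    return Scenario(years=years, coverage=coverage, channel_mix=channel_mix).validate()
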