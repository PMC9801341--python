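"""Independent re-implementations used as test oracles.

These deliberately avoid importing the implementation internals they
check; each codes the rule or formula from scratch in the most direct
way possible.
"""

from __future__ import annotations

import itertools
import math


def grade_by_rule_table(design: str, ratings: dict[str, str], flags: frozenset) -> int:
    """Ordinal grade (0..3) via explicit lookup tables, no arithmetic reuse."""
    start_table = {"rct_only": 3, "mixed": 2, "non_rct_only": 1}
    penalty_table = {"none": 0, "serious": 1, "very_serious": 2}
    level = start_table[design]
    penalties = [penalty_table[r] for r in ratings.values()]
    if sum(penalties) > 0:
        level = level - sum(penalties)
        if level < 0:
            level = 0
        return level
    # never downgraded: one step up per distinct reason, ceiling at high
    for _ in sorted({f for f in flags}):
        if level < 3:
            level += 1
    return level


def enumerate_grading_space():
    """All 3 x 3^5 x 4 evidence-profile combinations."""
    designs = ("rct_only", "mixed", "non_rct_only")
    ratings = ("none", "serious", "very_serious")
    criteria = (
        "indirectness",
        "risk_of_bias",
        "inconsistency",
        "imprecision",
        "publication_bias",
    )
    flag_sets = (
        frozenset(),
        frozenset({"large_effect"}),
        frozenset({"dose_response"}),
        frozenset({"large_effect", "dose_response"}),
    )
    for design in designs:
        for combo in itertools.product(ratings, repeat=len(criteria)):
            for flags in flag_sets:
                yield design, dict(zip(criteria, combo)), flags


def inverse_variance_pool(mds, ses):
    """Brute-force fixed-effect weighted mean and its CI."""
    weights = [1.0 / s**2 for s in ses]
    mean = sum(w * m for w, m in zip(weights, mds)) / sum(weights)
    se = math.sqrt(1.0 / sum(weights))
    return mean, se, mean - 1.959964 * se, mean + 1.959964 * se


def dl_tau2(mds, ses):
    """Closed-form DerSimonian-Laird moment estimator."""
    weights = [1.0 / s**2 for s in ses]
    mean = sum(w * m for w, m in zip(weights, mds)) / sum(weights)
    q = sum(w * (m - mean) ** 2 for w, m in zip(weights, mds))
    df = len(mds) - 1
    c = sum(weights) - sum(w**2 for w in weights) / sum(weights)
    if c <= 0:
        return 0.0
    return max(0.0, (q - df) / c)


def residual_product_averted(envelope, components, baseline, scaled):
    """Deaths averted by enumerating all 2^n coverage cells.

    ``components`` is a list of per-intervention (efficacy, affected
    fraction); ``baseline``/``scaled`` are the coverage vectors.  The
    no-intervention envelope is recovered from the baseline cell sum,
    then re-exposed to the scaled coverages.
    """

    def cell_sum(coverages):
        total = 0.0
        n = len(components)
        for mask in range(2**n):
            prob = 1.0
            risk = 1.0
            for i, (e, af) in enumerate(components):
                if mask >> i & 1:
                    prob *= coverages[i]
                    risk *= 1.0 - max(e, 0.0) * af
                else:
                    prob *= 1.0 - coverages[i]
            total += prob * risk
        return total

    return envelope * (1.0 - cell_sum(scaled) / cell_sum(baseline))
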