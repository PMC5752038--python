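"""Drug-combination scoring: Bliss-expected effect, fold excess additivism
(FEA), excess-over-sum, and a replicate-paired supra-additivity test.

Bliss independence treats two drugs as independent causes of death, so the
expected combined effect of fractions A and B is C = A + B - A*B. FEA is the
ratio of observed to Bliss-expected effect (>1 = supra-additive); it is never
clipped, so antagonism shows up as FEA < 1. Significance uses a one-sided
paired t-test on per-replicate observed-minus-expected differences (pairing by
replicate index preserves within-replicate correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    UndefinedFEAError,
)

DEFAULT_ALPHA = 0.05
#: p-value reported when all replicate differences are identical and positive
DEGENERATE_P = 1e-7


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise InvalidParameterError(f"{name} must be in [0,1], got {value}")


def bliss_expected(a: float, b: float) -> float:
    """Expected combined effect of independent agents: a + b - a*b."""
    _check_fraction("a", a)
    _check_fraction("b", b)
    return a + b - a * b


def fold_excess_additivism(observed: float, expected: float) -> float:
    """Observed over Bliss-expected effect; sub-additive ratios pass through."""
    if expected <= 0.0:
        raise UndefinedFEAError(
            "fold excess additivism not evaluable: expected effect is zero"
        )
    return observed / expected


def additive_excess(observed: float, a: float, b: float) -> float:
    """Observed combined effect minus the sum of single-agent effects."""
    _check_fraction("observed", observed)
    _check_fraction("a", a)
    _check_fraction("b", b)
    return observed - (a + b)


@dataclass(frozen=True)
class SupraAdditivityTest:
    fea: float | None            # mean(observed) / mean(expected); None if not evaluable
    p_value: float
    significant: bool
    t_statistic: float | None
    mean_difference: float
    degenerate_variance: bool
    alpha: float


def supra_additivity_test(
    observed_reps, a_reps, b_reps, alpha: float = DEFAULT_ALPHA
) -> SupraAdditivityTest:
    """One-sided paired test of observed > Bliss-expected across replicates.

    Per replicate i, d_i = observed_i - bliss_expected(a_i, b_i); a one-sample
    t-test (df = n-1) tests mean(d) > 0. If the differences have exactly zero
    variance the t statistic is undefined: an all-positive constant difference
    is reported as p < 1e-6 with a degenerate-variance flag (constant zero or
    negative differences are reported non-significant).
    """
    observed = [float(x) for x in observed_reps]
    a = [float(x) for x in a_reps]
    b = [float(x) for x in b_reps]
    n = len(observed)
    if not (len(a) == len(b) == n):
        raise InsufficientDataError("replicate lists must have equal length")
    if n < 2:
        raise InsufficientDataError(f"supra-additivity test needs >= 2 replicates, got {n}")
    expected = [bliss_expected(ai, bi) for ai, bi in zip(a, b)]
    for obs in observed:
        _check_fraction("observed", obs)
    d = np.array(observed) - np.array(expected)
    mean_d = float(d.mean())
    mean_expected = float(np.mean(expected))
    fea = float(np.mean(observed)) / mean_expected if mean_expected > 0 else None

    if float(np.ptp(d)) == 0.0:
        if mean_d > 0:
            p, t, degenerate = DEGENERATE_P, None, True
        elif mean_d == 0:
            p, t, degenerate = 0.5, 0.0, True
        else:
            p, t, degenerate = 1.0 - DEGENERATE_P, None, True
    else:
        res = stats.ttest_1samp(d, popmean=0.0, alternative="greater")
        p, t, degenerate = float(res.pvalue), float(res.statistic), False

    return SupraAdditivityTest(
        fea=fea,
        p_value=p,
        significant=bool(p < alpha),
        t_statistic=t,
        mean_difference=mean_d,
        degenerate_variance=degenerate,
        alpha=alpha,
    )


@dataclass(frozen=True)
class CombinationResult:
    """Full scoring record for one unordered drug pair."""

    agent_a: str
    agent_b: str
    observed_per_replicate: tuple[float, ...]
    effect_a_per_replicate: tuple[float, ...]
    effect_b_per_replicate: tuple[float, ...]
    expected_per_replicate: tuple[float, ...]
    fea: float | None
    excess: float
    p_value: float
    significant: bool
    degenerate_variance: bool
    alpha: float

    @property
    def pair_key(self) -> frozenset[str]:
        return frozenset((self.agent_a, self.agent_b))


def score_combination(
    agent_a: str,
    agent_b: str,
    observed_reps,
    a_reps,
    b_reps,
    alpha: float = DEFAULT_ALPHA,
) -> CombinationResult:
    """Score one pair: Bliss expectation per replicate, FEA, excess-over-sum,
    and the supra-additivity significance call."""
    test = supra_additivity_test(observed_reps, a_reps, b_reps, alpha=alpha)
    expected = tuple(bliss_expected(ai, bi) for ai, bi in zip(a_reps, b_reps))
    excess = additive_excess(
        float(np.mean([float(x) for x in observed_reps])),
        float(np.mean([float(x) for x in a_reps])),
        float(np.mean([float(x) for x in b_reps])),
    )
    return CombinationResult(
        agent_a=agent_a,
        agent_b=agent_b,
        observed_per_replicate=tuple(float(x) for x in observed_reps),
        effect_a_per_replicate=tuple(float(x) for x in a_reps),
        effect_b_per_replicate=tuple(float(x) for x in b_reps),
        expected_per_replicate=expected,
        fea=test.fea,
        excess=excess,
        p_value=test.p_value,
        significant=test.significant,
        degenerate_variance=test.degenerate_variance,
        alpha=alpha,
    )
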