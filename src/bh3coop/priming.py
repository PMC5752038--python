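"""Delta-priming statistics, the concentration-screening rule, and the
BAD-BH3 vs MS1-BH3 dichotomisation of agents.

Delta-priming normalises the agent-specific gain in peptide-induced
cytochrome-C release to the head-room left by the peptide-only baseline:

    delta = (p_agent_peptide - p_peptide) / (1 - p_peptide)

on release fractions (the percent form divides by 100 everywhere). Only the
peptide-in-untreated baseline is subtracted — no drug-alone correction — and
deltas are computed per matched replicate pair before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, stdev

from .errors import (
    IncompleteProfileError,
    InvalidParameterError,
    UndefinedBaselineError,
)

#: classification labels: which antagonist class the agent sensitises cells to
SENSITISES_TO_BCL2_ANTAGONISM = "SENSITISES_TO_BCL2_ANTAGONISM"
SENSITISES_TO_MCL1_ANTAGONISM = "SENSITISES_TO_MCL1_ANTAGONISM"
BOTH = "BOTH"
NEITHER = "NEITHER"

#: default minimum delta-priming to call an agent a primer for a peptide
DEFAULT_DELTA_THRESHOLD = 0.30
#: default ceiling on drug-alone release above which a profile is over-lethal
DEFAULT_DRUG_ALONE_CEILING = 0.10
#: screening rule bounds (release fractions)
SCREEN_PUMA_FLOOR = 0.75
SCREEN_CONTROL_CEILING = 0.10


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise InvalidParameterError(f"{name} must be in [0,1], got {value}")


def delta_priming(p_agent_peptide: float, p_peptide_only: float) -> float:
    """Agent-specific priming gain, normalised to the peptide-only baseline.

    May be negative (de-priming); never clipped. Undefined when the baseline is
    already 100% release.
    """
    _check_fraction("p_agent_peptide", p_agent_peptide)
    _check_fraction("p_peptide_only", p_peptide_only)
    if p_peptide_only >= 1.0:
        raise UndefinedBaselineError(
            "delta-priming undefined: peptide-only release is 100%"
        )
    return (p_agent_peptide - p_peptide_only) / (1.0 - p_peptide_only)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the priming-concentration screen for one agent/dose."""

    passed: bool
    reason: str
    p_with_puma: float
    p_with_control: float
    #: simple difference of the two screen bounds / measurements, percent scale
    simple_difference_pct: float
    #: the same pair pushed through the delta-priming formula
    normalised_delta: float


def screen_priming_concentration(p_with_puma: float, p_with_control: float) -> ScreenResult:
    """Is the dose suitable for profiling? Pass iff release with the
    promiscuous PUMA-BH3 peptide exceeds 75% while release with the inactive
    control peptide stays below 10% (both strict)."""
    _check_fraction("p_with_puma", p_with_puma)
    _check_fraction("p_with_control", p_with_control)
    puma_ok = p_with_puma > SCREEN_PUMA_FLOOR
    control_ok = p_with_control < SCREEN_CONTROL_CEILING
    if puma_ok and control_ok:
        reason = "pass"
    elif not puma_ok and not control_ok:
        reason = "PUMA and control criteria failed"
    elif not puma_ok:
        reason = "PUMA criterion failed (release with PUMA-BH3 not > 75%)"
    else:
        reason = "control criterion failed (release with control peptide not < 10%)"
    return ScreenResult(
        passed=puma_ok and control_ok,
        reason=reason,
        p_with_puma=p_with_puma,
        p_with_control=p_with_control,
        simple_difference_pct=100.0 * (p_with_puma - p_with_control),
        normalised_delta=(
            delta_priming(p_with_puma, p_with_control)
            if p_with_control < 1.0
            else float("nan")
        ),
    )


@dataclass(frozen=True)
class PrimingResult:
    """Delta-priming of one agent for one peptide across matched replicates."""

    agent: str
    peptide: str
    priming_time: float
    delta_per_replicate: tuple[float, ...]
    delta_mean: float
    delta_sd: float
    drug_alone_release_mean: float


def priming_result(
    agent: str,
    peptide: str,
    priming_time: float,
    p_agent_peptide_reps: list[float],
    p_peptide_only_reps: list[float],
    drug_alone_reps: list[float],
) -> PrimingResult:
    """Compute per-replicate deltas (matched replicate indices) and summarise."""
    if len(p_agent_peptide_reps) != len(p_peptide_only_reps):
        raise IncompleteProfileError(
            f"{agent}/{peptide}: replicate lists differ in length"
        )
    deltas = tuple(
        delta_priming(ap, p)
        for ap, p in zip(p_agent_peptide_reps, p_peptide_only_reps)
    )
    return PrimingResult(
        agent=agent,
        peptide=peptide,
        priming_time=priming_time,
        delta_per_replicate=deltas,
        delta_mean=mean(deltas),
        delta_sd=stdev(deltas) if len(deltas) > 1 else 0.0,
        drug_alone_release_mean=mean(drug_alone_reps) if drug_alone_reps else float("nan"),
    )


@dataclass(frozen=True)
class AgentProfile:
    """Dichotomised priming profile of one agent at one priming time."""

    agent: str
    priming_time: float
    delta_bad: float
    delta_ms1: float
    delta_puma: float | None = None
    screen_pass: bool | None = None
    class_: str = NEITHER
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD
    drug_alone_ceiling: float = DEFAULT_DRUG_ALONE_CEILING
    drug_alone_release: float = 0.0
    over_lethal: bool = False
    reversible_binder: bool = False
    time_dependent_class: bool = False
    flags: tuple[str, ...] = field(default=())


def classify_agent(
    delta_bad: float,
    delta_ms1: float,
    drug_alone: float,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    drug_alone_ceiling: float = DEFAULT_DRUG_ALONE_CEILING,
) -> tuple[str, tuple[str, ...]]:
    """Assign the dichotomisation class from the two deltas.

    An agent primes to a peptide when its delta reaches the threshold; priming
    to BAD-BH3 marks sensitisation to BCL-2 antagonism, priming to MS1 marks
    sensitisation to MCL-1 antagonism. An agent killing too much on its own
    (drug-alone release at or above the ceiling) is unclassifiable: NEITHER
    with an over-lethal flag.
    """
    if delta_bad is None or delta_ms1 is None:
        raise IncompleteProfileError("classification requires both deltas")
    _check_fraction("drug_alone", drug_alone)
    if drug_alone >= drug_alone_ceiling:
        return NEITHER, ("over_lethal",)
    primes_bad = delta_bad >= delta_threshold
    primes_ms1 = delta_ms1 >= delta_threshold
    if primes_bad and primes_ms1:
        return BOTH, ()
    if primes_bad:
        return SENSITISES_TO_BCL2_ANTAGONISM, ()
    if primes_ms1:
        return SENSITISES_TO_MCL1_ANTAGONISM, ()
    return NEITHER, ()


def build_profile(
    agent: str,
    priming_time: float,
    bad: PrimingResult,
    ms1: PrimingResult,
    puma: PrimingResult | None = None,
    screen: ScreenResult | None = None,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    drug_alone_ceiling: float = DEFAULT_DRUG_ALONE_CEILING,
    reversible_binder: bool = False,
    time_dependent_class: bool = False,
) -> AgentProfile:
    """Assemble an AgentProfile from per-peptide priming results."""
    drug_alone = bad.drug_alone_release_mean
    class_, flags = classify_agent(
        bad.delta_mean, ms1.delta_mean, drug_alone, delta_threshold, drug_alone_ceiling
    )
    return AgentProfile(
        agent=agent,
        priming_time=priming_time,
        delta_bad=bad.delta_mean,
        delta_ms1=ms1.delta_mean,
        delta_puma=puma.delta_mean if puma is not None else None,
        screen_pass=screen.passed if screen is not None else None,
        class_=class_,
        delta_threshold=delta_threshold,
        drug_alone_ceiling=drug_alone_ceiling,
        drug_alone_release=drug_alone,
        over_lethal="over_lethal" in flags,
        reversible_binder=reversible_binder,
        time_dependent_class=time_dependent_class,
        flags=flags,
    )
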