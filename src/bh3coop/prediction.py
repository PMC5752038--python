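"""Predict co-operative drug pairs from priming profiles and score the
predictions against measured combination outcomes.

The central rule: a pair is predicted co-operative exactly when one agent
sensitises cells to BCL-2 antagonism (primes to BAD-BH3) and the other to
MCL-1 antagonism (primes to MS1) — a BOTH-class agent can fill either role.
Reversible binders carry a caveat: the sequential profiling assay washes the
drug away before the peptide challenge, so their priming is invisible to the
assay (a known blind spot), and their pairs are flagged rather than trusted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .combination import CombinationResult
from .errors import PairingError
from .priming import (
    AgentProfile,
    BOTH,
    NEITHER,
    SENSITISES_TO_BCL2_ANTAGONISM,
    SENSITISES_TO_MCL1_ANTAGONISM,
)


def _roles(profile: AgentProfile) -> frozenset[str]:
    if profile.class_ == BOTH:
        return frozenset({SENSITISES_TO_BCL2_ANTAGONISM, SENSITISES_TO_MCL1_ANTAGONISM})
    if profile.class_ == NEITHER:
        return frozenset()
    return frozenset({profile.class_})


@dataclass(frozen=True)
class PredictionRecord:
    agent_a: str
    agent_b: str
    predicted_cooperative: bool
    rationale: str
    caveat_flags: frozenset[str]

    @property
    def pair_key(self) -> frozenset[str]:
        return frozenset((self.agent_a, self.agent_b))


def predict_cooperative(profile_a: AgentProfile, profile_b: AgentProfile) -> PredictionRecord:
    """Apply the complementary-class rule to a pair of agent profiles.

    Symmetric in its arguments. A NEITHER-class agent can never form a
    predicted-co-operative pair ("unprimed agent").
    """
    roles_a = _roles(profile_a)
    roles_b = _roles(profile_b)
    predicted = (
        SENSITISES_TO_BCL2_ANTAGONISM in roles_a
        and SENSITISES_TO_MCL1_ANTAGONISM in roles_b
    ) or (
        SENSITISES_TO_BCL2_ANTAGONISM in roles_b
        and SENSITISES_TO_MCL1_ANTAGONISM in roles_a
    )

    caveats = set()
    if profile_a.reversible_binder or profile_b.reversible_binder:
        caveats.add("reversible_binder_in_pair")
    if profile_a.time_dependent_class or profile_b.time_dependent_class:
        caveats.add("time_dependent_class")
    if profile_a.over_lethal or profile_b.over_lethal:
        caveats.add("over_lethal_agent")

    if NEITHER in (profile_a.class_, profile_b.class_):
        rationale = "unprimed agent"
    else:
        rationale = f"{profile_a.class_} x {profile_b.class_}"
        if predicted and BOTH in (profile_a.class_, profile_b.class_):
            caveats.add("both_class_in_pair")

    return PredictionRecord(
        agent_a=profile_a.agent,
        agent_b=profile_b.agent,
        predicted_cooperative=predicted,
        rationale=rationale,
        caveat_flags=frozenset(caveats),
    )


@dataclass(frozen=True)
class DiscordantPair:
    agent_a: str
    agent_b: str
    predicted: bool
    measured: bool
    caveat_flags: frozenset[str]


@dataclass(frozen=True)
class PanelEvaluation:
    """Confusion matrix of predicted vs measured co-operativity over a panel.

    Measured-positive means the combination was significantly supra-additive
    (one-sided p < alpha) with FEA > 1. Rates are None (not evaluable) when
    their denominator is zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    discordant: tuple[DiscordantPair, ...]

    @property
    def n_pairs(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def measured_positive(result: CombinationResult) -> bool:
    return bool(result.significant and result.fea is not None and result.fea > 1.0)


def evaluate_panel(
    predictions: list[PredictionRecord], results: list[CombinationResult]
) -> PanelEvaluation:
    """Match predictions to measured combination results by unordered pair key
    and tabulate the confusion counts."""
    by_pair = {r.pair_key: r for r in results}
    tp = fp = tn = fn = 0
    discordant: list[DiscordantPair] = []
    for pred in predictions:
        if pred.pair_key not in by_pair:
            raise PairingError(
                f"no combination result for pair {pred.agent_a} + {pred.agent_b}"
            )
        measured = measured_positive(by_pair[pred.pair_key])
        if pred.predicted_cooperative and measured:
            tp += 1
        elif pred.predicted_cooperative and not measured:
            fp += 1
        elif not pred.predicted_cooperative and not measured:
            tn += 1
        else:
            fn += 1
        if pred.predicted_cooperative != measured:
            discordant.append(
                DiscordantPair(
                    agent_a=pred.agent_a,
                    agent_b=pred.agent_b,
                    predicted=pred.predicted_cooperative,
                    measured=measured,
                    caveat_flags=pred.caveat_flags,
                )
            )
    return PanelEvaluation(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / (tp + fn) if (tp + fn) > 0 else None,
        specificity=tn / (tn + fp) if (tn + fp) > 0 else None,
        discordant=tuple(discordant),
    )
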