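"""Generative model for dynamic-BH3-profiling cytometry data.

The simulator draws per-cell anti-apoptotic "guardian" buffers for BCL-2 (R_B)
and MCL-1 (R_M) from independent log-normals. Drugs scale the buffer they
target — binders instantaneously, synthesis blockers by exponential protein
decay at the target's half-life (MCL-1 ~1 h, BCL-2 ~14 h). A BH3 peptide
challenge scales its target buffer(s) by (1 - efficiency). A cell undergoes
mitochondrial outer membrane permeabilisation (MOMP, read out as cytochrome-C
loss) when the residual buffers can no longer cover the threshold:

    R_B' + R_M' < theta

Additive buffering means either guardian alone can protect the cell, which is
what makes the assay's dichotomy work: antagonising one side only kills cells
whose other side has already been neutralised by a drug.

Event-level fluorescence is a two-component log10-normal mixture on the
cytochrome-C channel (released cells are dim), with optional mitochondrial
membrane potential (DiOC6-like) and viability-dye (7-AAD-like) channels.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.stats import norm

from .errors import ConfigurationError, InvalidParameterError

# --- mechanism vocabulary ---------------------------------------------------

BCL2_BINDER = "bcl2_binder"
BCL2_TRANSCRIPTIONAL = "bcl2_transcriptional"
MCL1_DEPLETER = "mcl1_depleter"
MCL1_REVERSIBLE_BINDER = "mcl1_reversible_binder"
DUAL_BINDER = "dual_binder"
INERT = "inert"

MECHANISMS = frozenset(
    {BCL2_BINDER, BCL2_TRANSCRIPTIONAL, MCL1_DEPLETER, MCL1_REVERSIBLE_BINDER,
     DUAL_BINDER, INERT}
)
#: mechanisms that act by stopping synthesis / destabilising the protein, so the
#: buffer falls with first-order protein decay instead of instantaneously
KINETIC_MECHANISMS = frozenset({BCL2_TRANSCRIPTIONAL, MCL1_DEPLETER})
#: which guardian buffer(s) each mechanism targets
MECHANISM_TARGETS = {
    BCL2_BINDER: ("B",),
    BCL2_TRANSCRIPTIONAL: ("B",),
    MCL1_DEPLETER: ("M",),
    MCL1_REVERSIBLE_BINDER: ("M",),
    DUAL_BINDER: ("B", "M"),
    INERT: (),
}

PEPTIDES = ("BAD", "MS1", "PUMA", "PUMA2A", "NONE")


# --- domain types -----------------------------------------------------------

@dataclass(frozen=True)
class AgentSpec:
    """Mechanistic description of one drug at its modelled assay dose.

    ``effect`` is the maximal fractional neutralisation (binders) or synthesis
    block (kinetic mechanisms) of the target buffer; ``intrinsic_lethality`` is
    a buffer-independent per-cell release probability the drug contributes on
    its own (composes with the buffer model by independence, i.e. exactly per
    Bliss).
    """

    name: str
    mechanism: str
    effect: float = 0.0
    reversible_on_washout: bool = False
    intrinsic_lethality: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"unknown mechanism {self.mechanism!r} for agent {self.name!r}"
            )
        if not 0.0 <= self.effect <= 1.0:
            raise InvalidParameterError(f"effect must be in [0,1], got {self.effect}")
        if not 0.0 <= self.intrinsic_lethality <= 1.0:
            raise InvalidParameterError(
                f"intrinsic_lethality must be in [0,1], got {self.intrinsic_lethality}"
            )
        if self.mechanism == MCL1_REVERSIBLE_BINDER and not self.reversible_on_washout:
            raise ConfigurationError(
                f"{self.name!r}: mcl1_reversible_binder implies reversible_on_washout"
            )
        if self.mechanism == INERT and self.effect != 0.0:
            raise ConfigurationError(f"{self.name!r}: inert agents must have effect 0")

    @property
    def targets(self) -> tuple[str, ...]:
        return MECHANISM_TARGETS[self.mechanism]


def _default_peptide_efficiency() -> dict[str, tuple[float, float]]:
    # (e_B, e_M): fraction of the targeted buffer neutralised by the peptide at
    # its assay concentration (3 uM BAD/MS1, 100 uM inactive PUMA2A control)
    return {
        "BAD": (0.98, 0.0),
        "MS1": (0.0, 0.98),
        "PUMA": (0.98, 0.98),
        "PUMA2A": (0.0, 0.0),
        "NONE": (0.0, 0.0),
    }


@dataclass(frozen=True)
class LatentParams:
    """Parameters of the latent MOMP model and the fluorescence read-out.

    Buffers are log-normal in natural-log space; fluorescence intensities are
    log10-normal in arbitrary units. ``replicate_log_theta_sd`` is the SD of a
    per-replicate-table log-normal jitter on the MOMP threshold and models
    day-to-day biological variability between replicates (set 0 to disable).
    """

    half_life_mcl1: float = 1.0    # hours
    half_life_bcl2: float = 14.0   # hours
    buffer_log_mean_B: float = 0.0
    buffer_log_sd_B: float = 0.25
    buffer_log_mean_M: float = 0.0
    buffer_log_sd_M: float = 0.25
    momp_threshold: float = 0.7
    peptide_efficiency: dict[str, tuple[float, float]] = field(
        default_factory=_default_peptide_efficiency
    )
    intensity_log10_mean_retained: float = 3.5
    intensity_log10_mean_released: float = 2.0
    intensity_log10_sd: float = 0.25
    aad_lag_prob: float = 0.5
    replicate_log_theta_sd: float = 0.05
    # optional-channel mixture means (log10 a.u.); SD shared with cytc channel
    dpsi_log10_mean_high: float = 3.0
    dpsi_log10_mean_low: float = 1.5
    aad_log10_mean_neg: float = 1.0
    aad_log10_mean_pos: float = 2.5

    def __post_init__(self) -> None:
        if self.half_life_mcl1 <= 0 or self.half_life_bcl2 <= 0:
            raise InvalidParameterError("half-lives must be positive")
        if self.momp_threshold <= 0:
            raise InvalidParameterError("momp_threshold must be positive")
        if not self.intensity_log10_mean_released < self.intensity_log10_mean_retained:
            raise InvalidParameterError(
                "released intensity mean must lie below retained mean"
            )
        for pep, (eb, em) in self.peptide_efficiency.items():
            if not (0.0 <= eb <= 1.0 and 0.0 <= em <= 1.0):
                raise InvalidParameterError(f"peptide efficiency out of [0,1] for {pep}")
        if not 0.0 <= self.aad_lag_prob <= 1.0:
            raise InvalidParameterError("aad_lag_prob must be in [0,1]")
        if self.replicate_log_theta_sd < 0:
            raise InvalidParameterError("replicate_log_theta_sd must be >= 0")


@dataclass(frozen=True)
class AgentExposure:
    """One drug exposure inside a condition: [start, end] in hours since the
    start of priming; ``washed_out`` means the drug was rinsed away at ``end``."""

    agent: str
    start: float = 0.0
    end: float = 4.0
    washed_out: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Condition:
    """One experimental condition: drugs on a schedule, then a peptide challenge."""

    condition_id: str
    agents: tuple[AgentExposure, ...] = ()
    peptide: str = "NONE"
    priming_duration: float = 4.0
    n_events: int = 10_000
    replicate: int | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.peptide not in PEPTIDES:
            raise ConfigurationError(f"unknown peptide {self.peptide!r}")
        if self.n_events < 0:
            raise ConfigurationError("n_events must be >= 0")
        for exp in self.agents:
            if not (0.0 <= exp.start <= exp.end <= self.priming_duration + 1e-9):
                raise ConfigurationError(
                    f"{self.condition_id}: exposure [{exp.start},{exp.end}] outside "
                    f"[0,{self.priming_duration}]"
                )

    @property
    def agent_names(self) -> tuple[str, ...]:
        return tuple(e.agent for e in self.agents)


@dataclass(frozen=True)
class Scenario:
    """A full experimental design: agents, conditions, latent model, seeding."""

    agents: tuple[AgentSpec, ...]
    conditions: tuple[Condition, ...]
    latent: LatentParams = field(default_factory=LatentParams)
    n_replicates: int = 3
    base_seed: int = 0

    def __post_init__(self) -> None:
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigurationError(f"duplicate condition_id(s): {dupes}")
        known = {a.name for a in self.agents}
        if len(known) != len(self.agents):
            raise ConfigurationError("duplicate agent names")
        for c in self.conditions:
            for name in c.agent_names:
                if name not in known:
                    raise ConfigurationError(
                        f"condition {c.condition_id!r} references unknown agent {name!r}"
                    )

    @property
    def agent_map(self) -> dict[str, AgentSpec]:
        return {a.name: a for a in self.agents}


@dataclass
class EventTable:
    """Per-cell events for one (condition, replicate) plus provenance metadata.

    ``data`` columns: cytc_intensity and optionally dpsi_intensity,
    aad_intensity, latent_released (0/1 ground truth).
    ``latent_p`` is the release probability actually used to generate the table
    (including any replicate-level threshold jitter).
    """

    data: pd.DataFrame
    condition_id: str
    replicate: int
    seed: int
    latent_p: float | None = None

    @property
    def n_events(self) -> int:
        return len(self.data)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with identifying columns prepended."""
        out = self.data.copy()
        out.insert(0, "replicate", self.replicate)
        out.insert(0, "condition_id", self.condition_id)
        return out


# --- kinetics ---------------------------------------------------------------

def buffer_level(
    mechanism: str,
    effect: float,
    t: float,
    half_life: float | None = None,
    washed_out: bool = False,
    reversible_on_washout: bool | None = None,
) -> float:
    """Fraction of the targeted guardian buffer remaining after exposure.

    Binders act instantaneously (remaining = 1 - effect). Synthesis-blocking
    mechanisms decay with the protein half-life:

        remaining(t) = (1 - effect) + effect * 2**(-t / half_life)

    After washout a reversible agent restores the buffer to 1; an irreversible
    agent freezes it at the washout-time level. ``t`` is the exposure duration
    in hours; ``reversible_on_washout`` defaults to the mechanism's convention
    (only the reversible MCL-1 binder is reversible).
    """
    if mechanism not in MECHANISMS:
        raise ConfigurationError(f"unknown mechanism {mechanism!r}")
    if not 0.0 <= effect <= 1.0:
        raise InvalidParameterError(f"effect must be in [0,1], got {effect}")
    if t < 0:
        raise InvalidParameterError(f"t must be >= 0, got {t}")
    if reversible_on_washout is None:
        reversible_on_washout = mechanism == MCL1_REVERSIBLE_BINDER

    if mechanism == INERT:
        return 1.0
    if washed_out and reversible_on_washout:
        return 1.0
    if mechanism in KINETIC_MECHANISMS:
        if half_life is None or half_life <= 0:
            raise InvalidParameterError("half_life must be positive for kinetic mechanisms")
        # irreversible washout freezes at the level reached at exposure end,
        # which is the same closed form evaluated at the exposure duration
        return (1.0 - effect) + effect * 2.0 ** (-t / half_life)
    # instantaneous binders
    return 1.0 - effect


def _half_life_for(latent: LatentParams, target: str) -> float:
    return latent.half_life_bcl2 if target == "B" else latent.half_life_mcl1


def condition_buffer_factors(
    condition: Condition, agent_map: dict[str, AgentSpec], latent: LatentParams
) -> tuple[float, float]:
    """Multiplicative residual factors (f_B, f_M) on the two guardian buffers
    after all drug exposures of the condition (peptide not included)."""
    f_b = 1.0
    f_m = 1.0
    for exposure in condition.agents:
        spec = agent_map[exposure.agent]
        for target in spec.targets:
            level = buffer_level(
                spec.mechanism,
                spec.effect,
                exposure.duration,
                _half_life_for(latent, target),
                washed_out=exposure.washed_out,
                reversible_on_washout=spec.reversible_on_washout,
            )
            if target == "B":
                f_b *= level
            else:
                f_m *= level
    return f_b, f_m


# --- latent release probability --------------------------------------------

_GL_NODES, _GL_WEIGHTS = leggauss(256)


@lru_cache(maxsize=16384)
def _p_scaled_buffer_sum_below(
    a: float, b: float, theta: float,
    mu_b: float, sd_b: float, mu_m: float, sd_m: float,
) -> float:
    """P(a*R_B + b*R_M < theta) for independent log-normal buffers.

    Evaluated deterministically: closed-form normal CDF when one scale is zero,
    otherwise 256-point Gauss-Legendre quadrature over the standard-normal
    variable behind R_B (accurate to well under 1e-4 for the parameter ranges
    used here).
    """
    if theta <= 0:
        return 0.0
    if a <= 0.0 and b <= 0.0:
        return 1.0
    if a <= 0.0:
        return float(norm.cdf((np.log(theta / b) - mu_m) / sd_m))
    if b <= 0.0:
        return float(norm.cdf((np.log(theta / a) - mu_b) / sd_b))
    z_max = (np.log(theta / a) - mu_b) / sd_b
    lo, hi = -9.0, min(z_max, 9.0)
    if hi <= lo:
        return 0.0
    z = 0.5 * (hi - lo) * _GL_NODES + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * _GL_WEIGHTS
    resid = theta - a * np.exp(mu_b + sd_b * z)
    inner = norm.cdf((np.log(resid / b) - mu_m) / sd_m)
    return float(np.sum(w * norm.pdf(z) * inner))


def latent_release_probability(
    condition: Condition,
    latent: LatentParams,
    agent_map: dict[str, AgentSpec] | None = None,
    theta: float | None = None,
) -> float:
    """Marginal probability that a cell releases cytochrome C in ``condition``.

    Per cell, R_B ~ LogNormal(mu_B, sd_B) and R_M ~ LogNormal(mu_M, sd_M) are
    scaled by the drugs' residual buffer factors and by the peptide's
    (1 - efficiency); the cell undergoes MOMP iff the scaled buffers sum below
    the threshold. Drugs' intrinsic lethality composes independently.
    """
    if agent_map is None:
        agent_map = {}
    for name in condition.agent_names:
        if name not in agent_map:
            raise ConfigurationError(
                f"condition {condition.condition_id!r}: unresolvable agent {name!r}"
            )
    if theta is None:
        theta = latent.momp_threshold
    f_b, f_m = condition_buffer_factors(condition, agent_map, latent)
    e_b, e_m = latent.peptide_efficiency[condition.peptide]
    p_buffer = _p_scaled_buffer_sum_below(
        f_b * (1.0 - e_b),
        f_m * (1.0 - e_m),
        theta,
        latent.buffer_log_mean_B,
        latent.buffer_log_sd_B,
        latent.buffer_log_mean_M,
        latent.buffer_log_sd_M,
    )
    p_survive = 1.0 - p_buffer
    for exposure in condition.agents:
        spec = agent_map[exposure.agent]
        if exposure.washed_out and spec.reversible_on_washout:
            continue  # washed-out reversible agents leave no trace
        p_survive *= 1.0 - spec.intrinsic_lethality
    return float(min(1.0, max(0.0, 1.0 - p_survive)))


# --- event simulation -------------------------------------------------------

def derive_seed(base_seed: int, condition_id: str, replicate: int, tag: str = "") -> int:
    """Stable sub-2**31 seed for one (condition, replicate[, purpose])."""
    key = f"{base_seed}:{condition_id}:{replicate}:{tag}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def simulate_condition(
    condition: Condition,
    latent: LatentParams,
    seed: int,
    agent_map: dict[str, AgentSpec] | None = None,
    channels: tuple[str, ...] = ("dpsi", "aad"),
    truth: bool = True,
    replicate: int | None = None,
    theta: float | None = None,
) -> EventTable:
    """Draw one event table for a condition at a fixed seed.

    Released cells' cytochrome-C intensity comes from the dim log10-normal
    component, retained cells from the bright one. If requested, MOMP-positive
    cells are membrane-potential-low, and viability-dye-positive with
    probability ``aad_lag_prob`` (the dye lags MOMP slightly).
    """
    rng = np.random.default_rng(seed)
    p = latent_release_probability(condition, latent, agent_map, theta=theta)
    n = condition.n_events
    released = rng.random(n) < p
    sd = latent.intensity_log10_sd
    log10_cytc = rng.normal(
        np.where(
            released,
            latent.intensity_log10_mean_released,
            latent.intensity_log10_mean_retained,
        ),
        sd,
    )
    cols: dict[str, np.ndarray] = {"cytc_intensity": 10.0 ** log10_cytc}
    if "dpsi" in channels:
        cols["dpsi_intensity"] = 10.0 ** rng.normal(
            np.where(released, latent.dpsi_log10_mean_low, latent.dpsi_log10_mean_high),
            sd,
        )
    if "aad" in channels:
        aad_pos = released & (rng.random(n) < latent.aad_lag_prob)
        cols["aad_intensity"] = 10.0 ** rng.normal(
            np.where(aad_pos, latent.aad_log10_mean_pos, latent.aad_log10_mean_neg),
            sd,
        )
    if truth:
        cols["latent_released"] = released.astype(int)
    rep = replicate if replicate is not None else (condition.replicate or 1)
    return EventTable(
        data=pd.DataFrame(cols),
        condition_id=condition.condition_id,
        replicate=rep,
        seed=seed,
        latent_p=p,
    )


def simulate_panel(
    scenario: Scenario,
    channels: tuple[str, ...] = ("dpsi", "aad"),
    truth: bool = True,
) -> list[EventTable]:
    """Simulate every condition x replicate of a scenario.

    Per-table seeds derive deterministically from the base seed; the MOMP
    threshold receives an independent per-table log-normal jitter modelling
    inter-replicate variability (``replicate_log_theta_sd``).
    """
    agent_map = scenario.agent_map
    tables: list[EventTable] = []
    for condition in scenario.conditions:
        for rep in range(1, scenario.n_replicates + 1):
            seed = derive_seed(scenario.base_seed, condition.condition_id, rep)
            theta = scenario.latent.momp_threshold
            if scenario.latent.replicate_log_theta_sd > 0:
                jitter_rng = np.random.default_rng(
                    derive_seed(scenario.base_seed, condition.condition_id, rep, "theta")
                )
                theta *= float(
                    np.exp(jitter_rng.normal(0.0, scenario.latent.replicate_log_theta_sd))
                )
            tables.append(
                simulate_condition(
                    condition,
                    scenario.latent,
                    seed,
                    agent_map,
                    channels=channels,
                    truth=truth,
                    replicate=rep,
                    theta=theta,
                )
            )
    return tables


# --- the default study panel -------------------------------------------------

#: reversible-binder profiling emulates the real assay, where the drug is
#: washed away before the peptide is delivered in permeabilisation buffer
PANEL_AGENTS = (
    AgentSpec("pladienolide-B", MCL1_DEPLETER, effect=1.0),
    AgentSpec("torin1", MCL1_DEPLETER, effect=1.0),
    AgentSpec("ABT-199", BCL2_BINDER, effect=0.96),
    AgentSpec("JQ1", BCL2_TRANSCRIPTIONAL, effect=1.0),
    AgentSpec("etoposide", MCL1_DEPLETER, effect=1.0, intrinsic_lethality=0.02),
    AgentSpec("AC220", MCL1_DEPLETER, effect=1.0, intrinsic_lethality=0.01),
    AgentSpec(
        "A-1210477", MCL1_REVERSIBLE_BINDER, effect=0.96, reversible_on_washout=True
    ),
)

#: agents whose class is only expressed after prolonged priming (long BCL-2
#: half-life): profiled and combined at 48 h with partners added for the final 4 h
LONG_PRIMING_AGENTS = {"JQ1": 48.0}
#: agents profiled with washout (sequential assay) but combined concurrently
WASHOUT_PROFILED_AGENTS = {"A-1210477"}


def _exposure(agent: str, priming: float, washed: bool = False) -> AgentExposure:
    return AgentExposure(agent, 0.0, priming, washed_out=washed)


def _partner_exposure(agent: str, priming: float, partner_priming: float) -> AgentExposure:
    # in a mixed-duration pair the short-acting partner joins for the final hours
    return AgentExposure(agent, priming - partner_priming, priming)


def build_default_panel(
    base_seed: int = 0,
    n_events: int = 10_000,
    n_replicates: int = 3,
    latent: LatentParams | None = None,
) -> Scenario:
    """The seven-agent study panel: profiling conditions for every agent
    (drug alone, +BAD, +MS1, +PUMA2A control) plus all pairwise combinations
    and peptide-only / untreated baselines."""
    if latent is None:
        latent = LatentParams()
    conditions: list[Condition] = []

    def add(cid: str, agents, peptide, priming, **meta):
        conditions.append(
            Condition(
                condition_id=cid,
                agents=tuple(agents),
                peptide=peptide,
                priming_duration=priming,
                n_events=n_events,
                meta=meta,
            )
        )

    # baselines: untreated without and with PUMA form the bimodal gating control
    add("untreated|NONE", (), "NONE", 4.0, role="control_untreated")
    add("untreated|PUMA", (), "PUMA", 4.0, role="control_puma")
    for pep in ("BAD", "MS1", "PUMA2A"):
        add(f"untreated|{pep}", (), pep, 4.0, role="peptide_baseline")
    # 48-h baselines so long-priming agents pair with duration-matched baselines
    for pep in ("BAD", "MS1", "PUMA2A", "NONE"):
        add(f"untreated-48h|{pep}", (), pep, 48.0, role="peptide_baseline_48")

    for spec in PANEL_AGENTS:
        priming = LONG_PRIMING_AGENTS.get(spec.name, 4.0)
        washed = spec.name in WASHOUT_PROFILED_AGENTS
        profile_exposure = _exposure(spec.name, priming, washed=washed)
        for pep in ("NONE", "BAD", "MS1", "PUMA", "PUMA2A"):
            add(
                f"{spec.name}|{pep}",
                (profile_exposure,),
                pep,
                priming,
                role="profiling",
                agent=spec.name,
                priming_time=priming,
            )
        if washed:
            # concurrent (unwashed) single needed as the combination reference
            add(
                f"{spec.name}+concurrent|NONE",
                (_exposure(spec.name, priming),),
                "NONE",
                priming,
                role="single",
                agent=spec.name,
            )

    def single_condition_id(name: str) -> str:
        return (
            f"{name}+concurrent|NONE"
            if name in WASHOUT_PROFILED_AGENTS
            else f"{name}|NONE"
        )

    names = [a.name for a in PANEL_AGENTS]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pa = LONG_PRIMING_AGENTS.get(a, 4.0)
            pb = LONG_PRIMING_AGENTS.get(b, 4.0)
            priming = max(pa, pb)
            exp_a = (
                AgentExposure(a, 0.0, priming)
                if pa == priming
                else _partner_exposure(a, priming, pa)
            )
            exp_b = (
                AgentExposure(b, 0.0, priming)
                if pb == priming
                else _partner_exposure(b, priming, pb)
            )
            add(
                f"{a}+{b}|NONE",
                (exp_a, exp_b),
                "NONE",
                priming,
                role="combination",
                agent_a=a,
                agent_b=b,
                single_a=single_condition_id(a),
                single_b=single_condition_id(b),
            )

    return Scenario(
        agents=PANEL_AGENTS,
        conditions=tuple(conditions),
        latent=latent,
        n_replicates=n_replicates,
        base_seed=base_seed,
    )


def build_schedule_scenario(
    base_seed: int = 0,
    n_events: int = 10_000,
    n_replicates: int = 3,
    latent: LatentParams | None = None,
) -> Scenario:
    """Sequential vs concurrent scheduling of a reversible MCL-1 binder with a
    BCL-2 binder: the reversible binder washed off before the BCL-2 binder is
    ineffective; the reverse order matches concurrent exposure."""
    if latent is None:
        latent = LatentParams()
    abt = next(a for a in PANEL_AGENTS if a.name == "ABT-199")
    a477 = next(a for a in PANEL_AGENTS if a.name == "A-1210477")
    conds = (
        Condition("abt199_alone", (AgentExposure("ABT-199", 4.0, 6.0),), "NONE", 6.0,
                  n_events),
        Condition(
            "seq_477_wash_then_199",
            (AgentExposure("A-1210477", 0.0, 4.0, washed_out=True),
             AgentExposure("ABT-199", 4.0, 6.0)),
            "NONE", 6.0, n_events,
        ),
        Condition(
            "seq_199_wash_then_477",
            (AgentExposure("ABT-199", 0.0, 4.0, washed_out=True),
             AgentExposure("A-1210477", 4.0, 6.0)),
            "NONE", 6.0, n_events,
        ),
        Condition(
            "concurrent_477_199",
            (AgentExposure("A-1210477", 0.0, 6.0),
             AgentExposure("ABT-199", 4.0, 6.0)),
            "NONE", 6.0, n_events,
        ),
    )
    return Scenario(
        agents=(abt, a477),
        conditions=conds,
        latent=latent,
        n_replicates=n_replicates,
        base_seed=base_seed,
    )
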