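"""Pipeline orchestration: simulate -> gate -> prime -> combine -> predict.

The analysis functions here are pure (scenario + event tables in, results
out); :func:`run_pipeline` wraps them with CSV/JSON persistence, logging and a
run report so a whole run is reproducible from one config and one seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .combination import DEFAULT_ALPHA, CombinationResult, score_combination
from .errors import ConfigurationError
from .gating import (
    ReleaseMeasurement,
    ThresholdFit,
    default_quadrant_thresholds,
    fit_release_threshold,
    percent_release,
    quadrant_fractions,
)
from .io import read_scenario, write_event_tables
from .prediction import (
    PanelEvaluation,
    PredictionRecord,
    evaluate_panel,
    predict_cooperative,
)
from .priming import (
    DEFAULT_DELTA_THRESHOLD,
    DEFAULT_DRUG_ALONE_CEILING,
    AgentProfile,
    PrimingResult,
    ScreenResult,
    build_profile,
    priming_result,
    screen_priming_concentration,
)
from .simulate import (
    MCL1_REVERSIBLE_BINDER,
    EventTable,
    Scenario,
    simulate_panel,
)

logger = logging.getLogger("bh3coop")

STAGES = ("simulate", "gate", "prime", "combine", "predict")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    scenario: Scenario | str | Path
    output_dir: str | Path = "bh3coop_run"
    stages: tuple[str, ...] = STAGES
    base_seed: int | None = None         # overrides the scenario's seed
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD
    drug_alone_ceiling: float = DEFAULT_DRUG_ALONE_CEILING
    alpha: float = DEFAULT_ALPHA
    channels: tuple[str, ...] = ("dpsi", "aad")
    truth: bool = True
    verbosity: int = 1

    def __post_init__(self) -> None:
        if tuple(self.stages) != STAGES[: len(self.stages)] or not self.stages:
            raise ConfigurationError(
                f"stages must be a prefix of {STAGES}, got {self.stages}"
            )
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0,1)")
        if not (0.0 <= self.delta_threshold <= 1.0):
            raise ConfigurationError("delta_threshold must be in [0,1]")
        if not (0.0 < self.drug_alone_ceiling <= 1.0):
            raise ConfigurationError("drug_alone_ceiling must be in (0,1]")


@dataclass
class RunReport:
    version: str
    base_seed: int
    thresholds: dict
    stage_rows: dict = field(default_factory=dict)
    file_hashes: dict = field(default_factory=dict)
    profiles: list = field(default_factory=list)
    combinations: list = field(default_factory=list)
    evaluation: dict | None = None
    skipped_stages: list = field(default_factory=list)


# --- pure analysis steps ----------------------------------------------------

def gate_tables(
    tables: list[EventTable], scenario: Scenario | None = None
) -> tuple[list[ReleaseMeasurement], ThresholdFit]:
    """Gate every table with one shared threshold fitted on the bimodal
    calibration pool (untreated cells with and without PUMA when tagged in the
    scenario; otherwise all drug-free conditions, otherwise everything)."""
    pool = _control_pool(tables, scenario)
    fit = fit_release_threshold(pool)
    logger.info("release threshold %.1f a.u. (fallback=%s)", fit.threshold, fit.fallback)
    return [percent_release(t, fit) for t in tables], fit


def _control_pool(tables: list[EventTable], scenario: Scenario | None) -> pd.DataFrame:
    control_ids: set[str] = set()
    if scenario is not None:
        control_ids = {
            c.condition_id
            for c in scenario.conditions
            if c.meta.get("role") in ("control_untreated", "control_puma")
        }
        if not control_ids:
            control_ids = {
                c.condition_id for c in scenario.conditions if not c.agents
            }
    selected = [t for t in tables if t.condition_id in control_ids] or tables
    return pd.concat([t.data[["cytc_intensity"]] for t in selected], ignore_index=True)


def _fractions_by_condition(
    measurements: list[ReleaseMeasurement],
) -> dict[str, list[float]]:
    """condition_id -> fractions ordered by replicate index."""
    grouped: dict[str, list[tuple[int, float]]] = {}
    for m in measurements:
        grouped.setdefault(m.condition_id, []).append((m.replicate, m.fraction_released))
    return {
        cid: [f for _, f in sorted(pairs)] for cid, pairs in grouped.items()
    }


def _baseline_condition_id(scenario: Scenario, peptide: str, priming: float) -> str | None:
    for c in scenario.conditions:
        if not c.agents and c.peptide == peptide and c.priming_duration == priming:
            return c.condition_id
    # fall back to any drug-free condition with the right peptide
    for c in scenario.conditions:
        if not c.agents and c.peptide == peptide:
            return c.condition_id
    return None


def profile_agents(
    scenario: Scenario,
    measurements: list[ReleaseMeasurement],
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    drug_alone_ceiling: float = DEFAULT_DRUG_ALONE_CEILING,
) -> tuple[list[PrimingResult], list[AgentProfile]]:
    """Compute per-peptide delta-priming and the dichotomised profile for every
    agent that has profiling conditions in the scenario."""
    fractions = _fractions_by_condition(measurements)
    agent_map = scenario.agent_map

    profiling: dict[tuple[str, float], dict[str, str]] = {}
    for c in scenario.conditions:
        if c.meta.get("role") != "profiling" or len(c.agents) != 1:
            continue
        key = (c.agents[0].agent, c.priming_duration)
        profiling.setdefault(key, {})[c.peptide] = c.condition_id

    results: list[PrimingResult] = []
    profiles: list[AgentProfile] = []
    for (agent, priming_time), by_peptide in sorted(profiling.items()):
        if "NONE" not in by_peptide:
            continue
        drug_alone = fractions[by_peptide["NONE"]]
        per_peptide: dict[str, PrimingResult] = {}
        for peptide in ("BAD", "MS1", "PUMA"):
            if peptide not in by_peptide:
                continue
            baseline_id = _baseline_condition_id(scenario, peptide, priming_time)
            if baseline_id is None or baseline_id not in fractions:
                continue
            if peptide == "PUMA" and max(fractions[baseline_id]) >= 1.0:
                # the promiscuous peptide can saturate the untreated baseline,
                # leaving the (optional) PUMA delta undefined
                continue
            res = priming_result(
                agent,
                peptide,
                priming_time,
                fractions[by_peptide[peptide]],
                fractions[baseline_id],
                drug_alone,
            )
            per_peptide[peptide] = res
            results.append(res)
        screen: ScreenResult | None = None
        if "PUMA" in by_peptide and "PUMA2A" in by_peptide:
            screen = screen_priming_concentration(
                float(np.mean(fractions[by_peptide["PUMA"]])),
                float(np.mean(fractions[by_peptide["PUMA2A"]])),
            )
        if "BAD" not in per_peptide or "MS1" not in per_peptide:
            continue
        spec = agent_map[agent]
        profiles.append(
            build_profile(
                agent,
                priming_time,
                per_peptide["BAD"],
                per_peptide["MS1"],
                per_peptide.get("PUMA"),
                screen,
                delta_threshold=delta_threshold,
                drug_alone_ceiling=drug_alone_ceiling,
                reversible_binder=(
                    spec.mechanism == MCL1_REVERSIBLE_BINDER or spec.reversible_on_washout
                ),
            )
        )

    # an agent profiled at several priming times with diverging classes is
    # time-dependent; flag every one of its profiles
    by_agent: dict[str, list[int]] = {}
    for i, p in enumerate(profiles):
        by_agent.setdefault(p.agent, []).append(i)
    for idxs in by_agent.values():
        classes = {profiles[i].class_ for i in idxs}
        if len(classes) > 1:
            for i in idxs:
                profiles[i] = replace(profiles[i], time_dependent_class=True)
    return results, profiles


def score_combinations(
    scenario: Scenario,
    measurements: list[ReleaseMeasurement],
    alpha: float = DEFAULT_ALPHA,
) -> list[CombinationResult]:
    """Score every combination-tagged condition against its single-agent
    reference conditions (pairing by replicate index)."""
    fractions = _fractions_by_condition(measurements)
    results = []
    for c in scenario.conditions:
        if c.meta.get("role") != "combination":
            continue
        agent_a = c.meta["agent_a"]
        agent_b = c.meta["agent_b"]
        single_a = c.meta["single_a"]
        single_b = c.meta["single_b"]
        for cid in (c.condition_id, single_a, single_b):
            if cid not in fractions:
                raise ConfigurationError(f"no release measurements for {cid!r}")
        results.append(
            score_combination(
                agent_a,
                agent_b,
                fractions[c.condition_id],
                fractions[single_a],
                fractions[single_b],
                alpha=alpha,
            )
        )
    return results


def predict_panel(
    profiles: list[AgentProfile], combinations: list[CombinationResult]
) -> tuple[list[PredictionRecord], PanelEvaluation | None]:
    """Predict each measured pair from the agents' profiles and evaluate.

    When an agent was profiled at several priming times, its class at the
    latest time is used (the class that prolonged priming reveals).
    """
    latest: dict[str, AgentProfile] = {}
    for p in sorted(profiles, key=lambda p: p.priming_time):
        latest[p.agent] = p
    predictions = []
    for combo in combinations:
        if combo.agent_a not in latest or combo.agent_b not in latest:
            continue
        predictions.append(
            predict_cooperative(latest[combo.agent_a], latest[combo.agent_b])
        )
    evaluation = evaluate_panel(predictions, combinations) if predictions else None
    return predictions, evaluation


# --- persistence ------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def release_frame(measurements: list[ReleaseMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition_id": m.condition_id,
                "replicate": m.replicate,
                "fraction_released": m.fraction_released,
                "n_events": m.n_events,
                "threshold_used": m.threshold_used,
            }
            for m in measurements
        ]
    )


def profiles_frame(profiles: list[AgentProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "agent": p.agent,
                "priming_time": p.priming_time,
                "delta_bad": p.delta_bad,
                "delta_ms1": p.delta_ms1,
                "delta_puma": p.delta_puma,
                "drug_alone_release": p.drug_alone_release,
                "screen_pass": p.screen_pass,
                "class": p.class_,
                "delta_threshold": p.delta_threshold,
                "drug_alone_ceiling": p.drug_alone_ceiling,
                "over_lethal": p.over_lethal,
                "reversible_binder": p.reversible_binder,
                "time_dependent_class": p.time_dependent_class,
            }
            for p in profiles
        ]
    )


def combinations_frame(results: list[CombinationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "agent_a": r.agent_a,
                "agent_b": r.agent_b,
                "observed_mean": float(np.mean(r.observed_per_replicate)),
                "effect_a_mean": float(np.mean(r.effect_a_per_replicate)),
                "effect_b_mean": float(np.mean(r.effect_b_per_replicate)),
                "expected_mean": float(np.mean(r.expected_per_replicate)),
                "fea": r.fea,
                "excess": r.excess,
                "p_value": r.p_value,
                "significant": r.significant,
                "degenerate_variance": r.degenerate_variance,
                "alpha": r.alpha,
            }
            for r in results
        ]
    )


def predictions_frame(predictions: list[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "agent_a": p.agent_a,
                "agent_b": p.agent_b,
                "predicted_cooperative": p.predicted_cooperative,
                "rationale": p.rationale,
                "caveat_flags": ";".join(sorted(p.caveat_flags)),
            }
            for p in predictions
        ]
    )


def evaluation_dict(evaluation: PanelEvaluation) -> dict:
    return {
        "tp": evaluation.tp,
        "fp": evaluation.fp,
        "tn": evaluation.tn,
        "fn": evaluation.fn,
        "sensitivity": evaluation.sensitivity,
        "specificity": evaluation.specificity,
        "discordant": [
            {
                "agent_a": d.agent_a,
                "agent_b": d.agent_b,
                "predicted": d.predicted,
                "measured": d.measured,
                "caveat_flags": sorted(d.caveat_flags),
            }
            for d in evaluation.discordant
        ],
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stage prefix, writing all intermediates as CSV
    plus a JSON report; deterministic given the base seed."""
    level = logging.WARNING if config.verbosity <= 0 else (
        logging.INFO if config.verbosity == 1 else logging.DEBUG
    )
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")

    scenario = (
        config.scenario
        if isinstance(config.scenario, Scenario)
        else read_scenario(config.scenario)
    )
    if config.base_seed is not None:
        scenario = replace(scenario, base_seed=config.base_seed)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    report = RunReport(
        version=__version__,
        base_seed=scenario.base_seed,
        thresholds={
            "delta_threshold": config.delta_threshold,
            "drug_alone_ceiling": config.drug_alone_ceiling,
            "alpha": config.alpha,
        },
        skipped_stages=[s for s in STAGES if s not in config.stages],
    )

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.10g")
        report.file_hashes[name] = _sha256(path)
        report.stage_rows[name] = int(len(frame))
        logger.info("wrote %s (%d rows, sha256 %s)", path, len(frame),
                    report.file_hashes[name][:12])

    logger.info("run: seed=%d, stages=%s", scenario.base_seed, list(config.stages))
    tables = simulate_panel(scenario, channels=config.channels, truth=config.truth)
    write_event_tables(tables, outdir / "events.csv")
    report.file_hashes["events.csv"] = _sha256(outdir / "events.csv")
    report.stage_rows["events.csv"] = int(sum(t.n_events for t in tables))

    measurements = None
    if "gate" in config.stages:
        measurements, fit = gate_tables(tables, scenario)
        report.thresholds["release_threshold"] = fit.threshold
        report.thresholds["release_threshold_fallback"] = fit.fallback
        emit("release.csv", release_frame(measurements))
        if all(ch in config.channels for ch in ("dpsi", "aad")):
            control = next(
                (t for t in tables
                 if t.condition_id.startswith("untreated") and "NONE" in t.condition_id),
                None,
            )
            if control is not None:
                dpsi_thr, aad_thr = default_quadrant_thresholds(control)
                report.thresholds["dpsi_threshold"] = dpsi_thr
                report.thresholds["aad_threshold"] = aad_thr
                quads = [quadrant_fractions(t, dpsi_thr, aad_thr) for t in tables]
                emit(
                    "quadrants.csv",
                    pd.DataFrame(
                        [
                            {"condition_id": q.condition_id, "replicate": q.replicate,
                             **q.as_dict()}
                            for q in quads
                        ]
                    ),
                )

    profiles: list[AgentProfile] = []
    if "prime" in config.stages and measurements is not None:
        priming_results, profiles = profile_agents(
            scenario, measurements, config.delta_threshold, config.drug_alone_ceiling
        )
        emit(
            "priming.csv",
            pd.DataFrame(
                [
                    {
                        "agent": r.agent,
                        "peptide": r.peptide,
                        "priming_time": r.priming_time,
                        "replicate": i + 1,
                        "delta": d,
                        "delta_mean": r.delta_mean,
                        "delta_sd": r.delta_sd,
                        "drug_alone_release_mean": r.drug_alone_release_mean,
                    }
                    for r in priming_results
                    for i, d in enumerate(r.delta_per_replicate)
                ]
            ),
        )
        emit("profiles.csv", profiles_frame(profiles))
        report.profiles = profiles_frame(profiles).to_dict(orient="records")

    combinations: list[CombinationResult] = []
    if "combine" in config.stages and measurements is not None:
        combinations = score_combinations(scenario, measurements, alpha=config.alpha)
        emit("combinations.csv", combinations_frame(combinations))
        (outdir / "combinations.json").write_text(
            json.dumps(
                [
                    {
                        "agent_a": r.agent_a,
                        "agent_b": r.agent_b,
                        "observed_per_replicate": list(r.observed_per_replicate),
                        "effect_a_per_replicate": list(r.effect_a_per_replicate),
                        "effect_b_per_replicate": list(r.effect_b_per_replicate),
                        "expected_per_replicate": list(r.expected_per_replicate),
                        "fea": r.fea,
                        "excess": r.excess,
                        "p_value": r.p_value,
                        "significant": r.significant,
                    }
                    for r in combinations
                ],
                indent=2,
            )
        )
        report.file_hashes["combinations.json"] = _sha256(outdir / "combinations.json")
        report.combinations = combinations_frame(combinations).to_dict(orient="records")

    if "predict" in config.stages and combinations and profiles:
        predictions, evaluation = predict_panel(profiles, combinations)
        emit("predictions.csv", predictions_frame(predictions))
        if evaluation is not None:
            report.evaluation = evaluation_dict(evaluation)
            (outdir / "evaluation.json").write_text(
                json.dumps(report.evaluation, indent=2)
            )
            report.file_hashes["evaluation.json"] = _sha256(outdir / "evaluation.json")

    (outdir / "report.json").write_text(
        json.dumps(
            {
                "version": report.version,
                "base_seed": report.base_seed,
                "thresholds": report.thresholds,
                "stage_rows": report.stage_rows,
                "file_hashes": report.file_hashes,
                "skipped_stages": report.skipped_stages,
                "profiles": report.profiles,
                "combinations": report.combinations,
                "evaluation": report.evaluation,
            },
            indent=2,
        )
    )
    _write_summary(outdir / "report.txt", report)
    return report


def _write_summary(path: Path, report: RunReport) -> None:
    lines = [
        f"bh3coop {report.version} run (seed {report.base_seed})",
        f"thresholds: {report.thresholds}",
    ]
    if report.skipped_stages:
        lines.append(f"skipped stages: {', '.join(report.skipped_stages)}")
    if report.profiles:
        lines.append("agent profiles:")
        for p in report.profiles:
            lines.append(
                f"  {p['agent']:>16} @{p['priming_time']:>4}h  "
                f"dBAD={p['delta_bad']:+.3f} dMS1={p['delta_ms1']:+.3f}  {p['class']}"
            )
    if report.combinations:
        lines.append("combinations:")
        for c in report.combinations:
            fea = "n/a" if c["fea"] is None else f"{c['fea']:.2f}"
            star = "*" if c["significant"] else " "
            lines.append(
                f"  {c['agent_a']} + {c['agent_b']}: obs={c['observed_mean']:.3f} "
                f"exp={c['expected_mean']:.3f} FEA={fea} p={c['p_value']:.3g}{star}"
            )
    if report.evaluation:
        e = report.evaluation
        lines.append(
            f"panel: TP={e['tp']} FP={e['fp']} TN={e['tn']} FN={e['fn']} "
            f"sens={e['sensitivity']} spec={e['specificity']}"
        )
    path.write_text("\n".join(lines) + "\n")
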