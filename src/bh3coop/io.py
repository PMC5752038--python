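"""CSV / YAML interchange.

Event tables travel as CSV with columns exactly
``condition_id, replicate, cytc_intensity, dpsi_intensity, aad_intensity,
latent_released`` (header mandatory; optional channels left empty when absent;
floats written with 10 significant digits so write-then-read is an identity up
to formatting). Scenarios are a documented YAML dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .simulate import (
    AgentExposure,
    AgentSpec,
    Condition,
    EventTable,
    LatentParams,
    Scenario,
)

EVENT_COLUMNS = [
    "condition_id",
    "replicate",
    "cytc_intensity",
    "dpsi_intensity",
    "aad_intensity",
    "latent_released",
]
REQUIRED_EVENT_COLUMNS = ["condition_id", "replicate", "cytc_intensity"]
FLOAT_FORMAT = "%.10g"


def write_event_tables(tables: list[EventTable], path) -> None:
    """Write one or more event tables to a single long-format CSV."""
    frames = [t.to_frame() for t in tables]
    combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=EVENT_COLUMNS
    )
    for col in EVENT_COLUMNS:
        if col not in combined.columns:
            combined[col] = np.nan
    combined[EVENT_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_event_table(path) -> pd.DataFrame:
    """Read an event CSV, validating the documented schema.

    Unknown columns raise a warning and are kept; missing required columns are
    an error; a headerless file is an error. An empty-but-headered file yields
    an empty frame.
    """
    frame = pd.read_csv(path)
    cols = list(frame.columns)
    if not set(REQUIRED_EVENT_COLUMNS) <= set(cols):
        # distinguish "headerless numeric file" from "missing column"
        looks_headerless = all(_is_number(c) for c in cols) and len(cols) > 0
        if looks_headerless:
            raise SchemaError("event CSV has no header row")
        missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in cols]
        raise SchemaError(f"event CSV missing required column(s): {missing}")
    unknown = [c for c in cols if c not in EVENT_COLUMNS]
    if unknown:
        warnings.warn(f"event CSV has unknown column(s): {unknown}", stacklevel=2)
    return frame


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except (TypeError, ValueError):
        return False


def split_event_tables(frame: pd.DataFrame) -> list[EventTable]:
    """Split a long-format event frame into per-(condition, replicate) tables."""
    tables = []
    if len(frame) == 0:
        return tables
    for (cid, rep), group in frame.groupby(["condition_id", "replicate"], sort=False):
        data = group.drop(columns=["condition_id", "replicate"]).reset_index(drop=True)
        data = data.dropna(axis=1, how="all")
        tables.append(
            EventTable(data=data, condition_id=str(cid), replicate=int(rep), seed=-1)
        )
    return tables


# --- scenario YAML ----------------------------------------------------------

def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "base_seed": scenario.base_seed,
        "n_replicates": scenario.n_replicates,
        "latent": {
            **{
                k: v
                for k, v in asdict(scenario.latent).items()
                if k != "peptide_efficiency"
            },
            "peptide_efficiency": {
                pep: list(eff)
                for pep, eff in scenario.latent.peptide_efficiency.items()
            },
        },
        "agents": [asdict(a) for a in scenario.agents],
        "conditions": [
            {
                "condition_id": c.condition_id,
                "agents": [asdict(e) for e in c.agents],
                "peptide": c.peptide,
                "priming_duration": c.priming_duration,
                "n_events": c.n_events,
                "meta": dict(c.meta),
            }
            for c in scenario.conditions
        ],
    }


def scenario_from_dict(payload: dict) -> Scenario:
    try:
        latent_payload = dict(payload.get("latent", {}))
        if "peptide_efficiency" in latent_payload:
            latent_payload["peptide_efficiency"] = {
                pep: tuple(eff)
                for pep, eff in latent_payload["peptide_efficiency"].items()
            }
        latent = LatentParams(**latent_payload)
        agents = tuple(AgentSpec(**a) for a in payload.get("agents", []))
        conditions = tuple(
            Condition(
                condition_id=c["condition_id"],
                agents=tuple(AgentExposure(**e) for e in c.get("agents", [])),
                peptide=c.get("peptide", "NONE"),
                priming_duration=c.get("priming_duration", 4.0),
                n_events=c.get("n_events", 10_000),
                meta=c.get("meta", {}) or {},
            )
            for c in payload.get("conditions", [])
        )
        return Scenario(
            agents=agents,
            conditions=conditions,
            latent=latent,
            n_replicates=payload.get("n_replicates", 3),
            base_seed=payload.get("base_seed", 0),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed scenario: {exc}") from exc


def write_scenario(scenario: Scenario, path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(scenario_to_dict(scenario), handle, sort_keys=False)


def read_scenario(path) -> Scenario:
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    if not isinstance(payload, dict):
        raise SchemaError("scenario YAML must be a mapping")
    return scenario_from_dict(payload)
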