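"""Session-log CSV round-trip and config-file loading.

The session CSV schema has one row per trial with the exact header::

    iteration,phase,agent_action,opponent_action,agent_payoff,opponent_payoff,
    agent_cum,opponent_cum,p_avoid,decision_time

Actions are coded rush=0/avoid=1; decision_time is empty when no key was
pressed (the field means "seconds until the avoid key", so absence is
information, not zero).

Config files (YAML or JSON) describe a session: payoff matrix (a builtin
name or four labeled cells), endowment, seed, phases (length + preset name
or explicit params), and the opponent policy descriptor.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .engine import PhaseSpec, SessionConfig, SessionLog, TrialRecord
from .game import Action, BUILTIN_MATRICES, PayoffMatrix
from .model import ModelParams, preset_params

__all__ = ["SESSION_COLUMNS", "write_session", "read_session", "load_config", "dump_config"]

SESSION_COLUMNS = [
    "iteration",
    "phase",
    "agent_action",
    "opponent_action",
    "agent_payoff",
    "opponent_payoff",
    "agent_cum",
    "opponent_cum",
    "p_avoid",
    "decision_time",
]


class SessionFormatError(ValueError):
    """Malformed session CSV; the message names the offending row."""


def write_session(log: SessionLog, path: Union[str, Path]) -> None:
    """Write a session log to CSV in the canonical schema."""
    frame = log.to_frame()
    frame.to_csv(path, index=False, columns=SESSION_COLUMNS)


def read_session(
    path: Union[str, Path], config: SessionConfig | None = None
) -> SessionLog:
    """Read a session CSV back into a SessionLog.

    Validation reports the first bad row with its 1-based data line number:
    action codes must be 0/1, payoff and score columns numeric, p_avoid in
    [0, 1].  An empty decision_time round-trips to None, not 0.  If no
    ``config`` is given, a minimal one is reconstructed from the phase
    column and the implied endowment.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise SessionFormatError(f"session CSV missing columns: {missing}")

    for col in ("agent_action", "opponent_action"):
        bad = ~frame[col].isin((0, 1))
        if bad.any():
            row = int(frame.index[bad][0]) + 1
            raise SessionFormatError(
                f"row {row}: bad action code {frame.loc[row - 1, col]!r} in "
                f"{col} (must be 0=rush or 1=avoid)"
            )
    for col in ("agent_payoff", "opponent_payoff", "agent_cum", "opponent_cum", "p_avoid"):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            row = int(frame.index[bad][0]) + 1
            raise SessionFormatError(f"row {row}: non-numeric value in {col}")
        frame[col] = values
    bad_p = (frame["p_avoid"] < 0) | (frame["p_avoid"] > 1)
    if bad_p.any():
        row = int(frame.index[bad_p][0]) + 1
        raise SessionFormatError(f"row {row}: p_avoid outside [0, 1]")

    if config is None:
        phase_lengths = frame["phase"].value_counts().sort_index()
        first = frame.iloc[0] if len(frame) else None
        endowment = (
            float(first["agent_cum"] - first["agent_payoff"]) if first is not None else 0.0
        )
        config = SessionConfig(
            phases=tuple(
                PhaseSpec(int(n), preset_params("mutual_exchange"))
                for n in phase_lengths
            ),
            endowment=endowment,
        )

    records = []
    for _, row in frame.iterrows():
        dt = row["decision_time"]
        records.append(
            TrialRecord(
                iteration=int(row["iteration"]),
                phase=int(row["phase"]),
                agent_action=Action.from_code(int(row["agent_action"])),
                opponent_action=Action.from_code(int(row["opponent_action"])),
                agent_payoff=float(row["agent_payoff"]),
                opponent_payoff=float(row["opponent_payoff"]),
                agent_cum=float(row["agent_cum"]),
                opponent_cum=float(row["opponent_cum"]),
                p_avoid=float(row["p_avoid"]),
                decision_time=None if pd.isna(dt) else float(dt),
            )
        )
    return SessionLog(config=config, records=records)


def _parse_matrix(spec) -> PayoffMatrix:
    if spec is None:
        return BUILTIN_MATRICES["chicken_default"]
    if isinstance(spec, str):
        try:
            return BUILTIN_MATRICES[spec]
        except KeyError:
            raise ValueError(
                f"unknown builtin matrix {spec!r}; available: {sorted(BUILTIN_MATRICES)}"
            ) from None
    return PayoffMatrix.from_dict(spec)


def _parse_phase(spec) -> PhaseSpec:
    n = int(spec["n_iterations"])
    if "preset" in spec:
        return PhaseSpec(n, preset_params(spec["preset"]))
    return PhaseSpec(n, ModelParams.from_dict(spec["params"]))


def load_config(path: Union[str, Path]) -> SessionConfig:
    """Load a session config from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "phases" not in data:
        raise ValueError(f"config {path} must be a mapping with a 'phases' list")
    return SessionConfig(
        phases=tuple(_parse_phase(ph) for ph in data["phases"]),
        matrix=_parse_matrix(data.get("matrix")),
        endowment=float(data.get("endowment", 20_000.0)),
        seed=int(data.get("seed", 0)),
        opponent=data.get("opponent", {"kind": "random_bernoulli", "p": 0.5}),
    )


def dump_config(config: SessionConfig, path: Union[str, Path]) -> None:
    """Write a session config to YAML (or JSON if the path ends in .json)."""
    data = {
        "matrix": config.matrix.to_dict(),
        "endowment": config.endowment,
        "seed": config.seed,
        "opponent": config.opponent,
        "phases": [
            {"n_iterations": ph.n_iterations, "params": ph.params.to_dict()}
            for ph in config.phases
        ],
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
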