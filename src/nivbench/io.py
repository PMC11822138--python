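"""Waveform-record CSV dialect, event files and YAML condition configs.

The record CSV has a header row and columns ``time_s, paw_cmh2o,
q_circuit_lpm, q_lung_lpm, q_leak_lpm, pmus_cmh2o, volume_l, vent_phase``;
events live in a companion JSON-lines file with fields ``t``, ``type``,
``payload``.  Externally recorded waveforms in the same dialect can be fed
straight into the analysis pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .virtual_bench import Event, WaveformRecord

__all__ = [
    "record_to_csv",
    "record_from_csv",
    "events_to_jsonl",
    "events_from_jsonl",
    "load_condition_config",
    "dump_condition_config",
]

_COLUMNS = {
    "paw": "paw_cmh2o",
    "q_circuit": "q_circuit_lpm",
    "q_lung": "q_lung_lpm",
    "q_leak": "q_leak_lpm",
    "pmus": "pmus_cmh2o",
    "volume": "volume_l",
    "vent_phase": "vent_phase",
}


def record_to_csv(record: WaveformRecord, path, events_path=None) -> None:
    """Write a record to CSV (and its events to a JSONL companion file)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": record.time})
    for key, col in _COLUMNS.items():
        df[col] = record.channels[key]
    df.to_csv(path, index=False, float_format="%.6g")
    events_to_jsonl(record.events, events_path or path.with_suffix(".events.jsonl"))


def record_from_csv(path, events_path=None) -> WaveformRecord:
    """Load a record from the CSV dialect; the events file is optional."""
    path = Path(path)
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("record too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    fs = round(fs, 6)
    channels = {key: df[col].to_numpy(dtype=float) for key, col in _COLUMNS.items()}
    events_path = Path(events_path) if events_path else path.with_suffix(".events.jsonl")
    events = events_from_jsonl(events_path) if events_path.exists() else []
    return WaveformRecord(fs, channels, events)


def events_to_jsonl(events, path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps({"t": e.t, "type": e.type, "payload": e.payload}) + "\n")


def events_from_jsonl(path) -> list[Event]:
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                d = json.loads(line)
                events.append(Event(d["t"], d["type"], d.get("payload", {})))
    return events


def load_condition_config(path) -> dict:
    """Load a YAML condition config (mechanics, PS, leak kind, sync mode,
    protocol and detector blocks, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("condition config must be a YAML mapping")
    return cfg


def dump_condition_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
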