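"""Readers/writers for the tabular interchange formats.

All tables are tab-separated UTF-8 text with a header row.  Spike times and
lick times are serialized as semicolon-packed lists of seconds with
sub-millisecond precision, so a 10-ms grid survives a round trip exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_SCHEMA = [
    "mouse",
    "session",
    "trial",
    "cue",
    "action",
    "condition",
    "lick_latency_s",
    "lick_times_s",
]

SPIKE_SCHEMA = ["neuron", "mouse", "session", "zone", "trial", "spike_times_s"]

#: the eight aldolase-C zones of left Crus II, lateral to medial
ZONES = ["7+", "6-", "6+", "5-", "5+", "5a-", "5a+", "4b-"]


class SchemaError(ValueError):
    pass


def pack_times(times) -> str:
    """Semicolon-pack a list of times (s); 0.1 ms precision."""
    return ";".join(f"{t:.4f}" for t in np.atleast_1d(np.asarray(times, dtype=float)))


def unpack_times(s) -> np.ndarray:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return np.array([])
    return np.array([float(x) for x in str(s).split(";")])


def write_table(df: pd.DataFrame, path, schema: list[str] | None = None) -> None:
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df[schema]
    df.to_csv(path, sep="\t", index=False)


def read_table(path, schema: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"lick_times_s": str, "spike_times_s": str})
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def write_factors(factors, path) -> None:
    """Serialize CP factors as a long-format table (mode, index, component, value)."""
    rows = []
    for r, lam in enumerate(factors.lam):
        rows.append(("lambda", 0, r, lam))
    for mode, mat in (
        ("neuron", factors.neuron),
        ("time", factors.time),
        ("condition", factors.condition),
    ):
        for i, row in enumerate(mat):
            for r, v in enumerate(row):
                rows.append((mode, i, r, v))
    pd.DataFrame(rows, columns=["mode", "index", "component", "value"]).to_csv(
        path, sep="\t", index=False
    )


def read_factors(path):
    from .tca import TCAFactors

    df = pd.read_csv(path, sep="\t")
    lam = df[df["mode"] == "lambda"].sort_values("component")["value"].to_numpy()

    def mat(mode):
        sub = df[df["mode"] == mode]
        n = sub["index"].max() + 1
        out = np.zeros((n, len(lam)))
        out[sub["index"], sub["component"]] = sub["value"]
        return out

    return TCAFactors(lam=lam, neuron=mat("neuron"), time=mat("time"), condition=mat("condition"))


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    seed: int | None
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = "0.1.0"
    started: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))
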