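"""Delimited-text readers and writers for the package's standard table formats.

All tables are comma- or tab-separated text with a header row; units are part
of the column names (amplitude_nA, time_s, cm_pF, vm_mV, ...). Traces are
two-column time/value files. A JSON sidecar records generator parameters and
seed for synthetic outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import AmplitudeSeries, EventSeries, Trace

AMPLITUDE_COLUMNS = ["cell_id", "condition_label", "sweep_index", "amplitude_nA"]
TRAIN_COLUMNS = ["cell_id", "condition_label", "stim_index", "amplitude_nA"]
EVENT_COLUMNS = ["unit_id", "time_s", "kind"]


class DataError(ValueError):
    """A data file is missing, malformed, or lacks a required column."""


def _read_table(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    return df


def read_amplitude_table(path: str | Path) -> pd.DataFrame:
    """Amplitude table: cell_id, condition_label, sweep_index, amplitude_nA."""
    df = _read_table(path, AMPLITUDE_COLUMNS)
    return df.sort_values(["cell_id", "condition_label", "sweep_index"]).reset_index(drop=True)


def write_amplitude_table(series: Iterable[AmplitudeSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        amps = s.in_nA()
        for i, a in enumerate(amps):
            rows.append((s.cell_id, s.condition_label, i, a))
    pd.DataFrame(rows, columns=AMPLITUDE_COLUMNS).to_csv(path, index=False)


def amplitude_table_to_series(df: pd.DataFrame) -> list[AmplitudeSeries]:
    out = []
    for (cell, cond), g in df.groupby(["cell_id", "condition_label"], sort=True):
        g = g.sort_values("sweep_index")
        out.append(
            AmplitudeSeries(
                g["amplitude_nA"].to_numpy(), unit="nA",
                condition_label=str(cond), cell_id=str(cell),
            )
        )
    return out


def read_train_table(path: str | Path) -> pd.DataFrame:
    """Train table: cell_id, condition_label, stim_index, amplitude_nA."""
    df = _read_table(path, TRAIN_COLUMNS)
    return df.sort_values(["cell_id", "condition_label", "stim_index"]).reset_index(drop=True)


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Event list: unit_id, time_s, kind (spike|stim)."""
    return _read_table(path, EVENT_COLUMNS)


def write_event_table(events: dict[str, dict[str, EventSeries]], path: str | Path) -> None:
    """``events[unit_id][kind]`` -> one tidy event table."""
    rows = []
    for unit_id, kinds in events.items():
        for kind, series in kinds.items():
            for t in series.times:
                rows.append((unit_id, t, kind))
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def write_trace(trace: Trace, path: str | Path, value_name: str | None = None) -> None:
    name = value_name or (f"value_{trace.unit}" if trace.unit else "value")
    pd.DataFrame({"time_s": trace.times, name: trace.values}).to_csv(path, index=False)


def read_trace(path: str | Path) -> Trace:
    df = _read_table(path, ["time_s"])
    value_cols = [c for c in df.columns if c != "time_s"]
    if not value_cols:
        raise DataError(f"{path}: trace file has no value column")
    col = value_cols[0]
    unit = col.rsplit("_", 1)[-1] if "_" in col else ""
    times = df["time_s"].to_numpy(float)
    if times.size < 2:
        raise DataError(f"{path}: trace needs at least 2 samples")
    rate = 1.0 / float(np.median(np.diff(times)))
    return Trace(times, df[col].to_numpy(float), sampling_rate=rate, unit=unit)


def write_sidecar(params: dict, path: str | Path) -> None:
    """JSON sidecar recording generator parameters and seed."""
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True, default=float) + "\n")
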