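"""Tabular and JSON I/O: TACs, input functions, cohort tables, result files."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .petkin.frames import FrameSchedule, TimeActivityCurve
from .petkin.idif import InputFunction


def write_tac_csv(tac: TimeActivityCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_s": tac.schedule.start_s,
            "duration_s": tac.schedule.duration_s,
            "activity": tac.activity_kBq_per_ml,
        }
    ).to_csv(path, index=False)


def read_tac_csv(path: str | Path) -> TimeActivityCurve:
    df = pd.read_csv(path)
    for col in ("start_s", "duration_s", "activity"):
        if col not in df.columns:
            raise ValueError(f"{path}: TAC CSV misses column {col!r}")
    sched = FrameSchedule(df["start_s"].to_numpy(), df["duration_s"].to_numpy())
    return TimeActivityCurve(sched, df["activity"].to_numpy())


def write_input_function_csv(input_function: InputFunction, path: str | Path) -> None:
    pd.DataFrame(
        {"time_min": input_function.times_min, "cp_kBq_per_ml": input_function.cp_kBq_per_ml}
    ).to_csv(path, index=False)


def read_input_function_csv(path: str | Path) -> InputFunction:
    df = pd.read_csv(path)
    for col in ("time_min", "cp_kBq_per_ml"):
        if col not in df.columns:
            raise ValueError(f"{path}: input-function CSV misses column {col!r}")
    return InputFunction(df["time_min"].to_numpy(), df["cp_kBq_per_ml"].to_numpy())


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
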