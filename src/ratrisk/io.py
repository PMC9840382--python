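"""Reading and writing the pipeline's on-disk formats.

Trial logs are long-format CSV with fixed column names and dtypes, one row per
trial; a JSON sidecar (``<name>.meta.json``) records the task config and seeds
so a session can be replayed exactly.  ROI time series are TSV with ROI names
in the first column and timepoint indices as the header.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ROITimeSeriesSet

RDT_COLUMNS = {
    "task": "string",
    "subject_id": "string",
    "session": "int64",
    "block": "int64",
    "trial": "int64",
    "trial_type": "string",
    "lever_offered": "string",
    "choice": "string",
    "reward": "int64",
    "shock": "bool",
    "omitted": "bool",
    "latency": "float64",
}

PRL_COLUMNS = {
    "task": "string",
    "subject_id": "string",
    "session": "int64",
    "trial": "int64",
    "choice_lever": "string",
    "correct_side": "string",
    "correct": "bool",
    "reward": "int64",
    "omitted": "bool",
    "latency": "float64",
}

_SCHEMAS = {"RDT": RDT_COLUMNS, "PRL": PRL_COLUMNS}


def write_trials(
    trials: pd.DataFrame, path, config=None, seeds: dict | None = None
) -> None:
    """Write a trial log CSV plus a replay sidecar with config and seeds."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False)
    meta = {
        "config": dataclasses.asdict(config) if config is not None else None,
        "seeds": seeds or {},
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, default=str)
    )


def read_trials(path) -> pd.DataFrame:
    """Read a trial log CSV, enforcing the schema dtypes."""
    df = pd.read_csv(path)
    task = str(df["task"].iloc[0]) if len(df) else "RDT"
    schema = _SCHEMAS.get(task, RDT_COLUMNS)
    missing = set(schema) - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    return df.astype(schema)


def write_roi_tsv(ts: ROITimeSeriesSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        ts.data, index=pd.Index(ts.roi_names, name="roi"),
        columns=np.arange(ts.n_timepoints),
    )
    frame.to_csv(path, sep="\t")


def read_roi_tsv(path, subject_id: str | None = None, tr: float = 2.0) -> ROITimeSeriesSet:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ROITimeSeriesSet(
        subject_id or Path(path).stem, tuple(frame.index), frame.to_numpy(), tr
    )
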