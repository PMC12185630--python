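"""CSV dialects for trials, estimates, and truth values.

All tabular files are RFC-4180 CSV, UTF-8, '.' decimal, header required.

Stepping dialect (one row per step)::

    participant_id,step_index,x_pelvis_m,xdot_pelvis_mps,ydot_pelvis_mps,x_foot_m,y_foot_m

Metabolic dialect (one row per breath)::

    participant_id,t_s,vo2_ml_s_kg,vco2_ml_s_kg

Truth dialect::

    participant_id,true_value

Row order within a participant is preserved; participants appear in
first-occurrence order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import MetabolicTrial, SteppingTrial

__all__ = [
    "STEPPING_COLUMNS",
    "METABOLIC_COLUMNS",
    "read_trials",
    "read_stepping",
    "read_metabolic",
    "write_trials",
    "read_truth",
    "write_truth",
]

STEPPING_COLUMNS = [
    "participant_id",
    "step_index",
    "x_pelvis_m",
    "xdot_pelvis_mps",
    "ydot_pelvis_mps",
    "x_foot_m",
    "y_foot_m",
]

METABOLIC_COLUMNS = ["participant_id", "t_s", "vo2_ml_s_kg", "vco2_ml_s_kg"]


def _load_checked(path, columns):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    numeric = [c for c in columns if c != "participant_id"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-finite value in column {col!r} at row {bad[0] + 2}"
            )
        df[col] = vals
    return df


def read_stepping(path) -> list[SteppingTrial]:
    """Read stepping trials grouped by participant; empty file -> []."""
    df = _load_checked(path, STEPPING_COLUMNS)
    trials = []
    for pid, g in df.groupby("participant_id", sort=False):
        g = g.sort_values("step_index", kind="stable")
        trials.append(
            SteppingTrial(
                participant_id=str(pid),
                x_pelvis=g["x_pelvis_m"].to_numpy(),
                xdot_pelvis=g["xdot_pelvis_mps"].to_numpy(),
                ydot_pelvis=g["ydot_pelvis_mps"].to_numpy(),
                x_foot=g["x_foot_m"].to_numpy(),
                y_foot=g["y_foot_m"].to_numpy(),
            )
        )
    return trials


def read_metabolic(path) -> list[MetabolicTrial]:
    """Read metabolic trials grouped by participant; validates monotone time."""
    df = _load_checked(path, METABOLIC_COLUMNS)
    trials = []
    for pid, g in df.groupby("participant_id", sort=False):
        t = g["t_s"].to_numpy()
        if t.size > 1 and np.any(np.diff(t) <= 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0])
            row = int(g.index[i + 1]) + 2
            raise ValueError(
                f"{path}: non-increasing breath time for participant "
                f"{pid!r} at row {row}"
            )
        trials.append(
            MetabolicTrial(
                participant_id=str(pid),
                t=t,
                vo2=g["vo2_ml_s_kg"].to_numpy(),
                vco2=g["vco2_ml_s_kg"].to_numpy(),
            )
        )
    return trials


def read_trials(path, problem: str):
    """Dispatch on problem: stepping CSV for foot placement, metabolic else."""
    if problem == "foot_placement":
        return read_stepping(path)
    if problem in ("walking_metabolic", "resting_metabolic"):
        return read_metabolic(path)
    raise ValueError(f"unknown problem {problem!r}")


def write_trials(trials, path) -> None:
    """Write trials (all stepping or all metabolic) in the matching dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    if not trials:
        raise ValueError("no trials to write")
    if isinstance(trials[0], SteppingTrial):
        for tr in trials:
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": tr.participant_id,
                        "step_index": np.arange(tr.n_steps),
                        "x_pelvis_m": tr.x_pelvis,
                        "xdot_pelvis_mps": tr.xdot_pelvis,
                        "ydot_pelvis_mps": tr.ydot_pelvis,
                        "x_foot_m": tr.x_foot,
                        "y_foot_m": tr.y_foot,
                    }
                )
            )
    elif isinstance(trials[0], MetabolicTrial):
        for tr in trials:
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": tr.participant_id,
                        "t_s": tr.t,
                        "vo2_ml_s_kg": tr.vo2,
                        "vco2_ml_s_kg": tr.vco2,
                    }
                )
            )
    else:
        raise TypeError(f"unsupported trial type {type(trials[0]).__name__}")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_truth(path) -> tuple[list[str], np.ndarray]:
    """Read a truth CSV -> (participant_ids, values)."""
    df = _load_checked(path, ["participant_id", "true_value"])
    return list(df["participant_id"].astype(str)), df["true_value"].to_numpy()


def write_truth(participant_ids, values, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"participant_id": list(participant_ids), "true_value": np.asarray(values)}
    ).to_csv(path, index=False)
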