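"""Tidy CSV interchange for kinematic trials and trial summaries.

One long kinematics file holds every trial: one row per sample with the
trial's condition labels repeated, positions in meters, time in seconds.
Velocity columns are optional on read (derived by central differences when
absent).  Summaries are one row per trial with angle columns in degrees.
A c3d reader would slot in here as an extension point; the shipped format
is plain CSV (RFC 4180, UTF-8, "." decimal) so outputs stay diffable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .crp import TrialSummary
from .synth import KinematicTrial, LoadType, Mode, TrialConfig, TrialMeta

__all__ = [
    "KINEMATICS_COLUMNS",
    "VELOCITY_COLUMNS",
    "SUMMARY_COLUMNS",
    "write_kinematics",
    "read_kinematics",
    "write_summaries",
    "read_summaries",
]

log = logging.getLogger(__name__)

KINEMATICS_COLUMNS = [
    "participant",
    "trial",
    "mode",
    "cycle_ms",
    "load_left",
    "load_right",
    "t_s",
    "xL_m",
    "yL_m",
    "xR_m",
    "yR_m",
]
VELOCITY_COLUMNS = ["vxL_ms", "vyL_ms", "vxR_ms", "vyR_ms"]

SUMMARY_COLUMNS = [
    "participant",
    "trial",
    "mode",
    "cycle_ms",
    "load_left",
    "load_right",
    "mean_crp_deg",
    "sd_crp_deg",
    "deviation_deg",
    "excluded",
]


def _trial_frame(trial: KinematicTrial, velocities: bool) -> pd.DataFrame:
    meta = trial.meta
    cfg = meta.config
    df = pd.DataFrame(
        {
            "participant": meta.participant,
            "trial": meta.trial,
            "mode": cfg.mode.value,
            "cycle_ms": cfg.cycle_ms,
            "load_left": cfg.load_left.value,
            "load_right": cfg.load_right.value,
            "t_s": trial.t,
            "xL_m": trial.pos_left[:, 0],
            "yL_m": trial.pos_left[:, 1],
            "xR_m": trial.pos_right[:, 0],
            "yR_m": trial.pos_right[:, 1],
        }
    )
    if velocities:
        df["vxL_ms"] = trial.vel_left[:, 0]
        df["vyL_ms"] = trial.vel_left[:, 1]
        df["vxR_ms"] = trial.vel_right[:, 0]
        df["vyR_ms"] = trial.vel_right[:, 1]
    return df


def write_kinematics(trials, path, velocities: bool = True) -> int:
    """Stream trials to one long CSV; returns the number of trials written."""
    path = Path(path)
    n = 0
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for trial in trials:
            _trial_frame(trial, velocities).to_csv(fh, index=False, header=(n == 0))
            n += 1
    if n == 0:
        # still emit a valid header for downstream schema checks
        cols = KINEMATICS_COLUMNS + (VELOCITY_COLUMNS if velocities else [])
        path.write_text(",".join(cols) + "\n", encoding="utf-8")
    return n


def read_kinematics(path) -> list[KinematicTrial]:
    """Read a kinematics CSV back into trials.

    Rows are grouped by (participant, trial) and sorted by time within each
    trial; timestamps must be uniform to 1e-9 s.  Malformed headers, NaN
    positions and non-uniform sampling raise with the offending column or
    trial named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in KINEMATICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"kinematics file {path} missing column(s): {missing}")
    if list(df.columns[: len(KINEMATICS_COLUMNS)]) != KINEMATICS_COLUMNS:
        raise ValueError(
            f"kinematics header must start with {KINEMATICS_COLUMNS} in order"
        )
    pos_cols = ["t_s", "xL_m", "yL_m", "xR_m", "yR_m"]
    bad = df[pos_cols].isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0])
        raise ValueError(f"NaN in kinematics near data row {row + 2} of {path}")
    has_vel = all(c in df.columns for c in VELOCITY_COLUMNS)

    trials = []
    # trial indices restart per coordination mode, so mode is part of the key
    for (pid, mode, tid), g in df.groupby(["participant", "mode", "trial"], sort=True):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy()
        dt = np.diff(t)
        if len(dt) == 0:
            raise ValueError(f"trial ({pid}, {mode}, {tid}) has a single sample")
        if np.max(np.abs(dt - dt[0])) > 1e-9:
            raise ValueError(f"non-uniform timestamps in trial ({pid}, {mode}, {tid})")
        fs = 1.0 / dt[0]
        pos_left = g[["xL_m", "yL_m"]].to_numpy()
        pos_right = g[["xR_m", "yR_m"]].to_numpy()
        if has_vel:
            vel_left = g[["vxL_ms", "vyL_ms"]].to_numpy()
            vel_right = g[["vxR_ms", "vyR_ms"]].to_numpy()
        else:
            vel_left = np.gradient(pos_left, dt[0], axis=0)
            vel_right = np.gradient(pos_right, dt[0], axis=0)
        cfg = TrialConfig(
            mode=Mode(g["mode"].iloc[0]),
            cycle_ms=float(g["cycle_ms"].iloc[0]),
            load_left=LoadType(g["load_left"].iloc[0]),
            load_right=LoadType(g["load_right"].iloc[0]),
            duration_s=max(len(t) / fs, 42.0),
            fs=fs,
        )
        meta = TrialMeta(
            participant=int(pid),
            trial=int(tid),
            config=cfg,
            delta_omega=float("nan"),
            Q=float("nan"),
        )
        trials.append(
            KinematicTrial(
                t=t,
                pos_left=pos_left,
                pos_right=pos_right,
                vel_left=vel_left,
                vel_right=vel_right,
                meta=meta,
            )
        )
    log.info("read_kinematics: %d trials from %s", len(trials), path)
    return trials


def write_summaries(summaries, path) -> int:
    """Write trial summaries (one row per trial); returns the row count."""
    rows = [
        {
            "participant": s.participant,
            "trial": s.trial,
            "mode": s.mode.value if isinstance(s.mode, Mode) else str(s.mode),
            "cycle_ms": s.cycle_ms,
            "load_left": s.load_left,
            "load_right": s.load_right,
            "mean_crp_deg": s.mean_crp_deg,
            "sd_crp_deg": s.sd_crp_deg,
            "deviation_deg": s.deviation_deg,
            "excluded": s.excluded,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False)
    return len(df)


def read_summaries(path) -> list[TrialSummary]:
    """Read a summary CSV back into :class:`TrialSummary` objects."""
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary file {path} missing column(s): {missing}")
    return [
        TrialSummary(
            participant=int(r.participant),
            trial=int(r.trial),
            mode=Mode(r.mode),
            cycle_ms=float(r.cycle_ms),
            load_left=str(r.load_left),
            load_right=str(r.load_right),
            mean_crp_deg=float(r.mean_crp_deg),
            sd_crp_deg=float(r.sd_crp_deg),
            deviation_deg=float(r.deviation_deg),
            excluded=bool(r.excluded),
        )
        for r in df.itertuples()
    ]
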