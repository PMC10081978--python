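"""Continuous relative phase (CRP) measurement pipeline.

Per-hand position traces are amplitude-centered (midrange removal), turned
into analytic signals via the Hilbert transform, and combined into a
per-sample relative phase

    CRP(t) = atan2(H1 x2 - H2 x1,  x1 x2 + H1 H2)

(the angle between the two analytic signals), folded to [0, 180] degrees so
that 0 denotes fully in-phase and 180 fully anti-phase movement.  Trials are
summarized by the mean and standard deviation of folded CRP over a fixed
steady-state window (12-42 s by default), after screening for phase
transitions (a sustained escape into the opposite coordination mode, which
disqualifies a trial from steady-state analysis).

Hilbert-transform phase estimates are unreliable within a fraction of a
cycle of the trace edges; closed-form comparisons in the tests therefore
exclude an edge margin of ``EDGE_MARGIN_S`` seconds per end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .synth import KinematicTrial, Mode, TrialMeta

__all__ = [
    "EDGE_MARGIN_S",
    "PhaseSeries",
    "CRPSeries",
    "TrialSummary",
    "center_signal",
    "analytic_signal",
    "phase_angle",
    "crp",
    "extract_window",
    "detect_phase_transition",
    "summarize_trial",
]

log = logging.getLogger(__name__)

#: seconds discarded from each end when comparing against closed forms
EDGE_MARGIN_S = 0.5


@dataclass
class PhaseSeries:
    """Unwrapped instantaneous phase of one hand (radians)."""

    t: np.ndarray
    phase: np.ndarray


@dataclass
class CRPSeries:
    """Folded continuous relative phase in degrees, on [0, 180].

    ``valid`` flags samples where the phase was well-defined (both analytic
    signals had non-vanishing amplitude); invalid samples are excluded from
    summaries.
    """

    t: np.ndarray
    crp_deg: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.crp_deg) == len(self.valid)):
            raise ValueError("t, crp_deg and valid must have equal length")


@dataclass
class TrialSummary:
    """Windowed per-trial summary of coordination stability and variability."""

    participant: int
    trial: int
    mode: Mode
    cycle_ms: float
    load_left: str
    load_right: str
    mean_crp_deg: float
    sd_crp_deg: float
    deviation_deg: float
    excluded: bool


def center_signal(x: np.ndarray) -> np.ndarray:
    """Amplitude-center a trace around zero by midrange removal.

    Returns ``x - (max(x) + min(x)) / 2`` so that the extremes become
    symmetric (max = -min).  A constant trace has no defined oscillation
    amplitude and is rejected.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValueError("expected a 1-D trace of length >= 2")
    lo, hi = float(np.min(arr)), float(np.max(arr))
    if hi == lo:
        raise ValueError("constant trace: amplitude centering is degenerate")
    return arr - (hi + lo) / 2.0


def analytic_signal(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real and imaginary parts of the analytic signal zeta = x + i H[x].

    The Hilbert transform is computed in the frequency domain (negative
    frequencies zeroed, positive doubled).  ``x`` should already be
    amplitude-centered; very short traces are rejected.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or len(arr) < 4:
        raise ValueError("expected a 1-D trace of length >= 4")
    zeta = hilbert(arr)
    return arr, np.imag(zeta)


def phase_angle(x: np.ndarray, H: np.ndarray, t: np.ndarray | None = None) -> PhaseSeries:
    """Unwrapped per-sample phase angle atan2(H, x) of an analytic signal.

    Samples where both components vanish have no defined angle; the previous
    sample's angle is propagated there (logged).
    """
    x = np.asarray(x, dtype=float)
    H = np.asarray(H, dtype=float)
    if x.shape != H.shape:
        raise ValueError("x and H must have equal length")
    ang = np.arctan2(H, x)
    dead = (x == 0.0) & (H == 0.0)
    if np.any(dead):
        log.warning("phase_angle: %d zero-amplitude samples, propagating phase", int(dead.sum()))
        idx = np.where(~dead, np.arange(len(x)), 0)
        np.maximum.accumulate(idx, out=idx)
        ang = ang[idx]
    ang = np.unwrap(ang)
    if t is None:
        t = np.arange(len(x), dtype=float)
    return PhaseSeries(t=np.asarray(t, dtype=float), phase=ang)


def _fold_deg(angle_rad: np.ndarray) -> np.ndarray:
    """Wrap an angle to (-pi, pi] and fold to [0, 180] degrees."""
    wrapped = np.mod(angle_rad + np.pi, 2.0 * np.pi) - np.pi
    # mod maps pi -> -pi; restore the (-pi, pi] convention before folding
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return np.degrees(np.abs(wrapped))


def crp(
    x1: np.ndarray,
    x2: np.ndarray,
    t: np.ndarray | None = None,
    fold: bool = True,
) -> CRPSeries:
    """Continuous relative phase between two raw position traces.

    ``x1`` is the right hand and ``x2`` the left hand by convention (the
    choice is immaterial after folding).  Centering is applied internally;
    the relative phase is the four-quadrant angle of the product
    zeta1 * conj(zeta2), i.e. atan2(H1 x2 - H2 x1, x1 x2 + H1 H2), folded to
    [0, 180] degrees.  Samples where both numerator and denominator are
    negligible relative to the signal amplitudes (amplitude dropout) are
    flagged invalid.
    """
    x1c, H1 = analytic_signal(center_signal(x1))
    x2c, H2 = analytic_signal(center_signal(x2))
    if len(x1c) != len(x2c):
        raise ValueError("traces must have equal length")
    num = H1 * x2c - H2 * x1c
    den = x1c * x2c + H1 * H2
    scale = np.max(num * num + den * den)
    valid = (num * num + den * den) > 1e-24 * scale
    n_bad = int((~valid).sum())
    if n_bad:
        # a lone flagged sample (typically t = 0 of a sine starting at zero)
        # is routine; a visible fraction of the trial is worth a warning
        level = logging.WARNING if n_bad > 0.001 * len(valid) else logging.DEBUG
        log.log(level, "crp: %d amplitude-dropout samples flagged", n_bad)
    ang = np.arctan2(num, den)
    out = _fold_deg(ang) if fold else np.degrees(ang)
    if t is None:
        t = np.arange(len(out), dtype=float)
    return CRPSeries(t=np.asarray(t, dtype=float), crp_deg=out, valid=valid)


def _window_mask(t: np.ndarray, start_s: float, end_s: float) -> np.ndarray:
    return (t >= start_s) & (t < end_s)


def extract_window(obj, start_s: float = 12.0, end_s: float = 42.0):
    """Restrict a trial or CRP series to the half-open window [start_s, end_s).

    At 1000 Hz the default window retains exactly 30 000 samples.  Raises if
    the data does not cover the window.
    """
    if isinstance(obj, KinematicTrial):
        t = obj.t
        if t[-1] + (t[1] - t[0]) < end_s - 1e-9:
            raise ValueError(
                f"trial (participant {obj.meta.participant}, trial {obj.meta.trial}) "
                f"shorter than window end {end_s} s"
            )
        m = _window_mask(t, start_s, end_s)
        return KinematicTrial(
            t=t[m],
            pos_left=obj.pos_left[m],
            pos_right=obj.pos_right[m],
            vel_left=obj.vel_left[m],
            vel_right=obj.vel_right[m],
            meta=obj.meta,
        )
    if isinstance(obj, CRPSeries):
        t = obj.t
        if t[-1] + (t[1] - t[0]) < end_s - 1e-9:
            raise ValueError(f"series shorter than window end {end_s} s")
        m = _window_mask(t, start_s, end_s)
        return CRPSeries(t=t[m], crp_deg=obj.crp_deg[m], valid=obj.valid[m])
    raise TypeError(f"cannot window object of type {type(obj).__name__}")


def detect_phase_transition(
    series: CRPSeries,
    intended_deg: float,
    window_s: float = 3.0,
    step_s: float = 0.5,
    threshold_deg: float = 90.0,
) -> bool:
    """Flag a sustained escape into the opposite coordination mode.

    True iff the moving average of folded CRP (3 s window, 0.5 s step by
    default) deviates from the intended phase by more than 90 degrees in any
    window — the trajectory crossed into the opposite mode's basin and
    stayed there long enough to dominate a window.  Brief single-sample
    excursions do not trigger.
    """
    t, v = series.t, series.crp_deg
    if len(t) < 2:
        log.warning("detect_phase_transition: series too short, returning False")
        return False
    dt = t[1] - t[0]
    win = int(round(window_s / dt))
    step = max(1, int(round(step_s / dt)))
    if win < 1 or win > len(v):
        log.warning("detect_phase_transition: series shorter than one window")
        return False
    csum = np.concatenate([[0.0], np.cumsum(v)])
    starts = np.arange(0, len(v) - win + 1, step)
    means = (csum[starts + win] - csum[starts]) / win
    return bool(np.any(np.abs(means - intended_deg) > threshold_deg))


def summarize_trial(
    trial: KinematicTrial,
    window: tuple[float, float] = (12.0, 42.0),
    transition_window_s: float = 3.0,
    transition_step_s: float = 0.5,
    transition_threshold_deg: float = 90.0,
) -> TrialSummary:
    """Run the full measurement pipeline on one trial.

    center -> analytic signal -> CRP -> steady-state window -> transition
    screen -> windowed mean and SD of folded CRP in degrees.  Mean and SD
    are ordinary arithmetic moments of the folded samples; the deviation is
    |mean - intended| with intended 0 (in-phase) or 180 (anti-phase).
    Excluded trials still carry their summaries but are flagged.
    """
    meta: TrialMeta = trial.meta
    cfg = meta.config
    series = crp(trial.pos_right[:, 1], trial.pos_left[:, 1], t=trial.t)
    windowed = extract_window(series, *window)
    intended = cfg.mode.intended_deg
    excluded = detect_phase_transition(
        windowed,
        intended,
        window_s=transition_window_s,
        step_s=transition_step_s,
        threshold_deg=transition_threshold_deg,
    )
    vals = windowed.crp_deg[windowed.valid]
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return TrialSummary(
        participant=meta.participant,
        trial=meta.trial,
        mode=cfg.mode,
        cycle_ms=cfg.cycle_ms,
        load_left=cfg.load_left.value,
        load_right=cfg.load_right.value,
        mean_crp_deg=mean,
        sd_crp_deg=sd,
        deviation_deg=abs(mean - intended),
        excluded=excluded,
    )
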