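"""Synthetic bimanual-trial generator.

Emulates robot-exoskeleton bimanual tracking trials: two hands oscillate
vertically between targets 10 cm apart, paced at a 750 ms or 1200 ms cycle,
sampled at 1000 Hz for 45 s, in one of two coordination modes (in-phase,
intended relative phase 0; anti-phase, intended pi) and one of nine load
conditions (none / viscous / elastic per arm, all ordered pairs).

Generation is phase-first: the relative phase phi(t) is simulated from the
extended-HKB Langevin equation

    dphi = (delta_omega - a sin phi - 2 b sin 2 phi) dt + sqrt(Q) dW

(Euler–Maruyama, dt = 1/fs) and then rendered into per-hand kinematics.
Load conditions act through a configurable mapping onto (delta_omega, Q):
matched loads leave the limbs symmetric (delta_omega = 0) while mismatched
loads detune them and raise the phase noise.  The robot's orthogonal force
fields (viscous, velocity-dependent, gain -15; elastic, displacement-
dependent, gain +15) are annotated per sample but are not fed back into the
limb kinematics — their behavioural effect is carried entirely by the
(delta_omega, Q) mapping, because no limb-impedance model is assumed.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .hkb import HKBParams, drift

__all__ = [
    "LoadType",
    "Mode",
    "TrialConfig",
    "ConditionDynamics",
    "DynamicsMapping",
    "DesignSpec",
    "KinematicTrial",
    "ForceTrace",
    "ALL_LOAD_PAIRS",
    "simulate_phase",
    "simulate_phase_ensemble",
    "synthesize_kinematics",
    "force_field",
    "trial_forces",
    "condition_to_dynamics",
    "generate_experiment",
]


class LoadType(str, enum.Enum):
    """Per-arm load condition applied by the robot."""

    NONE = "none"
    VISCOUS = "viscous"
    ELASTIC = "elastic"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


class Mode(str, enum.Enum):
    """Intended coordination mode."""

    IN_PHASE = "in_phase"
    ANTI_PHASE = "anti_phase"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value

    @property
    def intended_rad(self) -> float:
        return 0.0 if self is Mode.IN_PHASE else math.pi

    @property
    def intended_deg(self) -> float:
        return 0.0 if self is Mode.IN_PHASE else 180.0


#: the nine ordered (left, right) load pairs of the full factorial design
ALL_LOAD_PAIRS: tuple[tuple[LoadType, LoadType], ...] = tuple(
    (l, r) for l in LoadType for r in LoadType
)


@dataclass(frozen=True)
class TrialConfig:
    """Geometry, timing and sampling of one synthetic trial."""

    mode: Mode = Mode.IN_PHASE
    cycle_ms: float = 750.0
    load_left: LoadType = LoadType.NONE
    load_right: LoadType = LoadType.NONE
    duration_s: float = 45.0
    fs: float = 1000.0
    amplitude_cm: float = 10.0  # peak-to-peak excursion
    measurement_noise_m: float = 5e-4  # white positional noise, ~mm resolution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 42.0:
            raise ValueError(
                "duration_s must be >= 42 s so the 12-42 s analysis window exists"
            )
        if self.fs <= 2.0 / (self.cycle_ms / 1000.0):
            raise ValueError("sampling rate below Nyquist for the movement frequency")

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.fs)


@dataclass(frozen=True)
class ConditionDynamics:
    """Effective phase dynamics of one (load_left, load_right) pair."""

    delta_omega: float  # rad/s
    Q: float  # rad^2/s


@dataclass(frozen=True)
class DynamicsMapping:
    """Configurable map from load pair to (delta_omega, Q).

    Each load pulls the loaded arm's eigenfrequency by ``omega_pull`` rad/s;
    the detuning of a pair is pull(left) - pull(right), so matched pairs are
    exactly symmetric and swapping arms flips the sign.  Phase noise is a
    base intensity plus per-arm increments, doubled in the anti-phase mode
    (the shallower, more attention-demanding well).
    """

    omega_pull: dict = field(
        default_factory=lambda: {
            LoadType.NONE: 0.0,
            LoadType.VISCOUS: -0.35,
            LoadType.ELASTIC: -0.15,
        }
    )
    q_base: float = 0.02
    q_increment: dict = field(
        default_factory=lambda: {
            LoadType.NONE: 0.0,
            LoadType.VISCOUS: 0.01,
            LoadType.ELASTIC: 0.02,
        }
    )
    antiphase_q_factor: float = 2.0


@dataclass
class TrialMeta:
    """Provenance of one generated trial."""

    participant: int
    trial: int
    config: TrialConfig
    delta_omega: float
    Q: float


@dataclass
class KinematicTrial:
    """Per-hand 2-D kinematics of one trial (meters, seconds).

    The oscillation axis is y; x holds the constant lateral offset of each
    hand.  Arrays are (n, 2) with columns (x, y).
    """

    t: np.ndarray
    pos_left: np.ndarray
    pos_right: np.ndarray
    vel_left: np.ndarray
    vel_right: np.ndarray
    meta: TrialMeta

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("pos_left", "pos_right", "vel_left", "vel_right"):
            arr = getattr(self, name)
            if arr.shape != (n, 2):
                raise ValueError(f"{name} must have shape ({n}, 2), got {arr.shape}")


@dataclass
class ForceTrace:
    """Robot force annotation per sample and hand (newtons, (n, 2) arrays)."""

    F_left: np.ndarray
    F_right: np.ndarray


def simulate_phase_ensemble(
    params_a: float,
    params_b: float,
    delta_omega: np.ndarray,
    Q: np.ndarray,
    phi0: np.ndarray,
    fs: float,
    duration_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Euler–Maruyama integration of many phase trajectories at once.

    ``delta_omega``, ``Q`` and ``phi0`` are broadcast to a common ensemble
    size; the return is (n_paths, n_steps), unwrapped (not folded).
    """
    delta_omega, Q, phi0 = np.broadcast_arrays(
        np.atleast_1d(np.asarray(delta_omega, dtype=float)),
        np.atleast_1d(np.asarray(Q, dtype=float)),
        np.atleast_1d(np.asarray(phi0, dtype=float)),
    )
    if not np.all(np.isfinite(phi0)):
        raise ValueError("phi0 must be finite")
    if np.any(Q < 0):
        raise ValueError("noise intensity Q must be non-negative")
    if fs < 100.0:
        raise ValueError("fs must be >= 100 Hz for the explicit scheme")
    dt = 1.0 / fs
    max_drift = np.max(np.abs(delta_omega)) + params_a + 2.0 * params_b
    if max_drift * dt > 0.1:
        warnings.warn(
            "Euler step too coarse: |drift|*dt may exceed 0.1 rad", RuntimeWarning
        )
    n_steps = round(duration_s * fs)
    n_paths = len(phi0)
    out = np.empty((n_paths, n_steps))
    phi = phi0.astype(float).copy()
    out[:, 0] = phi
    sig = np.sqrt(Q * dt)
    stochastic = bool(np.any(sig > 0))
    two_b = 2.0 * params_b
    for i in range(1, n_steps):
        phi = phi + dt * (
            delta_omega - params_a * np.sin(phi) - two_b * np.sin(2.0 * phi)
        )
        if stochastic:
            phi = phi + sig * rng.standard_normal(n_paths)
        out[:, i] = phi
    return out


def simulate_phase(
    params: HKBParams,
    Q: float,
    phi0: float,
    fs: float = 1000.0,
    duration_s: float = 45.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one relative-phase trajectory phi(t).

    With ``Q = 0`` the trajectory is deterministic (the rng is never drawn
    from); with ``Q > 0`` it is reproducible for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    paths = simulate_phase_ensemble(
        params.a,
        params.b,
        np.array([params.delta_omega]),
        np.array([float(Q)]),
        np.array([float(phi0)]),
        fs,
        duration_s,
        rng,
    )
    return paths[0]


# lateral hand offsets from the body midline (m); arbitrary but fixed
_X_LEFT = -0.15
_X_RIGHT = 0.15


def synthesize_kinematics(
    phi: np.ndarray,
    config: TrialConfig,
    meta: TrialMeta | None = None,
    rng: np.random.Generator | None = None,
) -> KinematicTrial:
    """Render a relative-phase trajectory into per-hand kinematics.

    The left hand tracks the pacing oscillation theta(t) = 2 pi t / T and
    the right hand lags it by phi(t):

        y_left(t)  = (A/2) sin(theta)
        y_right(t) = (A/2) sin(theta - phi)

    so that phi = 0 gives mirror-identical traces and phi = pi gives exact
    counter-motion.  Velocities are the analytic time derivatives of the
    rendered positions (with phi-dot from a central-difference gradient);
    optional white Gaussian measurement noise is added to positions only.
    """
    phi = np.asarray(phi, dtype=float)
    if len(phi) != config.n_samples:
        raise ValueError(
            f"trajectory length {len(phi)} does not match config "
            f"({config.n_samples} samples)"
        )
    fs = config.fs
    t = np.arange(config.n_samples) / fs
    omega = 2.0 * np.pi / (config.cycle_ms / 1000.0)
    half_amp = config.amplitude_cm / 100.0 / 2.0  # cm peak-to-peak -> m half-amp
    theta = omega * t

    y_left = half_amp * np.sin(theta)
    y_right = half_amp * np.sin(theta - phi)
    phidot = np.gradient(phi, 1.0 / fs)
    vy_left = half_amp * omega * np.cos(theta)
    vy_right = half_amp * (omega - phidot) * np.cos(theta - phi)

    n = config.n_samples
    pos_left = np.column_stack([np.full(n, _X_LEFT), y_left])
    pos_right = np.column_stack([np.full(n, _X_RIGHT), y_right])
    vel_left = np.column_stack([np.zeros(n), vy_left])
    vel_right = np.column_stack([np.zeros(n), vy_right])

    if config.measurement_noise_m > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        pos_left = pos_left + rng.normal(0.0, config.measurement_noise_m, (n, 2))
        pos_right = pos_right + rng.normal(0.0, config.measurement_noise_m, (n, 2))

    if meta is None:
        meta = TrialMeta(
            participant=0, trial=0, config=config, delta_omega=float("nan"), Q=float("nan")
        )
    return KinematicTrial(
        t=t,
        pos_left=pos_left,
        pos_right=pos_right,
        vel_left=vel_left,
        vel_right=vel_right,
        meta=meta,
    )


# 90-degree rotation used by the robot's orthogonal force law
_ROT90 = np.array([[0.0, -1.0], [1.0, 0.0]])

VISCOUS_GAIN = -15.0
ELASTIC_GAIN = 15.0


def force_field(vel_or_disp: np.ndarray, load: LoadType) -> np.ndarray:
    """Orthogonal robot force for one hand, F = k R v (viscous) or k R (p - p0).

    ``vel_or_disp`` is the (n, 2) velocity trace for a viscous load or the
    (n, 2) position trace for an elastic load (displacement is taken from
    the first sample).  The rotation R = [[0, -1], [1, 0]] makes the force
    orthogonal to its input vector at every sample; gains are -15 for the
    viscous field and +15 for the elastic field.  (Both gains are quoted as
    magnitude-15 "per meter" style constants; a velocity-dependent gain is
    dimensionally N s/m, a position-dependent one N/m.)
    """
    arr = np.asarray(vel_or_disp, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) trace")
    if not np.all(np.isfinite(arr)):
        raise ValueError("trace must be finite")
    if load is LoadType.NONE:
        return np.zeros_like(arr)
    if load is LoadType.VISCOUS:
        return VISCOUS_GAIN * arr @ _ROT90.T
    if load is LoadType.ELASTIC:
        return ELASTIC_GAIN * (arr - arr[0]) @ _ROT90.T
    raise ValueError(f"unknown load type: {load!r}")


def trial_forces(trial: KinematicTrial) -> ForceTrace:
    """Annotate a trial with the robot force each hand would experience."""

    def one(load: LoadType, pos: np.ndarray, vel: np.ndarray) -> np.ndarray:
        return force_field(vel if load is LoadType.VISCOUS else pos, load)

    cfg = trial.meta.config
    return ForceTrace(
        F_left=one(cfg.load_left, trial.pos_left, trial.vel_left),
        F_right=one(cfg.load_right, trial.pos_right, trial.vel_right),
    )


def condition_to_dynamics(
    load_left: LoadType,
    load_right: LoadType,
    mode: Mode = Mode.IN_PHASE,
    mapping: DynamicsMapping | None = None,
) -> ConditionDynamics:
    """Map a load pair (and coordination mode) to effective (delta_omega, Q)."""
    if mapping is None:
        mapping = DynamicsMapping()
    try:
        d_omega = mapping.omega_pull[load_left] - mapping.omega_pull[load_right]
        q = mapping.q_base + mapping.q_increment[load_left] + mapping.q_increment[load_right]
    except KeyError as exc:  # pragma: no cover - defensive
        raise KeyError(f"dynamics mapping missing load type {exc}") from exc
    if mode is Mode.ANTI_PHASE:
        q *= mapping.antiphase_q_factor
    return ConditionDynamics(delta_omega=d_omega, Q=q)


@dataclass(frozen=True)
class DesignSpec:
    """Full factorial design of one synthetic experiment.

    Defaults reproduce the study conditions: per participant and per
    coordination mode, 9 load pairs x 2 cycling frequencies x 5 repetitions
    = 90 trials in seeded random order (180 trials per participant).
    Per-participant heterogeneity is a constant relative-phase bias
    (SD 2 degrees) and a multiplicative phase-noise factor (1 +/- 0.2),
    drawn once per participant, which gives downstream mixed models a
    non-degenerate participant variance component.
    """

    modes: Sequence[Mode] = (Mode.IN_PHASE, Mode.ANTI_PHASE)
    cycles_ms: Sequence[float] = (750.0, 1200.0)
    load_pairs: Sequence[tuple[LoadType, LoadType]] = ALL_LOAD_PAIRS
    repetitions: int = 5
    duration_s: float = 45.0
    fs: float = 1000.0
    amplitude_cm: float = 10.0
    measurement_noise_m: float = 5e-4
    hkb_a: float = 1.0
    hkb_b: float = 1.0
    mapping: DynamicsMapping = field(default_factory=DynamicsMapping)
    offset_sd_deg: float = 2.0
    noise_mult_sd: float = 0.2

    @property
    def trials_per_mode(self) -> int:
        return len(self.cycles_ms) * len(self.load_pairs) * self.repetitions


def generate_experiment(
    n_participants: int,
    design: DesignSpec | None = None,
    seed: int = 0,
) -> Iterator[KinematicTrial]:
    """Generate a full synthetic experiment, one trial at a time.

    Yields :class:`KinematicTrial` objects lazily (a full-size experiment is
    several hundred MB if materialized); wrap in ``list`` for small designs.
    Deterministic for a given (design, seed).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if design is None:
        design = DesignSpec()
    if design.repetitions < 1 or not design.load_pairs or not design.cycles_ms:
        raise ValueError("invalid design: empty factor or non-positive repetitions")
    rng = np.random.default_rng(seed)

    cells = [
        (cycle, pair)
        for cycle in design.cycles_ms
        for pair in design.load_pairs
        for _ in range(design.repetitions)
    ]

    for p in range(1, n_participants + 1):
        offset = math.radians(rng.normal(0.0, design.offset_sd_deg))
        noise_mult = max(0.1, rng.normal(1.0, design.noise_mult_sd))
        for mode in design.modes:
            order = rng.permutation(len(cells))
            d_omegas = np.empty(len(cells))
            qs = np.empty(len(cells))
            configs: list[TrialConfig] = []
            for k, idx in enumerate(order):
                cycle, (ll, lr) = cells[idx]
                dyn = condition_to_dynamics(ll, lr, mode, design.mapping)
                d_omegas[k] = dyn.delta_omega
                qs[k] = dyn.Q * noise_mult
                configs.append(
                    TrialConfig(
                        mode=mode,
                        cycle_ms=cycle,
                        load_left=ll,
                        load_right=lr,
                        duration_s=design.duration_s,
                        fs=design.fs,
                        amplitude_cm=design.amplitude_cm,
                        measurement_noise_m=design.measurement_noise_m,
                        seed=seed,
                    )
                )
            phi0 = np.full(len(cells), mode.intended_rad)
            paths = simulate_phase_ensemble(
                design.hkb_a,
                design.hkb_b,
                d_omegas,
                qs,
                phi0,
                design.fs,
                design.duration_s,
                rng,
            )
            for k, cfg in enumerate(configs):
                meta = TrialMeta(
                    participant=p,
                    trial=k + 1,
                    config=cfg,
                    delta_omega=float(d_omegas[k]),
                    Q=float(qs[k]),
                )
                yield synthesize_kinematics(paths[k] + offset, cfg, meta=meta, rng=rng)
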