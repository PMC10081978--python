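"""Extended Haken–Kelso–Bunz (HKB) relative-phase dynamics.

The relative phase ``phi`` between two rhythmically moving limbs evolves on
the tilted two-well potential

    V(phi) = -delta_omega * phi - a * cos(phi) - b * cos(2 * phi)

where ``a`` and ``b`` set the relative depth (and hence relative stability)
of the in-phase (phi = 0) and anti-phase (phi = pi) wells, and the detuning
``delta_omega`` is a symmetry-breaking term produced by a difference in the
two limbs' eigenfrequencies.  The dynamics adopted here are the overdamped
gradient flow

    dphi/dt = -dV/dphi = delta_omega - a * sin(phi) - 2 * b * sin(2 * phi)

which is the minimal equation of motion consistent with the potential.

This module is pure closed-form machinery: potential, drift, curvature,
fixed points, and the linearized small-noise prediction of stationary phase
variability.  It has no I/O and no randomness; the stochastic simulator in
:mod:`bimanual.synth` and the test suite both treat it as the oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "HKBParams",
    "FixedPoint",
    "potential",
    "drift",
    "curvature",
    "fixed_points",
    "predicted_sd",
]


@dataclass(frozen=True)
class HKBParams:
    """Coupling and detuning parameters of the extended HKB potential.

    Parameters
    ----------
    a : float
        In-phase coupling strength (1/s), ``a >= 0``.
    b : float
        Anti-phase coupling strength (1/s), ``b >= 0``.
    delta_omega : float
        Detuning (symmetry-breaking) term in rad/s; any sign.  Zero for
        limbs with identical eigenfrequencies.

    At least one of ``a``, ``b`` must be strictly positive, otherwise the
    landscape is degenerate (no wells).
    """

    a: float = 1.0
    b: float = 1.0
    delta_omega: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "delta_omega"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"HKBParams.{name} must be finite, got {v!r}")
        if self.a < 0 or self.b < 0:
            raise ValueError("coupling strengths a and b must be non-negative")
        if self.a == 0 and self.b == 0:
            raise ValueError("degenerate landscape: a and b are both zero")


@dataclass(frozen=True)
class FixedPoint:
    """A stationary relative phase of the gradient dynamics.

    ``phi_star`` lies in (-pi, pi]; ``stable`` is equivalent to positive
    curvature of the potential at ``phi_star``.
    """

    phi_star: float
    stable: bool
    curvature: float


def _validate_phi(phi):
    arr = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("phi must be finite")
    return arr


def potential(phi, params: HKBParams):
    """Evaluate V(phi) = -delta_omega*phi - a*cos(phi) - b*cos(2*phi)."""
    p = _validate_phi(phi)
    out = -params.delta_omega * p - params.a * np.cos(p) - params.b * np.cos(2.0 * p)
    return out if out.ndim else float(out)


def drift(phi, params: HKBParams):
    """Evaluate dphi/dt = -dV/dphi = delta_omega - a*sin(phi) - 2b*sin(2*phi)."""
    p = _validate_phi(phi)
    out = params.delta_omega - params.a * np.sin(p) - 2.0 * params.b * np.sin(2.0 * p)
    return out if out.ndim else float(out)


def curvature(phi, params: HKBParams):
    """Evaluate V''(phi) = a*cos(phi) + 4b*cos(2*phi) (detuning drops out)."""
    p = _validate_phi(phi)
    out = params.a * np.cos(p) + 4.0 * params.b * np.cos(2.0 * p)
    return out if out.ndim else float(out)


def fixed_points(params: HKBParams, grid_size: int = 4096) -> list[FixedPoint]:
    """Find all stationary phases of the gradient flow in (-pi, pi].

    Roots of the drift are located by a sign-change scan on a uniform grid
    followed by bisection (Brent) to 1e-12, then classified by the sign of
    the curvature.  An empty list is a valid return: for |delta_omega| larger
    than the maximal restoring drift no stationary phase exists and the
    relative phase wraps (loss of entrainment).
    """
    f = lambda x: drift(x, params)
    # closed grid over [-pi, pi]; a root within float noise of the +/-pi seam
    # cannot be bracketed by sign change, so near-zero grid values are taken
    # as roots directly (tolerance scaled to the drift magnitude)
    xs = np.linspace(-np.pi, np.pi, grid_size + 1)
    fs = drift(xs, params)
    zero_tol = 1e-12 * (abs(params.delta_omega) + params.a + 2.0 * params.b)
    roots: list[float] = []

    def _push(r: float) -> None:
        # canonicalize to (-pi, pi]; -pi and pi are the same phase
        if r <= -np.pi + 1e-9:
            r += 2.0 * np.pi
        for existing in roots:
            if abs(existing - r) < 1e-8:
                return
        roots.append(r)

    for i in range(grid_size + 1):
        if abs(fs[i]) <= zero_tol:
            _push(float(xs[i]))
        elif i < grid_size and abs(fs[i + 1]) > zero_tol and fs[i] * fs[i + 1] < 0.0:
            _push(float(brentq(f, float(xs[i]), float(xs[i + 1]), xtol=1e-12)))

    roots.sort()
    out = []
    for r in roots:
        c = curvature(r, params)
        out.append(FixedPoint(phi_star=r, stable=bool(c > 0), curvature=float(c)))
    return out


def predicted_sd(params: HKBParams, Q: float, fp: FixedPoint) -> float:
    """Small-noise prediction of the stationary SD of phi around a stable well.

    Linearizing the gradient flow with additive white noise of intensity
    ``Q`` (rad^2/s) around a stable fixed point gives an Ornstein–Uhlenbeck
    process with stationary standard deviation

        sd = sqrt(Q / (2 * V''(phi_star)))

    Valid only while the excursions stay well inside the basin
    (sd much smaller than the basin width); used as a simulation oracle,
    not as an empirical claim about movement data.
    """
    if not fp.stable:
        raise ValueError("predicted_sd requires a stable fixed point")
    if not (Q > 0):
        raise ValueError("noise intensity Q must be positive")
    return math.sqrt(Q / (2.0 * fp.curvature))
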