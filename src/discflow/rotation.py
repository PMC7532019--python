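"""Rotation kinematics: spinner settings ↔ angular velocity, centrifugal
acceleration, relative centrifugal force (RCF) and effective gravity.

All kinematics are steady-state; spin-up/spin-down transients are out of
scope.  RCF = ω²r / g₀ with g₀ = 9.80665 m/s².  Cells on a horizontally
spinning disc additionally feel standard gravity perpendicular to the disc
plane, so the effective gravity magnitude is the vector sum
√(1 + RCF²) (in units of g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .units_geometry import G0

#: Rotor radius (m) of a benchtop cell-culture centrifuge, back-derived from
#: its stated rpm ↔ g pairs (1000 rpm ≈ 216 g, 1500 rpm ≈ 485 g).  A distinct
#: preset — never mixed with the disc geometry.
BENCHTOP_ROTOR_RADIUS = 0.1928


def rpm_to_omega(speed_rpm: float) -> float:
    """rpm → angular velocity in rad/s (ω = 2π·rpm/60)."""
    return 2.0 * math.pi * speed_rpm / 60.0


def omega_to_rpm(omega: float) -> float:
    return omega * 60.0 / (2.0 * math.pi)


@dataclass(frozen=True)
class SpinState:
    """A spinner setting: rotational speed (rpm) and optional duration (s)."""

    speed_rpm: float
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.speed_rpm < 0:
            raise ValueError("rotational speed must be >= 0 rpm")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration must be > 0 s when given")

    @property
    def omega(self) -> float:
        """Angular velocity ω in rad/s."""
        return rpm_to_omega(self.speed_rpm)


def centrifugal_acceleration(state: SpinState, radius: float) -> float:
    """Centripetal acceleration ω²r (m/s²) at ``radius`` (m) from the axis."""
    if radius < 0:
        raise ValueError("radius must be >= 0 m")
    return state.omega**2 * radius


def rcf(state: SpinState, radius: float) -> float:
    """Relative centrifugal force ω²r/g₀ (dimensionless, units of g)."""
    return centrifugal_acceleration(state, radius) / G0


def effective_gravity(rcf_inplane: float) -> float:
    """Magnitude of the total acceleration sensed by cells, in g.

    The in-plane centrifugal acceleration and the out-of-plane standard
    gravity add vectorially: √(1 + RCF²).  Always ≥ 1 g; → 1 g at rest.
    """
    if rcf_inplane < 0:
        raise ValueError("RCF must be >= 0")
    return math.hypot(1.0, rcf_inplane)


def speed_for_rcf(target_rcf: float, radius: float) -> float:
    """Rotational speed (rpm) producing ``target_rcf`` (g) at ``radius`` (m).

    Exact inverse of :func:`rcf`; raises for a positive target at zero radius
    (no speed can generate centrifugal force on the axis).
    """
    if target_rcf < 0:
        raise ValueError("target RCF must be >= 0")
    if target_rcf == 0:
        return 0.0
    if radius <= 0:
        raise ValueError("unreachable target: positive RCF requires radius > 0")
    omega = math.sqrt(target_rcf * G0 / radius)
    return omega_to_rpm(omega)


def format_rcf(value_g: float) -> str:
    """Format an RCF the way the platform reports them: two significant
    figures below 10 g, one decimal in [10, 1000) g, integer above."""
    if value_g < 10.0:
        return f"{value_g:.2g} g"
    if value_g < 1000.0:
        return f"{value_g:.1f} g"
    return f"{value_g:.0f} g"
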