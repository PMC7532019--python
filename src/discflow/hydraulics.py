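"""Pressure and flow laws of the centrifugally perfused disc.

Three pressures act on the media channel:

* centrifugal: Δp_c = ½ ρ ω² (r₂² − r₁²), generated along the rotating liquid
  column between inner radius r₁ and outer radius r₂;
* hydrostatic: Δp_h = ρ g₀ H, from the out-of-plane fluid level H above the
  inlet (constant while spinning: the inlet compartment stays full to the
  brim, the effluent is pushed past the outlet port);
* capillary burst: p_v = −4σ cos(θ_max)/d, the maximum pressure a meniscus
  pinned in a circular port of diameter d can sustain before bursting.

The resulting flow through the shallow rectangular media channel (height h,
width w, h ≪ w, length L) is Hagen–Poiseuille with the first-order aspect
ratio correction:

    Q = h³ w Δp / (12 η L) · (1 − 0.630 h/w)

Entrance effects, bubble dynamics and channel compliance are neglected; the
dead-end tissue-chamber branch carries no net flow and is not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .rotation import SpinState
from .units_geometry import (
    G0,
    DiscGeometry,
    Finding,
    FluidProperties,
    validate_geometry,
)


class InvalidGeometryError(ValueError):
    """Raised when a flow computation is attempted on an invalid geometry."""

    def __init__(self, findings: list[Finding]):
        self.findings = findings
        super().__init__(
            "invalid geometry: " + "; ".join(f.message for f in findings)
        )


def centrifugal_pressure(
    fluid: FluidProperties, state: SpinState, r1: float, r2: float
) -> float:
    """Centrifugal pressure difference ½ρω²(r₂²−r₁²) in Pa.

    Zero at rest and for a zero-extent column; grows with ω².
    """
    if r1 < 0:
        raise ValueError("r1 must be >= 0 m")
    if r2 < r1:
        raise ValueError(f"r2 ({r2} m) must be >= r1 ({r1} m)")
    return 0.5 * fluid.density * state.omega**2 * (r2**2 - r1**2)


def hydrostatic_pressure(fluid: FluidProperties, head: float) -> float:
    """Hydrostatic pressure ρ·g₀·head in Pa; linear in the head height (m)."""
    if head < 0:
        raise ValueError("head height must be >= 0 m")
    return fluid.density * G0 * head


def burst_pressure(
    fluid: FluidProperties, port_diameter: float, theta_max_deg: float = 180.0
) -> float:
    """Maximum burst pressure of a meniscus pinned in a circular port, Pa.

    p_v = −4σ cos(θ_max)/d.  θ_max is the largest contact angle the liquid
    can build before spreading into the diverging section: 180° is the most
    conservative assumption (p_v = 4σ/d), 90° gives zero holding pressure.
    """
    if port_diameter <= 0:
        raise ValueError("port diameter must be > 0 m")
    if not (0.0 <= theta_max_deg <= 180.0):
        raise ValueError("theta_max must be in [0, 180] degrees")
    theta = math.radians(theta_max_deg)
    return -4.0 * fluid.surface_tension * math.cos(theta) / port_diameter


def channel_conductance(geom: DiscGeometry, fluid: FluidProperties) -> float:
    """Hydraulic conductance Q/Δp of the media channel, m³/(s·Pa).

    Inverse of the rectangular-channel resistance 12ηL / [h³w(1 − 0.630 h/w)].
    Raises :class:`InvalidGeometryError` on any error-level geometry finding.
    """
    errors = [f for f in validate_geometry(geom) if f.level == "error"]
    if errors:
        raise InvalidGeometryError(errors)
    h, w, length = geom.channel_height, geom.channel_width, geom.channel_length
    return h**3 * w * (1.0 - 0.630 * h / w) / (12.0 * fluid.viscosity * length)


def channel_flow(geom: DiscGeometry, fluid: FluidProperties, dp: float) -> float:
    """Volumetric flow (m³/s) through the media channel under ``dp`` (Pa).

    Linear in dp; a negative dp yields a reversed (negative) flow.
    """
    return channel_conductance(geom, fluid) * dp


@dataclass(frozen=True)
class PressureBudget:
    """All pressures at one spin state.  The driving pressure is the plain sum
    of the centrifugal and hydrostatic terms; capillary pinning is applied
    only by the perfusion model, not here."""

    dp_centrifugal: float
    dp_hydrostatic: float
    p_burst: float

    @property
    def dp_total_driving(self) -> float:
        return self.dp_centrifugal + self.dp_hydrostatic


def pressure_budget(
    geom: DiscGeometry,
    fluid: FluidProperties,
    state: SpinState,
    theta_max_deg: float = 180.0,
) -> PressureBudget:
    """Evaluate all three pressures for one geometry/fluid/spin state."""
    return PressureBudget(
        dp_centrifugal=centrifugal_pressure(fluid, state, geom.r_inner, geom.r_outer),
        dp_hydrostatic=hydrostatic_pressure(fluid, geom.head_height),
        p_burst=burst_pressure(fluid, geom.port_diameter, theta_max_deg),
    )
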