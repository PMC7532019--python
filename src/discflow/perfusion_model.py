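"""Candidate flow-vs-speed models for centrifugal perfusion.

Four variants are compared against flow measurements:

``hydrostatic_only``
    Q = C·Δp_h — constant in ω (C is the channel conductance).
``centrifugal_only``
    Q = C·Δp_c(ω) = B ω².
``combined``
    Q = B ω² + C·Δp_h.
``combined_pinned``
    The piecewise capillary-pinning model: the outlet port acts as a burst
    valve holding a permanent backpressure p_v, so

        Q(ω) = 0                 for ω < ω₀
        Q(ω) = B (ω² − ω₀²)      for ω ≥ ω₀

    with the burst speed ω₀² = (p_v − Δp_h) / (½ρ(r₂²−r₁²)) and the flow
    coefficient B = C · ½ρ(r₂²−r₁²).  The model is continuous at ω₀ (both
    branches give 0) and the hydrostatic drive is accounted for inside ω₀.

Pinning is modelled as a *permanent* constant backpressure at all ω ≥ ω₀ —
the effluent is pushed past the port, so no liquid accumulates above it to
quench the meniscus.  A one-shot valve (no backpressure after the first
burst) is deliberately not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .hydraulics import channel_conductance, channel_flow, hydrostatic_pressure
from .rotation import SpinState, omega_to_rpm, rpm_to_omega
from .units_geometry import DiscGeometry, FluidProperties

VARIANTS = ("hydrostatic_only", "centrifugal_only", "combined", "combined_pinned")


@dataclass(frozen=True)
class FlowModelSpec:
    """One flow-vs-speed model: variant plus its parameters.

    ``B`` is the flow coefficient in m³/s per (rad/s)²; ``omega0`` the burst
    threshold in rad/s (meaningful only for ``combined_pinned``).  ``B`` may
    be None for geometry-driven variants, in which case it is derived from
    the geometry/fluid handed to :func:`predict_flow`.
    """

    variant: str
    B: float | None = None
    omega0: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if self.B is not None and not (self.B > 0):
            raise ValueError("flow coefficient B must be > 0")
        if self.omega0 < 0:
            raise ValueError("omega0 must be >= 0 rad/s")

    @property
    def omega0_rpm(self) -> float:
        return omega_to_rpm(self.omega0)


def B_from_geometry(geom: DiscGeometry, fluid: FluidProperties) -> float:
    """Flow coefficient B = C · ½ρ(r₂²−r₁²), m³/s per (rad/s)².

    Depends only on channel dimensions and material properties; with the
    default geometry it inherits the ``assumed`` provenance of r₁, r₂ and L.
    """
    half_col = 0.5 * fluid.density * (geom.r_outer**2 - geom.r_inner**2)
    return channel_conductance(geom, fluid) * half_col


def omega0_from_burst(
    p_v: float,
    p_h: float,
    fluid: FluidProperties,
    r1: float,
    r2: float,
) -> float:
    """Burst angular velocity ω₀ = √((p_v − p_h)/(½ρ(r₂²−r₁²))), rad/s.

    If the burst pressure does not exceed the hydrostatic drive the valve
    bursts at rest and ω₀ = 0.
    """
    if r2 <= r1:
        raise ValueError("r2 must be > r1")
    half_col = 0.5 * fluid.density * (r2**2 - r1**2)
    return float(np.sqrt(max(0.0, p_v - p_h) / half_col))


def burst_from_omega0(
    omega0: float,
    p_h: float,
    fluid: FluidProperties,
    r1: float,
    r2: float,
) -> float:
    """Inverse of :func:`omega0_from_burst`: p_v = p_h + ω₀²·½ρ(r₂²−r₁²), Pa."""
    if r2 <= r1:
        raise ValueError("r2 must be > r1")
    return p_h + omega0**2 * 0.5 * fluid.density * (r2**2 - r1**2)


def _resolve_B(
    spec: FlowModelSpec, geom: DiscGeometry | None, fluid: FluidProperties | None
) -> float:
    if spec.B is not None:
        return spec.B
    if geom is None or fluid is None:
        raise ValueError(
            f"variant {spec.variant!r} without an explicit B requires geometry "
            "and fluid to derive the flow coefficient"
        )
    return B_from_geometry(geom, fluid)


def predict_flow(
    spec: FlowModelSpec,
    state: SpinState | float | np.ndarray,
    geom: DiscGeometry | None = None,
    fluid: FluidProperties | None = None,
):
    """Predicted volumetric flow (m³/s) at a spin state.

    ``state`` may be a :class:`SpinState`, an angular velocity in rad/s, or
    an array of angular velocities (vectorized).  Geometry and fluid are
    needed whenever the variant has a hydrostatic term or ``spec.B`` is None.
    Monotone nondecreasing in ω for every variant.
    """
    omega = state.omega if isinstance(state, SpinState) else np.asarray(state, float)
    scalar = np.ndim(omega) == 0

    if spec.variant == "combined_pinned":
        if spec.B is None:
            raise ValueError("combined_pinned requires an explicit B")
        q = spec.B * np.maximum(0.0, np.square(omega) - spec.omega0**2)
        return float(q) if scalar else q

    if spec.variant == "hydrostatic_only":
        if geom is None or fluid is None:
            raise ValueError("hydrostatic_only requires geometry and fluid")
        q_h = channel_flow(geom, fluid, hydrostatic_pressure(fluid, geom.head_height))
        return q_h if scalar else np.full(np.shape(omega), q_h)

    b = _resolve_B(spec, geom, fluid)
    q = b * np.square(omega)
    if spec.variant == "combined":
        if geom is None or fluid is None:
            raise ValueError("combined requires geometry and fluid")
        q = q + channel_flow(geom, fluid, hydrostatic_pressure(fluid, geom.head_height))
    return float(q) if scalar else q


def speed_for_flow(
    spec: FlowModelSpec,
    target_q: float,
    geom: DiscGeometry | None = None,
    fluid: FluidProperties | None = None,
) -> float:
    """Rotational speed (rpm) at which the model delivers ``target_q`` (m³/s).

    Solved in closed form (ω = √(target/B + ω₀²) for the pinned model).  A
    flow target the variant cannot reach by adjusting speed raises a
    ValueError naming the obstruction.
    """
    if target_q < 0:
        raise ValueError("target flow must be >= 0")

    if spec.variant == "hydrostatic_only":
        raise ValueError(
            "target unreachable by speed: hydrostatic-only flow is independent "
            "of rotation"
        )

    if spec.variant == "combined_pinned":
        if spec.B is None:
            raise ValueError("combined_pinned requires an explicit B")
        if target_q == 0.0:
            return 0.0  # canonical representative of every speed <= omega0
        return omega_to_rpm(float(np.sqrt(target_q / spec.B + spec.omega0**2)))

    b = _resolve_B(spec, geom, fluid)
    offset = 0.0
    if spec.variant == "combined":
        if geom is None or fluid is None:
            raise ValueError("combined requires geometry and fluid")
        offset = channel_flow(
            geom, fluid, hydrostatic_pressure(fluid, geom.head_height)
        )
        if target_q < offset:
            raise ValueError(
                f"target unreachable by speed: the hydrostatic floor is "
                f"{offset:.3g} m^3/s, above the requested {target_q:.3g} m^3/s"
            )
    return omega_to_rpm(float(np.sqrt((target_q - offset) / b)))


def spec_with_burst_pressure(
    spec: FlowModelSpec,
    p_v: float,
    geom: DiscGeometry,
    fluid: FluidProperties,
) -> FlowModelSpec:
    """Re-parameterize a pinned spec by burst pressure instead of ω₀."""
    p_h = hydrostatic_pressure(fluid, geom.head_height)
    omega0 = omega0_from_burst(p_v, p_h, fluid, geom.r_inner, geom.r_outer)
    return replace(spec, omega0=omega0)


# --- serialization ---------------------------------------------------------

def spec_to_dict(spec: FlowModelSpec) -> dict:
    return {
        "flow_model": {
            "variant": spec.variant,
            "B_m3_s_per_rad2_s2": spec.B,
            "omega0_rad_s": spec.omega0,
        }
    }


def spec_from_dict(doc: dict) -> FlowModelSpec:
    node = doc["flow_model"] if "flow_model" in doc else doc
    return FlowModelSpec(
        variant=node["variant"],
        B=node.get("B_m3_s_per_rad2_s2"),
        omega0=float(node.get("omega0_rad_s", 0.0)),
    )


def two_point_spec(
    point1: tuple[float, float],
    point2: tuple[float, float],
) -> FlowModelSpec:
    """Pinned-model spec passing exactly through two (rpm, μl/h) points.

    Convenience wrapper around the closed-form two-point solution; see
    :func:`discflow.burst_fit.two_point_solve` for the algebra.
    """
    from .burst_fit import two_point_solve

    sol = two_point_solve(point1, point2)
    return FlowModelSpec("combined_pinned", B=sol.B, omega0=sol.omega0)


__all__ = [
    "VARIANTS",
    "FlowModelSpec",
    "B_from_geometry",
    "omega0_from_burst",
    "burst_from_omega0",
    "predict_flow",
    "speed_for_flow",
    "spec_with_burst_pressure",
    "spec_to_dict",
    "spec_from_dict",
    "two_point_spec",
    "rpm_to_omega",
]
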