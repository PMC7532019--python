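"""Synthetic flow-measurement campaigns with the statistical structure of the
real experiment: effluent collected and weighed after 1 h of rotation at each
speed from 0 to 200 rpm, at least eight replicates per speed, scatter
summarized by the per-speed standard deviation.

The noise model is Gaussian on the flow with a relative component and an
absolute floor, sd = max(relative_sd·Q_true, floor_sd), truncated at zero by
resampling (clipping would put a point mass at exactly zero and distort the
sd).  The floor term gives the 0-rpm point its nonzero scatter — a few μl/h
of apparent flow is measured even at rest.  Effluent mass is derived from
the noisy flow exactly (mass = flow · duration · density), so mass
bookkeeping is conserved by construction.

What this generator does NOT emulate: evaporation losses, spin-down
transient volume, speed-controller error — the real campaign's unmodelled
systematics.  Recovery results on synthetic campaigns therefore show the
statistical identifiability of the model, not instrument accuracy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .burst_fit import FlowMeasurementSet, two_point_solve
from .perfusion_model import FlowModelSpec, predict_flow
from .rotation import rpm_to_omega
from .units_geometry import (
    M3_PER_S_TO_UL_PER_H,
    DiscGeometry,
    FluidProperties,
    water_properties,
)

#: Speeds of the reference campaign (rpm): rest to the highest tested speed.
DEFAULT_SPEEDS = (0.0, 50.0, 100.0, 150.0, 200.0)

#: The two reference measurements used to calibrate the default truth model.
CALIBRATION_POINTS = ((100.0, 97.0), (200.0, 445.0))


@dataclass(frozen=True)
class CampaignDesign:
    """Design of one synthetic measurement campaign.

    Defaults mirror the reference experiment: five speeds from 0 to 200 rpm,
    eight replicates per speed, 1 h collections.  ``relative_sd`` (12%) is a
    generator choice — replicate-level scatter was never published — and
    ``floor_sd`` (3 μl/h) matches the apparent flow observed at rest.
    """

    speeds_rpm: tuple[float, ...] = DEFAULT_SPEEDS
    n_replicates: int = 8
    duration_s: float = 3600.0
    relative_sd: float = 0.12
    floor_sd_ul_per_h: float = 3.0
    truth: FlowModelSpec = field(default_factory=lambda: calibrated_truth())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need n >= 1 replicates per speed")
        if self.duration_s <= 0:
            raise ValueError("collection duration must be > 0 s")
        if self.relative_sd < 0 or self.floor_sd_ul_per_h < 0:
            raise ValueError("noise magnitudes must be >= 0")


def calibrated_truth() -> FlowModelSpec:
    """Pinned-model truth calibrated exactly through the two reference
    measurements (100 rpm, 97 μl/h) and (200 rpm, 445 μl/h)."""
    sol = two_point_solve(*CALIBRATION_POINTS)
    return FlowModelSpec("combined_pinned", B=sol.B, omega0=sol.omega0)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) conditioned on >= 0, by resampling."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def simulate_campaign(
    design: CampaignDesign,
    geom: DiscGeometry | None = None,
    fluid: FluidProperties | None = None,
) -> FlowMeasurementSet:
    """Draw one campaign: replicate flows per speed plus effluent masses.

    True flows come from ``design.truth``; replicates are truncated-Gaussian
    around them; the effluent mass of each replicate is flow × duration ×
    density (grams), computed from the noisy flow so the mass column and the
    flow column are exactly consistent.  Deterministic per seed.
    """
    if fluid is None:
        fluid = water_properties(37.0)
    rng = np.random.default_rng(design.seed)
    rows = []
    for speed in design.speeds_rpm:
        q_true_si = predict_flow(design.truth, rpm_to_omega(speed), geom, fluid)
        q_true = q_true_si * M3_PER_S_TO_UL_PER_H
        sd = max(design.relative_sd * q_true, design.floor_sd_ul_per_h)
        flows = _truncated_normal(rng, q_true, sd, design.n_replicates)
        for f in flows:
            vol_ul = f * design.duration_s / 3600.0
            mass_g = vol_ul * 1e-9 * fluid.density * 1e3  # μl → m³ → kg → g
            rows.append(
                {
                    "speed_rpm": speed,
                    "flow_ul_per_h": f,
                    "effluent_mass_g": mass_g,
                }
            )
    replicates = pd.DataFrame(rows)
    return FlowMeasurementSet.from_replicates(
        replicates,
        duration_s=design.duration_s,
        metadata={
            "generator": "discflow.synthetic_data.simulate_campaign",
            "seed": design.seed,
            "truth_B_m3_s_per_rad2_s2": design.truth.B,
            "truth_omega0_rad_s": design.truth.omega0,
            "fluid_density_kg_m3": fluid.density,
        },
    )


#: Geometry fields eligible for perturbation (lengths only).
_PERTURBABLE = ("chamber_radius", "r_inner", "r_outer", "channel_length")


def perturb_geometry(
    geom: DiscGeometry, relative_sd: float, seed: int = 0
) -> DiscGeometry:
    """Jitter every *assumed* length by an independent lognormal factor.

    Sensitivity-study helper: fields with printed or derived provenance are
    left bit-identical; each assumed length is multiplied by
    exp(N(0, relative_sd)).  ``relative_sd`` must be in [0, 0.5].
    """
    if not (0.0 <= relative_sd <= 0.5):
        raise ValueError("relative_sd must be in [0, 0.5]")
    if relative_sd == 0.0:
        return geom
    rng = np.random.default_rng(seed)
    changes = {}
    for name in _PERTURBABLE:
        if geom.provenance_of(name) == "assumed":
            changes[name] = getattr(geom, name) * float(
                rng.lognormal(0.0, relative_sd)
            )
    return dataclasses.replace(geom, **changes)
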