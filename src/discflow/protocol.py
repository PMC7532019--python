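"""Spin-protocol planning: centrifugal cell loading, layered multi-cell-type
loading, and perfusion set-points, with cell-budget arithmetic.

Loading: a cell suspension pipetted into the tissue-channel inlets is spun
into the peripheral tissue chambers, where the cells sediment into a dense
pellet.  Loading accelerations stay below ~100 g (a routine cell-culture
acceleration); a flag is raised above that.  Perfusion: the disc rotates
slowly so that the in-plane RCF at the chambers stays below 1 g — any more
and the culture runs under hypergravity, which the platform is explicitly
designed to avoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .perfusion_model import FlowModelSpec, predict_flow, speed_for_flow
from .rotation import SpinState, effective_gravity, rcf, speed_for_rcf
from .units_geometry import (
    M3_PER_S_TO_UL_PER_H,
    DiscGeometry,
    FluidProperties,
    weakest_provenance,
)

#: Loading accelerations above this are flagged (still allowed up to 1000 g).
LOADING_RCF_FLAG_G = 100.0


@dataclass(frozen=True)
class Suspension:
    """A cell suspension: concentration (cells/μl) and volume per channel (μl)."""

    concentration_per_ul: float
    volume_ul: float

    def __post_init__(self) -> None:
        if self.concentration_per_ul < 0 or self.volume_ul < 0:
            raise ValueError("concentration and volume must be >= 0")

    @property
    def cells(self) -> int:
        """Cells delivered per chamber per loading step (exact product)."""
        return round(self.concentration_per_ul * self.volume_ul)


@dataclass(frozen=True)
class ProtocolStep:
    speed_rpm: float
    duration_s: float
    purpose: str
    rcf_at_chamber: float
    incubation_gap_min: float | None = None  # rest before the next step


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a stratified construct."""

    label: str
    concentration_per_ul: float
    volume_ul: float
    speed_rpm: float = 1500.0
    duration_s: float = 300.0
    incubation_gap_min: float = 120.0


@dataclass(frozen=True)
class LoadingProtocol:
    steps: tuple[ProtocolStep, ...]
    suspension: Suspension | None
    cells_per_chamber_per_step: int
    total_cells_per_chamber: int
    layers: tuple[LayerSpec, ...] | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PerfusionProtocol:
    speed_rpm: float
    rcf_at_chamber: float
    effective_gravity_g: float
    predicted_flow_ul_per_h: float
    flow_provenance: str
    hypergravity: bool
    service_interval_h: float = 24.0
    flags: tuple[str, ...] = ()


def plan_loading(
    target_rcf: float,
    duration_s: float,
    suspension: Suspension,
    geom: DiscGeometry,
) -> LoadingProtocol:
    """Plan a single-cell-type loading spin reaching ``target_rcf`` (g) at the
    chamber radius.  Zero suspension volume is a valid wetting-only run."""
    if not (0.0 < target_rcf <= 1000.0):
        raise ValueError("target RCF must be in (0, 1000] g")
    speed = speed_for_rcf(target_rcf, geom.chamber_radius)
    flags = []
    if target_rcf > LOADING_RCF_FLAG_G:
        flags.append(
            f"loading acceleration {target_rcf:g} g exceeds the routine "
            f"{LOADING_RCF_FLAG_G:g} g cell-culture range"
        )
    step = ProtocolStep(speed, duration_s, "centrifugal cell loading", target_rcf)
    cells = suspension.cells
    return LoadingProtocol(
        steps=(step,),
        suspension=suspension,
        cells_per_chamber_per_step=cells,
        total_cells_per_chamber=cells,
        flags=tuple(flags),
    )


def repeat_loading(protocol: LoadingProtocol, times: int = 2) -> LoadingProtocol:
    """Repeat a single-suspension loading step (doubling etc. the pellet)."""
    if times < 1:
        raise ValueError("times must be >= 1")
    import dataclasses

    return dataclasses.replace(
        protocol,
        steps=protocol.steps * times,
        total_cells_per_chamber=protocol.cells_per_chamber_per_step * times,
    )


def plan_layers(layers: list[LayerSpec], geom: DiscGeometry) -> LoadingProtocol:
    """Plan a stratified loading: one spin per layer, incubation gaps between.

    Needs at least two layers (use :func:`plan_loading` for a single one).
    Layer order is preserved; per-layer cell counts and the total per chamber
    are exact products.
    """
    if len(layers) < 2:
        raise ValueError("plan_layers needs >= 2 layers; use plan_loading")
    steps = []
    total = 0
    flags: list[str] = []
    for i, layer in enumerate(layers):
        state = SpinState(layer.speed_rpm)
        g = rcf(state, geom.chamber_radius)
        if g > LOADING_RCF_FLAG_G:
            flags.append(
                f"layer {layer.label!r}: {g:.1f} g exceeds the routine "
                f"{LOADING_RCF_FLAG_G:g} g range"
            )
        gap = layer.incubation_gap_min if i < len(layers) - 1 else None
        steps.append(
            ProtocolStep(
                layer.speed_rpm,
                layer.duration_s,
                f"load layer {i + 1}: {layer.label}",
                g,
                incubation_gap_min=gap,
            )
        )
        total += round(layer.concentration_per_ul * layer.volume_ul)
    per_step = round(layers[0].concentration_per_ul * layers[0].volume_ul)
    return LoadingProtocol(
        steps=tuple(steps),
        suspension=None,
        cells_per_chamber_per_step=per_step,
        total_cells_per_chamber=total,
        layers=tuple(layers),
        flags=tuple(flags),
    )


def plan_perfusion(
    spec: FlowModelSpec,
    geom: DiscGeometry,
    fluid: FluidProperties,
    speed_rpm: float | None = None,
    flow_ul_per_h: float | None = None,
) -> PerfusionProtocol:
    """Resolve a perfusion set-point from either a speed or a flow target.

    Exactly one of ``speed_rpm`` / ``flow_ul_per_h`` must be given.  The
    protocol reports the chamber RCF, the effective gravity √(1 + RCF²) and
    the predicted flow with the provenance of its weakest geometric input; a
    hypergravity flag is set whenever the chamber RCF exceeds 1 g.
    """
    if (speed_rpm is None) == (flow_ul_per_h is None):
        raise ValueError("give exactly one of speed_rpm or flow_ul_per_h")
    if speed_rpm is None:
        speed_rpm = speed_for_flow(
            spec, flow_ul_per_h / M3_PER_S_TO_UL_PER_H, geom, fluid
        )
    state = SpinState(speed_rpm)
    g = rcf(state, geom.chamber_radius)
    flow = predict_flow(spec, state, geom, fluid) * M3_PER_S_TO_UL_PER_H
    provenance_fields = ["chamber_radius"]
    if spec.variant != "combined_pinned" or spec.B is None:
        provenance_fields += ["r_inner", "r_outer", "channel_length"]
    flow_prov = (
        "derived"  # calibrated model: parameters come from measurements
        if spec.variant == "combined_pinned" and spec.B is not None
        else weakest_provenance(geom.provenance_of(f) for f in provenance_fields)
    )
    hyper = g > 1.0
    flags = ()
    if hyper:
        flags = (
            f"chamber RCF {g:.2g} g exceeds 1 g: culture would run under "
            "hypergravity",
        )
    return PerfusionProtocol(
        speed_rpm=speed_rpm,
        rcf_at_chamber=g,
        effective_gravity_g=effective_gravity(g),
        predicted_flow_ul_per_h=float(flow),
        flow_provenance=flow_prov,
        hypergravity=hyper,
        flags=flags,
    )


def disc_cell_budget(geom: DiscGeometry, cells_per_chamber: int) -> int:
    """Total cells needed to load every chamber of the disc."""
    if cells_per_chamber < 0:
        raise ValueError("cells_per_chamber must be >= 0")
    return cells_per_chamber * geom.total_chambers


# --- YAML round-trip -------------------------------------------------------

def loading_to_dict(p: LoadingProtocol) -> dict:
    return {
        "loading_protocol": {
            "steps": [
                {
                    "speed_rpm": s.speed_rpm,
                    "duration_s": s.duration_s,
                    "purpose": s.purpose,
                    "rcf_at_chamber_g": s.rcf_at_chamber,
                    "incubation_gap_min": s.incubation_gap_min,
                }
                for s in p.steps
            ],
            "suspension": None
            if p.suspension is None
            else {
                "concentration_per_ul": p.suspension.concentration_per_ul,
                "volume_ul": p.suspension.volume_ul,
            },
            "cells_per_chamber_per_step": p.cells_per_chamber_per_step,
            "total_cells_per_chamber": p.total_cells_per_chamber,
            "layers": None
            if p.layers is None
            else [
                {
                    "label": l.label,
                    "concentration_per_ul": l.concentration_per_ul,
                    "volume_ul": l.volume_ul,
                    "speed_rpm": l.speed_rpm,
                    "duration_s": l.duration_s,
                    "incubation_gap_min": l.incubation_gap_min,
                }
                for l in p.layers
            ],
            "flags": list(p.flags),
        }
    }


def loading_from_dict(doc: dict) -> LoadingProtocol:
    node = doc["loading_protocol"]
    susp = node["suspension"]
    layers = node["layers"]
    return LoadingProtocol(
        steps=tuple(
            ProtocolStep(
                s["speed_rpm"],
                s["duration_s"],
                s["purpose"],
                s["rcf_at_chamber_g"],
                s["incubation_gap_min"],
            )
            for s in node["steps"]
        ),
        suspension=None if susp is None else Suspension(**susp),
        cells_per_chamber_per_step=node["cells_per_chamber_per_step"],
        total_cells_per_chamber=node["total_cells_per_chamber"],
        layers=None if layers is None else tuple(LayerSpec(**l) for l in layers),
        flags=tuple(node["flags"]),
    )


def perfusion_to_dict(p: PerfusionProtocol) -> dict:
    return {
        "perfusion_protocol": {
            "speed_rpm": p.speed_rpm,
            "rcf_at_chamber_g": p.rcf_at_chamber,
            "effective_gravity_g": p.effective_gravity_g,
            "predicted_flow_ul_per_h": p.predicted_flow_ul_per_h,
            "flow_provenance": p.flow_provenance,
            "hypergravity": p.hypergravity,
            "service_interval_h": p.service_interval_h,
            "flags": list(p.flags),
        }
    }


def perfusion_from_dict(doc: dict) -> PerfusionProtocol:
    node = doc["perfusion_protocol"]
    return PerfusionProtocol(
        speed_rpm=node["speed_rpm"],
        rcf_at_chamber=node["rcf_at_chamber_g"],
        effective_gravity_g=node["effective_gravity_g"],
        predicted_flow_ul_per_h=node["predicted_flow_ul_per_h"],
        flow_provenance=node["flow_provenance"],
        hypergravity=node["hypergravity"],
        service_interval_h=node["service_interval_h"],
        flags=tuple(node["flags"]),
    )


def dump_yaml(doc: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
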