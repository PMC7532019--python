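"""Physical data model shared by the whole package: disc geometry, working-fluid
properties and unit conventions.

All computation inside the package is done in SI base units (m, kg, s, Pa,
rad/s).  Rotational speed in rpm, flow in μl/h, pressure in Pa and
acceleration in multiples of standard gravity appear only at interfaces and
in display helpers.  Every geometry value carries a provenance tag:

``printed``
    taken directly from the device description,
``derived``
    back-computed from a printed quantity (e.g. the chamber radius from a
    printed rpm ↔ RCF pair),
``assumed``
    a free placeholder needed to close the model (radii of the pumping liquid
    column, channel length); any result depending on one of these is flagged.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Mapping

import yaml

#: Standard gravity, m/s^2.  Fixed per run; all RCF values are relative to it.
G0 = 9.80665

#: Conversion from m^3/s to μl/h (1 m^3 = 1e9 μl, 1 h = 3600 s).
M3_PER_S_TO_UL_PER_H = 1e9 * 3600.0

#: Provenance ordering, weakest last.  Derived quantities inherit the weakest
#: provenance among their inputs.
PROVENANCE_ORDER = ("printed", "derived", "assumed")

_LENGTH_UNITS = {"m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "μm": 1e-6}


class UnsupportedTemperatureError(ValueError):
    """Raised when fluid properties are requested outside the built-in table."""


def weakest_provenance(tags: Iterable[str]) -> str:
    """Return the weakest tag in ``tags`` (printed < derived < assumed)."""
    worst = "printed"
    for tag in tags:
        if tag not in PROVENANCE_ORDER:
            raise ValueError(f"unknown provenance tag {tag!r}")
        if PROVENANCE_ORDER.index(tag) > PROVENANCE_ORDER.index(worst):
            worst = tag
    return worst


@dataclass(frozen=True)
class FluidProperties:
    """Bulk properties of the working liquid.

    Parameters
    ----------
    density:
        ρ in kg/m³.  A sanity band of (500, 2000) kg/m³ is enforced — wide
        enough for any aqueous medium, tight enough to catch unit mistakes.
    viscosity:
        Dynamic viscosity η in Pa·s.
    surface_tension:
        σ in N/m.
    temperature:
        Annotation only (°C); never used in computation.
    """

    density: float
    viscosity: float
    surface_tension: float
    temperature: float | None = None

    def __post_init__(self) -> None:
        if not (500.0 < self.density < 2000.0):
            raise ValueError(
                f"density {self.density} kg/m^3 outside the (500, 2000) sanity band"
            )
        if self.viscosity <= 0:
            raise ValueError("viscosity must be strictly positive")
        if self.surface_tension <= 0:
            raise ValueError("surface tension must be strictly positive")


# Handbook values for pure water at the tabulated temperatures.  Held fixed
# (no interpolation) so that every pressure printed by the package is exactly
# reproducible.  density kg/m^3, viscosity Pa s, surface tension N/m.
_WATER_TABLE: dict[float, tuple[float, float, float]] = {
    4.0: (999.97, 1.567e-3, 0.0750),
    20.0: (998.2, 1.002e-3, 0.0728),
    25.0: (997.0, 8.90e-4, 0.0720),
    37.0: (993.3, 6.92e-4, 0.0700),
}


def water_properties(temperature: float) -> FluidProperties:
    """Water properties at a tabulated temperature (4, 20, 25 or 37 °C).

    Untabulated temperatures raise :class:`UnsupportedTemperatureError` rather
    than silently interpolating: the table anchors reproducible pressure
    numbers and must not drift.
    """
    for t, (rho, eta, sigma) in _WATER_TABLE.items():
        if math.isclose(temperature, t, abs_tol=1e-9):
            return FluidProperties(rho, eta, sigma, temperature=t)
    supported = ", ".join(f"{t:g} °C" for t in sorted(_WATER_TABLE))
    raise UnsupportedTemperatureError(
        f"unsupported temperature {temperature} °C; tabulated values: {supported}"
    )


_GEOMETRY_LENGTH_FIELDS = (
    "chamber_radius",
    "r_inner",
    "r_outer",
    "channel_height",
    "channel_width",
    "channel_length",
    "port_diameter",
    "head_height",
)


@dataclass(frozen=True)
class DiscGeometry:
    """Radial positions and channel/port dimensions of a perfusion disc.

    All lengths in metres.

    Attributes
    ----------
    chamber_radius:
        Radial position of the tissue-chamber centroid; the radius at which
        RCF acting on the cells is reported.
    r_inner, r_outer:
        Effective inner radius of the pumping liquid column (middle of the
        inner reservoir compartment) and the media-channel outlet radius.
        These bound the centrifugally pumped column.
    channel_height, channel_width, channel_length:
        Rectangular media-channel cross-section (h ≤ w required; the shallow
        channel correction degrades for h/w > 0.5) and its length.
    port_diameter:
        Diameter of the circular reservoir exit port that acts as the
        capillary burst valve.
    head_height:
        Fluid level above the inlet, perpendicular to the disc plane; the
        hydrostatic head H.
    n_systems, chambers_per_system:
        Layout counts; total chambers = n_systems × chambers_per_system.
    disc_radius:
        Outer radius of the disc itself; r_outer must fit inside it.
    provenance:
        Map field name → printed | derived | assumed.
    """

    chamber_radius: float
    r_inner: float
    r_outer: float
    channel_height: float
    channel_width: float
    channel_length: float
    port_diameter: float
    head_height: float
    n_systems: int = 4
    chambers_per_system: int = 5
    disc_radius: float = 0.05
    provenance: Mapping[str, str] = field(default_factory=dict)

    @property
    def total_chambers(self) -> int:
        return self.n_systems * self.chambers_per_system

    @property
    def aspect_ratio(self) -> float:
        """h/w of the media channel."""
        return self.channel_height / self.channel_width

    def provenance_of(self, field_name: str) -> str:
        """Provenance tag of one field (defaults to ``assumed`` if untagged)."""
        return self.provenance.get(field_name, "assumed")


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``level`` is ``"error"`` or ``"warning"``."""

    level: str
    field: str
    message: str


def validate_geometry(geom: DiscGeometry) -> list[Finding]:
    """Check every geometry invariant; return one finding per violation.

    An empty list means the geometry is valid.  An aspect ratio h/w above 0.5
    yields a *warning* (the 0.630 shallow-channel correction loses accuracy
    there) while h > w is an outright error.
    """
    findings: list[Finding] = []
    for name in _GEOMETRY_LENGTH_FIELDS:
        value = getattr(geom, name)
        if not (value > 0):
            findings.append(Finding("error", name, f"{name} must be > 0, got {value}"))
    for name in ("n_systems", "chambers_per_system"):
        if getattr(geom, name) < 1:
            findings.append(Finding("error", name, f"{name} must be >= 1"))
    if geom.r_inner > 0 and geom.r_outer > 0:
        if geom.r_inner >= geom.r_outer:
            findings.append(
                Finding(
                    "error",
                    "r_inner",
                    f"r_inner ({geom.r_inner} m) must be < r_outer ({geom.r_outer} m): "
                    "the pumping liquid column would have zero or negative extent",
                )
            )
        if geom.r_outer > geom.disc_radius:
            findings.append(
                Finding(
                    "error",
                    "r_outer",
                    f"r_outer ({geom.r_outer} m) exceeds the disc radius "
                    f"({geom.disc_radius} m)",
                )
            )
    if geom.channel_height > 0 and geom.channel_width > 0:
        if geom.channel_height > geom.channel_width:
            findings.append(
                Finding(
                    "error",
                    "channel_height",
                    "channel height exceeds width; the shallow-channel flow law "
                    "requires h <= w",
                )
            )
        elif geom.aspect_ratio > 0.5:
            findings.append(
                Finding(
                    "warning",
                    "channel_height",
                    f"aspect ratio h/w = {geom.aspect_ratio:.3g} > 0.5; the "
                    "(1 - 0.630 h/w) correction degrades outside h << w",
                )
            )
    return findings


# ---------------------------------------------------------------------------
# YAML config I/O
# ---------------------------------------------------------------------------

def _field_to_yaml(value: float, units: str, provenance: str) -> dict:
    return {"value": value, "units": units, "provenance": provenance}


def geometry_to_dict(geom: DiscGeometry) -> dict:
    """Serialize a geometry to the config mapping (all lengths emitted in m).

    Lengths are written in SI so reading the file back reproduces every field
    bit-exactly (no unit conversion on the round trip).
    """
    out: dict = {}
    for name in _GEOMETRY_LENGTH_FIELDS + ("disc_radius",):
        out[name] = _field_to_yaml(getattr(geom, name), "m", geom.provenance_of(name))
    out["n_systems"] = geom.n_systems
    out["chambers_per_system"] = geom.chambers_per_system
    return {"geometry": out}


def geometry_from_dict(doc: Mapping) -> DiscGeometry:
    """Read a geometry from a config mapping, converting units to SI."""
    node = doc["geometry"] if "geometry" in doc else doc
    kwargs: dict = {}
    provenance: dict[str, str] = {}
    for name in _GEOMETRY_LENGTH_FIELDS + ("disc_radius",):
        if name not in node:
            if name == "disc_radius":
                continue
            raise KeyError(f"geometry config missing field {name!r}")
        entry = node[name]
        if isinstance(entry, Mapping):
            units = entry.get("units", "m")
            if units not in _LENGTH_UNITS:
                raise ValueError(f"unknown length unit {units!r} for {name}")
            kwargs[name] = entry["value"] * _LENGTH_UNITS[units]
            provenance[name] = entry.get("provenance", "assumed")
        else:
            kwargs[name] = float(entry)
            provenance[name] = "assumed"
    kwargs["n_systems"] = int(node.get("n_systems", 4))
    kwargs["chambers_per_system"] = int(node.get("chambers_per_system", 5))
    return DiscGeometry(provenance=provenance, **kwargs)


def write_geometry(geom: DiscGeometry, stream: IO[str] | str) -> None:
    doc = geometry_to_dict(geom)
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
    else:
        yaml.safe_dump(doc, stream, sort_keys=False)


def read_geometry(stream: IO[str] | str) -> DiscGeometry:
    if isinstance(stream, str):
        with open(stream) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(stream)
    return geometry_from_dict(doc)


def fluid_from_dict(doc: Mapping) -> FluidProperties:
    node = doc["fluid"] if "fluid" in doc else doc
    if "water_at_C" in node:
        return water_properties(float(node["water_at_C"]))
    return FluidProperties(
        density=float(node["density_kg_m3"]),
        viscosity=float(node["viscosity_Pa_s"]),
        surface_tension=float(node["surface_tension_N_m"]),
        temperature=node.get("temperature_C"),
    )


def fluid_to_dict(fluid: FluidProperties) -> dict:
    return {
        "fluid": {
            "density_kg_m3": fluid.density,
            "viscosity_Pa_s": fluid.viscosity,
            "surface_tension_N_m": fluid.surface_tension,
            "temperature_C": fluid.temperature,
        }
    }


def default_geometry() -> DiscGeometry:
    """The bundled default disc geometry (every printed dimension, plus the
    derived chamber radius and assumed column radii / channel length)."""
    text = resources.files("discflow.data").joinpath("organ_disc_default.yaml").read_text()
    return read_geometry_text(text)


def read_geometry_text(text: str) -> DiscGeometry:
    return geometry_from_dict(yaml.safe_load(text))


def replace_geometry(geom: DiscGeometry, **changes) -> DiscGeometry:
    """dataclasses.replace with the provenance map preserved unless overridden."""
    return dataclasses.replace(geom, **changes)
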