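"""Cylindrical multilayer finger model and ring-surface LED/PD placement.

The model is a finite cylinder (finger axis = z) made of concentric annular
layers — epidermis, dermis and a capillary-rich "microcirculation" core —
with blood vessels and bone embedded as axis-parallel cylinders inside the
core.  Default dimensions follow the anatomy used for reflective ring-PPG
simulation studies: total finger diameter 19.2 mm, 0.6 mm epidermis, 1 mm
dermis, 16 mm diameter microcirculation, ~1.2 mm diameter vessels.

Angles are measured counter-clockwise in the cross-sectional plane with 0°
at the volar (palm-side) midline; all lengths are in millimetres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "OpticalProperties",
    "FingerRegion",
    "FingerModel",
    "RingPlacement",
    "build_default_finger",
    "load_finger_config",
    "enumerate_layouts",
    "DEFAULT_WAVELENGTHS",
]

DEFAULT_WAVELENGTHS = (550, 628, 940)

REGION_LABELS = ("epidermis", "dermis", "microcirculation", "artery", "vein", "bone")


class FingerConfigError(ValueError):
    """Raised for inconsistent finger-model configuration."""


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption/scattering coefficients (1/mm), HG anisotropy g and index n."""

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise FingerConfigError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise FingerConfigError("anisotropy g must lie in (-1, 1)")
        if self.n < 1.0:
            raise FingerConfigError("refractive index must be >= 1")

    @property
    def mu_t(self) -> float:
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class FingerRegion:
    """One tissue region: a concentric annulus or an embedded parallel cylinder.

    Annuli use ``r_inner``/``r_outer``; embedded cylinders use ``center``
    (cross-sectional offset from the finger axis, mm) and ``radius``.
    ``props`` maps wavelength (nm) -> OpticalProperties.
    """

    label: str
    props: dict[int, OpticalProperties]
    r_inner: float | None = None
    r_outer: float | None = None
    center: tuple[float, float] | None = None
    radius: float | None = None

    @property
    def is_annulus(self) -> bool:
        return self.r_outer is not None

    def contains(self, x: float, y: float) -> bool:
        """Cross-sectional containment (z plays no role for parallel geometry)."""
        if self.is_annulus:
            r = math.hypot(x, y)
            return (self.r_inner or 0.0) <= r < self.r_outer
        cx, cy = self.center
        return math.hypot(x - cx, y - cy) < self.radius

    def cross_section_area(self) -> float:
        if self.is_annulus:
            return math.pi * (self.r_outer**2 - (self.r_inner or 0.0) ** 2)
        return math.pi * self.radius**2


@dataclass(frozen=True)
class FingerModel:
    """Ordered region collection; embedded cylinders shadow the annulus they sit in."""

    regions: tuple[FingerRegion, ...]
    outer_radius: float
    axial_length: float = 20.0
    wavelengths: tuple[int, ...] = DEFAULT_WAVELENGTHS

    def __post_init__(self) -> None:
        annuli = sorted(self.annuli, key=lambda r: r.r_outer)
        edge = 0.0
        for a in annuli:
            inner = a.r_inner or 0.0
            if not math.isclose(inner, edge, abs_tol=1e-9):
                raise FingerConfigError(
                    f"annuli must tile [0, outer_radius]; gap/overlap at r={inner}"
                )
            edge = a.r_outer
        if not math.isclose(edge, self.outer_radius, abs_tol=1e-9):
            raise FingerConfigError("outermost annulus must end at outer_radius")
        for reg in self.regions:
            missing = [w for w in self.wavelengths if w not in reg.props]
            if missing:
                raise FingerConfigError(
                    f"region '{reg.label}' lacks optical properties at {missing} nm"
                )

    @property
    def annuli(self) -> tuple[FingerRegion, ...]:
        return tuple(r for r in self.regions if r.is_annulus)

    @property
    def embedded(self) -> tuple[FingerRegion, ...]:
        return tuple(r for r in self.regions if not r.is_annulus)

    def locate_region(self, point) -> str:
        """Label of the innermost region containing ``point`` (3-vector, mm).

        Embedded cylinders take precedence over the annulus that hosts them;
        points beyond the outer radius or the end caps are 'ambient'.
        """
        x, y, z = point
        if not 0.0 <= z <= self.axial_length:
            return "ambient"
        if math.hypot(x, y) >= self.outer_radius:
            return "ambient"
        for reg in self.embedded:
            if reg.contains(x, y):
                return reg.label
        for reg in sorted(self.annuli, key=lambda r: r.r_outer):
            if reg.contains(x, y):
                return reg.label
        return "ambient"


@dataclass(frozen=True)
class RingPlacement:
    """LED and PD patches on the outer ring circumference.

    Angles in degrees (mod 360); apertures are the angular widths of the
    emitting/detecting patches; ``axial_extent`` is their length along the
    finger axis (mm), centred at mid-cylinder.
    """

    led_angle: float
    pd_angle: float
    led_aperture: float = 10.0
    pd_aperture: float = 10.0
    axial_extent: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "led_angle", self.led_angle % 360.0)
        object.__setattr__(self, "pd_angle", self.pd_angle % 360.0)

    @property
    def delta(self) -> float:
        """LED–PD angle Δ = (pd − led) mod 360."""
        return (self.pd_angle - self.led_angle) % 360.0

    def mirrored(self) -> "RingPlacement":
        """Reflection about the volar–dorsal symmetry axis (0°–180°)."""
        return RingPlacement(
            (-self.led_angle) % 360.0,
            (-self.pd_angle) % 360.0,
            self.led_aperture,
            self.pd_aperture,
            self.axial_extent,
        )


def _load_default_optics() -> dict[str, dict[int, OpticalProperties]]:
    text = resources.files("ringppg.data").joinpath("default_optics.json").read_text()
    raw = json.loads(text)
    table: dict[str, dict[int, OpticalProperties]] = {}
    for label, per_wl in raw.items():
        if label.startswith("_"):
            continue
        table[label] = {
            int(wl): OpticalProperties(**coeffs) for wl, coeffs in per_wl.items()
        }
    return table


def build_default_finger(
    wavelengths=DEFAULT_WAVELENGTHS,
    optics_table: dict[str, dict[int, OpticalProperties]] | None = None,
    axial_length: float = 20.0,
) -> FingerModel:
    """Default 19.2 mm-diameter finger.

    Epidermis annulus 9.0–9.6 mm, dermis 8.0–9.0 mm, microcirculation disk of
    radius 8.0 mm containing four 0.6 mm-radius vessels (volar arteries at
    ±30° from the volar midline, dorsal vessels at ±30° from the dorsal
    midline, centres at 6.5 mm radius) and a central 3 mm-radius bone.  Vessel
    and bone placement are assumptions (anatomy texts give only "on the sides
    of the finger") and are config-overridable.

    Optical properties default to the packaged literature-defaults table,
    which covers 550, 628 and 940 nm; other wavelengths require a
    user-supplied ``optics_table``.
    """
    wavelengths = tuple(sorted(int(w) for w in wavelengths))
    optics = optics_table if optics_table is not None else _load_default_optics()
    for label in REGION_LABELS:
        if label not in optics:
            raise FingerConfigError(f"optics table lacks region '{label}'")
        for w in wavelengths:
            if w not in optics[label]:
                raise FingerConfigError(
                    f"no optical properties for '{label}' at {w} nm; "
                    "supply an optics table covering this wavelength"
                )

    def props(label):
        return {w: optics[label][w] for w in wavelengths}

    vessel_r = 0.6
    vessel_c = 6.5
    regions = [
        FingerRegion("microcirculation", props("microcirculation"), r_inner=0.0, r_outer=8.0),
        FingerRegion("dermis", props("dermis"), r_inner=8.0, r_outer=9.0),
        FingerRegion("epidermis", props("epidermis"), r_inner=9.0, r_outer=9.6),
    ]
    for label, ang in (("artery", 30.0), ("artery", -30.0), ("vein", 150.0), ("vein", 210.0)):
        a = math.radians(ang)
        regions.append(
            FingerRegion(
                label,
                props(label),
                center=(vessel_c * math.cos(a), vessel_c * math.sin(a)),
                radius=vessel_r,
            )
        )
    regions.append(FingerRegion("bone", props("bone"), center=(0.0, 0.0), radius=3.0))
    return FingerModel(
        regions=tuple(regions),
        outer_radius=9.6,
        axial_length=axial_length,
        wavelengths=wavelengths,
    )


def load_finger_config(path: str | Path) -> FingerModel:
    """Build a FingerModel from a JSON config with ``regions`` and ``optics``.

    Schema::

        {"outer_radius": 9.6, "axial_length": 20.0, "wavelengths": [550],
         "regions": [{"label": "...", "r_inner": 0, "r_outer": 8.0}
                     | {"label": "...", "center": [x, y], "radius": 0.6}, ...],
         "optics": {"<label>": {"550": {"mu_a":..,"mu_s":..,"g":..,"n":..}}}}
    """
    raw = json.loads(Path(path).read_text())
    optics = {
        label: {int(w): OpticalProperties(**c) for w, c in per_wl.items()}
        for label, per_wl in raw["optics"].items()
    }
    wavelengths = tuple(int(w) for w in raw["wavelengths"])
    regions = []
    for spec in raw["regions"]:
        label = spec["label"]
        if label not in optics:
            raise FingerConfigError(f"region '{label}' has no optics entry")
        kwargs = dict(label=label, props={w: optics[label][w] for w in wavelengths})
        if "r_outer" in spec:
            kwargs.update(r_inner=float(spec.get("r_inner", 0.0)), r_outer=float(spec["r_outer"]))
        else:
            kwargs.update(center=tuple(spec["center"]), radius=float(spec["radius"]))
        regions.append(FingerRegion(**kwargs))
    return FingerModel(
        regions=tuple(regions),
        outer_radius=float(raw["outer_radius"]),
        axial_length=float(raw.get("axial_length", 20.0)),
        wavelengths=wavelengths,
    )


def enumerate_layouts(grid_step: float, **patch_kwargs) -> list[RingPlacement]:
    """All (led_angle, pd_angle) pairs on a ``grid_step``-degree grid.

    A 30° grid gives the 12 × 12 = 144 combinations used to emulate ring
    rotation: the 12 placements sharing one LED–PD angle Δ are the same
    sensor layout at 12 rotational positions.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n = 360.0 / grid_step
    if abs(n - round(n)) > 1e-9:
        raise ValueError("grid_step must divide 360")
    n = int(round(n))
    angles = [i * grid_step for i in range(n)]
    return [RingPlacement(a, b, **patch_kwargs) for a in angles for b in angles]
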