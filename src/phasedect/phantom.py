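"""Cylinder phantoms: specification, rasterization and the default layout.

The benchmark phantom is a circular water bath containing cylindrical
inserts of named materials (tubes in a sample-holder disc).  The bath keeps
refraction angles at the sample boundary small, preventing phase wrapping,
and provides the known-background region used to fix the DC level of the
phase reconstruction.

Geometry is 2-D single-slice, parallel beam.  Image arrays are indexed
(row = y, col = x) with pixel centers at half-integer grid coordinates and
the rotation axis at the grid center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interactions import AMParams, DEFAULT_AM_PARAMS
from .materials import Material, get_material, make_nai_solution

__all__ = ["CylinderInsert", "PhantomSpec", "table1_phantom", "rasterize"]


def _resolve(material: "Material | str") -> Material:
    if isinstance(material, Material):
        return material
    return get_material(material)


@dataclass(frozen=True)
class CylinderInsert:
    """A cylindrical insert: center (x, y) [mm], radius [mm], material."""

    center_mm: tuple[float, float]
    radius_mm: float
    material: Material | str

    def resolved(self) -> Material:
        return _resolve(self.material)


@dataclass(frozen=True)
class PhantomSpec:
    """Circular bath phantom with cylindrical inserts.

    Inserts must lie fully inside the container and the container fully
    inside the field of view, so that no projection is truncated.
    """

    inserts: tuple[CylinderInsert, ...]
    container_radius_mm: float = 18.0
    container_material: Material | str = "water"
    field_of_view_mm: float = 40.96

    def __post_init__(self):
        object.__setattr__(self, "inserts", tuple(self.inserts))
        if self.container_radius_mm <= 0:
            raise ValueError("container radius must be positive")
        if 2 * self.container_radius_mm > self.field_of_view_mm:
            raise ValueError("container does not fit inside the field of view")
        for ins in self.inserts:
            cx, cy = ins.center_mm
            if np.hypot(cx, cy) + ins.radius_mm > self.container_radius_mm + 1e-9:
                raise ValueError(
                    f"insert at ({cx}, {cy}) mm protrudes from the container"
                )

    def bath(self) -> Material:
        return _resolve(self.container_material)

    def disks(self, energy_kev: float, params: AMParams = DEFAULT_AM_PARAMS):
        """Flattened disk list as (cx_mm, cy_mm, r_mm, mu_cm1, delta).

        The container comes first; inserts carry their *absolute* values
        (rasterization composites them over the bath)."""
        out = []
        bath = self.bath()
        out.append((0.0, 0.0, self.container_radius_mm,
                    bath.mu(energy_kev, params), bath.delta(energy_kev)))
        for ins in self.inserts:
            m = ins.resolved()
            out.append((*ins.center_mm, ins.radius_mm,
                        m.mu(energy_kev, params), m.delta(energy_kev)))
        return out


def table1_phantom(nai_mg_ml: float = 5.9,
                   insert_radius_mm: float = 3.0,
                   ring_radius_mm: float = 11.0,
                   container_radius_mm: float = 18.0,
                   field_of_view_mm: float = 40.96) -> PhantomSpec:
    """Default seven-material benchmark phantom.

    Six tubes (NaI solution, blood, ethanol, PMMA, POM, nylon 6) on a ring
    inside a circular water bath; the bath itself is the seventh material.
    """
    names = ["blood", "ethanol", "pmma", "pom", "nylon6"]
    materials: list[Material | str] = [make_nai_solution(nai_mg_ml)] + names
    inserts = []
    for k, mat in enumerate(materials):
        ang = 2 * np.pi * k / len(materials)
        inserts.append(CylinderInsert(
            center_mm=(ring_radius_mm * np.cos(ang), ring_radius_mm * np.sin(ang)),
            radius_mm=insert_radius_mm,
            material=mat,
        ))
    return PhantomSpec(inserts=tuple(inserts),
                       container_radius_mm=container_radius_mm,
                       container_material="water",
                       field_of_view_mm=field_of_view_mm)


def _coverage(xc, yc, cx_mm, cy_mm, r_mm, pixel_mm, supersample):
    """Fractional pixel coverage of a disk, by subpixel area sampling."""
    n = xc.shape[0]
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    cov = np.zeros((n, n))
    for oy in offs:
        for ox in offs:
            dx = xc + ox * pixel_mm - cx_mm
            dy = yc + oy * pixel_mm - cy_mm
            cov += (dx * dx + dy * dy) <= r_mm * r_mm
    return cov / supersample**2


def rasterize(spec: PhantomSpec, n_pixels: int, pixel_um: float,
              energy_kev: float, params: AMParams = DEFAULT_AM_PARAMS,
              supersample: int = 8):
    """Ground-truth (μ [cm⁻¹], δ) maps of the phantom at one energy.

    Edges are anti-aliased by ``supersample``² subpixel area weighting.
    Returns two float arrays of shape (n_pixels, n_pixels).
    """
    pixel_mm = pixel_um / 1000.0
    half = n_pixels / 2.0
    coords = (np.arange(n_pixels) + 0.5 - half) * pixel_mm
    yc, xc = np.meshgrid(coords, coords, indexing="ij")
    mu = np.zeros((n_pixels, n_pixels))
    delta = np.zeros((n_pixels, n_pixels))
    for cx, cy, r, mu_v, d_v in spec.disks(energy_kev, params):
        cov = _coverage(xc, yc, cx, cy, r, pixel_mm, supersample)
        mu = mu * (1 - cov) + mu_v * cov
        delta = delta * (1 - cov) + d_v * cov
    return mu, delta
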