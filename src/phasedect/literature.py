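"""Bundled literature attenuation curves for attenuation-side calibration.

The interaction model neglects coherent scattering (about 10% of the total
attenuation of water at 25 keV), so calibrating the attenuation image's
effective energy against that same model would be circular and biased.
Calibration therefore uses total-attenuation literature values: bundled
NIST standard-grid knots, interpolated with a log-log cubic spline (the
knot spacing reproduces intermediate published values to ≈ 0.3%).
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .materials import get_material

__all__ = ["mu_literature", "literature_energy_range", "energy_from_mu_literature",
           "literature_materials"]


@lru_cache(maxsize=1)
def _tables() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    path = resources.files("phasedect.data").joinpath("attenuation_literature.csv")
    rows: dict[str, list[tuple[float, float]]] = {}
    with path.open() as fh:
        for rec in csv.DictReader(r for r in fh if not r.startswith("#")):
            rows.setdefault(rec["material"], []).append(
                (float(rec["energy_keV"]), float(rec["mu_over_rho_cm2_g"]))
            )
    out = {}
    for mat, pts in rows.items():
        pts.sort()
        e = np.array([p[0] for p in pts])
        v = np.array([p[1] for p in pts])
        out[mat] = (e, v)
    return out


@lru_cache(maxsize=None)
def _spline(material: str) -> CubicSpline:
    try:
        e, v = _tables()[material]
    except KeyError:
        raise KeyError(
            f"no bundled literature attenuation table for {material!r}; "
            f"available: {sorted(_tables())}"
        ) from None
    return CubicSpline(np.log(e), np.log(v))


def literature_materials() -> list[str]:
    return sorted(_tables())


def literature_energy_range(material: str) -> tuple[float, float]:
    e, _ = _tables()[material]
    return float(e[0]), float(e[-1])


def mu_literature(material: str, energy_kev) -> float | np.ndarray:
    """Literature linear attenuation coefficient μ(E) [cm⁻¹].

    Mass attenuation from the bundled table times the material's bundled
    mass density.  ``energy_kev`` must lie inside the table range.
    """
    lo, hi = literature_energy_range(material)
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < lo) or np.any(e > hi):
        raise ValueError(f"energy outside the tabulated {lo}-{hi} keV range")
    mu = np.exp(_spline(material)(np.log(e))) * get_material(material).density
    return mu if mu.ndim else float(mu)


def energy_from_mu_literature(mu_cm1: float, material: str) -> float:
    """Invert the literature curve: the energy at which μ_lit(E) = μ.

    μ_lit is strictly decreasing over the tabulated range here, so the root
    is unique; raises with the admissible range when μ falls outside it.
    """
    lo, hi = literature_energy_range(material)
    mu_hi, mu_lo = mu_literature(material, lo), mu_literature(material, hi)
    if not (mu_lo <= mu_cm1 <= mu_hi):
        raise ValueError(
            f"mu = {mu_cm1:.4g} cm^-1 outside the invertible range "
            f"[{mu_lo:.4g}, {mu_hi:.4g}] cm^-1 ({lo}-{hi} keV) for {material!r}"
        )
    return float(brentq(lambda e: mu_literature(material, e) - mu_cm1, lo, hi,
                        xtol=1e-10))
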