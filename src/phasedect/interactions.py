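"""Photon-interaction model linking (μ, δ) to electron density and Z_eff.

The attenuation coefficient is parametrized as a sum of a Compton term and
a photo-effect term,

    μ(E) = ρe σ_KN(E) + ρe C_P Z^C_Z / E^C_E ,

with the Klein–Nishina total cross section per electron σ_KN and empirical
constants (C_P, C_Z, C_E) fitted for the 15–35 keV diagnostic range.  The
refractive-index decrement is tied to the electron density by

    δ = r0 h² c² / (2π E²) · ρe ,

valid above the absorption edges of the constituents, where the atomic
scattering factor reduces to Z.  Inverting the attenuation model yields the
effective atomic number of a voxel from its measured (μ, ρe) pair.

Coherent scattering and K-edge discontinuities are deliberately outside the
model; see the methods note for the consequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DELTA_COEFF, ME_C2_KEV, SIGMA_THOMSON_CM2

__all__ = [
    "AMParams",
    "klein_nishina_sigma",
    "delta_from_rhoe",
    "rhoe_from_delta",
    "energy_from_delta",
    "mu_model",
    "zeff_from",
]

#: m⁻³ → cm⁻³
_M3_TO_CM3 = 1e-6


@dataclass(frozen=True)
class AMParams:
    """Empirical photo-effect parametrization constants.

    c_p is a cross-section prefactor in cm² (per electron, for E in keV),
    c_z the atomic-number exponent and c_e the energy exponent.  Defaults
    are the values fitted for a quasi-monochromatic ~25 keV beam.
    """

    c_p: float = 13.03e-24
    c_z: float = 3.42
    c_e: float = 2.97

    def photo_sigma(self, z, energy_kev):
        """Photo-effect cross section per electron [cm²] for atomic number z."""
        return self.c_p * np.asarray(z, dtype=float) ** self.c_z / energy_kev**self.c_e


DEFAULT_AM_PARAMS = AMParams()


def klein_nishina_sigma(energy_kev):
    """Total Klein–Nishina cross section per electron [cm²].

    Closed form in the reduced energy ε = E / mₑc²; strictly decreasing in E
    and approaching the Thomson cross section as E → 0.
    """
    energy_kev = np.asarray(energy_kev, dtype=float)
    if np.any(energy_kev <= 0):
        raise ValueError("photon energy must be positive")
    eps = energy_kev / ME_C2_KEV
    # guard against cancellation at very small eps: below ~1e-4 the closed
    # form still has ~8 significant digits in float64, good enough here
    log1p2e = np.log1p(2.0 * eps)
    term1 = (1.0 + eps) / eps**2 * (2.0 * (1.0 + eps) / (1.0 + 2.0 * eps) - log1p2e / eps)
    term2 = log1p2e / (2.0 * eps)
    term3 = (1.0 + 3.0 * eps) / (1.0 + 2.0 * eps) ** 2
    # 2 pi r0^2 = (3/4) sigma_Thomson; the bracket tends to 4/3 as eps -> 0
    two_pi_r0sq = 0.75 * SIGMA_THOMSON_CM2
    sigma = two_pi_r0sq * (term1 + term2 - term3)
    return sigma if sigma.ndim else float(sigma)


def delta_from_rhoe(rhoe_m3, energy_kev):
    """Refractive-index decrement δ for electron density ρe [m⁻³] at E [keV]."""
    if np.any(np.asarray(energy_kev) <= 0):
        raise ValueError("photon energy must be positive")
    return DELTA_COEFF * np.asarray(rhoe_m3, dtype=float) / energy_kev**2


def rhoe_from_delta(delta, energy_kev):
    """Electron density [m⁻³] from δ at E [keV] — exact inverse of
    :func:`delta_from_rhoe`.  Negative δ (noise) maps to negative ρe."""
    if np.any(np.asarray(energy_kev) <= 0):
        raise ValueError("photon energy must be positive")
    return np.asarray(delta, dtype=float) * energy_kev**2 / DELTA_COEFF


def energy_from_delta(delta, rhoe_m3):
    """Photon energy [keV] at which a material of electron density ρe has
    refractive-index decrement δ (closed-form inversion, E ∝ δ^{-1/2})."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("delta must be positive for energy inversion")
    e = np.sqrt(DELTA_COEFF * np.asarray(rhoe_m3, dtype=float) / delta)
    return e if e.ndim else float(e)


def mu_model(rhoe_m3, zeff, energy_kev, params: AMParams = DEFAULT_AM_PARAMS):
    """Linear attenuation coefficient [cm⁻¹] of the two-interaction model.

    At zeff = 0 the photo term vanishes and μ reduces to the pure Compton
    product ρe σ_KN(E).  ρe is converted to cm⁻³ internally.
    """
    rhoe = np.asarray(rhoe_m3, dtype=float)
    z = np.asarray(zeff, dtype=float)
    if np.any(z < 0):
        raise ValueError("effective atomic number must be non-negative")
    rhoe_cm3 = rhoe * _M3_TO_CM3
    mu = rhoe_cm3 * (klein_nishina_sigma(energy_kev) + params.photo_sigma(z, energy_kev))
    return mu if mu.ndim else float(mu)


def zeff_from(mu_cm1, rhoe_m3, energy_kev, params: AMParams = DEFAULT_AM_PARAMS,
              return_mask: bool = False):
    """Effective atomic number from a (μ, ρe) pair at energy E.

        Z_eff = [ (μ/ρe − σ_KN(E)) · E^C_E / C_P ]^{1/C_Z}

    Where the radicand is non-positive (noisy voxels whose μ falls below the
    pure Compton level) the result is clamped to 0; with ``return_mask=True``
    a boolean array marking the *valid* (unclamped) entries is also returned.
    Exact inverse of :func:`mu_model` for admissible μ.
    """
    mu = np.asarray(mu_cm1, dtype=float)
    rhoe = np.asarray(rhoe_m3, dtype=float)
    if np.any(rhoe <= 0):
        raise ValueError("electron density must be positive")
    rhoe_cm3 = rhoe * _M3_TO_CM3
    radicand = (mu / rhoe_cm3 - klein_nishina_sigma(energy_kev)) \
        * energy_kev**params.c_e / params.c_p
    valid = radicand > 0
    z = np.where(valid, np.maximum(radicand, 0.0), 0.0) ** (1.0 / params.c_z)
    z = np.where(valid, z, 0.0)
    if not z.ndim:
        z = float(z)
        valid = bool(valid)
    if return_mask:
        return z, valid
    return z
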