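"""Talbot–Lau phase-stepping forward simulation (parallel beam, 2-D).

The interferometer converts the transverse refraction angle α of the beam,

    α(s) = ∂/∂s ∫ δ dz ,

into a shift φ = (2π d / p₂) · α of the sinusoidal stepping curve sampled
by moving the analyzer grating (period p₂) in K discrete steps over one
period, at inter-grating distance d.  Attenuation reduces the curve's mean,
the sample's small-angle scattering its visibility (not modelled here).

Stepping frames follow

    I_k = N₀ · T · [1 + V sin(2πk/K + φ)],  k = 0 … K−1,

with photon-counting (Poisson) noise when enabled; reference frames use
T = 1, φ = 0.  Sign convention: a positive δ gradient toward +s yields a
positive φ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .phantom import PhantomSpec

__all__ = [
    "AcquisitionGeometry",
    "SteppingFrames",
    "project_line_integrals",
    "phantom_line_integrals",
    "dphase_from_delta_integrals",
    "differential_phase_sinogram",
    "synthesize_stepping",
    "TruncationWarning",
    "PhaseWrapWarning",
]


class TruncationWarning(UserWarning):
    """Object extends to the detector edge; projections are truncated."""


class PhaseWrapWarning(UserWarning):
    """|φ| exceeded π somewhere; the extracted phase will wrap."""


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Interferometer and scan geometry with the instrument's default values.

    Defaults: analyzer period p₂ = 5 µm, inter-grating distance d = 248 mm,
    7 phase steps, 160 µm effective detector pixels, 25 keV design energy.
    The desk-scale scan (256 pixels, 300 angles over 360°) is scaled down
    from the instrument's 350–380 projections; :meth:`full_scale` restores
    the original sampling.
    """

    p2_um: float = 5.0
    d_mm: float = 248.0
    n_steps: int = 7
    n_angles: int = 300
    angle_span_deg: float = 360.0
    n_pixels: int = 256
    pixel_um: float = 160.0
    design_energy_kev: float = 25.0
    visibility: float = 0.3
    counts_per_step: float = 1.0e4
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.visibility <= 1.0):
            raise ValueError("visibility must lie in (0, 1]")
        if self.n_steps < 3:
            raise ValueError("phase stepping needs at least 3 steps")
        if min(self.p2_um, self.d_mm, self.pixel_um, self.counts_per_step) <= 0:
            raise ValueError("geometry lengths and counts must be positive")
        if self.design_energy_kev <= 0:
            raise ValueError("design energy must be positive")

    @classmethod
    def full_scale(cls, **overrides) -> "AcquisitionGeometry":
        """Instrument-scale sampling: 384 detector pixels, 370 projections."""
        base = cls(n_pixels=384, n_angles=370)
        return replace(base, **overrides)

    @property
    def angles_rad(self) -> np.ndarray:
        span = np.deg2rad(self.angle_span_deg)
        return np.arange(self.n_angles) * span / self.n_angles

    @property
    def pixel_cm(self) -> float:
        return self.pixel_um * 1e-4

    @property
    def phase_coeff(self) -> float:
        """2π d / p₂ — converts refraction angle [rad] to stepping phase."""
        return 2.0 * np.pi * (self.d_mm * 1000.0) / self.p2_um

    @property
    def field_of_view_mm(self) -> float:
        return self.n_pixels * self.pixel_um / 1000.0


def project_line_integrals(image: np.ndarray, angles_rad: np.ndarray,
                           pixel_um: float) -> np.ndarray:
    """Parallel-beam line integrals of a square map, in (map units) · cm.

    Detector coordinate s = x cosθ + y sinθ; angle 0 sends rays along +y.
    Implemented by bilinear image rotation and column summation; linear in
    the input.  Emits :class:`TruncationWarning` when the object reaches the
    detector edge (non-zero values in the outermost channels).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("map must be a square 2-D array")
    sino = np.empty((len(angles_rad), image.shape[1]))
    for i, theta in enumerate(np.asarray(angles_rad, dtype=float)):
        # rotate by -theta so the ray direction becomes the row axis
        rot = ndimage.rotate(image, np.rad2deg(theta), reshape=False,
                             order=1, prefilter=False)
        sino[i] = rot.sum(axis=0)
    sino *= pixel_um * 1e-4
    scale = np.abs(sino).max()
    if scale > 0 and np.abs(sino[:, [0, -1]]).max() > 1e-6 * scale:
        warnings.warn("object reaches the detector edge; projections truncated",
                      TruncationWarning, stacklevel=2)
    return sino


def phantom_line_integrals(spec: PhantomSpec, geometry: AcquisitionGeometry,
                           energy_kev: float | None = None, params=None):
    """Exact analytic line integrals (μ and δ) of a disk phantom.

    Being unions of disks, phantom projections are sums of chord lengths,
    2√(r² − u²), weighted by each disk's contrast over what it replaces.
    Returns (P_mu [cm⁻¹·cm], P_delta [cm]) of shape (n_angles, n_pixels).
    """
    from .interactions import DEFAULT_AM_PARAMS

    if energy_kev is None:
        energy_kev = geometry.design_energy_kev
    if params is None:
        params = DEFAULT_AM_PARAMS
    angles = geometry.angles_rad
    n = geometry.n_pixels
    s = (np.arange(n) + 0.5 - n / 2.0) * geometry.pixel_um / 1000.0  # mm
    p_mu = np.zeros((len(angles), n))
    p_delta = np.zeros((len(angles), n))
    disks = spec.disks(energy_kev, params)
    # convert absolute disk values to contrast over the bath
    bath_mu, bath_delta = disks[0][3], disks[0][4]
    contrasts = [(cx, cy, r,
                  mu - (bath_mu if k else 0.0),
                  d - (bath_delta if k else 0.0))
                 for k, (cx, cy, r, mu, d) in enumerate(disks)]
    cos_t, sin_t = np.cos(angles)[:, None], np.sin(angles)[:, None]
    for cx, cy, r, c_mu, c_delta in contrasts:
        s0 = cx * cos_t + cy * sin_t  # projected center, (n_angles, 1)
        u2 = np.clip(r * r - (s[None, :] - s0) ** 2, 0.0, None)
        chord_cm = 2.0 * np.sqrt(u2) / 10.0  # mm -> cm
        p_mu += c_mu * chord_cm
        p_delta += c_delta * chord_cm
    return p_mu, p_delta


def dphase_from_delta_integrals(p_delta: np.ndarray,
                                geometry: AcquisitionGeometry) -> np.ndarray:
    """Stepping-phase-shift sinogram from a ∫δ dz sinogram [cm].

    α by central differences at the detector pitch (one-sided at the ends),
    then φ = (2π d / p₂) α.  Warns on |φ| > π.
    """
    alpha = np.gradient(np.asarray(p_delta, dtype=float), geometry.pixel_cm,
                        axis=1)
    phi = geometry.phase_coeff * alpha
    if np.abs(phi).max() > np.pi:
        warnings.warn("stepping phase exceeds pi; expect phase wrapping",
                      PhaseWrapWarning, stacklevel=2)
    return phi


def differential_phase_sinogram(delta_map: np.ndarray,
                                geometry: AcquisitionGeometry) -> np.ndarray:
    """Stepping-phase-shift sinogram φ of a rasterized δ map."""
    p_delta = project_line_integrals(delta_map, geometry.angles_rad,
                                     geometry.pixel_um)
    return dphase_from_delta_integrals(p_delta, geometry)


@dataclass(frozen=True)
class SteppingFrames:
    """Sample and reference count stacks, indexed (angle, step, pixel)."""

    sample: np.ndarray
    reference: np.ndarray
    geometry: AcquisitionGeometry
    seed: int | None = None

    def __post_init__(self):
        if self.sample.shape != self.reference.shape:
            raise ValueError("sample and reference stacks differ in shape")
        if self.sample.min() < 0 or self.reference.min() < 0:
            raise ValueError("photon counts must be non-negative")


def synthesize_stepping(transmission: np.ndarray, phi: np.ndarray,
                        geometry: AcquisitionGeometry, noise: bool = True,
                        rng: np.random.Generator | int | None = None
                        ) -> SteppingFrames:
    """Simulate phase-stepping frames for given (T, φ) sinograms.

    With noise enabled the frames are Poisson samples, reproducible for a
    given seed; without noise they sample the stepping sinusoid exactly, so
    a single-harmonic fit returns (T, φ) to machine precision.
    """
    t = np.asarray(transmission, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if t.shape != phi.shape:
        raise ValueError("transmission and phase sinograms differ in shape")
    if np.any(t <= 0) or np.any(t > 1.0 + 1e-9):
        raise ValueError("transmission must lie in (0, 1]")
    k = np.arange(geometry.n_steps)
    step_phase = 2.0 * np.pi * k / geometry.n_steps
    n0, vis = geometry.counts_per_step, geometry.visibility
    carrier = 1.0 + vis * np.sin(step_phase[None, :, None] + phi[:, None, :])
    sample = n0 * t[:, None, :] * carrier
    reference = np.broadcast_to(
        n0 * (1.0 + vis * np.sin(step_phase))[None, :, None], sample.shape
    ).copy()
    seed = None
    if noise:
        if rng is None:
            rng = geometry.seed
        if not isinstance(rng, np.random.Generator):
            seed = int(rng)
            rng = np.random.default_rng(seed)
        sample = rng.poisson(sample).astype(np.int64)
        reference = rng.poisson(reference).astype(np.int64)
    return SteppingFrames(sample=sample, reference=reference,
                          geometry=geometry, seed=seed)
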