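"""Filtered backprojection of the attenuation and phase channels.

The attenuation channel is reconstructed conventionally: −ln T gives line
integrals of μ, filtered with the Ram-Lak (ramp) kernel and backprojected.
The differential-phase channel is first rescaled to the refraction angle
α = φ p₂ / (2π d) = ∂s ∫δ dz and reconstructed with the Hilbert
(sign-function) kernel,

    G(ν) = sgn(ν) / (2πi),

which combined with the ∂s already present in the data acts as the ramp —
so both channels land on the exact same pixel grid (registration is
structural, never resampled).  The sign kernel suppresses the DC component
of each projection; the lost offset is restored by pinning a known
background region (the water-bath annulus) to its nominal δ.

Filters are built from their band-limited spatial kernels (Kak & Slaney
discretization) and applied in the frequency domain after zero-padding to
at least twice the detector width to suppress circular-convolution wrap.
Backprojection uses linear interpolation (ties at half-pixels resolve to
the lower index) with angular weight π/N: for a 360° span each line is
measured twice, which the half-Δθ weight accounts for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forward import AcquisitionGeometry

__all__ = ["SlicePair", "neglog", "scale_dphase", "fbp_ramlak", "fbp_hilbert",
           "FewAnglesWarning", "reconstruct_slice_pair", "bath_annulus_mask"]


class FewAnglesWarning(UserWarning):
    """Angular sampling is too sparse for the detector width (streaks)."""


@dataclass(frozen=True)
class SlicePair:
    """Co-registered reconstructed μ [cm⁻¹] and δ maps on one pixel grid."""

    mu: np.ndarray
    delta: np.ndarray
    pixel_um: float
    provenance: dict | None = None

    def __post_init__(self):
        if self.mu.shape != self.delta.shape:
            raise ValueError("mu and delta maps must share one grid")


def neglog(transmission: np.ndarray, floor: float = 1e-6):
    """Beer–Lambert inversion: −ln T as line integrals of μ [cm⁻¹ · cm].

    Non-positive transmissions are clamped to ``floor`` and flagged; returns
    (sinogram, clamped_mask).
    """
    t = np.asarray(transmission, dtype=float)
    clamped = t < floor
    return -np.log(np.where(clamped, floor, t)), clamped


def scale_dphase(dphase: np.ndarray, geometry: AcquisitionGeometry) -> np.ndarray:
    """Refraction-angle sinogram α = φ p₂ / (2π d) (dimensionless)."""
    return np.asarray(dphase, dtype=float) / geometry.phase_coeff


def _pad_width(n: int) -> int:
    return int(2 ** np.ceil(np.log2(2 * n)))


def _ramp_filter(m: int) -> np.ndarray:
    """FFT of the band-limited ramp's spatial kernel (pixel units)."""
    h = np.zeros(m)
    h[0] = 0.25
    odd = np.arange(1, m // 2, 2)
    h[odd] = -1.0 / (np.pi * odd) ** 2
    h[-odd] = h[odd]
    return np.real(np.fft.fft(h))


def _hilbert_filter(m: int) -> np.ndarray:
    """FFT of the band-limited kernel of sgn(ν)/(2πi) (pixel units)."""
    g = np.zeros(m)
    odd = np.arange(1, m // 2, 2)
    g[odd] = 1.0 / (np.pi**2 * odd)
    g[-odd] = -g[odd]
    return np.fft.fft(g)  # purely imaginary, odd


def _filter_sinogram(sino: np.ndarray, kernel_fft: np.ndarray) -> np.ndarray:
    n = sino.shape[1]
    m = len(kernel_fft)
    padded = np.zeros((sino.shape[0], m))
    padded[:, :n] = sino
    filt = np.fft.ifft(np.fft.fft(padded, axis=1) * kernel_fft[None, :], axis=1)
    return np.real(filt[:, :n])


def _backproject(filtered: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    n_angles, n = filtered.shape
    if n_angles < n / 2:
        warnings.warn(
            f"{n_angles} angles for {n} detector pixels; expect streaks",
            FewAnglesWarning, stacklevel=3,
        )
    c = (np.arange(n) - (n - 1) / 2.0)
    yy, xx = np.meshgrid(c, c, indexing="ij")
    out = np.zeros((n, n))
    idx = np.arange(n)
    for theta, row in zip(angles_rad, filtered):
        s = xx * np.cos(theta) + yy * np.sin(theta) + (n - 1) / 2.0
        out += np.interp(s, idx, row, left=0.0, right=0.0)
    return out * (np.pi / n_angles)


def _check_coverage(angles_rad: np.ndarray):
    a = np.asarray(angles_rad, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two projection angles")
    # angles sample [0, span) without the endpoint; extrapolate one step
    span = np.ptp(a) * a.size / (a.size - 1)
    if span < np.pi * 0.999:
        raise ValueError("projection angles must cover at least 180 degrees")


def fbp_ramlak(sinogram: np.ndarray, angles_rad: np.ndarray,
               pixel_um: float) -> np.ndarray:
    """Standard FBP of line-integral data; output in (sinogram units)/cm."""
    sino = np.asarray(sinogram, dtype=float)
    _check_coverage(angles_rad)
    kernel = _ramp_filter(_pad_width(sino.shape[1]))
    img = _backproject(_filter_sinogram(sino, kernel), angles_rad)
    return img / (pixel_um * 1e-4)


def fbp_hilbert(alpha_sinogram: np.ndarray, angles_rad: np.ndarray,
                background_mask: np.ndarray | None = None,
                background_value: float = 0.0) -> np.ndarray:
    """FBP of differential (transverse-derivative) projections.

    Input is the dimensionless refraction angle α = ∂s ∫δ dz; the output δ
    map needs no pixel-size scaling (the derivative already carries the
    inverse length).  Because the sign kernel has no DC response, the map's
    offset is indeterminate; if ``background_mask`` is given, the mean over
    the masked pixels is shifted to ``background_value``.
    """
    sino = np.asarray(alpha_sinogram, dtype=float)
    _check_coverage(angles_rad)
    kernel = _hilbert_filter(_pad_width(sino.shape[1]))
    img = _backproject(_filter_sinogram(sino, kernel), angles_rad)
    if background_mask is not None:
        if not np.any(background_mask):
            raise ValueError("background mask selects no pixels")
        img += background_value - img[background_mask].mean()
    return img


def bath_annulus_mask(n_pixels: int, pixel_um: float, r_inner_mm: float,
                      r_outer_mm: float) -> np.ndarray:
    """Pixels whose centers fall in an annulus around the grid center."""
    pixel_mm = pixel_um / 1000.0
    c = (np.arange(n_pixels) + 0.5 - n_pixels / 2.0) * pixel_mm
    yy, xx = np.meshgrid(c, c, indexing="ij")
    r = np.hypot(xx, yy)
    return (r >= r_inner_mm) & (r <= r_outer_mm)


def reconstruct_slice_pair(channels, geometry: AcquisitionGeometry,
                           bath_delta: float,
                           bath_annulus_mm: tuple[float, float],
                           provenance: dict | None = None) -> SlicePair:
    """Channel sinograms → co-registered (μ, δ) maps.

    ``bath_delta`` and ``bath_annulus_mm`` pin the phase map's DC offset to
    the known δ of the water bath over the given (inner, outer) radii.
    """
    line_mu, _ = neglog(channels.transmission)
    mu = fbp_ramlak(line_mu, geometry.angles_rad, geometry.pixel_um)
    alpha = scale_dphase(channels.dphase, geometry)
    mask = bath_annulus_mask(geometry.n_pixels, geometry.pixel_um,
                             *bath_annulus_mm)
    delta = fbp_hilbert(alpha, geometry.angles_rad,
                        background_mask=mask, background_value=bath_delta)
    prov = {"filters": ["ram-lak", "hilbert"],
            "n_angles": geometry.n_angles,
            "angle_span_deg": geometry.angle_span_deg,
            "bath_annulus_mm": list(bath_annulus_mm),
            "bath_delta": bath_delta}
    if provenance:
        prov.update(provenance)
    return SlicePair(mu=mu, delta=delta, pixel_um=geometry.pixel_um,
                     provenance=prov)
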