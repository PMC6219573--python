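"""Stepping-curve analysis: recover T, differential phase and visibility.

Each detector pixel sees a sinusoidal intensity while the analyzer grating
is stepped over one period.  A single-harmonic discrete Fourier fit — the
uniform-noise least-squares solution, exact for a pure first harmonic
sampled at K equispaced steps — yields mean level a₀, first-harmonic
amplitude a₁ and phase.  Comparing sample to reference fits gives the three
contrast channels: transmission a₀ˢ/a₀ʳ, differential phase (wrapped to
(−π, π]) and visibility ratio (a₁ˢ/a₀ˢ)/(a₁ʳ/a₀ʳ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import SteppingFrames

__all__ = ["StepFit", "ChannelSinograms", "wrap_phase", "fit_stepping",
           "extract_channels", "extract_from_frames"]


def wrap_phase(phase):
    """Wrap angles into (−π, π]."""
    return np.pi - np.mod(np.pi - np.asarray(phase, dtype=float), 2.0 * np.pi)


@dataclass(frozen=True)
class StepFit:
    """Per-pixel single-harmonic fit: I_k ≈ a0 · (1 + (a1/a0) sin(2πk/K + phase))."""

    a0: np.ndarray
    a1: np.ndarray
    phase: np.ndarray
    valid: np.ndarray  # False where a0 or a1 vanish (phase undefined)


@dataclass(frozen=True)
class ChannelSinograms:
    """Contrast channels relative to the reference scan, plus validity mask."""

    transmission: np.ndarray
    dphase: np.ndarray
    visibility_ratio: np.ndarray
    valid: np.ndarray


def fit_stepping(frames: np.ndarray, step_axis: int = -2) -> StepFit:
    """Single-harmonic DFT fit of stepping curves along ``step_axis``.

    a0 is the mean count, (a1, phase) come from the k = 1 discrete Fourier
    component of I_k = a0 + a1 sin(2πk/K + phase).  All-zero or constant
    curves are flagged invalid instead of raising.
    """
    frames = np.asarray(frames, dtype=float)
    k = frames.shape[step_axis]
    if k < 3:
        raise ValueError("need at least 3 phase steps")
    frames = np.moveaxis(frames, step_axis, -1)
    a0 = frames.mean(axis=-1)
    phases = 2.0 * np.pi * np.arange(k) / k
    f1 = (2.0 / k) * (frames * np.exp(-1j * phases)).sum(axis=-1)
    a1 = np.abs(f1)
    phase = wrap_phase(np.angle(f1) + np.pi / 2.0)
    scale = max(float(np.abs(a0).max(initial=0.0)), 1.0)
    valid = (a0 > 0) & (a1 > 1e-12 * scale)
    return StepFit(a0=a0, a1=a1, phase=np.where(valid, phase, 0.0), valid=valid)


def extract_channels(sample: StepFit, reference: StepFit) -> ChannelSinograms:
    """Relate sample to reference stepping fits.

    Identical fits give the identity channels (T = 1, Δφ = 0, V-ratio = 1).
    Invalid reference pixels propagate into the output mask; channel values
    are zero-filled there so downstream maps stay finite.
    """
    if sample.a0.shape != reference.a0.shape:
        raise ValueError("sample and reference fits differ in shape")
    valid = sample.valid & reference.valid
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(valid, sample.a0 / reference.a0, 0.0)
        vis = np.where(
            valid,
            (sample.a1 * reference.a0) / (sample.a0 * reference.a1),
            0.0,
        )
    dphase = np.where(valid, wrap_phase(sample.phase - reference.phase), 0.0)
    return ChannelSinograms(transmission=t, dphase=dphase,
                            visibility_ratio=vis, valid=valid)


def extract_from_frames(frames: SteppingFrames) -> ChannelSinograms:
    """Convenience: fit sample and reference stacks and extract channels."""
    return extract_channels(fit_stepping(frames.sample),
                            fit_stepping(frames.reference))
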