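# Methods

This note documents the physical model, the synthetic-data generator, the
numerical choices and the open design decisions behind `phasedect`. Symbols:
μ — linear attenuation coefficient [cm⁻¹]; δ — refractive-index decrement
(dimensionless); ρe — electron density [m⁻³]; E — photon energy [keV].

## Interaction model

The phase signal is tied to the electron density by

    δ(E) = (r₀ h² c² / 2π E²) ρe,

valid above the absorption edges of the constituents, where forward atomic
scattering factors reduce to Z. The relation is used in both directions:
δ from ρe in the forward model, ρe maps and energy calibration from δ in the
processing chain (E ∝ δ^{-1/2} for a known reference material).

Attenuation uses the two-interaction parametrization

    μ(E) = ρe σ_KN(E) + ρe C_P Z^{C_Z} / E^{C_E},

with the full Klein–Nishina total cross section per electron σ_KN(E) (closed
form in ε = E/mₑc²; Thomson limit 6.6525·10⁻²⁵ cm² as E → 0) and the
empirical constants C_P = 13.03·10⁻²⁴ (cm², for E in keV), C_Z = 3.42,
C_E = 2.97. These constants were fitted for a quasi-monochromatic beam near
25 keV; the model deliberately omits coherent scattering and K-edge
structure. Units close because ρe is converted to cm⁻³ inside the formula;
this convention (E in keV, cross sections in cm²) is fixed throughout.

Inversion for the effective atomic number,

    Z_eff = [ (μ/ρe − σ_KN(E)) · E^{C_E} / C_P ]^{1/C_Z},

is exact against the forward model (mutual-inversion property enforced at
1e-10). Voxels whose noisy μ falls below the Compton level ρe σ_KN have a
non-positive radicand; they are clamped to Z_eff = 0 and *masked* rather
than set to NaN, so every downstream map stays finite. Virtual monoenergetic
images evaluate the forward model at an arbitrary energy; masked voxels
contribute their Compton term only.

## Materials and mixtures

A material is (name, mass density, elemental composition); compositions may
be stoichiometric counts or mass fractions. Electron density follows from
ρ · N_A · Σ wᵢ Zᵢ/Aᵢ with a small bundled Z/A table (no network access).
Bundled densities: water 1.000, PMMA 1.189, ethanol 0.789 g/cm³; POM 1.421
and nylon 6 1.140 g/cm³ were fixed — within their normal physical ranges —
so that the computed electron densities match the published literature
values (4.56 and 3.76 ·10²⁹ m⁻³), since the benchmark's exact stock
materials are not specified. Blood uses the ICRU-44 composition at
1.060 g/cm³ plus a bundled record of published measured values (μ = 0.568
cm⁻¹ at 24.6 keV, Z_eff = 7.60, ρe = 3.54·10²⁹ m⁻³) that serves as the
blood decomposition basis.

**Mixture rule.** The effective atomic number of a compound uses
electron-fraction weighting of Z^{C_Z}:

    Z_eff = ( Σᵢ λᵢ Zᵢ^{C_Z} )^{1/C_Z},   λᵢ = electron fraction.

This is the unique rule under which the photo-effect term ρe Z_eff^{C_Z} is
additive over constituents — mixtures of two materials then lie exactly on
the line between them in the (ρe Z^{C_Z}, ρe) plane, which the decomposition
exploits.

**Iodine below the K-edge.** The Z^{3.42} power law is an empirical fit to
low-Z media. Raw extrapolation to Z = 53 overestimates the sub-K-edge
(33.17 keV) photo cross section of iodine by roughly an order of magnitude:
it would predict Z_eff ≈ 11.2 for a 5.9 mg/ml NaI solution whose measured
value is 7.97 ± 0.06, and μ ≈ 1.4 cm⁻¹ against a measured 0.597 cm⁻¹. The
model therefore assigns iodine an *effective* photo-electric atomic number,
calibrated once (closed-form, the radicand is linear in Z_I^{C_Z}) from a
bundled published attenuation value of a dilute NaI solution (0.609 cm⁻¹ at
24.6 keV for 5.9 mg/ml). The calibration yields Z_I,eff ≈ 26.4 and brings
the whole NaI-solution family — Z_eff, attenuation, VMI behaviour — into
agreement with the published benchmark values. It is valid only below the
K-edge, which bounds the model's energy range for iodine-bearing voxels.

**NaI solutions** use the additive-mass density model ρ = ρ_water + c/1000
(error < 2‰ for c ≤ 20 mg/ml; an explicit density can be supplied). Iodine
content is the NaI concentration times the iodine mass fraction of NaI
(126.904/149.894 ≈ 0.847), so 5.9 mg/ml NaI ≡ 5.0 mg/ml iodine.

## Synthetic-data generator

The generator emulates a Talbot–Lau interferometer at a quasi-monochromatic
compact synchrotron source:

| parameter | default | meaning |
|---|---|---|
| p₂ | 5 µm | analyzer-grating period |
| d | 248 mm | inter-grating distance |
| K | 7 | phase steps over one period |
| pixel | 160 µm | effective detector pitch |
| E₀ | 25 keV | design energy (ideal monochromatic) |
| V | 0.3 | reference fringe visibility |
| N₀ | 10⁴ | mean reference counts per pixel and step |
| scan | 256 px, 300 angles / 360° | desk-scale sampling |

The instrument's own sampling (350–380 projections, wider detector) is
available through `AcquisitionGeometry.full_scale()`; the desk-scale default
was chosen so the complete noiseless pipeline runs in about a second while
keeping FBP discretization errors well below the 1% acceptance level.
Visibility and counts are not published for the benchmark instrument; 0.3
and 10⁴ are typical values for this class and are configurable. The beam's
~3% intrinsic bandwidth is *not* simulated: the processing chain treats
measured data as effectively monochromatic via energy calibration, so the
synthetic truth is generated at a single energy and calibration must recover
exactly that energy (a sharp self-consistency check, which the pipeline
passes to < 0.05 keV).

Geometry is 2-D parallel beam (the modelled instrument sits ~15 m from a
source with mrad divergence, so magnification is ignored). Phantoms are
unions of disks: a circular water bath (the published setup uses a
rectangular tank; a circular bath keeps projections identical at all angles
and serves the same two purposes — bounding refraction angles below the
phase-wrapping limit and providing a known background) and cylindrical
inserts that must lie fully inside it (no truncation). Projections are
computed two ways: exact analytic chord sums for disk phantoms (used by the
pipeline) and a generic rotate-and-sum projector for arbitrary rasterized
maps (bilinear rotation; mass conservation to 0.1%). Ground-truth maps are
rasterized with 8×8 subpixel area weighting.

The differential-phase sinogram applies central differences at the detector
pitch to the δ line integrals — mimicking what the pixelated detector can
see — giving the refraction angle α = ∂s∫δ dz and the stepping phase
φ = (2π d/p₂) α. Sign convention: positive δ gradient toward +s gives
positive φ; a warning is emitted if |φ| > π anywhere (phase wrapping).
Stepping frames follow I_k = N₀ T [1 + V sin(2πk/K + φ)], Poisson-sampled
when noise is on, with the reference scan at T = 1, φ = 0; all randomness
flows through one seeded generator.

What the generator does **not** emulate: Fresnel fringe formation, grating
imperfections, detector PSF and spectral response, beam hardening,
vibration/drift between sample and reference scans, cone/fan geometry,
dark-field (small-angle scattering) contrast. Passing tests therefore
demonstrate the correctness and internal consistency of the processing
chain at realistic noise levels — not robustness to those instrumental
effects, nor the model-vs-reality discrepancies (coherent scattering,
K-edges) that real measurements carry.

## Signal extraction and reconstruction

Stepping curves are fitted with the single-harmonic discrete Fourier fit:
a₀ = mean, (a₁, phase) from the k = 1 DFT bin. At equispaced steps this is
the uniform-noise least-squares solution and is *exact* for pure first
harmonics of any K ≥ 3; its phase noise reaches the Cramér–Rao bound
σ_φ = √(2/(N₀K))/V for Poisson counts (verified by Monte Carlo to 10%).
An expectation-maximization stepping retrieval exists in the literature;
the DFT fit was chosen as the standard, fully specified reference method.
Phases wrap to (−π, π]; no spatial unwrapping is performed, because the
water bath bounds |φ| < π by design. All-zero or constant pixels are
flagged in a validity mask that propagates through channel extraction
(T = a₀ˢ/a₀ʳ, Δφ = wrap(φˢ − φʳ), visibility ratio).

Both channels are reconstructed by filtered backprojection on the *same*
grid — registration is structural, never resampled. The attenuation channel
takes −ln T (non-positive T clamped to a configurable floor and flagged)
through the Ram-Lak filter; the phase channel is rescaled to α and filtered
with the Hilbert kernel G(ν) = sgn(ν)/(2πi), which combined with the ∂s in
the data acts as the ramp. Numerical choices:

* filters built from their band-limited spatial kernels (ramp: h₀ = 1/4,
  hₙ = −1/(πn)² odd n; Hilbert: gₙ = 1/(π²n) odd n) and applied by FFT —
  this fixes the DC behaviour of the discrete ramp;
* zero-padding to the next power of two ≥ 2× detector width against
  circular-convolution wrap;
* linear interpolation in backprojection, ties at half-pixels to the lower
  index; pixel centers at half-integers, rotation axis at the grid center;
* angles in radians, counter-clockwise, angle 0 sends rays along +y;
  angular weight π/N (for a 360° span each line is measured twice, which
  the half-Δθ weight absorbs);
* the sign kernel has no DC response, so the δ map's offset is pinned by
  forcing the mean over a known water-bath annulus to the bath's nominal δ.

The two routes (Hilbert on derivatives vs Ram-Lak on integrals) agree to
better than 0.2% over disk interiors at the default sampling — comfortably
inside the 1% equivalence requirement; the residual comes from the central
difference's sinc-like roll-off near Nyquist, which only affects edges.

## Energy calibration

Each channel carries its own effective energy, obtained from ROI means in a
PMMA reference insert. The phase side inverts δ(E) in closed form. The
attenuation side supports two sources: (a) `"literature"` — monotone
inversion (bisection) of a bundled total-attenuation curve, built from NIST
standard-grid mass-attenuation knots (10–50 keV) with log-log cubic-spline
interpolation; the knot set reproduces independently published 24.6 keV
values of water and PMMA to ≤ 0.3%, and calibrating on the published PMMA
ROI value returns 24.6 keV. This mirrors the measured-data procedure, which
must *not* calibrate against the interaction model itself (the model lacks
coherent scattering, ~10% of water's attenuation at 25 keV — the
calibration would be circular and biased). (b) `"model"` — inversion of the
interaction model's own μ(E), which is the self-consistent choice for
synthetic data generated by that same model; the pipeline defaults to it.
Inside the processing chain, the attenuation energy E_μ enters all
attenuation-side formulas (Z_eff, VMI) and the phase energy E_δ converts δ
to ρe; the pairing is a documented convention, as published analyses carry
both energies without stating it.

## Basis decomposition

A voxel's material coordinates are decomposed onto two basis materials via
the inverse of the 2×2 matrix whose columns are the basis vectors; the
fractional contributions are multiplied by each basis material's mass
density in mg/ml (water 1000, blood 1060, "20 mg/ml NaI" → 20, i.e. NaI
content). The default contrast basis is the 20 mg/ml NaI solution — a
dilute salt solution represents clinically relevant iodine solutions'
density better than solid NaI mixed with water — against water or blood.

Two coordinate systems are implemented:

* **photo/Compton** (`"photo-compton"`, default): the additive pair
  (ρe Z_eff^{C_Z}, ρe). Because both coordinates are exactly linear in
  composition, any mixture of the basis materials is recovered exactly;
  the decomposition's only error under noise is propagated noise.
* **literal (Z_eff, ρe)** (`"zeff-rhoe"`): the matrix applied directly to
  the (Z_eff, ρe) vector. Z_eff is a C_Z-power mean and hence concave in
  concentration, so dilute solutions between the basis points are
  overestimated: for NaI at 1.0/2.5/4.0/5.3 mg/ml the noiseless bias is
  +0.30/+0.67/+0.94/+1.12 mg/ml — already above the 0.7 mg/ml accuracy the
  method is expected to deliver at the top of that range.

The default is the photo/Compton system: it is the coordinate system the
change of basis is defined from, and it is the only choice consistent with
the published sub-mg/ml accuracy of the iodine map. The literal mode is
retained behind the `coords` flag for comparison. With the default, the
iodine-recovery simulation (measurement-matched Gaussian noise σ_μ = 0.006
cm⁻¹ and σ_δ = 0.06·10⁻⁷ per pixel, 20×20 ROI averaging, 100 replicates)
recovers 1.0–5.3 mg/ml NaI with a maximum absolute error of ≈ 0.1 mg/ml,
inside the 0.7 mg/ml bound.

Negative concentrations are preserved: materials that are not mixtures of
the basis pair legitimately project outside the basis simplex, and the
resulting strictly negative iodine values for the plastics and ethanol are
what makes zero-threshold segmentation meaningful.

## VNC and VMI

The virtual non-contrast image replaces pixels with iodine content above a
threshold (default 0 mg/ml — "positive iodine content"; a noise-floor
multiple can be set for noisy data) by draws from a normal distribution
with the mean and standard deviation of a background ROI (bath water by
default), deterministic per seed; all other pixels are bit-identical to the
input μ map. Virtual monoenergetic images evaluate the forward model per
voxel at the requested energies (default 25, 70, 120 keV). At the
calibration energy the VMI reproduces the measured μ map to 1e-10
(inversion identity); at 120 keV the photo term has decayed to the percent
level and the VMI is proportional to the ρe (phase) image within 2% across
the benchmark materials.

## Known limitations

* No coherent scattering and no K-edges in the interaction model; the
  effective iodine photo-Z is anchored at 24.6 keV and only valid below
  33.17 keV. VMI values for iodine-bearing voxels above the K-edge ignore
  the edge step by construction.
* Partial-volume voxels at material boundaries violate the single-material
  model; Z_eff maps show the characteristic edge overshoot there, and those
  voxels are not quantitative (the maps carry a validity mask, but edge
  voxels with a positive radicand remain unmasked).
* The energy-calibration uncertainty of measured data (±0.2 keV class) is
  not propagated into the product maps.
* Single-slice 2-D; volumes are loops over slices.
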