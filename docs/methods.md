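# Methods

## Imaging model

The package models a 2D, scalar, aberration-free fluorescence microscope
whose illumination pattern is produced by imaging a binary LCOS mask into
the sample plane with spatially incoherent (LED) light.  Both optical
paths are diffraction-limited circular-aperture systems, so each carries
the incoherent OTF ("chat" function)

    T(ρ) = (2/π)(arccos ρ − ρ√(1−ρ²)),  ρ = ν/ν_c,  ν_c = 2·NA/λ,

evaluated at its own wavelength.  This choice, rather than a Gaussian
approximation, is deliberate: the whole design trade-off of an incoherent
SIM is that pattern contrast falls as `T(ρ_ex)` while an interference
(coherent) pattern would keep unit contrast, and the near-cutoff behaviour
of `T` is what decides the usable pattern frequencies.  The PSF obtained
by inverse transforming `T` is the Airy intensity pattern; the generated
PSF's FWHM agrees with a direct Airy computation to within a few percent
(Gaussian fits to an Airy core read ~5% low, which also applies to the
bead metrology below).

Polarization optics (LCOS quarter-wave switching, the polarizing beam
splitter) are abstracted to an ideal binary amplitude mask; an imperfect
polarization contrast can be emulated by scaling the modulation, but no
vectorial effects are modelled.  Everything is monochromatic per channel
and 2D; there is no volumetric PSF.

Units: wavelengths and sample-plane distances in nm, device pixel
pitches in µm, spatial frequencies in cycles/µm at every public surface.

## Default optical configuration

| parameter | default | meaning |
|---|---|---|
| `na` | 1.3 | oil-immersion objective NA |
| `magnification` | 100 | sample → image plane |
| `lambda_ex` / `lambda_em` | 460 / 515 nm | blue LED channel; the emission value is a typical green-emitting dye, a configuration choice, not a measured instrument value |
| `camera_pixel` | 6.5 µm | sCMOS pitch → 65 nm sample pixels |
| `slm_pixel` | 5.2 µm | SLM pitch → 52 nm projected pixels |

The SLM pitch is a free design parameter of the simulation.  5.2 µm makes
the projected SLM grid commensurate with the camera grid (ratio 4:5, so a
640-pixel SLM region maps onto a 512-pixel camera field) and puts the
4-pixel line period at 208 nm = 0.85 of the excitation cutoff
(5.65 cycles/µm), i.e. a high-frequency super-resolution repertoire.
Derived scales: emission cutoff 5.05 cycles/µm, widefield PSF FWHM
0.51·λ/NA ≈ 202 nm.

## Pattern repertoires and the pixel lattice

Masks are rasterized with a hard pixel-centre rule (a pixel is ON iff its
centre falls in the duty window) — LCOS pixels are binary, no dithering.
Three presets exist:

* `minimal9` — 0°/60°/120°, 3 phases 120° apart (the textbook isotropic
  minimum);
* `bio12` — 0°/45°/90°, 4 phases (the routine set);
* `fixed14` — 0°/45°/90°/135° with 4+3+4+3 phases (extended set for
  fixed samples).

A consequence of binary rasterization that strongly shaped these choices:
a line pattern is exactly periodic on the pixel lattice only along
lattice directions (0°, 45°, 90°, 135° — with diagonal periods snapped to
multiples of √2/2 pixel steps).  At other orientations (60°, 120°) the
thresholded pattern is quasi-periodic and carries Moiré side components
whose amplitude can rival a heavily OTF-attenuated fundamental.  Under
**3-phase** stepping those components fold into the unshifted band (order
3 aliases onto order 0), so `minimal9` tolerates its diagonals; under
**4-phase** stepping they fold onto the ±1 bands and corrupt the
reconstruction, so the 4-phase presets use lattice directions only.  The
same reasoning explains why square-pixel SLM repertoires in the field add
diagonal orientations rather than 60° sets.

Phase steps are `period/n_phases` pixels.  When that is not an integer
number of lattice steps the realized phases are quantized away from the
nominal uniform grid (e.g. the snapped 45° pattern at period 6 lattice
steps with 4 phases realizes steps of roughly 120°/60°/120°).  The
repertoire masks are therefore treated as the ground truth: consumers
read the *realized* phase of each mask (single-frequency DFT of the mask
at the pattern frequency) rather than trusting the nominal grid.

Duty is 0.5 everywhere by default, giving equal mark-to-area ratio (MAR)
across orientations and, for phase-commensurate periods, an exactly
homogeneous summed illumination.  `mar_uniformity` and
`homogeneity_residual` verify this per repertoire; the shipped presets
stay within 0.05 (MAR spread) and 0.1 (homogeneity, borders excluded) on
all tested grids, with exact zeros for commensurate axis-aligned sets.

## Pattern projection

`project_pattern` images a mask into the sample plane in three exact
steps: (1) replicate the mask onto a 4× finer grid — the SLM transmission
is piecewise constant over pixel cells, and the replicated grid
represents that cell structure with a Nyquist frequency far above the
excitation cutoff; (2) multiply by the excitation OTF in the Fourier
domain (this removes all pattern harmonics above the cutoff — they never
fold into the passband, which they would if the mask were treated as
point samples on the camera grid); (3) Fourier-crop to the camera grid
(exact for the now band-limited signal; a residual out-of-band energy
above 1e-6 raises an aliasing error).  The projected fundamental's
Fourier coefficient, relative to the mask's cell-representation
coefficient, equals `T(ρ_ex)` to numerical precision — the package's
testable statement of the coherent-vs-incoherent contrast argument.

## Acquisition simulation

`simulate_acquisition` forms `(D·I_i) ⊗ PSF_em` per pattern, scales the
scene so the fully-illuminated widefield peak equals `peak_photons`
(default 10⁴, a photon budget choice typical of bead benchmarks), then
applies Poisson shot noise and Gaussian read noise (default 2 photons
RMS) from one seeded generator — identical seeds give bit-identical
stacks.  `peak_photons = 0` disables shot noise for noise-free oracles.

A two-plane phantom adds defocused background: the background density is
blurred by a Gaussian defocus kernel with `σ_def = defocus·NA/n_oil`
(n_oil = 1.518) and illuminated by the *defocus-filtered* pattern — i.e.
the same Gaussian low-pass applied to the illumination, which attenuates
the pattern fundamental by `exp(−(2π f σ_def)²/2)`.  This Gaussian model
(rather than a defocused Stokseth OTF) is a documented approximation;
the sectioning benchmarks are ratio-based and insensitive to its exact
shape.

## SR-SIM reconstruction

Classical frequency-domain recombination:

1. **Pattern parameters.** By default (`phase_source="metadata"`) the
   frequency vector follows from the spec'd period/orientation and the
   phases are read off the rasterized masks, which is exact for simulated
   stacks.  `phase_source="estimated"` recovers both from the frames: the
   product `conj(S0)·S+1` oscillates at **k** with the object envelope,
   so |FT| of it carries the emitter structure factor peaked at **k**;
   the peak is refined to sub-pixel precision by direct single-frequency
   DFT maximization (initialized at the metadata value and bounded to
   ±20% of it when metadata exists, because rasterization Moiré can
   outshine a weak fundamental in a global search).  Phases come from a
   matched filter (frame minus widefield projected onto the widefield
   modulated at **k** — coherent over the whole band, hence robust when
   the emission OTF at **k** is small), iterated against the separated
   side band.  For 3-phase groups the −1-band cross-term is removed
   exactly by an alternating-least-squares solve of
   `p_i = α e^{−iφ_i} + β e^{+iφ_i}`; for 4 equally spaced phases that
   two-term model is structurally non-identifiable (a one-parameter
   family fits any readout), so the β-blind estimate is reported with a
   documented ~±(|β/α|) radian bias.  A stack with no significant pattern
   peak raises `PatternEstimationError` naming the angle.
2. **Band separation.** The linear mixing
   `F_i = S0 + e^{−iφ_i}S+1 + e^{+iφ_i}S−1` is inverted exactly for 3
   phases and by least squares for more; degenerate phase sets (condition
   number > 1e8) are rejected.  Separation followed by remixing is exact
   to 1e-10.
3. **Shift and recombine.** Bands are Fourier zero-padded onto a 2×
   grid, side bands moved by ∓**k** with real-space phase ramps (exact
   for sub-pixel **k**), rescaled to the S0 amplitude using the complex
   modulation factor measured in the OTF overlap region (|c| below 1e-3
   drops the band — a zero-contrast stack degrades gracefully to a
   Wiener-filtered widefield image), and combined as
   `D = Σ conj(O_b)B_b / (Σ O_b² + w²)` with `w` = `wiener_w` = 0.05 of
   the peak OTF, followed by triangle (Lukosz) apodization to the
   passband `|k|_max + ν_c,em`.

The reported passband obeys the linear-SIM two-fold bound for every
admissible pattern: a pattern above the emission cutoff would leave no
modulation in the camera frames at all (the camera cannot see it), so
admissible frequencies satisfy `|k| ≤ ν_c,em` and
`passband/ν_c,em ≤ 2`.

## OS-SIM reconstruction

Square-law demodulation per orientation,
`OS = sqrt(Σ_{i<j}(F_i−F_j)²)·√2/n`, averaged over orientations.  The
`√2/n` normalization returns exactly the local modulation amplitude for
any number of equally spaced phases (a per-pair normalization like
`1/√n_pairs` would retain a residual `√(n/(n−1))` phase-count
dependence).  Pairwise differencing does not cancel noise: each pair
contributes `2σ²` in expectation, which rectifies into a positive floor
wherever defocused light is bright.  When the stack carries a noise
model this expectation (Poisson variance = local widefield mean, plus
read variance) is subtracted before the square root, clipped at zero.

The sectioning benchmark builds a two-plane phantom with in-focus
structures confined to one half of the field and background structures
to the other, and compares the background half's share of the **L2
energy** (Σ image²) between the OS and widefield images; with a 2 µm
defocus and a coarse (10-pixel-period) pattern the OS share is below
0.02× the widefield share — comfortably inside the 0.2× acceptance
bound, which also holds with margin to spare for the residual
noise-floor fluctuations that survive the bias subtraction.

## Metrology

Bead FWHMs are isotropic 2D Gaussian + offset least-squares fits,
`FWHM = 2√(2 ln 2)·σ·pixel`; fits that fail or pin σ at a bound raise
(and are excluded, with indices reported, by the per-field aggregator).
Reported values are raw: convolution with the 100 nm bead inflates the
measured width above the true PSF FWHM and no bead-size deconvolution is
applied.  Two-point resolvability uses the interpolated profile through
both centres and a Rayleigh-like criterion: resolved iff two maxima exist
with an intervening dip at least 10% (configurable) below the lower
maximum.  Spectral support is the largest radius at which the azimuthally
averaged log-power exceeds a high-frequency noise floor (99th percentile
of the outer 15% of radii) by 0.5 decades; a spectrum that never rises
above its own floor (white noise) is reported as supported to the edge.

## Synthetic data: what it does and does not show

The generators reproduce the geometry of the standard bench tests (bead
fields with enforced separations, sub-diffraction pairs, two-plane
scenes) under exactly known optics and noise.  Passing benchmarks
therefore demonstrate the *algorithmic* claims — contrast attenuation by
`T(ρ)`, band recombination up to the two-fold bound, square-law
sectioning — under ideal conditions.  They do not capture: aberrations
or field-dependent PSFs, imperfect polarization contrast, SLM defects or
timing jitter, fluorophore photophysics (bleaching, blinking), camera
fixed-pattern noise, or 3D structure beyond the single defocused plane.
Measured hardware values are correspondingly *upper bounds* for the
simulation: the benchmark asserts the simulated SR-SIM and widefield
bead FWHMs do not exceed the bench-measured 169 nm and 294 nm, and the
aberration-free simulation lands well below both (≈101 nm and ≈197 nm).

## Problem sizes and determinism

The shipped benchmarks use 512² camera fields (640² SLM regions, 2560²
projection grids), 20 beads, 12 or 9 frames — a full run of the bead
experiment takes well under a minute; unit tests run on 256² fields.
Every stochastic step (bead placement, shot/read noise) flows from
explicit integer seeds through `numpy.random.default_rng`, and the
acceptance script derives all of its seeds from one `--seed` argument.

## Known limitations

* 2D only; the defocus model is a Gaussian approximation.
* 4-phase pattern-phase *estimation* carries the documented
  identifiability bias (metadata phases, the default, are exact).
* The estimated-path frequency search requires either metadata
  initialization or a clearly dominant fundamental; sparse scenes with
  patterns very close to the emission cutoff are at the edge of what any
  correlation-based estimator can do.
* Repertoire export aims at "ordered multi-page TIFF + human-readable
  sidecar" interoperability; no byte-level compatibility with any
  specific reconstruction package's container format is claimed.
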