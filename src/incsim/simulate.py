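"""Forward model: project binary SLM patterns and simulate raw acquisitions.

Image formation follows the direct-projection (non-interference) scheme:
the binary SLM mask is imaged into the sample plane through the excitation
path, so the illumination is the mask resampled to the sample grid and
low-pass filtered by the *incoherent excitation OTF* — pattern harmonics
beyond the cutoff vanish and the fundamental arrives with contrast
``T(rho)``.  Fluorescence is the pointwise product of illumination and
fluorophore density, blurred by the emission PSF, scaled to a photon
budget, and detected with Poisson shot noise plus Gaussian read noise.

SLM-to-sample resampling is done by Fourier zero-padding/cropping (exact
for band-limited signals); with the default matched pixel pitches the
projected SLM grid coincides with the camera sample grid and resampling is
the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .config import OpticalConfig
from .fourier import fourier_resample
from .optics import otf_model, otf_on_grid
from .patterns import PatternSequence
from .phantoms import Phantom

__all__ = ["NoiseModel", "RawStack", "project_pattern", "simulate_acquisition"]

#: refractive index of immersion oil, used in the defocus model
N_OIL = 1.518

#: tolerated out-of-band energy fraction when downsampling a projected pattern
ALIAS_TOL = 1e-6


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: photon budget, read noise and RNG seed.

    ``peak_photons`` scales the scene so the brightest pixel of the
    fully-illuminated widefield image carries that many expected photons;
    0 disables shot noise entirely (frames stay in arbitrary linear units).
    """

    peak_photons: float = 1e4
    read_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_photons < 0:
            raise ValueError("peak_photons must be >= 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")

    def to_dict(self) -> dict:
        return {
            "peak_photons": float(self.peak_photons),
            "read_sigma": float(self.read_sigma),
            "seed": int(self.seed),
        }


@dataclass
class RawStack:
    """Per-pattern camera frames plus the provenance needed to reconstruct."""

    frames: NDArray[np.float64]  # (n_frames, H, W), photons
    sequence: PatternSequence | None
    config: OpticalConfig
    noise: NoiseModel | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.sequence is not None and len(self.sequence) != len(self.frames):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.sequence)} patterns"
            )

    def __len__(self) -> int:
        return len(self.frames)


def project_pattern(
    mask: np.ndarray, config: OpticalConfig, oversample: int = 4
) -> NDArray[np.float64]:
    """Image a binary SLM mask into the sample plane.

    Returns the illumination map in [0, 1] on the camera sample grid: the
    mask, resampled by the SLM→sample demagnification and low-pass
    filtered by the incoherent excitation OTF.  The mean (DC) level of the
    mask is preserved.

    The SLM transmission is piecewise constant over pixel cells, so the
    mask is first replicated onto an ``oversample``-times finer grid (a
    cell-accurate representation whose Nyquist frequency lies far above
    the excitation cutoff — pattern harmonics are then removed by the OTF
    instead of folding into the passband), filtered, and Fourier-cropped
    to the camera sample grid.
    """
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary {0, 1}")
    m = mask.astype(float)

    ratio = config.slm_sample_pixel / config.sample_pixel
    out_shape = (m.shape[0] * ratio, m.shape[1] * ratio)
    rounded = (round(out_shape[0]), round(out_shape[1]))
    if not (np.isclose(out_shape[0], rounded[0], atol=1e-6)
            and np.isclose(out_shape[1], rounded[1], atol=1e-6)):
        raise ValueError(
            f"SLM/sample pixel ratio {ratio} does not map a {m.shape} mask "
            "onto an integer sample grid; choose commensurate pitches"
        )
    if min(rounded) < 8:
        raise ValueError("projected pattern smaller than 8x8 sample pixels")

    fine = np.repeat(np.repeat(m, oversample, axis=0), oversample, axis=1)
    fine_pixel = config.slm_sample_pixel / oversample
    ex = otf_model(config, "excitation")
    nyquist_fine = 1000.0 / (2.0 * fine_pixel)
    if ex.cutoff >= nyquist_fine:
        raise ValueError(
            "oversampled SLM grid still undersamples the excitation cutoff; "
            "increase `oversample`"
        )
    otf = otf_on_grid(ex, fine.shape, fine_pixel)
    illum = np.fft.ifft2(np.fft.fft2(fine) * otf).real
    try:
        illum = fourier_resample(illum, rounded, alias_tol=ALIAS_TOL)
    except ValueError as exc:
        raise ValueError(
            "pattern frequency unresolvable on the sample grid "
            f"(aliasing): {exc}"
        ) from exc
    return np.clip(illum, 0.0, 1.0)


def _defocus_sigma_nm(defocus_nm: float, config: OpticalConfig) -> float:
    """Gaussian defocus-blur width sigma = defocus * NA / n_oil."""
    return defocus_nm * config.na / N_OIL


def _gaussian_transfer(shape: tuple[int, int], pixel_nm: float, sigma_nm: float):
    fy = np.fft.fftfreq(shape[0], d=pixel_nm)
    fx = np.fft.fftfreq(shape[1], d=pixel_nm)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    return np.exp(-2.0 * np.pi**2 * sigma_nm**2 * f2)


def simulate_acquisition(
    phantom: Phantom,
    seq: PatternSequence,
    config: OpticalConfig,
    noise: NoiseModel | None = None,
) -> RawStack:
    """Simulate one raw SIM acquisition: one camera frame per pattern.

    frame_i = Poisson(s · [(density · illum_i) ⊗ PSF_em + background_i])
              + N(0, read_sigma)

    where ``s`` scales the fully-illuminated widefield peak to
    ``peak_photons``.  A phantom background plane contributes defocused
    light: its density is blurred by a defocused PSF and it sees the
    illumination low-pass filtered by the same defocus kernel, which
    suppresses the pattern modulation out of focus.  Deterministic given
    the noise seed.
    """
    if noise is None:
        noise = NoiseModel(peak_photons=0.0, read_sigma=0.0)
    if not np.isclose(phantom.pixel, config.sample_pixel, rtol=1e-6):
        raise ValueError(
            f"phantom pixel {phantom.pixel} nm does not match the config "
            f"sample pixel {config.sample_pixel} nm"
        )
    D = phantom.density
    illums = [project_pattern(m, config) for m in seq.masks]
    if illums and illums[0].shape != D.shape:
        raise ValueError(
            f"projected pattern shape {illums[0].shape} does not match "
            f"phantom shape {D.shape}"
        )

    em = otf_model(config, "emission")
    otf_em = otf_on_grid(em, D.shape, phantom.pixel)

    def blur_em(img: np.ndarray) -> np.ndarray:
        return np.fft.ifft2(np.fft.fft2(img) * otf_em).real

    gdef = None
    bg = None
    if phantom.background_plane is not None:
        bg, defocus = phantom.background_plane
        sigma = _defocus_sigma_nm(defocus, config)
        gdef = _gaussian_transfer(D.shape, phantom.pixel, sigma)

    expected = []
    for illum in illums:
        sig = blur_em(D * illum)
        if bg is not None:
            illum_def = np.fft.ifft2(np.fft.fft2(illum) * gdef).real
            sig = sig + np.fft.ifft2(np.fft.fft2(bg * illum_def) * otf_em * gdef).real
        expected.append(sig)

    # photon scaling referenced to the fully illuminated widefield image
    if noise.peak_photons > 0:
        wf = blur_em(D)
        if bg is not None:
            wf = wf + np.fft.ifft2(np.fft.fft2(bg) * otf_em * gdef).real
        peak = wf.max()
        scale = noise.peak_photons / peak if peak > 0 else 1.0
    else:
        scale = 1.0

    rng = np.random.default_rng(noise.seed)
    frames = []
    for sig in expected:
        f = scale * sig
        if noise.peak_photons > 0:
            f = rng.poisson(np.clip(f, 0.0, None)).astype(float)
        if noise.read_sigma > 0:
            f = f + rng.normal(0.0, noise.read_sigma, size=f.shape)
        frames.append(f)
    return RawStack(
        frames=np.stack(frames) if frames else np.zeros((0,) + D.shape),
        sequence=seq,
        config=config,
        noise=noise,
    )
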