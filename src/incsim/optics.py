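"""Diffraction-limited incoherent optics: OTF, PSF and contrast curves.

The imaging model is the classical incoherent transfer function of a
circular aperture ("chat" function),

    T(rho) = (2/pi) * (arccos(rho) - rho * sqrt(1 - rho^2)),   rho = nu/nu_c,

with cutoff ``nu_c = 2 NA / lambda``.  When a binary illumination pattern
is imaged (rather than interfered) into the sample plane with LED light,
this same function attenuates the pattern contrast: the fundamental of a
pattern at normalized frequency rho arrives with contrast T(rho), dropping
to zero at the diffraction limit.  A coherent interference pattern keeps
full contrast at any frequency below its cutoff — the two curves are
exposed side by side in :func:`pattern_contrast_curve` because the gap
between them is what separates LED/SLM projection systems from laser
interference systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "OTFModel",
    "incoherent_otf_value",
    "pattern_contrast_curve",
    "widefield_cutoff",
    "otf_model",
    "otf_on_grid",
    "psf_from_otf",
]

#: amplitudes below RING_EPS * max are treated as FFT ringing and clipped
RING_EPS = 1e-9


def incoherent_otf_value(rho: ArrayLike) -> NDArray[np.float64] | float:
    """Incoherent circular-aperture OTF at normalized frequency ``rho``.

    Parameters
    ----------
    rho : array_like
        Spatial frequency divided by the cutoff 2 NA / lambda.  Must be
        non-negative.

    Returns
    -------
    Contrast in [0, 1]; 1 at rho = 0, 0 at and beyond rho = 1.
    """
    r = np.asarray(rho, dtype=float)
    if np.any(r < 0):
        raise ValueError("normalized frequency must be non-negative")
    inside = np.clip(r, 0.0, 1.0)
    val = (2.0 / np.pi) * (np.arccos(inside) - inside * np.sqrt(1.0 - inside**2))
    val = np.where(r >= 1.0, 0.0, val)
    if np.isscalar(rho) or np.ndim(rho) == 0:
        return float(val)
    return val


def pattern_contrast_curve(rhos: ArrayLike, mode: str) -> NDArray[np.float64]:
    """Pattern contrast vs normalized frequency for either illumination mode.

    ``mode='coherent'`` models an interference-generated pattern: unit
    contrast for every frequency below the cutoff.  ``mode='incoherent'``
    models direct imaging of the pattern with spatially incoherent light,
    where the OTF attenuates the contrast.
    """
    r = np.asarray(rhos, dtype=float)
    if np.any(r < 0):
        raise ValueError("normalized frequencies must be non-negative")
    if mode == "coherent":
        return np.where(r < 1.0, 1.0, 0.0)
    if mode == "incoherent":
        return np.asarray(incoherent_otf_value(r), dtype=float)
    raise ValueError(f"unknown contrast mode: {mode!r}")


def widefield_cutoff(config, role: str = "emission") -> float:
    """Incoherent cutoff frequency 2 NA / lambda in cycles/µm."""
    lam_nm = config.wavelength(role)
    return 2.0 * config.na / (lam_nm / 1000.0)


@dataclass(frozen=True)
class OTFModel:
    """Radially symmetric incoherent OTF with a hard cutoff.

    cutoff is stored in cycles/µm (the package's external frequency unit).
    """

    cutoff: float
    wavelength_role: str = "emission"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.wavelength_role not in ("excitation", "emission"):
            raise ValueError(f"bad wavelength role: {self.wavelength_role!r}")

    def value(self, freq_cyc_per_um: ArrayLike) -> NDArray[np.float64] | float:
        """OTF at (non-negative) radial frequency in cycles/µm."""
        return incoherent_otf_value(np.abs(np.asarray(freq_cyc_per_um)) / self.cutoff)


def otf_model(config, role: str) -> OTFModel:
    """Build the diffraction-limited OTF for the excitation or emission path."""
    return OTFModel(cutoff=widefield_cutoff(config, role), wavelength_role=role)


def _freq_grid_cyc_per_um(shape: tuple[int, int], pixel_nm: float):
    """fftfreq-ordered (fy, fx) grids in cycles/µm for a given pixel size."""
    fy = np.fft.fftfreq(shape[0], d=pixel_nm) * 1000.0
    fx = np.fft.fftfreq(shape[1], d=pixel_nm) * 1000.0
    return np.meshgrid(fy, fx, indexing="ij")


def otf_on_grid(model: OTFModel, shape: tuple[int, int], pixel_nm: float) -> NDArray[np.float64]:
    """Sample the radial OTF on an fftfreq-ordered 2D frequency grid."""
    fy, fx = _freq_grid_cyc_per_um(shape, pixel_nm)
    return np.asarray(incoherent_otf_value(np.hypot(fy, fx) / model.cutoff))


def psf_from_otf(model: OTFModel, grid_shape: tuple[int, int], pixel_nm: float) -> NDArray[np.float64]:
    """Real-space PSF by inverse Fourier transform of the radial OTF.

    The grid must sample the cutoff: ``pixel < 1/(2 nu_c)``.  The result is
    centred (fftshifted), non-negative after clipping sub-``RING_EPS``
    ringing, and normalized to unit sum.
    """
    nyquist = 1000.0 / (2.0 * pixel_nm)  # cycles/µm
    if model.cutoff >= nyquist:
        raise ValueError(
            f"grid undersamples the OTF: pixel {pixel_nm} nm gives Nyquist "
            f"{nyquist:.3f} cycles/um but the cutoff is {model.cutoff:.3f}; "
            f"need pixel < {1000.0 / (2.0 * model.cutoff):.1f} nm"
        )
    otf = otf_on_grid(model, grid_shape, pixel_nm)
    psf = np.fft.fftshift(np.fft.ifft2(otf).real)
    peak = psf.max()
    psf[np.abs(psf) < RING_EPS * peak] = 0.0
    psf = np.clip(psf, 0.0, None)
    return psf / psf.sum()
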