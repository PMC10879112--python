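"""Resolution and image-quality metrology.

The resolution metric mirrors standard bead metrology: fit an isotropic 2D
Gaussian (plus constant offset) to each isolated sub-diffraction bead and
report FWHM = 2 sqrt(2 ln 2) sigma in nm.  Note the measured FWHM upper-
bounds the true PSF FWHM — convolution with the finite bead (100 nm)
inflates it slightly; values are reported raw, without bead-size
deconvolution.

Two-point resolvability uses a Rayleigh-like dip criterion on the profile
along the inter-centre axis: resolved iff two local maxima exist with an
intervening minimum at least ``min_dip`` (default 10%) below the lower
maximum.

Spectral support is the largest radius at which the azimuthally averaged
log-power spectrum stays above a percentile-defined high-frequency noise
floor — a quantitative version of eyeballing the FFT of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "FWHMReport",
    "FitError",
    "fit_gaussian_fwhm",
    "mean_fwhm_over_beads",
    "pair_resolved",
    "radial_spectrum_support",
    "max_intensity_projection",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


class FitError(RuntimeError):
    """Raised when a Gaussian fit does not converge or hits its bounds."""


@dataclass
class FWHMReport:
    """Per-bead FWHM values (nm) with summary statistics."""

    per_bead: list[float]
    excluded: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.per_bead)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_bead))

    @property
    def sd(self) -> float:
        return float(np.std(self.per_bead, ddof=1)) if self.n > 1 else 0.0


def _gauss2d(coords, amp, y0, x0, sigma, offset):
    y, x = coords
    return amp * np.exp(-((y - y0) ** 2 + (x - x0) ** 2) / (2 * sigma**2)) + offset


def fit_gaussian_fwhm(
    image: NDArray[np.float64],
    center_guess: tuple[float, float],
    pixel: float,
    window: int = 15,
) -> float:
    """FWHM (nm) of an isotropic 2D Gaussian fit around ``center_guess``.

    ``center_guess`` is (row, col) in pixels; ``pixel`` the grid pitch in
    nm; ``window`` the half-size of the square fit region in pixels.
    """
    r0 = int(round(center_guess[0]))
    c0 = int(round(center_guess[1]))
    lo_r, hi_r = max(0, r0 - window), min(image.shape[0], r0 + window + 1)
    lo_c, hi_c = max(0, c0 - window), min(image.shape[1], c0 + window + 1)
    patch = np.asarray(image[lo_r:hi_r, lo_c:hi_c], dtype=float)
    if patch.size < 9:
        raise FitError("fit window outside the image")
    span = patch.max() - patch.min()
    if span <= 0 or not np.isfinite(span):
        raise FitError("flat or degenerate fit window")

    yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c].astype(float)
    pk = np.unravel_index(int(np.argmax(patch)), patch.shape)
    p0 = (span, lo_r + pk[0], lo_c + pk[1], max(1.0, window / 5.0), patch.min())
    sigma_max = float(window)
    bounds = (
        [0.0, lo_r, lo_c, 0.3, -np.inf],
        [np.inf, hi_r, hi_c, sigma_max, np.inf],
    )
    try:
        popt, _ = curve_fit(
            _gauss2d,
            (yy.ravel(), xx.ravel()),
            patch.ravel(),
            p0=p0,
            bounds=bounds,
            maxfev=5000,
        )
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    sigma = popt[3]
    if sigma <= 0.31 or sigma >= sigma_max * 0.99:
        raise FitError(f"fitted sigma {sigma:.3f} px at the parameter bound")
    return float(FWHM_PER_SIGMA * sigma * pixel)


def mean_fwhm_over_beads(
    image: NDArray[np.float64],
    positions: NDArray[np.float64],
    pixel: float,
    window: int = 15,
) -> FWHMReport:
    """Fit every bead and aggregate; failed fits are excluded and listed.

    ``positions`` is (n, 2) bead centres in *pixels* (row, col).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(positions) == 0:
        raise ValueError("at least one bead position required")
    values: list[float] = []
    excluded: list[int] = []
    for i, pos in enumerate(positions):
        try:
            values.append(fit_gaussian_fwhm(image, tuple(pos), pixel, window))
        except FitError:
            excluded.append(i)
    if not values:
        raise FitError("all bead fits failed")
    return FWHMReport(per_bead=values, excluded=excluded)


def pair_resolved(
    image: NDArray[np.float64],
    center_a: tuple[float, float],
    center_b: tuple[float, float],
    pixel: float,
    min_dip: float = 0.10,
    oversample: int = 4,
    extend: float = 1.0,
) -> tuple[bool, float]:
    """Two-point resolvability along the inter-centre axis.

    Extracts the interpolated intensity profile through both centres
    (extended by ``extend`` times the separation on each side), locates
    local maxima, and declares the pair resolved iff two maxima exist with
    an intervening minimum at least ``min_dip`` below the lower maximum.
    Returns ``(resolved, dip_depth)`` with dip depth relative to the lower
    maximum (0 when unresolved).
    """
    a = np.asarray(center_a, dtype=float)
    b = np.asarray(center_b, dtype=float)
    sep = np.linalg.norm(b - a)
    if sep == 0:
        raise ValueError("bead centres coincide")
    direction = (b - a) / sep
    n = max(16, int(np.ceil(sep * (1 + 2 * extend) * oversample)))
    t = np.linspace(-extend * sep, (1 + extend) * sep, n)
    coords = a[:, None] + direction[:, None] * t[None, :]
    profile = map_coordinates(np.asarray(image, dtype=float), coords, order=3)

    peaks, _ = find_peaks(profile)
    if len(peaks) < 2:
        return False, 0.0
    # two strongest local maxima
    top = peaks[np.argsort(profile[peaks])[-2:]]
    lo_pk, hi_pk = np.sort(top)
    valley = float(profile[lo_pk:hi_pk + 1].min())
    lower_max = float(min(profile[lo_pk], profile[hi_pk]))
    if lower_max <= 0:
        return False, 0.0
    dip = (lower_max - valley) / lower_max
    return bool(dip >= min_dip), float(dip)


def radial_spectrum_support(
    image: NDArray[np.float64],
    pixel: float,
    noise_floor_percentile: float = 99.0,
    margin_decades: float = 0.5,
    floor_radius_fraction: float = 0.85,
) -> float:
    """Radius (cycles/µm) of detectable spectral support.

    Azimuthally averages the log10 power spectrum; the noise floor is the
    given percentile of the average beyond ``floor_radius_fraction`` of the
    maximum radius; the support is the largest radius whose average exceeds
    floor + ``margin_decades``.  If no radius exceeds the floor the
    spectrum is flat out to the edge (noise-like, no band limit) and the
    maximum represented radius is returned.
    """
    img = np.asarray(image, dtype=float)
    if img.shape[0] < 64 or img.shape[1] < 64:
        raise ValueError("image must be at least 64x64 for a stable spectrum")
    if np.ptp(img) == 0:
        raise ValueError("constant image has no spectral support")
    ps = np.abs(np.fft.fft2(img - img.mean())) ** 2
    fy = np.fft.fftfreq(img.shape[0], d=pixel) * 1000.0
    fx = np.fft.fftfreq(img.shape[1], d=pixel) * 1000.0
    rad = np.hypot(fy[:, None], fx[None, :])
    rmax = min(abs(fy).max(), abs(fx).max())
    nbins = min(img.shape) // 2
    edges = np.linspace(0.0, rmax, nbins + 1)
    idx = np.digitize(rad.ravel(), edges) - 1
    valid = (idx >= 0) & (idx < nbins)
    logp = np.log10(ps.ravel() + 1e-300)
    prof = np.full(nbins, -np.inf)
    counts = np.bincount(idx[valid], minlength=nbins)
    sums = np.bincount(idx[valid], weights=logp[valid], minlength=nbins)
    nonzero = counts > 0
    prof[nonzero] = sums[nonzero] / counts[nonzero]
    centers = 0.5 * (edges[:-1] + edges[1:])
    outer = nonzero & (centers >= floor_radius_fraction * rmax)
    if not np.any(outer):
        raise ValueError("no high-frequency bins available for the noise floor")
    floor = np.percentile(prof[outer], noise_floor_percentile)
    above = nonzero & (prof > floor + margin_decades)
    if not np.any(above):
        # spectrum indistinguishable from its own floor everywhere:
        # broadband (noise-like) image, supported out to the edge
        return float(rmax)
    return float(centers[np.max(np.nonzero(above))])


def max_intensity_projection(stack_of_planes: NDArray[np.float64], axis: int = 0):
    """Pixelwise maximum over planes."""
    arr = np.asarray(stack_of_planes)
    if arr.size == 0:
        raise ValueError("empty stack")
    return arr.max(axis=axis)
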