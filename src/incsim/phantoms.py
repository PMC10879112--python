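"""Synthetic fluorophore phantoms for resolution and sectioning tests.

The phantoms mirror the standard bench tests for a SIM system: fields of
isolated 100 nm beads for PSF/FWHM metrology, sub-diffraction bead pairs
for two-point resolution, and two-plane scenes (in-focus structure plus a
defocused background plane) for optical-sectioning measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "Phantom",
    "generate_bead_phantom",
    "generate_bead_pair",
    "generate_two_plane_phantom",
]


@dataclass
class Phantom:
    """A 2D fluorophore density map on the sample grid.

    density is in expected photons per pixel at unit illumination.  An
    optional ``background_plane`` is a second density map located
    ``defocus`` nm out of the focal plane, used for sectioning phantoms.
    ``positions`` records generator ground-truth emitter centres in nm
    (row, col) when available.
    """

    density: NDArray[np.float64]
    pixel: float  # nm
    background_plane: tuple[NDArray[np.float64], float] | None = None
    positions: NDArray[np.float64] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.pixel <= 0:
            raise ValueError("pixel size must be positive")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if self.background_plane is not None:
            bg, defocus = self.background_plane
            if bg.shape != self.density.shape:
                raise ValueError("background plane must match the focal shape")
            if defocus <= 0:
                raise ValueError("defocus must be positive (use a plain phantom)")


def _rasterize_disk(density: np.ndarray, center_rc_px: tuple[float, float], radius_px: float,
                    amplitude: float) -> None:
    """Add a uniform disk: pixels whose centre lies inside the radius."""
    r0, c0 = center_rc_px
    lo_r = max(0, int(np.floor(r0 - radius_px - 1)))
    hi_r = min(density.shape[0], int(np.ceil(r0 + radius_px + 2)))
    lo_c = max(0, int(np.floor(c0 - radius_px - 1)))
    hi_c = min(density.shape[1], int(np.ceil(c0 + radius_px + 2)))
    rr = np.arange(lo_r, hi_r, dtype=float)[:, None]
    cc = np.arange(lo_c, hi_c, dtype=float)[None, :]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    density[lo_r:hi_r, lo_c:hi_c] += amplitude * inside


def generate_bead_phantom(
    n_beads: int,
    shape: tuple[int, int],
    pixel: float,
    *,
    bead_diameter: float = 100.0,
    min_separation: float = 1000.0,
    seed: int = 0,
    amplitude: float = 1.0,
    margin: float = 1500.0,
    max_attempts: int = 10_000,
) -> Phantom:
    """Field of isolated uniform-intensity beads at rejection-sampled positions.

    Parameters are in nm except ``shape`` (pixels).  ``margin`` keeps beads
    away from the field edges so fit windows stay inside the image.
    Raises if ``n_beads`` cannot be placed within ``max_attempts`` draws.
    """
    if min_separation <= bead_diameter:
        raise ValueError("min_separation must exceed the bead diameter")
    rng = np.random.default_rng(seed)
    density = np.zeros(shape, dtype=float)
    field_nm = (shape[0] * pixel, shape[1] * pixel)
    if n_beads > 0 and (field_nm[0] <= 2 * margin or field_nm[1] <= 2 * margin):
        raise ValueError("field too small for the requested margin")
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_beads:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_beads} beads with min separation "
                f"{min_separation} nm in {max_attempts} attempts"
            )
        attempts += 1
        cand = (
            rng.uniform(margin, field_nm[0] - margin),
            rng.uniform(margin, field_nm[1] - margin),
        )
        if all(np.hypot(cand[0] - y, cand[1] - x) >= min_separation for y, x in centers):
            centers.append(cand)
    radius_px = bead_diameter / 2.0 / pixel
    for y, x in centers:
        _rasterize_disk(density, (y / pixel, x / pixel), radius_px, amplitude)
    return Phantom(
        density=density,
        pixel=pixel,
        positions=np.asarray(centers, dtype=float).reshape(-1, 2),
    )


def generate_bead_pair(
    separation: float,
    shape: tuple[int, int],
    pixel: float,
    *,
    bead_diameter: float = 100.0,
    amplitude: float = 1.0,
) -> Phantom:
    """Two identical beads ``separation`` nm apart, centred in the field.

    The pair is oriented along the image x-axis (columns).
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if separation < pixel:
        raise ValueError(
            f"separation {separation} nm is below one pixel ({pixel} nm)"
        )
    density = np.zeros(shape, dtype=float)
    cy = (shape[0] - 1) / 2.0 * pixel
    cx = (shape[1] - 1) / 2.0 * pixel
    centers = [(cy, cx - separation / 2.0), (cy, cx + separation / 2.0)]
    radius_px = bead_diameter / 2.0 / pixel
    for y, x in centers:
        _rasterize_disk(density, (y / pixel, x / pixel), radius_px, amplitude)
    return Phantom(density=density, pixel=pixel,
                   positions=np.asarray(centers, dtype=float))


def generate_two_plane_phantom(
    focal_map: NDArray[np.float64],
    background_map: NDArray[np.float64],
    defocus: float,
    pixel: float,
) -> Phantom:
    """In-focus structure plus a background plane ``defocus`` nm away.

    When simulated, the background plane is blurred by a defocused PSF and
    sees a defocus-attenuated illumination pattern, so it contributes
    out-of-focus light with (nearly) no pattern modulation.
    """
    if focal_map.shape != background_map.shape:
        raise ValueError("focal and background maps must share a shape")
    if defocus <= 0:
        raise ValueError("defocus must be positive; use a single-plane phantom")
    return Phantom(
        density=np.asarray(focal_map, dtype=float),
        pixel=pixel,
        background_plane=(np.asarray(background_map, dtype=float), float(defocus)),
    )
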