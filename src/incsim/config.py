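"""Optical configuration shared by every stage of the pipeline.

All frequency/space scales in the package derive from a single
:class:`OpticalConfig`: the objective (NA, magnification), the excitation
and emission wavelengths, and the physical pixel pitches of the camera and
of the spatial light modulator (SLM).  Sample-plane pixel sizes are always
*derived* from these, never stored independently.

Unit conventions
----------------
* wavelengths and sample-plane pixels: nanometres
* physical device pixel pitches (camera, SLM): micrometres
* spatial frequencies at the public API: cycles/µm
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OpticalConfig:
    """Objective, wavelengths and device pixel pitches.

    Parameters
    ----------
    na : float
        Numerical aperture of the objective, 0 < NA <= 1.7.
    magnification : float
        Total magnification between sample plane and camera / SLM plane.
    lambda_ex : float
        Excitation (illumination) wavelength in nm.
    lambda_em : float
        Emission (fluorescence) wavelength in nm.
    camera_pixel : float
        Camera pixel pitch in µm.
    slm_pixel : float
        SLM pixel pitch in µm.  The SLM sits in an image plane, so one SLM
        pixel projects to ``slm_pixel / magnification`` in the sample.
    """

    na: float = 1.3
    magnification: float = 100.0
    lambda_ex: float = 460.0
    lambda_em: float = 515.0
    camera_pixel: float = 6.5
    slm_pixel: float = 5.2

    def __post_init__(self) -> None:
        if not 0.0 < self.na <= 1.7:
            raise ValueError(f"NA must be in (0, 1.7], got {self.na}")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        for name in ("lambda_ex", "lambda_em"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("camera_pixel", "slm_pixel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def sample_pixel(self) -> float:
        """Sample-plane pixel of the camera in nm (camera_pixel / M)."""
        return self.camera_pixel / self.magnification * 1000.0

    @property
    def slm_sample_pixel(self) -> float:
        """Projected size of one SLM pixel in the sample plane, in nm."""
        return self.slm_pixel / self.magnification * 1000.0

    def wavelength(self, role: str) -> float:
        """Wavelength in nm for ``role`` ('excitation' or 'emission')."""
        if role == "excitation":
            return self.lambda_ex
        if role == "emission":
            return self.lambda_em
        raise ValueError(f"unknown wavelength role: {role!r}")

    def to_dict(self) -> dict:
        return {
            "na": self.na,
            "magnification": self.magnification,
            "lambda_ex": self.lambda_ex,
            "lambda_em": self.lambda_em,
            "camera_pixel": self.camera_pixel,
            "slm_pixel": self.slm_pixel,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        return cls(**{k: float(v) for k, v in d.items()})
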