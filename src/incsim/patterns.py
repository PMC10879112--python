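"""Binary SLM line-pattern repertoires.

An LCOS microdisplay used in amplitude mode is a binary mask: each pixel
either transmits or blocks.  SIM repertoires are sets of periodic line
patterns at a few orientations, phase-stepped along the pattern normal so
that (a) the frequency-shifted information can be separated during
reconstruction and (b) the summed illumination over the repertoire is
homogeneous.  Patterns at different orientations are built with the same
duty cycle so the mark-to-area ratio (MAR, the switched-on fraction of the
display) — and hence the delivered dose — matches across angles.

Rasterization rule: a pixel is ON iff its centre's fractional position
along the pattern normal, offset by ``phase_index/n_phases`` of a period,
falls inside the duty window.  No anti-aliasing: LCOS pixels are binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "PatternSpec",
    "PatternSequence",
    "make_line_pattern",
    "mark_to_area_ratio",
    "build_repertoire",
    "homogeneity_residual",
    "mar_uniformity",
    "PRESETS",
]

#: preset name -> list of (angle_deg, n_phases)
#
# minimal9 is the textbook isotropic set (3 orientations 60° apart, 3 phases
# 120° apart).  The 4-phase repertoires use lattice directions (0°, 45°,
# 90°, 135°) instead: on a square pixel grid only those orientations
# rasterize to exactly periodic binary patterns, while e.g. 60° lines
# acquire Moiré side components that leak into the ±1 bands under 4-phase
# stepping (3-phase stepping folds the offending order into the 0 band,
# which is why minimal9 tolerates its diagonals).
PRESETS: dict[str, list[tuple[float, int]]] = {
    "minimal9": [(0.0, 3), (60.0, 3), (120.0, 3)],
    "bio12": [(0.0, 4), (45.0, 4), (90.0, 4)],
    "fixed14": [(0.0, 4), (45.0, 3), (90.0, 4), (135.0, 3)],
}


@dataclass(frozen=True)
class PatternSpec:
    """One line pattern: orientation, period, phase step and duty cycle.

    angle is in degrees CCW from the image x-axis (the stripe direction);
    period is in SLM pixels along the pattern normal and may be
    non-integer (diagonal lattice directions).
    """

    angle: float
    period: float
    phase_index: int
    n_phases: int
    duty: float = 0.5

    def __post_init__(self) -> None:
        if self.period < 2.0:
            raise ValueError(f"period must be >= 2 SLM pixels, got {self.period}")
        if not 0.0 < self.duty < 1.0:
            raise ValueError(f"duty must be in (0, 1), got {self.duty}")
        if not 0 <= self.phase_index < self.n_phases:
            raise ValueError(
                f"phase_index {self.phase_index} outside [0, {self.n_phases})"
            )

    @property
    def phase(self) -> float:
        """Phase offset in radians (2π · phase_index / n_phases)."""
        return 2.0 * np.pi * self.phase_index / self.n_phases

    def to_dict(self) -> dict:
        return {
            "angle": float(self.angle),
            "period": float(self.period),
            "phase_index": int(self.phase_index),
            "n_phases": int(self.n_phases),
            "duty": float(self.duty),
        }


@dataclass
class PatternSequence:
    """Ordered binary masks with their generating specs."""

    masks: list[NDArray[np.uint8]]
    specs: list[PatternSpec]
    shape: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.masks) != len(self.specs):
            raise ValueError("masks and specs must have equal length")
        if self.masks:
            if self.shape is None:
                self.shape = self.masks[0].shape
            for m in self.masks:
                if m.shape != tuple(self.shape):
                    raise ValueError("all masks must share one shape")
                _check_binary(m)

    def __len__(self) -> int:
        return len(self.masks)

    def angles(self) -> list[float]:
        """Distinct orientations in order of first appearance."""
        seen: list[float] = []
        for s in self.specs:
            if s.angle not in seen:
                seen.append(s.angle)
        return seen

    def by_angle(self) -> dict[float, list[int]]:
        """Frame indices grouped by orientation."""
        groups: dict[float, list[int]] = {}
        for i, s in enumerate(self.specs):
            groups.setdefault(s.angle, []).append(i)
        return groups


def _check_binary(mask: np.ndarray) -> None:
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be strictly binary {0, 1}")


def make_line_pattern(spec: PatternSpec, shape: tuple[int, int]) -> NDArray[np.uint8]:
    """Rasterize one binary line pattern on the SLM pixel grid.

    Pixel (r, c) is ON iff ``frac(u/period - phase_index/n_phases)`` falls
    in ``[0, duty)`` where ``u = r cos(angle) + c sin(angle)`` is the pixel
    centre's coordinate along the pattern normal.  angle = 0 gives
    horizontal stripes; angle = 90 gives their transpose.
    """
    if shape[0] < 8 or shape[1] < 8:
        raise ValueError(f"shape must be at least 8x8, got {shape}")
    theta = np.deg2rad(spec.angle)
    r = np.arange(shape[0], dtype=float)[:, None]
    c = np.arange(shape[1], dtype=float)[None, :]
    u = r * np.cos(theta) + c * np.sin(theta)
    frac = np.mod(u / spec.period - spec.phase_index / spec.n_phases, 1.0)
    # lattice points that land exactly on a window boundary accumulate
    # ±1 ulp float noise; round so the on/off decision is consistent for
    # equal fractional positions (and frac == 1.0 - eps wraps to 0 = ON)
    frac = np.round(frac, 9)
    frac = np.where(frac >= 1.0, frac - 1.0, frac)
    return (frac < spec.duty).astype(np.uint8)


def mark_to_area_ratio(mask: np.ndarray) -> float:
    """Fraction of SLM pixels switched on (the MAR)."""
    _check_binary(mask)
    return float(np.count_nonzero(mask)) / mask.size


def _diagonal_period(base_period: float) -> float:
    """Nearest lattice-representable period along a 45° direction.

    Along a diagonal, pixel centres advance in steps of sqrt(2)/2 along the
    pattern normal, so representable periods are multiples of that step.
    """
    step = np.sqrt(2.0) / 2.0
    k = max(3, round(base_period / step))  # keep >= 2 px
    return k * step


def build_repertoire(
    preset: str,
    shape: tuple[int, int],
    base_period: float,
    duty: float = 0.5,
) -> PatternSequence:
    """Build a named pattern repertoire (angle-major, phase-minor order).

    Presets
    -------
    ``minimal9``
        3 orientations (0°, 60°, 120°) × 3 phases 120° apart.
    ``bio12``
        3 orientations (0°, 60°, 120°) × 4 phases 90° apart.
    ``fixed14``
        4 orientations (0°, 45°, 90°, 135°) with 4+3+4+3 phases; the
        diagonal periods are snapped to the pixel lattice so the
        sample-plane spatial frequency stays consistent across angles.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    specs: list[PatternSpec] = []
    masks: list[NDArray[np.uint8]] = []
    for angle, n_phases in PRESETS[preset]:
        period = base_period
        if np.isclose(angle % 90.0, 45.0):
            period = _diagonal_period(base_period)
        for phase_index in range(n_phases):
            s = PatternSpec(
                angle=angle,
                period=period,
                phase_index=phase_index,
                n_phases=n_phases,
                duty=duty,
            )
            specs.append(s)
            masks.append(make_line_pattern(s, shape))
    return PatternSequence(masks=masks, specs=specs, shape=tuple(shape))


def homogeneity_residual(seq: PatternSequence, border: int = 0) -> float:
    """Max relative deviation of the summed illumination from its mean.

    ``S(r, c)`` is the pixelwise sum over all masks; the residual is
    ``max |S - mean(S)| / mean(S)``.  0 means the repertoire tiles the
    display perfectly.  ``border`` pixels can be excluded at each edge.
    """
    if len(seq) == 0:
        raise ValueError("empty pattern sequence")
    S = np.sum(np.stack([m.astype(float) for m in seq.masks]), axis=0)
    if border > 0:
        S = S[border:-border, border:-border]
    mean = S.mean()
    if mean == 0:
        raise ValueError("all-off sequence: homogeneity undefined (mean 0)")
    return float(np.max(np.abs(S - mean)) / mean)


def mar_uniformity(seq: PatternSequence) -> float:
    """Max pairwise difference of per-angle mean MAR across orientations."""
    groups = seq.by_angle()
    if len(groups) < 2:
        raise ValueError("MAR uniformity needs at least 2 orientations")
    per_angle = {
        a: float(np.mean([mark_to_area_ratio(seq.masks[i]) for i in idx]))
        for a, idx in groups.items()
    }
    return max(
        abs(per_angle[a] - per_angle[b]) for a, b in combinations(per_angle, 2)
    )
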