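"""SR-SIM and OS-SIM reconstruction from raw pattern stacks.

Super-resolution path (classical frequency-domain recombination): for each
orientation the phase-stepped frames are separated into the unshifted band
S0 and the two frequency-shifted bands S±1 by inverting the linear mixing

    F_i = S0 + e^{-i phi_i} S+1 + e^{+i phi_i} S-1 ,

the side bands are moved back by the pattern frequency k on a two-fold
upsampled Fourier grid (sub-pixel shifts via real-space phase ramps),
rescaled to a common amplitude using the measured modulation depth, and
all bands are recombined with a generalized Wiener filter weighted by each
band's OTF, followed by triangle apodization over the extended support
``|k_max| + emission cutoff``.

Optical-sectioning path: square-law detection.  Only in-focus structure
carries pattern modulation, so the root-sum of squared pairwise frame
differences per orientation isolates the modulated (in-focus) component
and rejects the defocused background; the result is normalized to be
independent of the phase origin and of the number of phase steps.

Pattern parameters (frequency vector and phases per orientation) are
estimated from the data by default, since nominal hardware phases are only
approximate; metadata values can be requested instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import minimize

from .fourier import fourier_resample
from .optics import incoherent_otf_value, widefield_cutoff
from .simulate import RawStack

__all__ = [
    "ReconstructionParams",
    "SRResult",
    "OSResult",
    "PatternEstimationError",
    "widefield_from_stack",
    "estimate_pattern_parameters",
    "separate_bands",
    "reconstruct_sr_sim",
    "reconstruct_os_sim",
]


class PatternEstimationError(RuntimeError):
    """Raised when no significant pattern peak can be located in a stack."""


@dataclass(frozen=True)
class ReconstructionParams:
    """Knobs of the SR recombination.

    wiener_w is the Wiener regularization relative to the peak OTF;
    apodization is 'triangle' (Lukosz ramp to the passband edge) or 'none';
    phase_source selects metadata pattern parameters (the default: the
    repertoire's rasterized masks determine the realized frequencies and
    phases exactly) or estimation from the frames (for stacks whose
    metadata is nominal or missing); upsample is the Fourier zero-padding
    factor (1 or 2).
    """

    wiener_w: float = 0.05
    apodization: str = "triangle"
    phase_source: str = "metadata"
    upsample: int = 2

    def __post_init__(self) -> None:
        if self.wiener_w <= 0:
            raise ValueError("wiener_w must be positive")
        if self.apodization not in ("none", "triangle"):
            raise ValueError(f"unknown apodization {self.apodization!r}")
        if self.phase_source not in ("metadata", "estimated"):
            raise ValueError(f"unknown phase_source {self.phase_source!r}")
        if self.upsample not in (1, 2):
            raise ValueError("upsample must be 1 or 2")

    def to_dict(self) -> dict:
        return {
            "wiener_w": self.wiener_w,
            "apodization": self.apodization,
            "phase_source": self.phase_source,
            "upsample": self.upsample,
        }


@dataclass
class SRResult:
    """Super-resolved image plus the pattern parameters actually used."""

    image: NDArray[np.float64]
    pixel: float  # nm, of the (possibly upsampled) output grid
    k_est: dict[float, tuple[float, float]]  # angle -> (ky, kx) cycles/µm
    phases_est: dict[float, list[float]]  # angle -> phases (rad)
    passband_radius: float  # cycles/µm
    params: ReconstructionParams = field(default_factory=ReconstructionParams)


@dataclass
class OSResult:
    """Optically sectioned image (square-law demodulation)."""

    image: NDArray[np.float64]
    pixel: float  # nm
    method: str = "square-law"


def widefield_from_stack(stack: RawStack) -> NDArray[np.float64]:
    """Pixelwise mean of the frames — the equivalent widefield image.

    Valid because a homogeneous repertoire sums to a uniform effective
    illumination.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    return stack.frames.mean(axis=0)


def _angle_groups(stack: RawStack) -> dict[float, list[int]]:
    if stack.sequence is None:
        raise ValueError("stack carries no pattern-sequence metadata")
    return stack.sequence.by_angle()


def _nominal_parameters(stack: RawStack) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Pattern k (cycles/µm, (ky,kx)) and phases from sequence metadata.

    The frequency vector follows from the spec'd period and orientation.
    Phases are read from the rasterized masks themselves (single-frequency
    DFT at k on the SLM grid): binary rasterization quantizes the phase
    steps of lattice-incommensurate patterns, so the realized phases can
    differ from the nominal ``2π·phase_index/n_phases`` grid, and the
    masks are the ground truth the projection optics actually sees.
    """
    out: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    slm_pixel = stack.config.slm_sample_pixel
    for angle, idx in _angle_groups(stack).items():
        spec = stack.sequence.specs[idx[0]]
        period_nm = spec.period * slm_pixel
        mag = 1000.0 / period_nm  # cycles/µm
        theta = np.deg2rad(angle)
        kvec = np.array([np.cos(theta), np.sin(theta)]) * mag
        k_cpp_slm = kvec * slm_pixel / 1000.0
        phases = []
        for i in idx:
            mask = stack.sequence.masks[i].astype(complex)
            c = _single_freq_dft(mask, k_cpp_slm)
            if abs(c) < 1e-3 * mask.size:
                # unmodulated mask: no fundamental to read a phase from,
                # keep the nominal phase grid
                phases.append(stack.sequence.specs[i].phase)
            else:
                phases.append(float((-np.angle(c)) % (2 * np.pi)))
        out[angle] = (kvec, np.asarray(phases))
    return out


def separate_bands(
    frames: NDArray[np.float64], phases
) -> tuple[NDArray[np.complex128], NDArray[np.complex128], NDArray[np.complex128]]:
    """Invert the phase-mixing system into (S0, S+1, S-1) components.

    ``frames`` is (n, H, W) with n >= 3; ``phases`` the n pattern phases in
    radians, pairwise distinct modulo 2π.  Solved exactly for 3 phases and
    by least squares for more.  The returned components are complex images
    in real space; their Fourier transforms are the unshifted and the two
    frequency-shifted object bands.
    """
    frames = np.asarray(frames, dtype=float)
    phases = np.asarray(phases, dtype=float)
    n = len(frames)
    if n < 3:
        raise ValueError(f"band separation needs >= 3 phases, got {n}")
    if len(phases) != n:
        raise ValueError("one phase per frame required")
    M = np.stack(
        [np.ones(n), np.exp(-1j * phases), np.exp(1j * phases)], axis=1
    )
    if np.linalg.cond(M) > 1e8:
        raise ValueError(
            "singular phase-mixing matrix: phases must be pairwise distinct "
            "modulo 2π"
        )
    flat = frames.reshape(n, -1)
    sol, *_ = np.linalg.lstsq(M, flat, rcond=None)
    H, W = frames.shape[1:]
    # for real frames the solution has S0 real (DC real-positive) and
    # S-1 = conj(S+1); the exact lstsq solution preserves the remix
    # round-trip F_i = S0 + e^{-i phi_i} S+1 + e^{+i phi_i} S-1
    return sol[0].reshape(H, W), sol[1].reshape(H, W), sol[2].reshape(H, W)


def _single_freq_dft(q: NDArray[np.complex128], k_cpp: np.ndarray) -> complex:
    """DFT of q at one (possibly non-integer) frequency in cycles/pixel."""
    H, W = q.shape
    ey = np.exp(-2j * np.pi * k_cpp[0] * np.arange(H))
    ex = np.exp(-2j * np.pi * k_cpp[1] * np.arange(W))
    return complex(ey @ q @ ex)


def _estimate_angle(
    frames: NDArray[np.float64],
    nominal_phases: np.ndarray,
    pixel_nm: float,
    k_min_cyc_um: float,
    k_nominal: np.ndarray | None = None,
    search_frac: float = 0.2,
    peak_snr: float = 2.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate (k cycles/µm, phases) for one orientation group.

    The product ``conj(S0) * S+1`` oscillates at the pattern frequency
    with the object envelope, so the magnitude of its Fourier transform
    carries a sharp peak (the emitter structure factor) at k riding on a
    broad envelope.  With a nominal frequency from pattern metadata the
    peak is refined locally from the nominal value and must stay within
    ``search_frac`` of it; without metadata, a global grid search above
    ``k_min_cyc_um`` locates it first.  In both cases the refined peak
    must exceed ``peak_snr`` times the median spectral floor, otherwise
    the stack is flagged as unmodulated.
    """
    s0, sp, _ = separate_bands(frames, nominal_phases)
    q = np.conj(s0) * sp
    Q = np.abs(np.fft.fft2(q))
    fy = np.fft.fftfreq(q.shape[0], d=pixel_nm) * 1000.0
    fx = np.fft.fftfreq(q.shape[1], d=pixel_nm) * 1000.0
    rad = np.hypot(fy[:, None], fx[None, :])
    allowed = rad >= k_min_cyc_um
    if not np.any(allowed):
        raise PatternEstimationError("frequency search region is empty")

    if k_nominal is not None:
        k0_cpp = np.asarray(k_nominal, dtype=float) * pixel_nm / 1000.0
    else:
        vals = np.where(allowed, Q, 0.0)
        peak_idx = np.unravel_index(int(np.argmax(vals)), Q.shape)
        peak = vals[peak_idx]
        floor = np.median(Q[allowed])
        if floor <= 0 or peak / floor < peak_snr:
            raise PatternEstimationError(
                "no significant pattern peak found (uniform or unmodulated "
                "illumination?)"
            )
        k0_cpp = np.array(
            [peak_idx[0] / q.shape[0], peak_idx[1] / q.shape[1]], dtype=float
        )
        k0_cpp = (k0_cpp + 0.5) % 1.0 - 0.5  # wrap into (-0.5, 0.5]

    def neg(k):
        return -np.abs(_single_freq_dft(q, np.asarray(k)))

    step = 1.0 / max(q.shape)
    res = minimize(
        neg,
        k0_cpp,
        method="Nelder-Mead",
        options={
            "xatol": step * 1e-4,
            "fatol": 0.0,
            "maxiter": 200,
            "initial_simplex": k0_cpp + step * np.array(
                [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]
            ),
        },
    )
    k_cpp = np.asarray(res.x)
    peak_val = float(np.abs(_single_freq_dft(q, k_cpp)))
    floor = float(np.median(Q[allowed]))
    if floor <= 0 or peak_val / floor < peak_snr:
        raise PatternEstimationError(
            "no significant pattern peak found (uniform or unmodulated "
            "illumination?)"
        )
    if k_nominal is not None:
        drift = np.linalg.norm(k_cpp - k0_cpp)
        if drift > search_frac * np.linalg.norm(k0_cpp):
            raise PatternEstimationError(
                "refined pattern frequency drifted away from the nominal "
                "value; estimation unreliable"
            )

    phases = _refine_phases(frames, k_cpp)
    k_cyc_um = k_cpp / pixel_nm * 1000.0
    return k_cyc_um, phases


def _als_phases(p: np.ndarray, iters: int = 30) -> np.ndarray:
    """Solve ``p_i = alpha e^{-i phi_i} + beta e^{+i phi_i}`` for the phases.

    alpha is the matched +1-band response and beta a speckle cross-term
    from the -1 band; the beta-blind estimate ``-arg(p_i)`` is biased by
    ~|beta/alpha| radians.  Alternating least squares over (alpha, beta)
    and per-frame unit-modulus roots of ``beta z^2 - p z + alpha = 0``
    removes the bias.  Only sound for 3 phase steps: with 4 equally
    spaced steps the two-term model is non-identifiable (a one-parameter
    family of phase sets reproduces any readout exactly), so callers fall
    back to the beta-blind estimate there.
    """
    z0 = np.conj(p) / np.abs(p)

    def residual(z, alpha, beta):
        return float(np.sum(np.abs(alpha * np.conj(z) + beta * z - p) ** 2))

    z = z0.copy()
    best = None
    for _ in range(iters):
        M = np.stack([np.conj(z), z], axis=1)
        (alpha, beta), *_ = np.linalg.lstsq(M, p, rcond=None)
        if best is None:
            best = (residual(z, alpha, beta), z.copy())
        if abs(beta) < 1e-12 * max(abs(alpha), 1e-300):
            break
        disc = np.sqrt(p**2 - 4.0 * alpha * beta)
        roots = np.stack([(p + disc) / (2 * beta), (p - disc) / (2 * beta)])
        cost = np.abs(np.abs(roots) - 1.0) + np.abs(roots / np.abs(roots) - z)
        z_new = roots[np.argmin(cost, axis=0), np.arange(len(p))]
        z_new = z_new / np.abs(z_new)
        if np.allclose(z_new, z, atol=1e-12):
            z = z_new
            break
        z = z_new
    M = np.stack([np.conj(z), z], axis=1)
    (alpha, beta), *_ = np.linalg.lstsq(M, p, rcond=None)
    drift = np.max(np.abs(np.angle(z * np.conj(z0))))
    if best is not None and (residual(z, alpha, beta) > best[0]
                             or drift > np.deg2rad(30.0)):
        z = best[1]
    return np.angle(z) % (2 * np.pi)


def _refine_phases(frames: NDArray[np.float64], k_cpp: np.ndarray,
                   outer_iters: int = 4) -> np.ndarray:
    """Pattern phases at frequency ``k_cpp`` (cycles/pixel) per frame.

    Initial readouts come from a matched filter (each mean-subtracted
    frame projected onto the widefield modulated at k — coherent over the
    whole band, so robust to shot noise even when the emission OTF at k
    is weak).  The estimate is then iterated against the separated side
    band itself.  For 3-phase groups the -1-band cross-term is removed by
    :func:`_als_phases`; for more phases the beta-blind argument is used
    (see the identifiability note there).
    """
    n = len(frames)
    wf = frames.mean(axis=0)
    yy = np.arange(frames.shape[1], dtype=float)[:, None]
    xx = np.arange(frames.shape[2], dtype=float)[None, :]
    ref = wf * np.exp(2j * np.pi * (k_cpp[0] * yy + k_cpp[1] * xx))
    p = np.array([np.vdot(ref, f - wf) for f in frames])
    solve = _als_phases if n == 3 else lambda q: (-np.angle(q)) % (2 * np.pi)
    phases = solve(p)
    for _ in range(outer_iters):
        s0, sp, _ = separate_bands(frames, phases)
        c = np.array([np.vdot(sp, f - s0.real) for f in frames])
        new = solve(c)
        if np.max(np.abs(np.exp(1j * new) - np.exp(1j * phases))) < 1e-9:
            phases = new
            break
        phases = new
    return phases


def estimate_pattern_parameters(
    stack: RawStack,
    angle_grouping: dict[float, list[int]] | None = None,
    k_min_fraction: float = 0.25,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Estimate the pattern frequency vector and phases per orientation.

    The pattern peak is located on the Fourier grid from the
    cross-correlation of the separated side band with the unshifted band,
    then refined to sub-pixel precision by maximizing the continuous DFT
    magnitude.  Phases are read from the complex argument of each mean-
    subtracted frame at the refined frequency.  Frequencies below
    ``k_min_fraction`` of the emission cutoff are excluded from the search
    (they belong to the widefield envelope).

    Raises :class:`PatternEstimationError` when no significant off-centre
    peak exists.
    """
    groups = angle_grouping if angle_grouping is not None else _angle_groups(stack)
    cutoff = widefield_cutoff(stack.config, "emission")
    pixel = stack.config.sample_pixel
    out: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for angle, idx in groups.items():
        frames = stack.frames[idx]
        if len(frames) < 3:
            raise ValueError(
                f"angle {angle}: need >= 3 frames per orientation, got {len(frames)}"
            )
        nominal = np.array([2 * np.pi * i / len(frames) for i in range(len(frames))])
        k_nominal = None
        if stack.sequence is not None:
            nominal = np.array([stack.sequence.specs[i].phase for i in idx])
            k_nominal = _nominal_parameters(stack)[angle][0]
        try:
            out[angle] = _estimate_angle(
                frames, nominal, pixel, k_min_fraction * cutoff,
                k_nominal=k_nominal,
            )
        except PatternEstimationError as exc:
            raise PatternEstimationError(f"angle {angle}: {exc}") from exc
    return out


def _band_weight_overlap(B0, Bb, O0, Ob, thresh: float = 0.15) -> complex:
    """Complex modulation factor of a shifted band relative to the S0 band."""
    W = (O0 > thresh) & (Ob > thresh)
    num = np.sum(np.conj(B0[W] * Ob[W]) * (Bb[W] * O0[W]))
    den = np.sum(np.abs(B0[W] * Ob[W]) ** 2)
    if den == 0:
        return 0.0 + 0.0j
    return complex(num / den)


def reconstruct_sr_sim(
    stack: RawStack, params: ReconstructionParams | None = None
) -> SRResult:
    """Frequency-domain SR-SIM reconstruction (generalized Wiener).

    Requires >= 3 phase frames per orientation.  Per orientation the bands
    are separated, the side bands shifted back by the pattern frequency on
    the upsampled grid and rescaled by the measured modulation factor;
    bands from all orientations are then combined as

        D(k) = sum_b conj(O_b) B_b / (sum_b |O_b|^2 + w^2)

    and apodized over the extended passband.  Orientations whose measured
    modulation is negligible contribute their widefield band only, so a
    zero-contrast stack degrades to a Wiener-filtered widefield image.
    """
    if params is None:
        params = ReconstructionParams()
    groups = _angle_groups(stack)
    for angle, idx in groups.items():
        if len(idx) < 3:
            raise ValueError(
                f"angle {angle}: SR-SIM needs >= 3 phases per orientation, "
                f"got {len(idx)}"
            )

    config = stack.config
    pixel = config.sample_pixel
    cutoff_em = widefield_cutoff(config, "emission")

    if params.phase_source == "metadata" and stack.sequence is not None:
        pattern = _nominal_parameters(stack)
    else:
        try:
            pattern = estimate_pattern_parameters(stack)
        except PatternEstimationError:
            if stack.sequence is not None:
                # unmodulated data: fall back to nominal k; the measured
                # modulation factor will be ~0 and side bands get dropped
                pattern = _nominal_parameters(stack)
            else:
                raise

    n0, n1 = stack.frames.shape[1:]
    u = params.upsample
    fine_shape = (n0 * u, n1 * u)
    fine_pixel = pixel / u
    fy = np.fft.fftfreq(fine_shape[0], d=fine_pixel) * 1000.0
    fx = np.fft.fftfreq(fine_shape[1], d=fine_pixel) * 1000.0
    FY, FX = np.meshgrid(fy, fx, indexing="ij")

    yy = np.arange(fine_shape[0], dtype=float)[:, None]
    xx = np.arange(fine_shape[1], dtype=float)[None, :]

    num = np.zeros(fine_shape, dtype=complex)
    den = np.zeros(fine_shape, dtype=float)
    k_est: dict[float, tuple[float, float]] = {}
    phases_est: dict[float, list[float]] = {}
    k_mags: list[float] = []
    min_modulation = 1e-3

    for angle, idx in groups.items():
        kvec, phases = pattern[angle]
        k_est[angle] = (float(kvec[0]), float(kvec[1]))
        phases_est[angle] = [float(p) for p in phases]
        s0, sp, sm = separate_bands(stack.frames[idx], phases)
        s0f = fourier_resample(s0, fine_shape)
        spf = fourier_resample(sp, fine_shape)
        smf = fourier_resample(sm, fine_shape)

        k_cpp = kvec * fine_pixel / 1000.0  # cycles per fine pixel
        ramp = np.exp(-2j * np.pi * (k_cpp[0] * yy + k_cpp[1] * xx))
        B0 = np.fft.fft2(s0f)
        Bp = np.fft.fft2(spf * ramp)
        Bm = np.fft.fft2(smf * np.conj(ramp))

        O0 = np.asarray(incoherent_otf_value(np.hypot(FY, FX) / cutoff_em))
        Op = np.asarray(
            incoherent_otf_value(np.hypot(FY + kvec[0], FX + kvec[1]) / cutoff_em)
        )
        Om = np.asarray(
            incoherent_otf_value(np.hypot(FY - kvec[0], FX - kvec[1]) / cutoff_em)
        )

        num += np.conj(O0) * B0
        den += O0**2
        cp = _band_weight_overlap(B0, Bp, O0, Op)
        cm = _band_weight_overlap(B0, Bm, O0, Om)
        if abs(cp) > min_modulation and abs(cm) > min_modulation:
            num += np.conj(Op) * (Bp / cp)
            num += np.conj(Om) * (Bm / cm)
            den += Op**2 + Om**2
            k_mags.append(float(np.hypot(*kvec)))

    dhat = num / (den + params.wiener_w**2)
    k_pattern_max = max(k_mags) if k_mags else 0.0
    passband = k_pattern_max + cutoff_em
    rad = np.hypot(FY, FX)
    if params.apodization == "triangle":
        apo = np.clip(1.0 - rad / passband, 0.0, 1.0)
    else:
        apo = (rad <= passband).astype(float)
    image = np.fft.ifft2(dhat * apo).real
    return SRResult(
        image=image,
        pixel=fine_pixel,
        k_est=k_est,
        phases_est=phases_est,
        passband_radius=passband,
        params=params,
    )


def reconstruct_os_sim(stack: RawStack, subtract_noise_bias: bool = True) -> OSResult:
    """Optical sectioning by square-law demodulation.

    Per orientation with n equally spaced phases,

        OS = sqrt( sum_{i<j} (F_i - F_j)^2 ) * sqrt(2) / n

    which returns exactly the local modulation amplitude for sinusoidal
    frames, independent of the phase origin and of n; orientations are then
    averaged.  Unmodulated (out-of-focus) light cancels in the pairwise
    differences.

    Pairwise differences of noisy frames do not cancel noise: each pair
    contributes an expected ``2 sigma^2`` per pixel, which rectifies into
    a positive floor wherever (defocused) light is bright.  When the
    stack carries a noise model, ``subtract_noise_bias`` removes this
    expectation using the Poisson variance (the local widefield mean in
    photons) plus the read-noise variance, clipping at zero.
    """
    groups = _angle_groups(stack)
    out = np.zeros(stack.frames.shape[1:], dtype=float)
    noise = stack.noise
    shot = (
        subtract_noise_bias
        and noise is not None
        and (noise.peak_photons > 0 or noise.read_sigma > 0)
    )
    for angle, idx in groups.items():
        frames = stack.frames[idx]
        n = len(frames)
        if n < 3:
            raise ValueError(
                f"angle {angle}: OS-SIM needs >= 3 phases per orientation, "
                f"got {n}"
            )
        acc = np.zeros_like(out)
        for i in range(n):
            for j in range(i + 1, n):
                acc += (frames[i] - frames[j]) ** 2
        if shot:
            var = np.clip(frames.mean(axis=0), 0.0, None) if noise.peak_photons > 0 else 0.0
            var = var + noise.read_sigma**2
            acc = np.clip(acc - (n * (n - 1) / 2) * 2.0 * var, 0.0, None)
        out += np.sqrt(acc) * (np.sqrt(2.0) / n)
    out /= len(groups)
    return OSResult(image=out, pixel=stack.config.sample_pixel)
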