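"""Shared FFT helpers: exact band-limited resampling and frequency grids."""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray

__all__ = ["fourier_resample", "freq_grids_cyc_per_um"]


def freq_grids_cyc_per_um(shape: tuple[int, int], pixel_nm: float):
    """fftfreq-ordered (fy, fx) 1D axes in cycles/µm."""
    fy = np.fft.fftfreq(shape[0], d=pixel_nm) * 1000.0
    fx = np.fft.fftfreq(shape[1], d=pixel_nm) * 1000.0
    return fy, fx


def fourier_resample(
    img: NDArray,
    out_shape: tuple[int, int],
    alias_tol: float | None = None,
) -> NDArray:
    """Resample by centred spectrum zero-padding (up) or cropping (down).

    Exact for band-limited signals and DC-preserving.  Real input yields
    real output; complex input stays complex.  When cropping, ``alias_tol``
    (if given) bounds the spectral energy fraction that may be discarded —
    more means the signal would alias and a ValueError is raised.
    """
    was_real = not np.iscomplexobj(img)
    spec = np.fft.fftshift(np.fft.fft2(img))
    n0, n1 = img.shape
    m0, m1 = out_shape
    out = np.zeros(out_shape, dtype=complex)

    def bounds(n: int, m: int) -> tuple[int, int]:
        k = min(n, m)
        lo = (max(n, m) - k) // 2
        return lo, lo + k

    if m0 >= n0 and m1 >= n1:  # pad
        r0, r1 = bounds(m0, n0)
        c0, c1 = bounds(m1, n1)
        out[r0:r1, c0:c1] = spec
    elif m0 <= n0 and m1 <= n1:  # crop
        r0, r1 = bounds(n0, m0)
        c0, c1 = bounds(n1, m1)
        kept = spec[r0:r1, c0:c1]
        if alias_tol is not None:
            total = float(np.sum(np.abs(spec) ** 2))
            inside = float(np.sum(np.abs(kept) ** 2))
            if total > 0 and (total - inside) / total > alias_tol:
                raise ValueError(
                    "signal has spectral content beyond the output Nyquist "
                    "frequency and would alias"
                )
        out = kept.copy()
    else:
        raise ValueError("mixed pad/crop resampling is not supported")
    res = np.fft.ifft2(np.fft.ifftshift(out)) * ((m0 * m1) / (n0 * n1))
    return res.real if was_real else res
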