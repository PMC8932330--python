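"""Empirical mode decomposition by classical sifting.

Decomposes a signal into intrinsic mode functions (IMFs) — locally
zero-mean oscillatory components obtained by repeatedly subtracting the mean
of the upper and lower cubic-spline envelopes — plus a monotonic-ish
residue. By construction the IMFs and residue sum exactly to the input
(each IMF is subtracted from the running signal), which is the completeness
property downstream denoising relies on.

Boundary handling mirrors the extrema about the signal ends before fitting
the envelope splines, the standard remedy for spline end swings.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus take midpoints)."""
    dx = np.diff(x)
    # collapse exact plateaus by nudging with the sign of the last move
    sign = np.sign(dx)
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.diff(sign)
    maxima = np.where(flips < 0)[0] + 1
    minima = np.where(flips > 0)[0] + 1
    return maxima, minima


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through the extrema at ``idx``, with extrema
    mirrored about both ends to tame boundary behaviour."""
    # mirror up to two extrema on each side
    left = idx[:2]
    right = idx[-2:]
    ext_i = np.concatenate([-left[::-1], idx, 2 * (n - 1) - right[::-1]])
    ext_v = np.concatenate([x[left[::-1]], x[idx], x[right[::-1]]])
    order = np.argsort(ext_i)
    ext_i, ext_v = ext_i[order], ext_v[order]
    keep = np.concatenate([[True], np.diff(ext_i) > 0])
    spline = CubicSpline(ext_i[keep], ext_v[keep])
    return spline(np.arange(n))


def _sift_once(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """One sifting pass. Returns (candidate IMF, enough-extrema flag)."""
    maxima, minima = _local_extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        return x, False
    n = len(x)
    upper = _mirrored_envelope(x, maxima, n)
    lower = _mirrored_envelope(x, minima, n)
    return x - 0.5 * (upper + lower), True


def emd(
    x: np.ndarray,
    max_imfs: int = 12,
    sd_threshold: float = 0.2,
    max_siftings: int = 50,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Decompose ``x`` into IMFs and a residue.

    Parameters
    ----------
    x
        1-D signal.
    max_imfs
        Upper bound on the number of IMFs extracted.
    sd_threshold
        Cauchy-type stopping criterion for the inner sifting loop: stop when
        the normalized squared difference between consecutive sifts falls
        below this value.
    max_siftings
        Hard cap on sifting passes per IMF.

    Returns
    -------
    (imfs, residue) with ``sum(imfs) + residue == x`` to machine precision.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D signal")
    if len(x) < 8:
        raise ValueError(f"signal too short for EMD: {len(x)} samples")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residue)
        if len(maxima) + len(minima) < 4:
            break  # residue has too few oscillations left
        h = residue
        for _ in range(max_siftings):
            h_new, ok = _sift_once(h)
            if not ok:
                break
            denom = np.sum(h**2) + 1e-300
            sd = np.sum((h - h_new) ** 2) / denom
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        residue = residue - h
    return imfs, residue


def reconstruct(imfs: list[np.ndarray], residue: np.ndarray) -> np.ndarray:
    """Sum of IMFs plus residue (the inverse of :func:`emd`)."""
    out = residue.copy()
    for imf in imfs:
        out = out + imf
    return out
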