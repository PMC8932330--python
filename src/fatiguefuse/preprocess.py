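"""Denoising chain for raw ECG / sEMG windows.

The chain runs in a fixed order:

1. zero-phase low-pass (100 Hz for ECG, 500 Hz for sEMG) to strip
   high-frequency interference,
2. adaptive 49.5–50 Hz notch (plus harmonics inside the channel passband)
   against powerline pickup,
3. EMD + wavelet noise reduction: the signal is decomposed into intrinsic
   mode functions and the noise-dominated initial IMFs are wavelet-
   thresholded — not discarded — before reconstruction, so signal content
   sharing those scales survives.

All steps preserve signal length and sampling rate. Filters are zero-phase
(forward–backward IIR) so R-peak timing is not distorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .emd import emd
from .records import SignalRecord

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


def lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass; unit passband gain, equal length."""
    if not 0 < cutoff < fs / 2:
        raise ValueError(
            f"cutoff must lie in (0, fs/2)=(0, {fs / 2}), got {cutoff}")
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


@njit(cache=False)
def _lms_cancel(x, ref_sin, ref_cos, mu, w0, w1):  # pragma: no cover - numba
    n = x.shape[0]
    out = np.empty(n)
    for i in range(n):
        est = w0 * ref_sin[i] + w1 * ref_cos[i]
        e = x[i] - est
        out[i] = e
        w0 += 2.0 * mu * e * ref_sin[i]
        w1 += 2.0 * mu * e * ref_cos[i]
    return out, w0, w1


def _lms_cancel_py(x, ref_sin, ref_cos, mu, w0, w1):
    out = np.empty(len(x))
    for i in range(len(x)):
        est = w0 * ref_sin[i] + w1 * ref_cos[i]
        e = x[i] - est
        out[i] = e
        w0 += 2.0 * mu * e * ref_sin[i]
        w1 += 2.0 * mu * e * ref_cos[i]
    return out, w0, w1


def adaptive_notch(
    x: np.ndarray,
    fs: float,
    freqs: tuple[float, ...] = (50.0, 100.0, 150.0),
    mu: float = 5e-4,
    warm_start: bool = True,
    method: str = "lms",
) -> np.ndarray:
    """Suppress powerline interference and its harmonics.

    ``method="lms"`` (default) is a reference-free adaptive noise canceler:
    for each target frequency an internally generated quadrature pair
    (sin/cos at that frequency) is scaled by two LMS-adapted weights and
    subtracted, which tracks slow drifts of the interference amplitude and
    phase within the 49.5–50 Hz band. A warm-start pass converges the
    weights before the output pass so the adaptation transient does not leak
    interference into the output. ``method="iir"`` is a fixed zero-phase
    IIR-notch fallback.

    The effective notch is narrow (set by ``mu``), so neighbouring
    physiological content — e.g. 40 Hz — passes essentially unchanged.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2
    freqs = tuple(f for f in freqs if 0 < f < nyq)
    if method == "iir":
        out = x
        padlen = min(len(x) - 1, int(2 * fs))  # high-Q notch rings long
        for f in freqs:
            b, a = sps.iirnotch(f, Q=f / 2.0, fs=fs)
            out = sps.filtfilt(b, a, out, padlen=padlen)
        return out
    if method != "lms":
        raise ValueError(f"unknown notch method {method!r}")
    t = np.arange(len(x)) / fs
    out = x
    kern = _lms_cancel if _HAVE_NUMBA else _lms_cancel_py
    for f in freqs:
        ref_sin = np.sin(2 * np.pi * f * t)
        ref_cos = np.cos(2 * np.pi * f * t)
        w0 = w1 = 0.0
        if warm_start:
            _, w0, w1 = kern(out, ref_sin, ref_cos, mu, w0, w1)
        out, _, _ = kern(out, ref_sin, ref_cos, mu, w0, w1)
    return out


def wavelet_threshold(
    x: np.ndarray,
    wavelet: str = "db4",
    level: int = 4,
    mode: str = "soft",
) -> np.ndarray:
    """Wavelet shrinkage with the universal threshold.

    The noise scale is the median absolute deviation of the finest detail
    coefficients divided by 0.6745; threshold ``sigma * sqrt(2 ln N)`` is
    applied to all detail levels (soft by default). Symmetric extension.
    """
    x = np.asarray(x, dtype=float)
    level = min(level, pywt.dwt_max_level(len(x), pywt.Wavelet(wavelet)))
    if level < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(max(len(x), 2)))
    denoised = [coeffs[0]] + [
        pywt.threshold(c, thr, mode=mode) for c in coeffs[1:]
    ]
    out = pywt.waverec(denoised, wavelet, mode="symmetric")
    return out[: len(x)]


def emd_dwt_denoise(
    x: np.ndarray,
    n_initial_imfs: int = 3,
    wavelet: str = "db4",
    level: int = 4,
    mode: str = "soft",
    threshold: bool = True,
) -> np.ndarray:
    """EMD + DWT noise reduction.

    The signal is decomposed into IMFs; the first ``n_initial_imfs`` IMFs —
    the scales where wideband noise concentrates — are wavelet-thresholded
    instead of discarded, and the signal is rebuilt as thresholded initial
    IMFs + remaining IMFs + residue. With ``threshold=False`` the
    reconstruction reproduces the input (completeness check).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2**level:
        raise ValueError(
            f"signal of {len(x)} samples too short for a depth-{level} DWT")
    imfs, residue = emd(x)
    out = residue.copy()
    for k, imf in enumerate(imfs):
        if threshold and k < n_initial_imfs:
            out = out + wavelet_threshold(imf, wavelet, level, mode)
        else:
            out = out + imf
    return out


@dataclass
class PreprocessConfig:
    """Configuration of the full denoising chain."""

    ecg_lowpass_hz: float = 100.0
    semg_lowpass_hz: float = 500.0
    notch_freqs: tuple[float, ...] = (50.0, 100.0, 150.0)
    notch_method: str = "lms"
    notch_mu: float = 5e-4
    denoise: bool = True
    n_initial_imfs: int = 3
    wavelet: str = "db4"
    wavelet_level: int = 4
    threshold_mode: str = "soft"

    def lowpass_for(self, channel: str) -> float:
        return self.ecg_lowpass_hz if channel == "ecg" else self.semg_lowpass_hz


def preprocess_record(
    record: SignalRecord, config: PreprocessConfig | None = None
) -> SignalRecord:
    """Run the full chain (low-pass → notch → EMD+DWT) on every channel."""
    if config is None:
        config = PreprocessConfig()
    out: dict[str, np.ndarray] = {}
    for name, x in record.samples.items():
        cutoff = config.lowpass_for(name)
        y = lowpass(x, record.fs, cutoff)
        harmonics = tuple(f for f in config.notch_freqs if f < cutoff * 1.05)
        if harmonics:
            y = adaptive_notch(y, record.fs, harmonics, mu=config.notch_mu,
                               method=config.notch_method)
        if config.denoise:
            y = emd_dwt_denoise(
                y,
                n_initial_imfs=config.n_initial_imfs,
                wavelet=config.wavelet,
                level=config.wavelet_level,
                mode=config.threshold_mode,
            )
        out[name] = y
    return SignalRecord(samples=out, fs=record.fs, label=record.label,
                        ground_truth=record.ground_truth)
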