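"""The 11 fatigue features: 3 HRV features from ECG, 4 per sEMG channel.

ECG block (a=3)
    ``ECG_mean``  mean RR interval (s) — shortens as heart rate rises,
    ``ECG_LF``    RR-tachogram band power in 0.04–0.15 Hz,
    ``ECG_LF/HF`` ratio of low- to high-frequency (0.15–0.40 Hz) band power,
    an index of sympathovagal balance.

sEMG block (b=4 per channel × 2 channels)
    ``IEMG`` integrated rectified amplitude  Σ|x(k)|/Fs  (mV·s),
    ``RMS``  root-mean-square amplitude (mV),
    ``MPF``  mean power frequency — the power-weighted spectral centroid
    ∫ f·P(f) df / ∫ P(f) df (Hz),
    ``MF``   median frequency — the frequency splitting cumulative spectral
    power in half (Hz). MPF and MF compress toward low frequencies as a
    muscle fatigues.

All spectral features share one Welch PSD code path so they are mutually
consistent; MF uses linear interpolation between spectral bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .records import (
    FEATURE_NAMES,
    FeatureVector,
    QualityError,
    SignalRecord,
    UndefinedFeatureError,
)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


# ---------------------------------------------------------------------------
# spectral helpers — single PSD code path for every spectral feature


def psd(x: np.ndarray, fs: float, nperseg: int = 1024) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (Hann window, 50% overlap)."""
    x = np.asarray(x, dtype=float)
    nper = min(nperseg, len(x))
    return sps.welch(x, fs=fs, window="hann", nperseg=nper,
                     noverlap=nper // 2, detrend="constant")


def _band_power(f: np.ndarray, p: np.ndarray, band: tuple[float, float]) -> float:
    """Integrated PSD over ``band`` by trapezoid rule (band-edge clipped)."""
    lo, hi = band
    grid = np.unique(np.concatenate([f[(f >= lo) & (f <= hi)], [lo, hi]]))
    grid = grid[(grid >= f[0]) & (grid <= f[-1])]
    if len(grid) < 2:
        return 0.0
    pg = np.interp(grid, f, p)
    return float(np.trapezoid(pg, grid))


# ---------------------------------------------------------------------------
# ECG / HRV features


@dataclass
class RRSeries:
    """An RR-interval sequence with its originating R-peak times."""

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.beat_times) >= 2 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def rr(self) -> np.ndarray:
        """RR interval durations (s)."""
        return np.diff(self.beat_times)

    @property
    def m(self) -> int:
        """Number of RR intervals."""
        return len(self.beat_times) - 1 if len(self.beat_times) else 0


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    refractory_s: float = 0.2,
) -> np.ndarray:
    """R-peak times by a derivative-energy detector (Pan–Tompkins style).

    Band-pass 5–25 Hz (isolates QRS energy) → differentiate → square →
    moving-window integrate (150 ms) → pick peaks above an adaptive
    threshold with a 200 ms refractory period, then refine each peak to the
    local maximum of the signal itself.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs:
        raise QualityError("ECG window shorter than 2 s")
    sos = sps.butter(2, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    qrs = sps.sosfiltfilt(sos, ecg)
    d = np.diff(qrs, prepend=qrs[0])
    energy = d * d
    win = max(int(0.15 * fs), 1)
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    peak_level = np.percentile(integ, 99)
    if peak_level <= 1e-18 or np.ptp(ecg) < 1e-12:
        raise QualityError("no detectable R-peaks (flat or near-flat ECG)")
    height = 0.25 * peak_level
    locs, _ = sps.find_peaks(integ, height=height,
                             distance=max(int(refractory_s * fs), 1))
    if len(locs) == 0:
        raise QualityError("no detectable R-peaks above threshold")
    half = max(int(0.10 * fs), 1)
    refined = []
    for loc in locs:
        lo, hi = max(loc - half, 0), min(loc + half + 1, len(ecg))
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory after refinement
    keep = [refined[0]]
    for r in refined[1:]:
        if (r - keep[-1]) / fs >= refractory_s:
            keep.append(r)
        elif ecg[r] > ecg[keep[-1]]:
            keep[-1] = r
    return np.asarray(keep) / fs


def ecg_mean(rr: RRSeries) -> float:
    """Mean RR interval (s): (1/M) Σ RR_i."""
    if rr.m < 1:
        raise ValueError("cannot average an empty RR series")
    return float(np.mean(rr.rr))


def band_powers_from_tachogram(
    times: np.ndarray,
    rr_values: np.ndarray,
    resample_hz: float = 4.0,
) -> tuple[float, float]:
    """LF and HF band power of an RR tachogram.

    The unevenly sampled tachogram (RR value at each beat time) is cubic-
    interpolated to a uniform ``resample_hz`` grid, mean-removed, and its
    Welch PSD integrated over the LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz)
    bands. Units: s² (power of the RR fluctuation).
    """
    times = np.asarray(times, dtype=float)
    rr_values = np.asarray(rr_values, dtype=float)
    if len(times) < 4:
        raise ValueError("tachogram too short for spectral estimation")
    grid = np.arange(times[0], times[-1], 1.0 / resample_hz)
    uniform = CubicSpline(times, rr_values)(grid)
    uniform = uniform - np.mean(uniform)
    nper = min(256, len(uniform))
    f, p = sps.welch(uniform, fs=resample_hz, window="hann", nperseg=nper,
                     noverlap=nper // 2, detrend="constant")
    return _band_power(f, p, LF_BAND), _band_power(f, p, HF_BAND)


def hrv_band_powers(rr: RRSeries, min_intervals: int = 16) -> tuple[float, float, float]:
    """(LF power, HF power, LF/HF ratio) of an RR series.

    Raises :class:`UndefinedFeatureError` when the HF power vanishes — the
    ratio is then undefined and is never silently reported as 0.
    """
    if rr.m < min_intervals:
        raise ValueError(
            f"need >= {min_intervals} RR intervals for spectral estimation, "
            f"got {rr.m}")
    lf, hf = band_powers_from_tachogram(rr.beat_times[1:], rr.rr)
    if not np.isfinite(hf) or hf <= 0.0:
        raise UndefinedFeatureError("HF band power is zero; LF/HF undefined")
    return lf, hf, lf / hf


# ---------------------------------------------------------------------------
# sEMG features


def iemg(x: np.ndarray, fs: float) -> float:
    """Integrated EMG Σ|x(k)|/Fs (mV·s)."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("IEMG of an empty window is undefined")
    return float(np.sum(np.abs(x)) / fs)


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude sqrt((1/N) Σ x(k)²) (mV)."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("RMS of an empty window is undefined")
    return float(np.sqrt(np.mean(x * x)))


def mpf(x: np.ndarray, fs: float, min_samples: int = 256) -> float:
    """Mean power frequency: spectral centroid ∫f·P df / ∫P df (Hz)."""
    x = np.asarray(x, dtype=float)
    if len(x) < min_samples:
        raise ValueError(f"MPF needs >= {min_samples} samples, got {len(x)}")
    f, p = psd(x, fs)
    total = np.trapezoid(p, f)
    if total <= 0:
        raise UndefinedFeatureError("zero total power; MPF undefined")
    return float(np.trapezoid(f * p, f) / total)


def mf(x: np.ndarray, fs: float, min_samples: int = 256) -> float:
    """Median frequency: f_m with ∫₀^{f_m} P df = ½ ∫ P df (Hz)."""
    x = np.asarray(x, dtype=float)
    if len(x) < min_samples:
        raise ValueError(f"MF needs >= {min_samples} samples, got {len(x)}")
    f, p = psd(x, fs)
    total = np.trapezoid(p, f)
    if total <= 0:
        raise UndefinedFeatureError("zero total power; MF undefined")
    cum = np.concatenate([[0.0], np.cumsum(np.diff(f) * (p[1:] + p[:-1]) / 2)])
    return float(np.interp(total / 2.0, cum, f))


# ---------------------------------------------------------------------------
# assembly


def extract_features(record: SignalRecord) -> FeatureVector:
    """Assemble the ordered 11-feature vector from a preprocessed window.

    Order: [ECG_mean, ECG_LF, ECG_LF/HF | R: IEMG, RMS, MPF, MF |
    L: IEMG, RMS, MPF, MF]; the window label is carried through. Per-feature
    failures are re-raised with the offending channel named.
    """
    values = np.empty(len(FEATURE_NAMES))
    try:
        peaks = detect_r_peaks(record.channel("ecg"), record.fs)
        rr = RRSeries(peaks)
        values[0] = ecg_mean(rr)
        lf, hf, ratio = hrv_band_powers(rr)
        values[1], values[2] = lf, ratio
    except (QualityError, UndefinedFeatureError, ValueError) as exc:
        raise type(exc)(f"ECG channel: {exc}") from exc
    for block, name in ((3, "semg_r"), (7, "semg_l")):
        x = record.channel(name)
        try:
            values[block + 0] = iemg(x, record.fs)
            values[block + 1] = rms(x)
            values[block + 2] = mpf(x, record.fs)
            values[block + 3] = mf(x, record.fs)
        except (UndefinedFeatureError, ValueError) as exc:
            raise type(exc)(f"{name} channel: {exc}") from exc
    return FeatureVector(values=values, label=record.label)


def extract_dataset(records) -> list[FeatureVector]:
    """Extract features for a sequence of windows."""
    return [extract_features(r) for r in records]
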