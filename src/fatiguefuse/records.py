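"""Core containers shared across the pipeline stages.

A :class:`SignalRecord` is one labeled multichannel window of samples at a
fixed sampling rate; a :class:`FeatureVector` is the 11-dimensional fatigue
descriptor extracted from it (3 heart-rate-variability features from the ECG
channel, 4 amplitude/spectral features per sEMG channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: canonical channel order: ECG, right-leg semitendinosus sEMG, left-leg
#: tibialis anterior sEMG
CHANNELS = ("ecg", "semg_r", "semg_l")

#: fatigue-state label coding: relaxed -1, transition 0, tired +1
STATES = (-1, 0, 1)

#: canonical order of the 11 fatigue features: ECG block (a=3) then the two
#: sEMG blocks (b=8)
FEATURE_NAMES = (
    "ECG_mean",
    "ECG_LF",
    "ECG_LFHF",
    "sEMG_R_IEMG",
    "sEMG_R_RMS",
    "sEMG_R_MPF",
    "sEMG_R_MF",
    "sEMG_L_IEMG",
    "sEMG_L_RMS",
    "sEMG_L_MPF",
    "sEMG_L_MF",
)

ECG_BLOCK = slice(0, 3)
SEMG_BLOCK = slice(3, 11)
N_FEATURES = len(FEATURE_NAMES)


class QualityError(ValueError):
    """A signal window failed a quality check (e.g. no detectable R-peaks)."""


class UndefinedFeatureError(ValueError):
    """A feature is mathematically undefined for this input (e.g. LF/HF with
    zero high-frequency power). Raised rather than silently returning 0."""


@dataclass
class SignalRecord:
    """One window of synchronously recorded channels.

    Parameters
    ----------
    samples
        Mapping from channel name to 1-D array (mV). All channels present
        must have equal length.
    fs
        Sampling frequency in Hz.
    label
        Fatigue state in {-1, 0, 1}, or ``None`` when unlabeled.
    ground_truth
        Optional generator-side record: the parameters that produced the
        window, the clean (contaminant-free) components and true R-peak
        times. Only synthetic data carries this.
    """

    samples: dict[str, np.ndarray]
    fs: float
    label: Optional[int] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        lengths = {k: len(v) for k, v in self.samples.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        if self.label is not None and self.label not in STATES:
            raise ValueError(f"label must be in {STATES}, got {self.label}")
        for k, v in self.samples.items():
            self.samples[k] = np.asarray(v, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.samples.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.samples.keys())

    def channel(self, name: str) -> np.ndarray:
        if name not in self.samples:
            raise KeyError(f"record has no channel {name!r}; has {self.channels}")
        return self.samples[name]

    def time(self) -> np.ndarray:
        """Sample times in seconds starting at 0."""
        return np.arange(self.n_samples) / self.fs


@dataclass
class FeatureVector:
    """The 11 fatigue features of one window, in canonical order."""

    values: np.ndarray
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(
                f"expected {N_FEATURES} features, got shape {self.values.shape}"
            )
        if self.label is not None and self.label not in STATES:
            raise ValueError(f"label must be in {STATES}, got {self.label}")

    @property
    def ecg_block(self) -> np.ndarray:
        """ECG-derived features [ECG_mean, ECG_LF, ECG_LF/HF] (a=3)."""
        return self.values[ECG_BLOCK]

    @property
    def semg_block(self) -> np.ndarray:
        """sEMG-derived features, both channels (b=8)."""
        return self.values[SEMG_BLOCK]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def feature_matrix(
    vectors: Sequence[FeatureVector],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors into (X, y); unlabeled entries get label NaN."""
    X = np.vstack([fv.values for fv in vectors])
    y = np.array(
        [fv.label if fv.label is not None else np.nan for fv in vectors]
    )
    return X, y
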