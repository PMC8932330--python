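"""Structured run configuration: per-stage parameter blocks, one global seed.

Unknown keys are rejected (typos should fail loudly, not be ignored), and
every pipeline run writes a resolved-config snapshot next to its outputs so
results stay attributable. All per-stage seeds are derived deterministically
from the single global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


def _check_keys(block: dict, cls, where: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} in section {where!r}; "
            f"known keys: {sorted(known)}")


@dataclass
class SynthgenBlock:
    n_per_state: int = 400
    window_s: float = 30.0
    fs: float = 2000.0
    profile: str = "default"  # "default" | "complementary"


@dataclass
class PreprocessBlock:
    ecg_lowpass_hz: float = 100.0
    semg_lowpass_hz: float = 500.0
    notch_freqs: tuple = (50.0, 100.0, 150.0)
    notch_method: str = "lms"
    denoise: bool = True
    n_initial_imfs: int = 3
    wavelet: str = "db4"
    wavelet_level: int = 4


@dataclass
class IpsoSvmBlock:
    q: int = 50
    c1: float = 0.5
    c2: float = 0.5
    omega: float = 0.8
    h_e: float = 0.95
    max_iter: int = 100
    v_max: float = 2.0
    C: float = 10.0
    sigma: float = float(np.sqrt(11.0))
    inner_test_fraction: float = 0.3


@dataclass
class EvaluateBlock:
    n_rep: int = 20
    test_fraction: float = 0.3
    models: tuple = ("ipso_svm", "bpnn", "knn", "lda")
    compare_modalities: bool = True


@dataclass
class RunConfig:
    """Umbrella configuration for the whole pipeline."""

    seed: int = 0
    out_dir: str = "fatiguefuse_run"
    log_level: str = "INFO"
    synthgen: SynthgenBlock = field(default_factory=SynthgenBlock)
    preprocess: PreprocessBlock = field(default_factory=PreprocessBlock)
    ipso_svm: IpsoSvmBlock = field(default_factory=IpsoSvmBlock)
    evaluate: EvaluateBlock = field(default_factory=EvaluateBlock)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        _check_keys(data, cls, "<root>")
        blocks = {}
        for name, sub_cls in (
            ("synthgen", SynthgenBlock),
            ("preprocess", PreprocessBlock),
            ("ipso_svm", IpsoSvmBlock),
            ("evaluate", EvaluateBlock),
        ):
            block = dict(data.pop(name, {}) or {})
            _check_keys(block, sub_cls, name)
            for key, value in block.items():
                if isinstance(value, list):
                    block[key] = tuple(value)
            blocks[name] = sub_cls(**block)
        return cls(**data, **blocks)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def snapshot(self, path) -> None:
        """Write the resolved configuration (with its hash) next to outputs."""
        data = self.to_dict()
        data["config_hash"] = self.hash()
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)
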