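"""End-to-end pipeline: synthgen → preprocess → features → train → evaluate.

Each stage writes its artifacts under the run directory and is skipped on
rerun when its outputs already exist (unless forced), so a failed run can be
resumed. Every run writes a resolved-config snapshot; a failure leaves a
``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import evaluate as ev
from . import features as feat
from . import io as ffio
from . import synthgen
from .config import RunConfig
from .ipso_svm import IpsoSvmClassifier, SwarmConfig
from .preprocess import PreprocessConfig, preprocess_record

log = logging.getLogger("fatiguefuse")

STAGES = ("synthgen", "preprocess", "features", "train", "evaluate")


def _swarm_config(cfg: RunConfig) -> SwarmConfig:
    b = cfg.ipso_svm
    return SwarmConfig(q=b.q, c1=b.c1, c2=b.c2, omega=b.omega, h_e=b.h_e,
                       max_iter=b.max_iter, v_max=b.v_max,
                       seed=cfg.stage_seed("train"))


def _preprocess_config(cfg: RunConfig) -> PreprocessConfig:
    b = cfg.preprocess
    return PreprocessConfig(
        ecg_lowpass_hz=b.ecg_lowpass_hz, semg_lowpass_hz=b.semg_lowpass_hz,
        notch_freqs=tuple(b.notch_freqs), notch_method=b.notch_method,
        denoise=b.denoise, n_initial_imfs=b.n_initial_imfs,
        wavelet=b.wavelet, wavelet_level=b.wavelet_level)


def run_pipeline(cfg: RunConfig, force: bool = False) -> Path:
    """Run all stages; returns the run directory. Raises on stage failure."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.snapshot(out / "resolved_config.yaml")
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    try:
        raw_dir = out / "raw"
        if force or not (raw_dir / "manifest.csv").exists():
            _stage_synthgen(cfg, raw_dir)
        pre_dir = out / "preprocessed"
        if force or not (pre_dir / "manifest.csv").exists():
            _stage_preprocess(cfg, raw_dir, pre_dir)
        features_csv = out / "features.csv"
        if force or not features_csv.exists():
            _stage_features(cfg, pre_dir, features_csv)
        model_json = out / "model.json"
        if force or not model_json.exists():
            _stage_train(cfg, features_csv, model_json)
        report_json = out / "report.json"
        if force or not report_json.exists():
            _stage_evaluate(cfg, features_csv, out)
        return out
    except Exception as exc:
        marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _timed(stage):
    def deco(fn):
        def wrap(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            result = fn(*args, **kwargs)
            log.info("stage %s: done in %.1f s", stage, time.perf_counter() - t0)
            return result
        return wrap
    return deco


@_timed("synthgen")
def _stage_synthgen(cfg: RunConfig, raw_dir: Path) -> None:
    b = cfg.synthgen
    maker = (synthgen.complementary_profile if b.profile == "complementary"
             else synthgen.default_profile)
    profile = maker(fs=b.fs)
    records = synthgen.generate_dataset(
        n_per_state=b.n_per_state, window_s=b.window_s, profile=profile,
        seed=cfg.stage_seed("synthgen"))
    ffio.write_dataset(records, raw_dir)


@_timed("preprocess")
def _stage_preprocess(cfg: RunConfig, raw_dir: Path, pre_dir: Path) -> None:
    pconf = _preprocess_config(cfg)
    records = ffio.read_dataset(raw_dir)
    processed = [preprocess_record(r, pconf) for r in records]
    ffio.write_dataset(processed, pre_dir)


@_timed("features")
def _stage_features(cfg: RunConfig, pre_dir: Path, features_csv: Path) -> None:
    records = ffio.read_dataset(pre_dir)
    vectors = feat.extract_dataset(records)
    ffio.write_feature_table(vectors, features_csv)


@_timed("train")
def _stage_train(cfg: RunConfig, features_csv: Path, model_json: Path) -> None:
    X, y = ffio.read_feature_table(features_csv)
    clf = IpsoSvmClassifier(
        cfg=_swarm_config(cfg), C=cfg.ipso_svm.C, sigma=cfg.ipso_svm.sigma,
        inner_test_fraction=cfg.ipso_svm.inner_test_fraction)
    clf.fit(X, y.astype(int))
    clf.save(model_json)


@_timed("evaluate")
def _stage_evaluate(cfg: RunConfig, features_csv: Path, out: Path) -> None:
    X, y = ffio.read_feature_table(features_csv)
    y = y.astype(int)
    b = cfg.evaluate
    seed = cfg.stage_seed("evaluate")
    factories = {}
    if "ipso_svm" in b.models:
        factories["ipso_svm"] = ev.ipso_svm_factory(
            cfg=_swarm_config(cfg), C=cfg.ipso_svm.C, sigma=cfg.ipso_svm.sigma)
    baselines = ev.baseline_classifiers()
    for name in b.models:
        if name in baselines:
            factories[name] = baselines[name]
    reports = ev.compare_classifiers(
        X, y, factories, n_rep=b.n_rep, test_fraction=b.test_fraction,
        seed=seed)
    payload = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "models": {name: rep.to_dict() for name, rep in reports.items()},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    if b.compare_modalities:
        table = ev.compare_modalities(
            X, y, cfg=_swarm_config(cfg), C=cfg.ipso_svm.C,
            n_rep=b.n_rep, test_fraction=b.test_fraction, seed=seed)
        table.to_csv(out / "comparison.csv")
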