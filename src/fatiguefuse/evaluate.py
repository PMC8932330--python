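"""Monte Carlo cross-validation, recognition rates and classifier baselines.

Recognition rate is the fraction of test samples classified correctly.
:func:`mccv` repeats stratified random train/test splits, training a fresh
classifier per split and aggregating per-class rates and the confusion
matrix. Baselines (BP neural network, K-nearest neighbours, linear
discriminant analysis) run through the identical MCCV path as the fused
model, and :func:`compare_modalities` evaluates ECG-only, sEMG-only and
fused models on identical splits (shared split seeds), so observed
differences are attributable to the models rather than split noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .ipso_svm import IpsoSvmClassifier, SwarmConfig
from .records import ECG_BLOCK, SEMG_BLOCK, STATES

STATE_NAMES = {-1: "relaxed", 0: "transition", 1: "tired"}


def recognition_rate(predictions: Sequence[int], truths: Sequence[int]) -> float:
    """Fraction of samples correctly identified."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if len(predictions) == 0:
        raise ValueError("recognition rate of zero samples is undefined")
    if len(predictions) != len(truths):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs "
            f"{len(truths)} truths")
    return float(np.mean(predictions == truths))


@dataclass
class EvaluationReport:
    """Aggregated MCCV results for one classifier."""

    per_class_rate: dict[int, float]
    mean_rate: float
    confusion: np.ndarray  # rows = truth, cols = prediction, classes sorted
    n_repetitions: int
    per_rep_rates: list[float]
    seed: int

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)

    def to_dict(self) -> dict:
        return {
            "per_class_rate": {str(k): v for k, v in self.per_class_rate.items()},
            "mean_rate": self.mean_rate,
            "confusion": self.confusion.tolist(),
            "classes": list(STATES),
            "n_repetitions": self.n_repetitions,
            "per_rep_rates": list(self.per_rep_rates),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            per_class_rate={int(k): float(v)
                            for k, v in d["per_class_rate"].items()},
            mean_rate=float(d["mean_rate"]),
            confusion=np.asarray(d["confusion"], dtype=int),
            n_repetitions=int(d["n_repetitions"]),
            per_rep_rates=[float(v) for v in d["per_rep_rates"]],
            seed=int(d["seed"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def mccv(
    X: np.ndarray,
    y: Sequence[int],
    classifier_factory: Callable[[int], object],
    n_rep: int = 20,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> EvaluationReport:
    """Monte Carlo cross-validation with stratified random splits.

    ``classifier_factory(rep_seed)`` must return a fresh object with
    ``fit(X, y)`` and ``predict(X)``; one is created per repetition so no
    state leaks between splits.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    splitter = StratifiedShuffleSplit(
        n_splits=n_rep, test_size=test_fraction, random_state=seed % (2**31 - 1))
    confusion = np.zeros((len(STATES), len(STATES)), dtype=int)
    per_rep: list[float] = []
    for rep, (tr, te) in enumerate(splitter.split(X, y)):
        if set(np.unique(y[tr])) != set(STATES) or len(te) == 0:
            raise ValueError(
                "a class vanished from a split; lower test_fraction or add data")
        clf = classifier_factory(seed + 1000 * rep)
        clf.fit(X[tr], y[tr])
        pred = np.asarray(clf.predict(X[te]))
        per_rep.append(recognition_rate(pred, y[te]))
        confusion += confusion_matrix(y[te], pred, labels=list(STATES))
    row_sums = confusion.sum(axis=1)
    per_class = {
        c: float(confusion[i, i] / row_sums[i]) if row_sums[i] else float("nan")
        for i, c in enumerate(STATES)
    }
    return EvaluationReport(
        per_class_rate=per_class,
        mean_rate=float(np.mean(per_rep)),
        confusion=confusion,
        n_repetitions=n_rep,
        per_rep_rates=per_rep,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# classifier factories


def ipso_svm_factory(
    cfg: Optional[SwarmConfig] = None,
    C: float = 10.0,
    sigma: Optional[float] = None,
    optimize: bool = True,
) -> Callable[[int], IpsoSvmClassifier]:
    """Factory producing fresh (optionally PSO-fused) SVM classifiers."""
    base = cfg or SwarmConfig()

    def make(seed: int) -> IpsoSvmClassifier:
        run_cfg = SwarmConfig(
            q=base.q, c1=base.c1, c2=base.c2, omega=base.omega,
            h_e=base.h_e, max_iter=base.max_iter, v_max=base.v_max,
            seed=seed % (2**31 - 1))
        kw = {} if sigma is None else {"sigma": sigma}
        return IpsoSvmClassifier(cfg=run_cfg, C=C, optimize=optimize, **kw)

    return make


def baseline_classifiers(
    bpnn_hidden: tuple[int, ...] = (16,),
    knn_k: int = 5,
) -> dict[str, Callable[[int], object]]:
    """The three comparison baselines under the common factory interface.

    BPNN: one hidden layer (16 units), early stopping. KNN: Euclidean,
    k=5. LDA: pooled covariance. Each trains on standardized, unfused
    features (a StandardScaler is part of every pipeline).
    """

    def bpnn(seed: int):
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=bpnn_hidden, early_stopping=True,
                          validation_fraction=0.2, n_iter_no_change=25,
                          max_iter=1000, random_state=seed % (2**31 - 1)))

    def knn(seed: int):
        return make_pipeline(StandardScaler(), KNeighborsClassifier(knn_k))

    def lda(seed: int):
        return make_pipeline(StandardScaler(), LinearDiscriminantAnalysis())

    return {"bpnn": bpnn, "knn": knn, "lda": lda}


def compare_classifiers(
    X: np.ndarray,
    y: Sequence[int],
    factories: dict[str, Callable[[int], object]],
    n_rep: int = 20,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> dict[str, EvaluationReport]:
    """Evaluate several classifiers on identical MCCV splits."""
    return {
        name: mccv(X, y, factory, n_rep=n_rep, test_fraction=test_fraction,
                   seed=seed)
        for name, factory in factories.items()
    }


def noise_replacement_weights(
    X: np.ndarray,
    y: Sequence[int],
    noise_block: slice = ECG_BLOCK,
    n_runs: int = 10,
    cfg: Optional[SwarmConfig] = None,
    n_fitness_splits: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Can the swarm tell informative features from noise?

    One feature block is replaced by standard-normal noise and the fused
    model refit ``n_runs`` times with different seeds; each run records the
    mean optimized weight over the informative block and over the noise
    block. A working optimizer should put more trust in the informative
    block in (nearly) every run.

    The fitness is averaged over ``n_fitness_splits`` inner splits: the true
    generalization gain from downweighting a noise block is a few percent,
    below single-split eval noise, so a single-split fitness lets the swarm
    overfit split luck instead of the signal.
    """
    from .ipso_svm import fit_ipso_svm

    X = np.asarray(X, dtype=float)
    base = cfg or SwarmConfig(max_iter=30, h_e=1.0)
    informative = np.ones(X.shape[1], dtype=bool)
    informative[noise_block] = False
    rows = []
    for run in range(n_runs):
        run_seed = (seed + run) % (2**31 - 1)
        rng = np.random.default_rng(run_seed)
        Xn = X.copy()
        Xn[:, noise_block] = rng.normal(
            size=(len(X), Xn[:, noise_block].shape[1]))
        run_cfg = SwarmConfig(q=base.q, c1=base.c1, c2=base.c2,
                              omega=base.omega, h_e=base.h_e,
                              max_iter=base.max_iter, v_max=base.v_max,
                              seed=run_seed)
        _, d, rep = fit_ipso_svm(Xn, y, cfg=run_cfg,
                                 n_fitness_splits=n_fitness_splits)
        rows.append({
            "run": run,
            "seed": run_seed,
            "mean_weight_informative": float(d.d[informative].mean()),
            "mean_weight_noise": float(d.d[~informative].mean()),
            "final_h_g": rep["final_h_g"],
        })
    return pd.DataFrame(rows)


def compare_modalities(
    X: np.ndarray,
    y: Sequence[int],
    cfg: Optional[SwarmConfig] = None,
    C: float = 10.0,
    n_rep: int = 20,
    test_fraction: float = 0.3,
    seed: int = 0,
    fuse_single_modalities: bool = False,
) -> pd.DataFrame:
    """ECG-only vs sEMG-only vs fused, on identical MCCV splits.

    The fused row uses the PSO-fused model; the single-modality rows use the
    plain (identity-fusion) OVO-SVM on that block by default — within one
    modality the features share provenance, so there is little for fusion
    weights to arbitrate (set ``fuse_single_modalities=True`` to optimize
    them anyway). Kernel width follows the √(n features) heuristic per block.

    Returns a tidy 3-row table: modality × (3 per-class rates + mean).
    """
    X = np.asarray(X, dtype=float)
    blocks = {
        "ecg": X[:, ECG_BLOCK],
        "semg": X[:, SEMG_BLOCK],
        "fused": X,
    }
    rows = []
    reports = {}
    for name, Xb in blocks.items():
        optimize = (name == "fused") or fuse_single_modalities
        factory = ipso_svm_factory(
            cfg=cfg, C=C, sigma=float(np.sqrt(Xb.shape[1])), optimize=optimize)
        rep = mccv(Xb, y, factory, n_rep=n_rep, test_fraction=test_fraction,
                   seed=seed)
        reports[name] = rep
        rows.append({
            "modality": name,
            **{f"rate_{STATE_NAMES[c]}": rep.per_class_rate[c] for c in STATES},
            "mean_rate": rep.mean_rate,
            "sem_rate": float(np.std(rep.per_rep_rates, ddof=1)
                              / np.sqrt(rep.n_repetitions)),
        })
    table = pd.DataFrame(rows).set_index("modality")
    table.attrs["reports"] = reports
    return table
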