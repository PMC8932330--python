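"""PSO-optimized feature fusion on top of the one-vs-one RBF-SVM.

The fused sample is the elementwise product x_i = [d_1 f_i1, …, d_a f_ia,
d_{a+1} e_i1, …, d_{a+b} e_ib] of a fusion-coefficient vector d with the
concatenated, standardized ECG (a=3) and sEMG (b=8) feature blocks. The
coefficients act as trust degrees: the swarm searches the simplex-like set
{d : Σd_k = a+b, d_k ≥ 0} for weights maximizing the recognition rate of
the OVO-SVM retrained per candidate.

Particle swarm updates are the classic inertia form

    v ← ω v + c1 r1 (p_best − x) + c2 r2 (g_best − x),   x ← x + v,

with per-dimension uniform r1, r2, velocities clamped to ±v_max, and every
position mapped back onto the constraint set (negatives mirrored, vector
rescaled to sum a+b). The run stops when the global best recognition rate
reaches the expected fitness h_e or after max_iter iterations.

Features are z-scored with training-set statistics before fusion — the raw
features mix seconds, Hz and mV·s, so unscaled weights would be meaningless.
The PSO fitness is evaluated on a stratified inner split carved out of the
training set, keeping the outer test set out of coefficient optimization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .records import FeatureVector, N_FEATURES, STATES
from .svm import OvoSvmModel, train_ovo_svm

DEFAULT_C = 10.0
DEFAULT_SIGMA = float(np.sqrt(N_FEATURES))  # kernel width heuristic: √(n features)


# ---------------------------------------------------------------------------
# fusion coefficients


@dataclass
class FusionCoefficients:
    """Nonnegative weight vector d with Σ d_k = len(d) (= a+b = 11)."""

    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 1:
            raise ValueError("fusion coefficients must be a vector")
        total = len(self.d)
        if abs(self.d.sum() - total) > 1e-9:
            raise ValueError(
                f"coefficients must sum to {total}, got {self.d.sum():.12f}")
        if np.any(self.d < -1e-12):
            raise ValueError("fusion coefficients must be nonnegative")
        self.d = np.maximum(self.d, 0.0)

    def __len__(self) -> int:
        return len(self.d)

    @classmethod
    def ones(cls, dim: int = N_FEATURES) -> "FusionCoefficients":
        return cls(np.ones(dim))


def project_coefficients(raw: np.ndarray) -> np.ndarray:
    """Map a raw vector onto {d : Σd = len(d), d ≥ 0}.

    Negative components are mirrored about zero (reflected, not clipped)
    before rescaling to the required sum; an all-zero vector maps to the
    uniform weights. Reflection keeps a coordinate that overshoots the
    boundary alive: clipping it to zero is an absorbing state for the swarm
    once the personal and global bests are zero there too, which traps the
    search on a boundary facet.
    """
    raw = np.abs(np.asarray(raw, dtype=float))
    s = raw.sum()
    if s <= 0:
        return np.ones(len(raw))
    return raw * (len(raw) / s)


def fuse(features, coefficients: FusionCoefficients) -> np.ndarray:
    """Elementwise product of the weights with feature vector(s)."""
    if isinstance(features, FeatureVector):
        features = features.values
    features = np.asarray(features, dtype=float)
    if features.shape[-1] != len(coefficients):
        raise ValueError(
            f"dimension mismatch: features have {features.shape[-1]} "
            f"columns, coefficients {len(coefficients)}")
    return features * coefficients.d


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Scaler:
    """Per-feature z-scoring with training-set statistics."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        std = np.std(X, axis=0)
        return cls(mean=np.mean(X, axis=0), std=np.where(std > 1e-12, std, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(np.asarray(d["mean"], float), np.asarray(d["std"], float))


# ---------------------------------------------------------------------------
# particle swarm


@dataclass
class SwarmConfig:
    """PSO settings.

    Defaults are the desk-scale profile (q=50, max_iter=100);
    :func:`study_swarm_config` returns the study-scale profile with
    q=2000, c1=c2=0.5, ω=0.8 and expected fitness 0.95.
    """

    q: int = 50
    c1: float = 0.5
    c2: float = 0.5
    omega: float = 0.8
    h_e: float = 0.95
    max_iter: int = 100
    v_max: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError(f"swarm size must be >= 1, got {self.q}")
        if min(self.c1, self.c2, self.omega) < 0:
            raise ValueError("c1, c2 and omega must be nonnegative")
        if not 0 <= self.h_e <= 1:
            raise ValueError(f"expected fitness must be in [0, 1], got {self.h_e}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def study_swarm_config(seed: int = 0) -> SwarmConfig:
    """Study-scale swarm: q=2000, c1=c2=0.5, ω=0.8, expected fitness 95%."""
    return SwarmConfig(q=2000, c1=0.5, c2=0.5, omega=0.8, h_e=0.95,
                       max_iter=200, seed=seed)


def pso_optimize(
    fitness_fn: Callable[[np.ndarray], float],
    cfg: SwarmConfig,
    dim: int = N_FEATURES,
) -> tuple[FusionCoefficients, list[float]]:
    """Maximize ``fitness_fn`` over the constrained coefficient set.

    Returns the best coefficients found and the per-iteration trace of the
    global-best fitness h_g (index 0 is the initial population's best). The
    trace is non-decreasing by construction; the whole trajectory is
    determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    pos = np.vstack([
        project_coefficients(rng.uniform(0.0, 1.0, dim)) for _ in range(cfg.q)
    ])
    vel = rng.uniform(-1.0, 1.0, (cfg.q, dim))
    fit = np.array([fitness_fn(p) for p in pos])
    pbest_pos = pos.copy()
    pbest_fit = fit.copy()
    g = int(np.argmax(fit))
    gbest_pos, gbest_fit = pos[g].copy(), float(fit[g])
    history = [gbest_fit]
    for _ in range(cfg.max_iter):
        if gbest_fit >= cfg.h_e:
            break
        r1 = rng.uniform(size=(cfg.q, dim))
        r2 = rng.uniform(size=(cfg.q, dim))
        vel = (cfg.omega * vel
               + cfg.c1 * r1 * (pbest_pos - pos)
               + cfg.c2 * r2 * (gbest_pos[None, :] - pos))
        np.clip(vel, -cfg.v_max, cfg.v_max, out=vel)
        pos = pos + vel
        pos = np.vstack([project_coefficients(p) for p in pos])
        fit = np.array([fitness_fn(p) for p in pos])
        improved = fit > pbest_fit
        pbest_pos[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest_fit = float(pbest_fit[g])
            gbest_pos = pbest_pos[g].copy()
        history.append(gbest_fit)
    return FusionCoefficients(project_coefficients(gbest_pos)), history


# ---------------------------------------------------------------------------
# recognition-rate fitness and the end-to-end fit


def fitness(
    d: np.ndarray | FusionCoefficients,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
    y_eval: np.ndarray,
    C: float = DEFAULT_C,
    sigma: float = DEFAULT_SIGMA,
) -> float:
    """Recognition rate of an OVO-SVM trained on features fused with ``d``.

    Both splits must already be standardized; the training split must
    contain all three states.
    """
    if len(X_train) == 0 or len(X_eval) == 0:
        raise ValueError("fitness requires non-empty train and eval splits")
    if not isinstance(d, FusionCoefficients):
        d = FusionCoefficients(project_coefficients(d))
    model = train_ovo_svm(fuse(X_train, d), y_train, C=C, sigma=sigma)
    pred = model.predict(fuse(X_eval, d))
    return float(np.mean(pred == np.asarray(y_eval)))


@dataclass
class IpsoSvmClassifier:
    """End-to-end fused classifier: z-score → PSO fusion → OVO RBF-SVM.

    With ``optimize=False`` the coefficients stay at the identity (all
    ones), which reduces the model to a plain OVO-SVM on standardized
    features — the unfused reference the fusion is compared against.
    """

    cfg: SwarmConfig = field(default_factory=SwarmConfig)
    C: float = DEFAULT_C
    sigma: float = DEFAULT_SIGMA
    optimize: bool = True
    inner_test_fraction: float = 0.3
    n_fitness_splits: int = 1
    scaler: Optional[Scaler] = None
    coefficients: Optional[FusionCoefficients] = None
    model: Optional[OvoSvmModel] = None
    report: dict = field(default_factory=dict)

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "IpsoSvmClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        missing = [c for c in STATES if c not in set(np.unique(y))]
        if missing:
            raise ValueError(f"training data is missing class(es) {missing}")
        self.scaler = Scaler.fit(X)
        Xs = self.scaler.transform(X)
        dim = X.shape[1]
        if self.optimize:
            # stratified inner split(s) carved out of the training data; the
            # outer test set never enters coefficient optimization. Averaging
            # the recognition rate over several inner splits
            # (n_fitness_splits > 1) reduces fitness variance when the effect
            # of a weight change is smaller than single-split noise.
            from sklearn.model_selection import StratifiedShuffleSplit

            splitter = StratifiedShuffleSplit(
                n_splits=self.n_fitness_splits,
                test_size=self.inner_test_fraction,
                random_state=self.cfg.seed % (2**31 - 1))
            splits = list(splitter.split(Xs, y))

            def fitness_fn(d: np.ndarray) -> float:
                return float(np.mean([
                    fitness(d, Xs[tr], y[tr], Xs[ev], y[ev],
                            C=self.C, sigma=self.sigma)
                    for tr, ev in splits
                ]))

            self.coefficients, history = pso_optimize(
                fitness_fn, self.cfg, dim=dim)
            self.report = {
                "iterations": len(history) - 1,
                "final_h_g": history[-1],
                "h_g_trace": history,
            }
        else:
            self.coefficients = FusionCoefficients.ones(dim)
            self.report = {"iterations": 0, "final_h_g": None, "h_g_trace": []}
        self.model = train_ovo_svm(
            fuse(Xs, self.coefficients), y, C=self.C, sigma=self.sigma)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None or self.scaler is None:
            raise RuntimeError("classifier has not been fitted")
        fused = fuse(self.scaler.transform(X), self.coefficients)
        return self.model.predict(fused)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        if self.model is None:
            raise RuntimeError("cannot serialize an unfitted classifier")
        return {
            "format": "fatiguefuse-ipso-svm",
            "version": 1,
            "C": self.C,
            "sigma": self.sigma,
            "optimize": self.optimize,
            "cfg": {
                "q": self.cfg.q, "c1": self.cfg.c1, "c2": self.cfg.c2,
                "omega": self.cfg.omega, "h_e": self.cfg.h_e,
                "max_iter": self.cfg.max_iter, "v_max": self.cfg.v_max,
                "seed": self.cfg.seed,
            },
            "scaler": self.scaler.to_dict(),
            "coefficients": self.coefficients.d.tolist(),
            "model": self.model.to_dict(),
            "report": {k: v for k, v in self.report.items() if k != "h_g_trace"},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IpsoSvmClassifier":
        obj = cls(
            cfg=SwarmConfig(**d["cfg"]),
            C=float(d["C"]),
            sigma=float(d["sigma"]),
            optimize=bool(d["optimize"]),
        )
        obj.scaler = Scaler.from_dict(d["scaler"])
        obj.coefficients = FusionCoefficients(np.asarray(d["coefficients"]))
        obj.model = OvoSvmModel.from_dict(d["model"])
        obj.report = dict(d.get("report", {}))
        return obj

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "IpsoSvmClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_ipso_svm(
    dataset: Sequence[FeatureVector] | np.ndarray,
    labels: Optional[Sequence[int]] = None,
    cfg: Optional[SwarmConfig] = None,
    C: float = DEFAULT_C,
    sigma: float = DEFAULT_SIGMA,
    inner_test_fraction: float = 0.3,
    n_fitness_splits: int = 1,
) -> tuple[IpsoSvmClassifier, FusionCoefficients, dict]:
    """Fit the full pipeline on a labeled feature dataset.

    ``dataset`` may be a list of :class:`FeatureVector` (labels taken from
    them) or a feature matrix with ``labels`` given separately. Returns the
    fitted classifier, the optimal fusion coefficients and a training report
    (iterations used, final global-best fitness).
    """
    if labels is None:
        from .records import feature_matrix

        X, y = feature_matrix(list(dataset))
        if np.any(np.isnan(y)):
            raise ValueError("dataset contains unlabeled feature vectors")
        y = y.astype(int)
    else:
        X = np.asarray(dataset, dtype=float)
        y = np.asarray(labels, dtype=int)
    clf = IpsoSvmClassifier(
        cfg=cfg or SwarmConfig(), C=C, sigma=sigma,
        inner_test_fraction=inner_test_fraction,
        n_fitness_splits=n_fitness_splits)
    clf.fit(X, y)
    return clf, clf.coefficients, clf.report
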