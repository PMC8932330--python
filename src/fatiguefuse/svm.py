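"""One-vs-one ensemble of binary soft-margin RBF-SVMs for the 3 fatigue states.

Three binary sub-models are trained, one per state pair ((-1,0), (-1,1),
(0,1)). Each solves the usual soft-margin dual

    max Σα_i − ½ ΣΣ α_i α_j y_i y_j K(x_i, x_j)
    s.t. 0 ≤ α_i ≤ C,  Σ α_i y_i = 0,

with the Gaussian kernel K(x, x') = exp(−‖x − x'‖²/σ²). Prediction lets the
three sub-models vote via the sign of f(x) = Σ α*_i y_i K(x, x_i) + b*;
vote ties are broken by the largest summed |decision value| and then by the
lowest class label — deterministic and order-independent.

The binary QP is solved by scikit-learn's SVC (libsvm); the ensemble stores
the support vectors, signed dual coefficients and bias of each sub-model, so
serialized models predict without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .records import STATES

PAIRS = ((-1, 0), (-1, 1), (0, 1))


def rbf_kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    """exp(−‖a_i − b_j‖² / σ²) for all row pairs."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    sq = (
        np.sum(a * a, axis=1)[:, None]
        + np.sum(b * b, axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return np.exp(-np.maximum(sq, 0.0) / sigma**2)


@dataclass
class BinarySvm:
    """One trained pair classifier: decision > 0 votes for ``pos_label``."""

    neg_label: int
    pos_label: int
    support_vectors: np.ndarray
    dual_coef: np.ndarray  # signed: α_i y_i with y ∈ {−1 for neg, +1 for pos}
    bias: float
    C: float
    sigma: float

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        k = rbf_kernel(np.atleast_2d(X), self.support_vectors, self.sigma)
        return k @ self.dual_coef + self.bias

    @property
    def alphas(self) -> np.ndarray:
        """Unsigned dual variables α_i (all in [0, C])."""
        return np.abs(self.dual_coef)

    def dual_feasibility(self) -> tuple[float, float]:
        """(max constraint violation of 0 ≤ α ≤ C, |Σ α_i y_i|)."""
        box = max(float(np.max(self.alphas - self.C)), 0.0)
        box = max(box, max(float(np.max(-self.alphas)), 0.0))
        return box, abs(float(np.sum(self.dual_coef)))

    def to_dict(self) -> dict:
        return {
            "neg_label": self.neg_label,
            "pos_label": self.pos_label,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "C": self.C,
            "sigma": self.sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinarySvm":
        return cls(
            neg_label=int(d["neg_label"]),
            pos_label=int(d["pos_label"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            bias=float(d["bias"]),
            C=float(d["C"]),
            sigma=float(d["sigma"]),
        )


def _fit_pair(
    X: np.ndarray, y: np.ndarray, neg: int, pos: int, C: float, sigma: float
) -> BinarySvm:
    mask = (y == neg) | (y == pos)
    Xp, yp = X[mask], np.where(y[mask] == pos, 1.0, -1.0)
    svc = SVC(C=C, kernel="rbf", gamma=1.0 / sigma**2, tol=1e-6)
    svc.fit(Xp, yp)
    # libsvm's dual_coef_ is α_i y_i ordered by class; decision > 0 predicts
    # the larger mapped class (+1 here, i.e. ``pos``)
    return BinarySvm(
        neg_label=neg,
        pos_label=pos,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        C=C,
        sigma=sigma,
    )


@dataclass
class OvoSvmModel:
    """Three binary sub-models plus the voting rule."""

    sub_models: list[BinarySvm] = field(default_factory=list)

    @property
    def fitted(self) -> bool:
        return len(self.sub_models) == len(PAIRS)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("OVO model has not been trained")
        X = np.atleast_2d(X)
        n = len(X)
        votes = {c: np.zeros(n) for c in STATES}
        strength = {c: np.zeros(n) for c in STATES}
        for sub in self.sub_models:
            f = sub.decision_values(X)
            pos = f > 0
            votes[sub.pos_label] += pos
            votes[sub.neg_label] += ~pos
            strength[sub.pos_label] += np.where(pos, np.abs(f), 0.0)
            strength[sub.neg_label] += np.where(~pos, np.abs(f), 0.0)
        vote_mat = np.column_stack([votes[c] for c in STATES])
        str_mat = np.column_stack([strength[c] for c in STATES])
        out = np.empty(n, dtype=int)
        classes = np.asarray(STATES)
        for i in range(n):
            best = np.max(vote_mat[i])
            tied = np.where(vote_mat[i] == best)[0]
            if len(tied) > 1:
                # tie-break 1: largest summed |decision value|;
                # tie-break 2: lowest class label (classes are sorted)
                tied = tied[str_mat[i, tied] == np.max(str_mat[i, tied])]
            out[i] = classes[tied[0]]
        return out

    def decision_table(self, X: np.ndarray) -> np.ndarray:
        """Raw decision values, one column per state pair (for diagnostics)."""
        return np.column_stack(
            [sub.decision_values(np.atleast_2d(X)) for sub in self.sub_models]
        )

    def to_dict(self) -> dict:
        return {"sub_models": [s.to_dict() for s in self.sub_models]}

    @classmethod
    def from_dict(cls, d: dict) -> "OvoSvmModel":
        return cls(sub_models=[BinarySvm.from_dict(s) for s in d["sub_models"]])


def train_ovo_svm(
    X: np.ndarray, y: np.ndarray, C: float = 10.0, sigma: float = np.sqrt(11.0)
) -> OvoSvmModel:
    """Train the three pairwise sub-models on (already fused) features."""
    if C <= 0 or sigma <= 0:
        raise ValueError(f"C and sigma must be positive, got C={C}, sigma={sigma}")
    y = np.asarray(y)
    present = set(np.unique(y).astype(int))
    missing = [c for c in STATES if c not in present]
    if missing:
        raise ValueError(f"training data is missing class(es) {missing}")
    X = np.asarray(X, dtype=float)
    return OvoSvmModel(
        sub_models=[_fit_pair(X, y, neg, pos, C, sigma) for neg, pos in PAIRS]
    )
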