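"""Two-class Fisher discriminant analysis.

The discriminant direction maximizes the between-class over within-class
scatter Rayleigh quotient, found as the leading generalized eigenvector of
``S_b phi = lambda (S_w + eps I) phi``. The default decision threshold is
the midpoint of the projected class means; the sign convention is fixed so
that the lesion class projects above the threshold.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Union

import numpy as np
from scipy import linalg

from .errors import ParameterError

__all__ = ["FdaModel", "scatter_matrices", "fit_fda", "score", "classify"]

MODEL_FORMAT_VERSION = 1


@dataclasses.dataclass
class FdaModel:
    w: np.ndarray                       # discriminant direction
    c: float                            # projected-means midpoint threshold
    mu1: np.ndarray                     # lesion-class mean (normalized space)
    mu2: np.ndarray                     # background-class mean
    epsilon: float
    norm_stats: Optional[tuple[np.ndarray, np.ndarray]] = None
    sign_flipped: bool = False
    feature_names: Optional[tuple[str, ...]] = None

    def to_json(self) -> str:
        payload = {
            "version": MODEL_FORMAT_VERSION,
            "w": self.w.tolist(),
            "c": self.c,
            "mu1": self.mu1.tolist(),
            "mu2": self.mu2.tolist(),
            "epsilon": self.epsilon,
            "sign_flipped": self.sign_flipped,
            "norm_mu": None if self.norm_stats is None else self.norm_stats[0].tolist(),
            "norm_sigma": None if self.norm_stats is None else self.norm_stats[1].tolist(),
            "feature_names": list(self.feature_names) if self.feature_names else None,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FdaModel":
        d = json.loads(text)
        norm_stats = None
        if d.get("norm_mu") is not None:
            norm_stats = (np.asarray(d["norm_mu"]), np.asarray(d["norm_sigma"]))
        return cls(
            w=np.asarray(d["w"], dtype=np.float64),
            c=float(d["c"]),
            mu1=np.asarray(d["mu1"], dtype=np.float64),
            mu2=np.asarray(d["mu2"], dtype=np.float64),
            epsilon=float(d["epsilon"]),
            norm_stats=norm_stats,
            sign_flipped=bool(d.get("sign_flipped", False)),
            feature_names=tuple(d["feature_names"]) if d.get("feature_names") else None,
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "FdaModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def scatter_matrices(
    X1: np.ndarray, X2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Between- and within-class scatter matrices and class means.

    ``S_b = sum_k n_k (mu_k - mu)(mu_k - mu)^T`` with *mu* the overall mean;
    ``S_w = sum_k sum_{x in C_k} (x - mu_k)(x - mu_k)^T``.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=np.float64))
    X2 = np.atleast_2d(np.asarray(X2, dtype=np.float64))
    if X1.shape[0] < 2 or X2.shape[0] < 2:
        raise ParameterError(
            f"each class needs >= 2 samples, got {X1.shape[0]} and {X2.shape[0]}"
        )
    if X1.shape[1] != X2.shape[1]:
        raise ParameterError("class matrices disagree on feature dimension")
    mu1 = X1.mean(axis=0)
    mu2 = X2.mean(axis=0)
    n1, n2 = X1.shape[0], X2.shape[0]
    mu = (X1.sum(axis=0) + X2.sum(axis=0)) / (n1 + n2)
    d1 = (mu1 - mu)[:, None]
    d2 = (mu2 - mu)[:, None]
    s_b = n1 * (d1 @ d1.T) + n2 * (d2 @ d2.T)
    c1 = X1 - mu1
    c2 = X2 - mu2
    s_w = c1.T @ c1 + c2.T @ c2
    return s_b, s_w, mu1, mu2


def fit_fda(
    X1: np.ndarray, X2: np.ndarray, epsilon: Optional[float] = None
) -> FdaModel:
    """Fit the discriminant on lesion samples *X1* vs background *X2*.

    *epsilon* is a ridge added to ``S_w``; by default
    ``1e-6 * trace(S_w) / d``. Pass ``epsilon=0`` to disable (raises a
    helpful error when ``S_w`` is singular).
    """
    s_b, s_w, mu1, mu2 = scatter_matrices(X1, X2)
    d = s_w.shape[0]
    if epsilon is None:
        epsilon = 1e-6 * float(np.trace(s_w)) / d
    s_w_reg = s_w + epsilon * np.eye(d)

    try:
        eigvals, eigvecs = linalg.eigh(s_b, s_w_reg)
    except linalg.LinAlgError as exc:
        raise ParameterError(
            "within-class scatter is singular; refit with epsilon > 0"
        ) from exc
    w = eigvecs[:, int(np.argmax(eigvals))]
    norm = float(np.linalg.norm(w))
    if norm == 0.0:
        raise ParameterError("degenerate discriminant direction")
    w = w / norm

    sign_flipped = False
    if float(w @ mu1) < float(w @ mu2):
        w = -w
        sign_flipped = True
    c = float(w @ (mu1 + mu2) / 2.0)
    return FdaModel(
        w=w, c=c, mu1=mu1, mu2=mu2, epsilon=float(epsilon),
        sign_flipped=sign_flipped,
    )


def closed_form_direction(
    X1: np.ndarray, X2: np.ndarray, epsilon: Optional[float] = None
) -> np.ndarray:
    """Two-class closed form ``w propto (S_w + eps I)^-1 (mu_1 - mu_2)``."""
    _, s_w, mu1, mu2 = scatter_matrices(X1, X2)
    d = s_w.shape[0]
    if epsilon is None:
        epsilon = 1e-6 * float(np.trace(s_w)) / d
    w = np.linalg.solve(s_w + epsilon * np.eye(d), mu1 - mu2)
    return w / np.linalg.norm(w)


def score(model: FdaModel, x: np.ndarray) -> Union[float, np.ndarray]:
    """Project sample(s) onto the discriminant direction."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        return float(model.w @ x)
    return x @ model.w


def classify(
    model: FdaModel, x: np.ndarray, c_override: Optional[float] = None
) -> Union[bool, np.ndarray]:
    """Lesion iff the projection strictly exceeds the threshold."""
    threshold = model.c if c_override is None else float(c_override)
    s = score(model, x)
    if np.isscalar(s):
        return bool(s > threshold)
    return s > threshold
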