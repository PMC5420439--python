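"""Per-candidate 31-dimensional feature vectors.

Layout (fixed order):

* 28 channel statistics: for each of the 7 channels, ``(max, min, mean,
  median)`` over the candidate's pixels;
* 2 global statistics: mean and population standard deviation of the
  enhanced green plane inside the field of view;
* 1 contextual score comparing the candidate's mean green intensity with
  its neighbours', weighted by inverse squared barycenter distance.

Feature vectors are z-normalized per dimension; the normalization statistics
are fitted on the training set and reused at prediction time.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNEL_NAMES, ChannelStack
from .errors import ParameterError
from .preprocess import FovMask, PreprocessedImage
from .superpixels import Candidate

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES",
    "candidate_channel_stats",
    "global_stats",
    "contextual_feature",
    "assemble_features",
    "normalize_features",
    "features_to_frame",
    "frame_to_features",
]

_STAT_NAMES = ("max", "min", "mean", "median")
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{st}" for ch in CHANNEL_NAMES for st in _STAT_NAMES
) + ("global_mean", "global_std", "context_score")
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 31


def candidate_channel_stats(stack: ChannelStack, cand: Candidate) -> np.ndarray:
    """``(max, min, mean, median)`` per channel over the candidate pixels."""
    if cand.area < 1:
        raise ParameterError(f"candidate {cand.label} has no pixels")
    rr = cand.pixel_coords[:, 0]
    cc = cand.pixel_coords[:, 1]
    out = np.empty(28)
    for i, ch in enumerate(stack.channels):
        vals = ch[rr, cc]
        out[4 * i : 4 * i + 4] = (
            vals.max(),
            vals.min(),
            vals.mean(),
            np.median(vals),
        )
    return out


def global_stats(pre: PreprocessedImage, fov: FovMask) -> tuple[float, float]:
    """Mean and population std of the enhanced green plane inside the FOV."""
    vals = pre.green_enhanced[fov.mask]
    return float(vals.mean()), float(vals.std())


def contextual_feature(
    cands: Sequence[Candidate],
    green_enhanced: np.ndarray,
    fov: FovMask,
    denominator: str = "pixels",
) -> np.ndarray:
    """Contextual score per candidate.

    For candidate *i* with neighbours *N(i)*::

        S_i = sum_{j in N(i)} (av_i / av_global) * d1(i, j) / d2(i, j)  / denom

    where ``d1 = +(av_i - av_j)^2`` when the candidate is at most as bright
    as its neighbour (dark spot: positive evidence) and negative otherwise,
    and ``d2`` is the squared barycenter distance. ``denom`` is the
    candidate's pixel count (default) or its neighbour count.
    """
    if denominator not in ("pixels", "neighbors"):
        raise ParameterError(f"unknown denominator mode {denominator!r}")
    av_global = float(green_enhanced[fov.mask].mean())
    if av_global <= 0:
        raise ParameterError("global mean green intensity must be positive")

    av = np.array(
        [green_enhanced[c.pixel_coords[:, 0], c.pixel_coords[:, 1]].mean() for c in cands]
    )
    bary = np.array([c.barycenter for c in cands])

    scores = np.zeros(len(cands))
    for i, cand in enumerate(cands):
        neigh = sorted(cand.neighbor_ids)
        if not neigh:
            continue
        total = 0.0
        used = 0
        for j in neigh:
            d2 = float(((bary[i] - bary[j]) ** 2).sum())
            if d2 == 0.0:
                warnings.warn(
                    f"candidates {cand.label} and {cands[j].label} share a "
                    "barycenter; pair skipped in contextual feature"
                )
                continue
            diff2 = float((av[i] - av[j]) ** 2)
            d1 = diff2 if av[i] <= av[j] else -diff2
            total += (av[i] / av_global) * d1 / d2
            used += 1
        denom = cand.area if denominator == "pixels" else max(used, 1)
        scores[i] = total / denom
    return scores


def assemble_features(
    stats28: np.ndarray, global2: Sequence[float], s_i: float
) -> np.ndarray:
    """Concatenate the feature groups into the frozen 31-entry layout."""
    stats28 = np.asarray(stats28, dtype=np.float64)
    if stats28.shape != (28,):
        raise ParameterError(f"expected 28 channel stats, got {stats28.shape}")
    if len(global2) != 2:
        raise ParameterError(f"expected 2 global stats, got {len(global2)}")
    vec = np.concatenate([stats28, np.asarray(global2, dtype=np.float64), [float(s_i)]])
    assert vec.shape == (N_FEATURES,)
    return vec


def normalize_features(
    all_raw: np.ndarray,
    stats: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Z-normalize feature columns.

    When *stats* is None the per-dimension mean and population std are
    fitted on *all_raw* (requires >= 2 rows) and returned for reuse.
    Constant columns map to zero with a warning.
    """
    X = np.asarray(all_raw, dtype=np.float64)
    if X.ndim != 2:
        raise ParameterError(f"expected n x d matrix, got shape {X.shape}")
    if stats is None:
        if X.shape[0] < 2:
            raise ParameterError("need at least 2 samples to fit normalization")
        mu = X.mean(axis=0)
        sigma = X.std(axis=0)
    else:
        mu, sigma = (np.asarray(a, dtype=np.float64) for a in stats)
        if mu.shape != (X.shape[1],) or sigma.shape != (X.shape[1],):
            raise ParameterError(
                f"normalization stats of dim {mu.shape} do not match data "
                f"dim {X.shape[1]}"
            )
    degenerate = sigma == 0.0
    if degenerate.any() and stats is None:
        warnings.warn(
            f"{int(degenerate.sum())} constant feature column(s) mapped to zero"
        )
    safe_sigma = np.where(degenerate, 1.0, sigma)
    Xn = (X - mu) / safe_sigma
    Xn[:, degenerate] = 0.0
    return Xn, (mu, sigma)


def features_to_frame(
    raw: np.ndarray,
    candidate_ids: Iterable[int],
    image_id: str = "",
    labels: Optional[Iterable[int]] = None,
) -> pd.DataFrame:
    """Feature matrix as a table with the fixed 31-name header."""
    raw = np.atleast_2d(np.asarray(raw, dtype=np.float64))
    df = pd.DataFrame(raw, columns=list(FEATURE_NAMES))
    df.insert(0, "candidate_id", list(candidate_ids))
    df.insert(0, "image_id", image_id)
    df["label"] = list(labels) if labels is not None else -1
    return df


def frame_to_features(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`features_to_frame`: returns ``(X, labels)``."""
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ParameterError(f"feature table missing columns: {missing}")
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    labels = df["label"].to_numpy() if "label" in df.columns else np.full(len(df), -1)
    return X, labels
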