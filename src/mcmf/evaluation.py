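"""Image-based and pixel-based performance assessment.

Image-based: each image is scored by its best candidate and ranked against
the image-level label (lesion present / absent). Pixel-based: predicted
connected components are validated against ground-truth components with a
>= 75 % area-overlap rule.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError

__all__ = [
    "EvalReport",
    "image_score",
    "confusion_and_rates",
    "roc_auc",
    "pixel_based_validation",
]

NO_CANDIDATE_SCORE = float("-inf")
_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclasses.dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    criterion: str
    roc_points: Optional[tuple[tuple[float, float], ...]] = None
    auc: Optional[float] = None

    @property
    def sensitivity(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom > 0 else None

    @property
    def specificity(self) -> Optional[float]:
        denom = self.tn + self.fp
        return self.tn / denom if denom > 0 else None


def image_score(candidate_scores: Sequence[float]) -> float:
    """Maximum candidate score; ``-inf`` for an image with no candidates so
    that it ranks below every scored image."""
    scores = list(candidate_scores)
    if not scores:
        return NO_CANDIDATE_SCORE
    return float(max(scores))


def confusion_and_rates(
    labels: Sequence[bool], predictions: Sequence[bool], criterion: str = "image_based"
) -> EvalReport:
    """Confusion counts and rates from boolean labels/predictions."""
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(predictions, dtype=bool)
    if y.shape != p.shape:
        raise ParameterError(f"shape mismatch: {y.shape} vs {p.shape}")
    tp = int(np.sum(y & p))
    fn = int(np.sum(y & ~p))
    fp = int(np.sum(~y & p))
    tn = int(np.sum(~y & ~p))
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, criterion=criterion)


def roc_auc(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[tuple[tuple[float, float], ...], float]:
    """ROC points ``(1 - specificity, sensitivity)`` and trapezoid AUC.

    Equal scores are grouped into a single threshold step, which makes the
    trapezoid area identical to the tie-corrected Mann-Whitney statistic.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ParameterError("scores and labels must be matching 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("ROC needs both positive and negative samples")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group ties: indices where a new (lower) score starts
    distinct = np.nonzero(np.diff(s_sorted))[0]
    block_ends = np.concatenate([distinct, [len(s_sorted) - 1]])
    cum_tp = np.cumsum(y_sorted)
    cum_fp = np.cumsum(~y_sorted)

    tpr = np.concatenate([[0.0], cum_tp[block_ends] / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], cum_fp[block_ends] / n_neg, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    points = tuple((float(x), float(t)) for x, t in zip(fpr, tpr))
    return points, auc


def pixel_based_validation(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    min_overlap: float = 0.75,
    strict_upper: bool = False,
    tn_count: int = 0,
) -> EvalReport:
    """Connected-component validation of a lesion mask.

    A ground-truth component counts as TP when the prediction covers at
    least *min_overlap* of its area (with ``strict_upper=True`` a fully
    covered component is rejected, reproducing the literal "< 100 %"
    reading); otherwise it is a FN. Predicted components touching no ground
    truth are FPs. TN is not defined at component level; *tn_count* lets the
    caller supply the count of correctly rejected candidates.
    """
    pred = np.asarray(pred_mask, dtype=bool)
    gt = np.asarray(gt_mask, dtype=bool)
    if pred.shape != gt.shape:
        raise ParameterError(f"mask shape mismatch: {pred.shape} vs {gt.shape}")
    if not 0.0 < min_overlap <= 1.0:
        raise ParameterError(f"min_overlap must lie in (0, 1], got {min_overlap}")

    gt_labels, n_gt = ndi.label(gt, structure=_EIGHT_CONN)
    pred_labels, n_pred = ndi.label(pred, structure=_EIGHT_CONN)

    tp = fn = 0
    for comp in range(1, n_gt + 1):
        comp_mask = gt_labels == comp
        area = int(comp_mask.sum())
        covered = int((pred & comp_mask).sum())
        coverage = covered / area
        hit = coverage >= min_overlap and (coverage < 1.0 if strict_upper else True)
        if hit:
            tp += 1
        else:
            fn += 1

    fp = 0
    for comp in range(1, n_pred + 1):
        comp_mask = pred_labels == comp
        if not (gt & comp_mask).any():
            fp += 1

    return EvalReport(
        tp=tp, fp=fp, tn=int(tn_count), fn=fn, criterion="pixel_based"
    )
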