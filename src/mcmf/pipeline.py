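"""End-to-end orchestration: image -> candidates -> features -> detection.

This module wires the stage modules together for training and inference;
all numerical substance lives in the stage modules themselves.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from . import evaluation, fda, features, postprocess, preprocess, superpixels
from .channels import ChannelConfig, ChannelStack, build_channel_stack
from .errors import ParameterError
from .fda import FdaModel
from .postprocess import FoveaGeometry, LesionMap, VesselConfig, VesselMap
from .preprocess import FovMask, FundusImage, PreprocessedImage
from .superpixels import Candidate, SlicParams, SuperpixelMap

__all__ = [
    "PipelineConfig",
    "ImageAnalysis",
    "DetectionResult",
    "analyze_image",
    "candidate_labels",
    "train_on_images",
    "detect",
]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    slic: SlicParams = SlicParams()
    channels: ChannelConfig = ChannelConfig()
    vessels: VesselConfig = VesselConfig()
    fovea: FoveaGeometry = FoveaGeometry()
    fov_threshold: float = preprocess.DEFAULT_FOV_THRESHOLD
    clahe_clip: float = preprocess.DEFAULT_CLAHE_CLIP
    clahe_tiles: int = preprocess.DEFAULT_CLAHE_TILES
    context_denominator: str = "pixels"
    vessel_overlap_frac: float = 0.5
    candidate_label_min_frac: float = 0.3
    suppress_vessels: bool = True
    suppress_fovea: bool = True


@dataclasses.dataclass
class ImageAnalysis:
    image: FundusImage
    fov: FovMask
    pre: PreprocessedImage
    spmap: SuperpixelMap
    candidates: list[Candidate]
    stack: ChannelStack
    raw_features: np.ndarray  # n_candidates x 31


@dataclasses.dataclass
class DetectionResult:
    analysis: ImageAnalysis
    scores: np.ndarray              # FDA projection per candidate
    predictions: np.ndarray         # after postprocessing
    predictions_raw: np.ndarray     # before postprocessing
    suppressed: np.ndarray          # candidates eligible for suppression
    lesion_map: LesionMap
    vessel_map: Optional[VesselMap]
    image_score: float


def analyze_image(img: FundusImage, config: PipelineConfig) -> ImageAnalysis:
    """Run preprocessing, segmentation and feature extraction on one image."""
    fov = preprocess.compute_fov_mask(img, threshold=config.fov_threshold)
    pre = preprocess.enhance(
        img, fov, clahe_clip=config.clahe_clip, tile=config.clahe_tiles
    )
    spmap = superpixels.slic_segment(pre, fov, config.slic)
    cands = superpixels.extract_candidates(spmap, config.slic)
    stack = build_channel_stack(pre, config.channels)
    g = features.global_stats(pre, fov)
    context = features.contextual_feature(
        cands, pre.green_enhanced, fov, denominator=config.context_denominator
    )
    raw = np.stack(
        [
            features.assemble_features(
                features.candidate_channel_stats(stack, cand), g, context[i]
            )
            for i, cand in enumerate(cands)
        ]
    )
    return ImageAnalysis(
        image=img, fov=fov, pre=pre, spmap=spmap, candidates=cands,
        stack=stack, raw_features=raw,
    )


def candidate_labels(
    cands: Sequence[Candidate], lesion_mask: np.ndarray, min_frac: float = 0.3
) -> np.ndarray:
    """Ground-truth candidate labels: lesion iff at least *min_frac* of the
    candidate's pixels fall inside the lesion mask."""
    out = np.zeros(len(cands), dtype=bool)
    for i, cand in enumerate(cands):
        rr, cc = cand.pixel_coords[:, 0], cand.pixel_coords[:, 1]
        out[i] = lesion_mask[rr, cc].mean() >= min_frac
    return out


def train_on_images(
    images: Sequence[FundusImage],
    lesion_masks: Sequence[np.ndarray],
    config: PipelineConfig,
) -> tuple[FdaModel, list[ImageAnalysis]]:
    """Extract features from all training images and fit the classifier."""
    if len(images) != len(lesion_masks):
        raise ParameterError("images and masks differ in length")
    analyses = [analyze_image(img, config) for img in images]
    X_parts, y_parts = [], []
    for analysis, mask in zip(analyses, lesion_masks):
        X_parts.append(analysis.raw_features)
        y_parts.append(
            candidate_labels(
                analysis.candidates, mask, config.candidate_label_min_frac
            )
        )
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ParameterError(
            "training set needs at least 2 lesion and 2 background candidates"
        )
    Xn, stats = features.normalize_features(X)
    model = fda.fit_fda(Xn[y], Xn[~y])
    model.norm_stats = stats
    model.feature_names = features.FEATURE_NAMES
    return model, analyses


def detect(
    img: FundusImage,
    model: FdaModel,
    config: PipelineConfig,
    c_override: Optional[float] = None,
    analysis: Optional[ImageAnalysis] = None,
) -> DetectionResult:
    """Classify candidates and apply vessel/fovea suppression.

    The image-level score is the maximum FDA projection over candidates that
    survive suppression (suppression itself is threshold-free, so the score
    supports ROC sweeps).
    """
    if model.norm_stats is None:
        raise ParameterError("model carries no normalization statistics")
    if analysis is None:
        analysis = analyze_image(img, config)
    Xn, _ = features.normalize_features(analysis.raw_features, stats=model.norm_stats)
    scores = np.asarray(fda.score(model, Xn), dtype=np.float64)
    preds_raw = np.asarray(fda.classify(model, Xn, c_override=c_override), dtype=bool)

    # threshold-free suppression eligibility: treat every candidate as if
    # predicted red, see which would be removed
    all_red = np.ones(len(analysis.candidates), dtype=bool)
    vessel_map = None
    if config.suppress_vessels:
        vessel_map = postprocess.vessel_map_multiscale(
            analysis.pre.clahe_gray,
            scales=config.vessels.scales,
            fov=analysis.fov,
            config=config.vessels,
        )
        all_red = postprocess.suppress_vessel_candidates(
            analysis.candidates, all_red, vessel_map, config.vessel_overlap_frac
        )
    if config.suppress_fovea:
        od = postprocess.locate_optic_disc(analysis.pre, analysis.fov)
        h, w = analysis.fov.shape
        all_red = postprocess.suppress_fovea(
            analysis.candidates,
            all_red,
            od.center,
            od.diameter,
            image_center=(h / 2.0, w / 2.0),
            geometry=config.fovea,
        )
    suppressed = ~all_red
    predictions = preds_raw & ~suppressed

    lesion_map = postprocess.final_lesion_map(
        analysis.candidates, predictions, analysis.fov.shape, scores=scores
    )
    surviving = scores[~suppressed]
    img_score = evaluation.image_score(surviving.tolist())
    return DetectionResult(
        analysis=analysis,
        scores=scores,
        predictions=predictions,
        predictions_raw=preds_raw,
        suppressed=suppressed,
        lesion_map=lesion_map,
        vessel_map=vessel_map,
        image_score=img_score,
    )
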