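"""Vessel and fovea false-positive suppression.

Vessels are segmented by a multiscale morphological pipeline run on the
CLAHE green plane at disc radii 2..5 and fused with a pixelwise OR; lesion
candidates overlapping the vessel mask, or sitting in the estimated fovea
region, are relabeled non-lesion.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from skimage import filters, morphology

from .channels import DEFAULT_LINE_ANGLES, line_footprint
from .errors import ParameterError
from .preprocess import FovMask, PreprocessedImage
from .superpixels import Candidate

__all__ = [
    "VesselConfig",
    "VesselMap",
    "FoveaGeometry",
    "OpticDisc",
    "LesionMap",
    "vessel_map_single_scale",
    "vessel_map_multiscale",
    "suppress_vessel_candidates",
    "suppress_fovea",
    "locate_optic_disc",
    "final_lesion_map",
]

DEFAULT_SCALES = (2, 3, 4, 5)


@dataclasses.dataclass(frozen=True)
class VesselConfig:
    scales: tuple[int, ...] = DEFAULT_SCALES
    line_length: int = 9
    line_angles: tuple[int, ...] = DEFAULT_LINE_ANGLES
    recon_marker_radius: int = 1   # erosion radius for the reconstruction marker
    step5_mode: str = "otsu"       # "otsu" | "minima"

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.scales):
            raise ParameterError(f"scales must be >= 1, got {self.scales}")
        if self.step5_mode not in ("otsu", "minima"):
            raise ParameterError(f"unknown step5_mode {self.step5_mode!r}")


@dataclasses.dataclass(frozen=True)
class VesselMap:
    mask: np.ndarray
    per_scale_masks: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        fused = np.zeros_like(self.mask, dtype=bool)
        for m in self.per_scale_masks:
            fused |= m
        if not np.array_equal(fused, self.mask):
            raise ParameterError("vessel mask is not the OR of per-scale masks")


@dataclasses.dataclass(frozen=True)
class FoveaGeometry:
    """Fovea location relative to the optic disc, in OD-diameter units."""

    distance_factor: float = 2.5   # OD center -> fovea center displacement
    radius_factor: float = 1.0     # suppression radius around the fovea


@dataclasses.dataclass(frozen=True)
class OpticDisc:
    center: tuple[float, float]
    diameter: float
    low_confidence: bool = False


@dataclasses.dataclass(frozen=True)
class LesionMap:
    mask: np.ndarray
    candidate_scores: dict[int, float]


def vessel_map_single_scale(
    clahe_gray: np.ndarray,
    radius: int,
    fov: Optional[FovMask] = None,
    config: Optional[VesselConfig] = None,
) -> np.ndarray:
    """Binary vessel mask at one disc-structuring-element scale.

    Steps: background by opening-then-closing; subtract to make dark
    curvilinear structures bright; sum of 12 line openings; opening by
    reconstruction to keep connected ridges; binarize and close.
    """
    if radius < 1:
        raise ParameterError(f"scale radius must be >= 1, got {radius}")
    cfg = config or VesselConfig()
    img = np.asarray(clahe_gray, dtype=np.float64)
    disk = morphology.disk(radius)

    f1 = morphology.closing(morphology.opening(img, disk), disk)
    f2 = np.clip(f1 - img, 0.0, None)

    f3 = np.zeros_like(f2)
    for angle in cfg.line_angles:
        f3 += morphology.opening(f2, line_footprint(cfg.line_length, angle))

    if f3.max() <= 0.0:
        return np.zeros(img.shape, dtype=bool)

    marker = morphology.erosion(f3, morphology.disk(cfg.recon_marker_radius))
    f4 = morphology.reconstruction(marker, f3, method="dilation")

    inside = fov.mask if fov is not None else np.ones(img.shape, dtype=bool)
    if cfg.step5_mode == "otsu":
        vals = f4[inside]
        if float(vals.max() - vals.min()) <= 1e-12:
            return np.zeros(img.shape, dtype=bool)
        thr = filters.threshold_otsu(vals)
        binary = (f4 > thr) & inside
    else:
        minima = morphology.local_minima(f4, connectivity=2)
        binary = (~minima) & (f4 > 0) & inside
    return morphology.closing(binary, morphology.footprint_rectangle((3, 3)))


def vessel_map_multiscale(
    clahe_gray: np.ndarray,
    scales: Sequence[int] = DEFAULT_SCALES,
    fov: Optional[FovMask] = None,
    config: Optional[VesselConfig] = None,
) -> VesselMap:
    """OR-fusion of the single-scale vessel masks."""
    if not scales:
        raise ParameterError("need at least one scale")
    cfg = config or VesselConfig()
    per_scale = tuple(
        vessel_map_single_scale(clahe_gray, r, fov=fov, config=cfg) for r in scales
    )
    fused = np.zeros_like(per_scale[0])
    for m in per_scale:
        fused = fused | m
    return VesselMap(mask=fused, per_scale_masks=per_scale)


def suppress_vessel_candidates(
    cands: Sequence[Candidate],
    predictions: np.ndarray,
    vessels: VesselMap,
    overlap_frac: float = 0.5,
) -> np.ndarray:
    """Relabel lesion candidates whose vessel overlap strictly exceeds
    *overlap_frac* of their area."""
    if not 0.0 <= overlap_frac <= 1.0:
        raise ParameterError(f"overlap_frac must lie in [0, 1], got {overlap_frac}")
    out = np.asarray(predictions, dtype=bool).copy()
    for i, cand in enumerate(cands):
        if not out[i]:
            continue
        rr, cc = cand.pixel_coords[:, 0], cand.pixel_coords[:, 1]
        overlap = float(vessels.mask[rr, cc].sum()) / cand.area
        if overlap > overlap_frac:
            out[i] = False
    return out


def fovea_center_estimate(
    od_center: tuple[float, float],
    od_diameter: float,
    image_center: tuple[float, float],
    geometry: Optional[FoveaGeometry] = None,
) -> tuple[float, float]:
    """Fovea center: displaced from the OD toward the image center."""
    geo = geometry or FoveaGeometry()
    od = np.asarray(od_center, dtype=np.float64)
    target = np.asarray(image_center, dtype=np.float64)
    vec = target - od
    norm = float(np.linalg.norm(vec))
    if norm == 0.0:
        return tuple(od)
    unit = vec / norm
    fovea = od + geo.distance_factor * od_diameter * unit
    return (float(fovea[0]), float(fovea[1]))


def suppress_fovea(
    cands: Sequence[Candidate],
    predictions: np.ndarray,
    od_center: tuple[float, float],
    od_diameter: float,
    image_center: tuple[float, float],
    geometry: Optional[FoveaGeometry] = None,
) -> np.ndarray:
    """Relabel lesion candidates whose barycenter falls inside the estimated
    fovea region."""
    geo = geometry or FoveaGeometry()
    fovea = np.asarray(
        fovea_center_estimate(od_center, od_diameter, image_center, geo)
    )
    radius = geo.radius_factor * od_diameter
    out = np.asarray(predictions, dtype=bool).copy()
    for i, cand in enumerate(cands):
        if not out[i]:
            continue
        dist = float(np.linalg.norm(np.asarray(cand.barycenter) - fovea))
        if dist <= radius:
            out[i] = False
    return out


def locate_optic_disc(
    pre: PreprocessedImage,
    fov: FovMask,
    diameter_fraction: float = 1.0 / 6.0,
    confidence_threshold: float = 0.25,
) -> OpticDisc:
    """Brightest-region heuristic for the optic disc.

    Heavy Gaussian blur of the RGB mean intensity; maximum inside an eroded
    FOV (ties break to the smallest ``(row, col)``). Diameter defaults to a
    sixth of the FOV diameter.
    """
    from scipy import ndimage as ndi

    h, w = fov.shape
    intensity = pre.rgb_enhanced.mean(axis=2)
    sigma = max(3.0, min(h, w) / 32.0)
    blurred = ndi.gaussian_filter(intensity, sigma=sigma)

    fov_diameter = 2.0 * np.sqrt(fov.area / np.pi)
    erosion_r = max(1, int(round(fov_diameter * diameter_fraction / 2)))
    inner = morphology.erosion(fov.mask, morphology.disk(erosion_r))
    if not inner.any():
        inner = fov.mask

    masked = np.where(inner, blurred, -np.inf)
    flat_idx = int(np.argmax(masked))  # row-major: first max = smallest (row, col)
    center = (flat_idx // w, flat_idx % w)
    peak = float(masked[center])
    return OpticDisc(
        center=(float(center[0]), float(center[1])),
        diameter=float(fov_diameter * diameter_fraction),
        low_confidence=peak < confidence_threshold,
    )


def final_lesion_map(
    cands: Sequence[Candidate],
    predictions: np.ndarray,
    shape: tuple[int, int],
    scores: Optional[np.ndarray] = None,
) -> LesionMap:
    """Union of the pixels of lesion-labeled candidates."""
    mask = np.zeros(shape, dtype=bool)
    kept: dict[int, float] = {}
    preds = np.asarray(predictions, dtype=bool)
    for i, cand in enumerate(cands):
        if not preds[i]:
            continue
        mask[cand.pixel_coords[:, 0], cand.pixel_coords[:, 1]] = True
        kept[cand.label] = float(scores[i]) if scores is not None else float("nan")
    return LesionMap(mask=mask, candidate_scores=kept)
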