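"""Synthetic fundus phantoms with per-pixel ground truth.

A phantom has a dark circular field of view on a black surround, a bright
optic disc, a dark fovea, a branching dark vessel tree and small dark
round/blob lesions. Geometry follows the usual anatomy: the fovea sits at
the image center and the optic disc is displaced sideways by 2.5 optic-disc
diameters, so the default fovea-suppression geometry locates it correctly.

All randomness flows through one seeded generator; the rendered image is
quantized to the 8-bit grid so that a PNG round trip is lossless.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology

from .errors import ParameterError

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_synthetic_fundus",
    "generate_labeled_dataset",
]

_BASE_COLOR = np.array([0.70, 0.50, 0.24])
_OD_COLOR = np.array([0.95, 0.88, 0.55])


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    size: tuple[int, int] = (512, 512)
    seed: int = 0
    n_microaneurysms: int = 6
    n_hemorrhages: int = 2
    ma_radius_range: tuple[int, int] = (4, 6)
    hem_radius_range: tuple[int, int] = (6, 9)
    lesion_contrast: float = 0.15
    vessel_widths: tuple[int, ...] = (2, 3, 4, 5, 6)
    noise_sigma: float = 0.02
    od_center: Optional[tuple[float, float]] = None
    od_radius: Optional[float] = None
    fovea_center: Optional[tuple[float, float]] = None
    fovea_radius: Optional[float] = None
    background_gradient: float = 0.15
    n_vessel_branches: int = 7

    def __post_init__(self) -> None:
        if not 0.0 < self.lesion_contrast < 1.0:
            raise ParameterError(
                f"lesion_contrast must lie in (0, 1), got {self.lesion_contrast}"
            )
        if self.size[0] < 64 or self.size[1] < 64:
            raise ParameterError(f"phantom size too small: {self.size}")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


@dataclasses.dataclass(frozen=True)
class PhantomTruth:
    lesion_mask: np.ndarray
    vessel_mask: np.ndarray
    od_mask: np.ndarray
    fovea_mask: np.ndarray
    fov_mask: np.ndarray
    lesion_components: tuple[tuple[tuple[float, float], float, str], ...]
    od_center: tuple[float, float]
    od_radius: float
    fovea_center: tuple[float, float]
    fovea_radius: float


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _resolve_geometry(spec: PhantomSpec, rng: np.random.Generator):
    h, w = spec.size
    center = (h / 2.0, w / 2.0)
    fov_radius = 0.47 * min(h, w)
    # default OD size matches the detector's FOV-diameter/6 heuristic
    od_radius = spec.od_radius if spec.od_radius is not None else 0.075 * min(h, w)
    fovea_radius = (
        spec.fovea_radius if spec.fovea_radius is not None else 0.05 * min(h, w)
    )
    fovea_center = spec.fovea_center if spec.fovea_center is not None else center
    if spec.od_center is not None:
        od_center = spec.od_center
    else:
        side = -1.0 if rng.random() < 0.5 else 1.0
        od_center = (center[0], center[1] + side * 5.0 * od_radius)

    for name, c, r in (
        ("optic disc", od_center, od_radius),
        ("fovea", fovea_center, fovea_radius),
    ):
        dist = np.hypot(c[0] - center[0], c[1] - center[1])
        if dist + r > fov_radius:
            raise ParameterError(f"{name} geometry extends outside the FOV")
    return center, fov_radius, od_center, od_radius, fovea_center, fovea_radius


def _draw_vessels(
    spec: PhantomSpec,
    rng: np.random.Generator,
    fov_center: tuple[float, float],
    fov_radius: float,
    od_center: tuple[float, float],
    fovea_center: tuple[float, float],
    fovea_clear_radius: float,
) -> np.ndarray:
    """Random-walk vessel tree growing out of the optic disc."""
    h, w = spec.size
    mask = np.zeros((h, w), dtype=bool)
    widths = list(spec.vessel_widths)
    n_branches = max(spec.n_vessel_branches, len(widths))
    angles = rng.permutation(np.linspace(0.0, 2 * np.pi, n_branches, endpoint=False))

    for b in range(n_branches):
        width = widths[b % len(widths)]
        pos = np.array(od_center, dtype=np.float64)
        theta = float(angles[b]) + rng.normal(0.0, 0.2)
        pts = []
        for _ in range(int(2.2 * fov_radius)):
            theta += rng.normal(0.0, 0.12)
            pos = pos + np.array([np.sin(theta), np.cos(theta)]) * 1.5
            if np.hypot(pos[0] - fov_center[0], pos[1] - fov_center[1]) > fov_radius - width - 2:
                break
            if np.hypot(pos[0] - fovea_center[0], pos[1] - fovea_center[1]) < fovea_clear_radius:
                break
            pts.append((int(round(pos[0])), int(round(pos[1]))))
        if len(pts) < 4:
            continue
        canvas = np.zeros((h, w), dtype=bool)
        rr = np.clip([p[0] for p in pts], 0, h - 1)
        cc = np.clip([p[1] for p in pts], 0, w - 1)
        canvas[rr, cc] = True
        mask |= morphology.dilation(canvas, morphology.disk(max(1, width // 2)))
    return mask


def generate_synthetic_fundus(spec: PhantomSpec) -> tuple["FundusImage", PhantomTruth]:
    """Render a phantom and its ground truth (truth recorded before noise)."""
    from .preprocess import FundusImage

    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    center, fov_radius, od_center, od_radius, fovea_center, fovea_radius = (
        _resolve_geometry(spec, rng)
    )

    rr, cc = np.ogrid[:h, :w]
    dist_center = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    fov_mask = dist_center <= fov_radius

    # smooth illumination: radial falloff plus a random linear tilt
    tilt_dir = rng.uniform(0.0, 2 * np.pi)
    tilt = (
        (rr - center[0]) * np.sin(tilt_dir) + (cc - center[1]) * np.cos(tilt_dir)
    ) / fov_radius
    illum = 1.0 - spec.background_gradient * (dist_center / fov_radius) ** 2
    illum = illum - 0.3 * spec.background_gradient * tilt
    img = _BASE_COLOR[None, None, :] * illum[..., None]

    # optic disc: soft bright blend
    d_od = np.sqrt((rr - od_center[0]) ** 2 + (cc - od_center[1]) ** 2)
    od_alpha = np.clip(1.3 - d_od / od_radius, 0.0, 1.0)
    od_mask = d_od <= od_radius
    img = img + od_alpha[..., None] * (_OD_COLOR - _BASE_COLOR)[None, None, :] * 0.85

    # fovea: soft dark dip
    d_f = np.sqrt((rr - fovea_center[0]) ** 2 + (cc - fovea_center[1]) ** 2)
    f_alpha = np.clip(1.2 - d_f / fovea_radius, 0.0, 1.0)
    fovea_mask = d_f <= fovea_radius
    img[..., 0] -= 0.06 * f_alpha
    img[..., 1] -= 0.08 * f_alpha

    od_diameter = 2.0 * od_radius
    fovea_clear = 1.6 * od_diameter  # keep vessels and lesions off the fovea zone
    vessel_mask = _draw_vessels(
        spec, rng, center, fov_radius, od_center, fovea_center, fovea_clear
    )
    img[..., 0] = np.where(vessel_mask, img[..., 0] - 0.12, img[..., 0])
    img[..., 1] = np.where(vessel_mask, img[..., 1] - 0.22, img[..., 1])
    img[..., 2] = np.where(vessel_mask, img[..., 2] - 0.05, img[..., 2])

    # lesions: planted off-vessel, off-OD, away from the fovea zone
    lesion_mask = np.zeros((h, w), dtype=bool)
    components: list[tuple[tuple[float, float], float, str]] = []
    keep_out = morphology.dilation(vessel_mask, morphology.disk(3))
    keep_out |= morphology.dilation(od_mask, morphology.disk(5))

    def plant(kind: str, radius_range: tuple[int, int], n_blobs: tuple[int, int]):
        nonlocal lesion_mask
        for _ in range(200):
            radius = float(rng.integers(radius_range[0], radius_range[1] + 1))
            r0 = rng.uniform(0.0, fov_radius - radius - 4.0)
            phi = rng.uniform(0.0, 2 * np.pi)
            cy = center[0] + r0 * np.sin(phi)
            cx = center[1] + r0 * np.cos(phi)
            if np.hypot(cy - fovea_center[0], cx - fovea_center[1]) < fovea_clear + radius:
                continue
            blob = np.zeros((h, w), dtype=bool)
            k = int(rng.integers(n_blobs[0], n_blobs[1] + 1))
            for _ in range(k):
                jy = cy + rng.uniform(-radius / 2, radius / 2)
                jx = cx + rng.uniform(-radius / 2, radius / 2)
                blob |= _disc_mask((h, w), (jy, jx), radius)
            grown = morphology.dilation(blob, morphology.disk(2))
            if (grown & (keep_out | lesion_mask)).any():
                continue
            lesion_mask |= blob
            components.append(((cy, cx), radius, kind))
            return
        raise ParameterError(
            f"could not place a {kind} without touching vessels/OD/fovea; "
            "reduce lesion count or size"
        )

    for _ in range(spec.n_microaneurysms):
        plant("microaneurysm", spec.ma_radius_range, (1, 1))
    for _ in range(spec.n_hemorrhages):
        plant("hemorrhage", spec.hem_radius_range, (2, 5))

    img[..., 0] = np.where(lesion_mask, img[..., 0] - 0.6 * spec.lesion_contrast, img[..., 0])
    img[..., 1] = np.where(lesion_mask, img[..., 1] - spec.lesion_contrast, img[..., 1])

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.where(fov_mask[..., None], img, 0.0)
    img = np.clip(img, 0.0, 1.0)
    # quantize to the 8-bit grid so a PNG round trip is bitwise lossless
    img = np.round(img * 255.0) / 255.0

    truth = PhantomTruth(
        lesion_mask=lesion_mask,
        vessel_mask=vessel_mask,
        od_mask=od_mask,
        fovea_mask=fovea_mask,
        fov_mask=fov_mask,
        lesion_components=tuple(components),
        od_center=(float(od_center[0]), float(od_center[1])),
        od_radius=float(od_radius),
        fovea_center=(float(fovea_center[0]), float(fovea_center[1])),
        fovea_radius=float(fovea_radius),
    )
    return FundusImage(pixels=img, source_path=f"<phantom seed={spec.seed}>"), truth


def save_phantom(
    img, truth: PhantomTruth, out_dir: str, image_id: str
) -> tuple[str, str]:
    """Write the image and its lesion mask as PNGs; returns both paths."""
    os.makedirs(out_dir, exist_ok=True)
    img_path = os.path.join(out_dir, f"{image_id}.png")
    mask_path = os.path.join(out_dir, f"{image_id}_lesions.png")
    iio.imwrite(img_path, np.round(img.pixels * 255.0).astype(np.uint8))
    iio.imwrite(mask_path, (truth.lesion_mask * 255).astype(np.uint8))
    return img_path, mask_path


def generate_labeled_dataset(
    n_images: int,
    spec_template: PhantomSpec,
    seed: int,
    out_dir: str,
) -> pd.DataFrame:
    """Render *n_images* phantoms to *out_dir* with a manifest CSV.

    Image *i* uses seed ``seed + i``; the manifest records the image-level
    label (1 iff the lesion mask is nonempty).
    """
    rows = []
    for i in range(n_images):
        spec = dataclasses.replace(spec_template, seed=seed + i)
        img, truth = generate_synthetic_fundus(spec)
        image_id = f"phantom_{i:03d}"
        img_path, mask_path = save_phantom(img, truth, out_dir, image_id)
        rows.append(
            {
                "image_id": image_id,
                "path": img_path,
                "mask_path": mask_path,
                "n_lesions": len(truth.lesion_components),
                "label": int(truth.lesion_mask.any()),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
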