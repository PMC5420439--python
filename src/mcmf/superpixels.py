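"""SLIC superpixel segmentation and candidate extraction.

The segmentation is a local k-means in the joint ``[l, a, b, row, col]``
space. Pixel-to-center distance is

    D = sqrt(d_lab^2 + (m / S)^2 * d_xy^2)

with ``S`` the grid interval (region size) and ``m`` the compactness weight.
Each center only competes for pixels inside a ``2S x 2S`` window around it;
pixels covered by no window fall back to an exhaustive search so that every
field-of-view pixel receives a label.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import color as skcolor
from skimage import measure

from .errors import DegenerateInputError, ParameterError
from .preprocess import FovMask, PreprocessedImage

__all__ = [
    "SlicParams",
    "SuperpixelMap",
    "Candidate",
    "rgb_to_lab",
    "initialize_centers",
    "assign_step",
    "slic_segment",
    "extract_candidates",
]

NEIGHBOR_RADIUS_FACTOR = 7  # neighbourhood radius in units of the region size


@dataclasses.dataclass(frozen=True)
class SlicParams:
    region_size: int = 50
    compactness: float = 10.0
    n_iters: int = 10
    enforce_connectivity: bool = True
    min_region_fraction: float = 0.25
    move_tol: float = 0.5

    def __post_init__(self) -> None:
        if self.region_size < 2:
            raise ParameterError(f"region_size must be >= 2, got {self.region_size}")
        if not 1.0 <= self.compactness <= 40.0:
            raise ParameterError(
                f"compactness must lie in [1, 40], got {self.compactness}"
            )
        if self.n_iters < 1:
            raise ParameterError(f"n_iters must be >= 1, got {self.n_iters}")
        if not 0.0 <= self.min_region_fraction < 1.0:
            raise ParameterError("min_region_fraction must lie in [0, 1)")


@dataclasses.dataclass(frozen=True)
class SuperpixelMap:
    """Label raster: ``-1`` outside the FOV, ``0..N-1`` inside."""

    labels: np.ndarray
    n_superpixels: int

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.labels.shape)


@dataclasses.dataclass(frozen=True)
class Candidate:
    """One superpixel viewed as a lesion candidate."""

    label: int
    pixel_coords: np.ndarray  # (N_i, 2) int array of (row, col)
    barycenter: tuple[float, float]
    area: int
    neighbor_ids: frozenset[int] = frozenset()


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """sRGB (values in [0,1], D65) to CIELAB."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ParameterError(f"expected H x W x 3, got {img.shape}")
    return skcolor.rgb2lab(img)


def initialize_centers(
    lab: np.ndarray, fov_mask: np.ndarray, region_size: int
) -> np.ndarray:
    """Seed centers on a regular grid, perturbed to the lowest-gradient
    pixel of each seed's 3x3 neighbourhood. Returns (K, 5) array of
    ``[l, a, b, row, col]``."""
    h, w = fov_mask.shape
    s = region_size
    gy, gx = np.gradient(lab[..., 0])
    grad = np.hypot(gy, gx)

    centers = []
    for r0 in np.arange(s // 2, h, s):
        for c0 in np.arange(s // 2, w, s):
            if not fov_mask[r0, c0]:
                continue
            r_lo, r_hi = max(0, r0 - 1), min(h, r0 + 2)
            c_lo, c_hi = max(0, c0 - 1), min(w, c0 + 2)
            win = grad[r_lo:r_hi, c_lo:c_hi]
            k = int(np.argmin(win))
            r = r_lo + k // win.shape[1]
            c = c_lo + k % win.shape[1]
            if not fov_mask[r, c]:
                r, c = r0, c0
            centers.append([lab[r, c, 0], lab[r, c, 1], lab[r, c, 2], float(r), float(c)])
    if not centers:
        raise DegenerateInputError("no superpixel seed falls inside the FOV")
    return np.asarray(centers, dtype=np.float64)


def assign_step(
    lab: np.ndarray,
    centers: np.ndarray,
    region_size: int,
    compactness: float,
    fov_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One SLIC assignment sweep.

    Every FOV pixel is assigned to the center minimizing
    ``d_lab^2 + (m/S)^2 d_xy^2``, searching a ``2S x 2S`` window per center
    with an exhaustive fallback for uncovered pixels. Returns an int label
    raster (``-1`` outside the FOV).
    """
    h, w = lab.shape[:2]
    if fov_mask is None:
        fov_mask = np.ones((h, w), dtype=bool)
    s = region_size
    weight = (compactness / s) ** 2

    best = np.full((h, w), np.inf)
    labels = np.full((h, w), -1, dtype=np.int32)
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)

    for k, (lk, ak, bk, rk, ck) in enumerate(centers):
        r_lo = max(0, int(np.floor(rk)) - s)
        r_hi = min(h, int(np.ceil(rk)) + s + 1)
        c_lo = max(0, int(np.floor(ck)) - s)
        c_hi = min(w, int(np.ceil(ck)) + s + 1)
        patch = lab[r_lo:r_hi, c_lo:c_hi]
        d_lab2 = (
            (patch[..., 0] - lk) ** 2
            + (patch[..., 1] - ak) ** 2
            + (patch[..., 2] - bk) ** 2
        )
        d_xy2 = (
            (rows[r_lo:r_hi, None] - rk) ** 2 + (cols[None, c_lo:c_hi] - ck) ** 2
        )
        d2 = d_lab2 + weight * d_xy2
        view = best[r_lo:r_hi, c_lo:c_hi]
        better = (d2 < view) & fov_mask[r_lo:r_hi, c_lo:c_hi]
        view[better] = d2[better]
        labels[r_lo:r_hi, c_lo:c_hi][better] = k

    orphan = fov_mask & (labels < 0)
    if orphan.any():
        rr, cc = np.nonzero(orphan)
        d_lab2 = ((lab[rr, cc, None, :] - centers[None, :, :3]) ** 2).sum(axis=-1)
        d_xy2 = (rr[:, None] - centers[None, :, 3]) ** 2 + (
            cc[:, None] - centers[None, :, 4]
        ) ** 2
        labels[rr, cc] = np.argmin(d_lab2 + weight * d_xy2, axis=1)
    return labels


def _update_centers(
    lab: np.ndarray, labels: np.ndarray, n_centers: int
) -> tuple[np.ndarray, np.ndarray]:
    h, w = labels.shape
    flat = labels.ravel()
    inside = flat >= 0
    idx = flat[inside]
    counts = np.bincount(idx, minlength=n_centers).astype(np.float64)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    feats = np.stack(
        [lab[..., 0].ravel(), lab[..., 1].ravel(), lab[..., 2].ravel(),
         rr.ravel().astype(np.float64), cc.ravel().astype(np.float64)],
        axis=1,
    )[inside]
    sums = np.zeros((n_centers, 5))
    np.add.at(sums, idx, feats)
    nonempty = counts > 0
    sums[nonempty] /= counts[nonempty, None]
    return sums, nonempty


def _enforce_connectivity(
    labels: np.ndarray, min_size: int
) -> np.ndarray:
    """Split labels into 4-connected components and merge fragments smaller
    than *min_size* into the adjacent component with the most boundary
    contact."""
    comp = measure.label(labels, background=-1, connectivity=1)
    # comp: 0 for background, 1..M for components
    n_comp = comp.max()
    if n_comp == 0:
        return labels
    sizes = np.bincount(comp.ravel(), minlength=n_comp + 1)
    root = np.arange(n_comp + 1)

    def find(x: int) -> int:
        while root[x] != x:
            root[x] = root[root[x]]
            x = root[x]
        return x

    # adjacency counts between 4-neighbouring distinct components
    pairs = []
    a, b = comp[:, :-1].ravel(), comp[:, 1:].ravel()
    pairs.append((a, b))
    a, b = comp[:-1, :].ravel(), comp[1:, :].ravel()
    pairs.append((a, b))
    from collections import defaultdict

    contact: dict[int, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for a, b in pairs:
        diff = (a != b) & (a > 0) & (b > 0)
        for x, y in zip(a[diff], b[diff]):
            contact[x][y] += 1
            contact[y][x] += 1

    order = np.argsort(sizes[1:], kind="stable") + 1
    for cid in order:
        if sizes[cid] >= min_size:
            continue
        neigh = contact.get(cid)
        if not neigh:
            continue  # isolated island: keep even if small
        # dominant neighbour by current-root contact count
        merged: dict[int, int] = defaultdict(int)
        for other, cnt in neigh.items():
            r = find(other)
            if r != find(cid):
                merged[r] += cnt
        if not merged:
            continue
        target = max(sorted(merged), key=lambda k: merged[k])
        root[find(cid)] = target

    final = np.array([find(i) for i in range(n_comp + 1)])
    # compact roots to 0..N-1
    uniq = np.unique(final[1:])
    remap = {int(u): i for i, u in enumerate(uniq)}
    lut = np.full(n_comp + 1, -1, dtype=np.int32)
    for i in range(1, n_comp + 1):
        lut[i] = remap[int(final[i])]
    return lut[comp]


def slic_segment(
    pre: PreprocessedImage,
    fov: FovMask,
    params: SlicParams,
) -> SuperpixelMap:
    """Run the full SLIC segmentation on the enhanced image."""
    s = params.region_size
    if fov.area < s * s:
        raise DegenerateInputError(
            f"FOV area {fov.area} smaller than one grid cell ({s * s})"
        )
    lab = rgb_to_lab(pre.rgb_enhanced)
    centers = initialize_centers(lab, fov.mask, s)
    labels = assign_step(lab, centers, s, params.compactness, fov.mask)
    for _ in range(params.n_iters - 1):
        new_centers, nonempty = _update_centers(lab, labels, len(centers))
        new_centers[~nonempty] = centers[~nonempty]
        move = np.abs(new_centers[:, 3:] - centers[:, 3:]).max()
        centers = new_centers
        if move <= params.move_tol:
            break
        labels = assign_step(lab, centers, s, params.compactness, fov.mask)

    if params.enforce_connectivity:
        min_size = max(1, int(round(params.min_region_fraction * s * s)))
        labels = _enforce_connectivity(labels, min_size)
    else:
        # compact label ids anyway
        uniq = np.unique(labels[labels >= 0])
        lut = np.full(int(labels.max()) + 1, -1, dtype=np.int32)
        lut[uniq] = np.arange(len(uniq), dtype=np.int32)
        labels = np.where(labels >= 0, lut[np.clip(labels, 0, None)], -1)

    labels = np.where(fov.mask, labels, -1).astype(np.int32)
    n = int(labels.max()) + 1
    return SuperpixelMap(labels=labels, n_superpixels=n)


def extract_candidates(
    sp: SuperpixelMap, params: SlicParams
) -> list[Candidate]:
    """One candidate per superpixel, with barycenter and the neighbour set
    of all candidates whose barycenters lie within ``7 * region_size``."""
    labels = sp.labels
    n = sp.n_superpixels
    rr, cc = np.nonzero(labels >= 0)
    lab_flat = labels[rr, cc]
    order = np.argsort(lab_flat, kind="stable")
    rr, cc, lab_flat = rr[order], cc[order], lab_flat[order]
    bounds = np.searchsorted(lab_flat, np.arange(n + 1))

    barycenters = np.empty((n, 2))
    coords_per = []
    for i in range(n):
        lo, hi = bounds[i], bounds[i + 1]
        pts = np.stack([rr[lo:hi], cc[lo:hi]], axis=1)
        coords_per.append(pts)
        barycenters[i] = pts.mean(axis=0)

    radius = NEIGHBOR_RADIUS_FACTOR * params.region_size
    neighbor_sets: list[set[int]] = [set() for _ in range(n)]
    if n > 1:
        tree = cKDTree(barycenters)
        for i, j in tree.query_pairs(r=float(radius)):
            neighbor_sets[i].add(j)
            neighbor_sets[j].add(i)

    return [
        Candidate(
            label=i,
            pixel_coords=coords_per[i],
            barycenter=(float(barycenters[i, 0]), float(barycenters[i, 1])),
            area=int(len(coords_per[i])),
            neighbor_ids=frozenset(neighbor_sets[i]),
        )
        for i in range(n)
    ]
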