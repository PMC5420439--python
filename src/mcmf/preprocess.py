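"""Image loading, field-of-view masking and contrast enhancement.

The pipeline operates on RGB fundus photographs rescaled to ``[0, 1]``.
Enhancement is CLAHE applied per RGB channel followed by a small Gaussian
smoothing; the green plane of the result drives most downstream channels.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import exposure

from .errors import DegenerateInputError, FormatError, ParameterError

__all__ = [
    "FundusImage",
    "FovMask",
    "PreprocessedImage",
    "load_fundus",
    "compute_fov_mask",
    "gaussian_smooth",
    "enhance",
]

DEFAULT_FOV_THRESHOLD = 0.06
DEFAULT_CLAHE_CLIP = 0.01
DEFAULT_CLAHE_TILES = 8
GAUSSIAN_WIDTH = 5
GAUSSIAN_SIGMA = 1.0


@dataclasses.dataclass(frozen=True)
class FundusImage:
    """An RGB fundus photograph with float pixels in ``[0, 1]``."""

    pixels: np.ndarray
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"expected H x W x 3 RGB raster, got shape {px.shape}"
            )
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise FormatError(f"image too small: {px.shape[:2]}")
        if not np.all(np.isfinite(px)):
            raise FormatError("non-finite pixel values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise FormatError("pixel values outside [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclasses.dataclass(frozen=True)
class FovMask:
    """Boolean mask of the circular camera aperture (field of view)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise FormatError(f"mask must be 2-D, got shape {m.shape}")
        if not m.any():
            raise DegenerateInputError("empty field-of-view mask")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.mask.shape)


@dataclasses.dataclass(frozen=True)
class PreprocessedImage:
    """Enhancement products shared by the whole pipeline.

    Attributes
    ----------
    rgb_enhanced : ndarray
        CLAHE + Gaussian smoothed RGB image.
    green_enhanced : ndarray
        Green plane of ``rgb_enhanced``.
    green_raw : ndarray
        Green plane of the *unenhanced* input image.
    clahe_gray : ndarray
        Green plane of the CLAHE result before smoothing; input to the
        multiscale vessel detector.
    """

    rgb_enhanced: np.ndarray
    green_enhanced: np.ndarray
    green_raw: np.ndarray
    clahe_gray: np.ndarray

    def __post_init__(self) -> None:
        shapes = {
            self.rgb_enhanced.shape[:2],
            self.green_enhanced.shape,
            self.green_raw.shape,
            self.clahe_gray.shape,
        }
        if len(shapes) != 1:
            raise FormatError(f"inconsistent raster shapes: {shapes}")
        for arr in (self.rgb_enhanced, self.green_enhanced, self.green_raw, self.clahe_gray):
            if arr.min() < 0.0 or arr.max() > 1.0 or not np.all(np.isfinite(arr)):
                raise FormatError("preprocessed raster outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.green_enhanced.shape)


def load_fundus(path: str) -> FundusImage:
    """Read an RGB raster image from *path* and rescale it to ``[0, 1]``.

    Raises
    ------
    FormatError
        If the image is not 3-channel RGB (grayscale and RGBA are rejected,
        naming the offending channel count).
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failures vary per backend
        raise IOError(f"could not read image {path!r}: {exc}") from exc
    if raw.ndim != 3 or raw.shape[2] != 3:
        nchan = 1 if raw.ndim == 2 else raw.shape[2]
        raise FormatError(
            f"{path!r}: expected 3-channel RGB input, got {nchan} channel(s)"
        )
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        px = raw.astype(np.float64) / float(info.max)
    else:
        px = raw.astype(np.float64)
        if px.max() > 1.0:  # float image stored on a 0..255 scale
            px = px / 255.0
    return FundusImage(pixels=np.clip(px, 0.0, 1.0), source_path=str(path))


def compute_fov_mask(
    img: FundusImage, threshold: float = DEFAULT_FOV_THRESHOLD
) -> FovMask:
    """Threshold the RGB maximum, keep the largest component, fill holes."""
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"fov threshold must be in (0, 1), got {threshold}")
    bright = img.pixels.max(axis=2) > threshold
    if not bright.any():
        raise DegenerateInputError(
            f"no pixel exceeds FOV threshold {threshold}"
        )
    labels, n = ndi.label(bright, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        bright = labels == int(np.argmax(sizes))
    filled = ndi.binary_fill_holes(bright)
    return FovMask(mask=filled)


def gaussian_smooth(
    arr: np.ndarray, sigma: float = GAUSSIAN_SIGMA, width: int = GAUSSIAN_WIDTH
) -> np.ndarray:
    """Smooth with a truncated ``width x width`` Gaussian kernel."""
    if width < 1 or width % 2 == 0:
        raise ParameterError(f"width must be odd and >= 1, got {width}")
    return ndi.gaussian_filter(arr, sigma=sigma, radius=width // 2, mode="reflect")


def _clahe_channel(channel: np.ndarray, clip: float, tile: int) -> np.ndarray:
    # equalize_adapthist degenerates on (near-)constant input; a constant
    # plane carries no contrast to equalize, so it is passed through.
    if float(channel.max() - channel.min()) < 1.0 / 1024.0:
        return channel.copy()
    h, w = channel.shape
    kernel = (max(1, h // tile), max(1, w // tile))
    return exposure.equalize_adapthist(channel, kernel_size=kernel, clip_limit=clip)


def enhance(
    img: FundusImage,
    fov: Optional[FovMask] = None,
    clahe_clip: float = DEFAULT_CLAHE_CLIP,
    tile: int = DEFAULT_CLAHE_TILES,
    gaussian_width: int = GAUSSIAN_WIDTH,
    gaussian_sigma: float = GAUSSIAN_SIGMA,
) -> PreprocessedImage:
    """CLAHE per RGB channel followed by Gaussian smoothing.

    Outside the field of view the original pixels are kept so that the black
    surround does not get amplified. The smoothing kernel is
    ``gaussian_width`` x ``gaussian_width`` (default 5) with
    ``sigma = gaussian_sigma`` (default 1).
    """
    if clahe_clip <= 0:
        raise ParameterError(f"clahe_clip must be > 0, got {clahe_clip}")
    if tile < 2:
        raise ParameterError(f"tile must be >= 2, got {tile}")
    if gaussian_width < 1 or gaussian_width % 2 == 0:
        raise ParameterError(f"gaussian_width must be odd and >= 1, got {gaussian_width}")
    if gaussian_sigma <= 0:
        raise ParameterError(f"gaussian_sigma must be > 0, got {gaussian_sigma}")

    px = img.pixels
    clahe = np.empty_like(px)
    for c in range(3):
        clahe[..., c] = _clahe_channel(px[..., c], clahe_clip, tile)
    if fov is not None:
        inside = fov.mask
        clahe = np.where(inside[..., None], clahe, px)

    smoothed = np.empty_like(clahe)
    for c in range(3):
        smoothed[..., c] = gaussian_smooth(
            clahe[..., c], sigma=gaussian_sigma, width=gaussian_width
        )
    smoothed = np.clip(smoothed, 0.0, 1.0)
    clahe = np.clip(clahe, 0.0, 1.0)
    return PreprocessedImage(
        rgb_enhanced=smoothed,
        green_enhanced=smoothed[..., 1],
        green_raw=px[..., 1],
        clahe_gray=clahe[..., 1],
    )
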