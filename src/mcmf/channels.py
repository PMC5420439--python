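"""The seven derived grayscale channel images.

Order is frozen (feature indices depend on it):

1. ``I_G``             raw green plane
2. ``I_green``         enhanced green plane
3. ``I_dark_enhanced`` ASF background estimate minus the enhanced green
4. ``I_lesions``       shade-corrected image with linear (vessel) structures
                       removed; dark round structures come out high-valued
5. ``I_close``         morphological closing of the enhanced green
6. ``I_hue``           hue plane of the enhanced RGB image
7. ``I_M``             magenta plane of the enhanced RGB image in CMYK
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import morphology

from .errors import FormatError, ParameterError
from .preprocess import PreprocessedImage

__all__ = [
    "ChannelConfig",
    "ChannelStack",
    "CHANNEL_NAMES",
    "line_footprint",
    "asf",
    "channel_dark_enhanced",
    "channel_lesions",
    "channel_close",
    "channel_hue",
    "channel_m_cmyk",
    "build_channel_stack",
]

CHANNEL_NAMES = (
    "I_G",
    "I_green",
    "I_dark_enhanced",
    "I_lesions",
    "I_close",
    "I_hue",
    "I_M",
)

# 15..165 step 15 lists 11 directions; 0 deg completes the set of 12.
DEFAULT_LINE_ANGLES = tuple(range(0, 180, 15))
REFERENCE_WIDTH = 1500  # image width the default kernel sizes were chosen for


@dataclasses.dataclass(frozen=True)
class ChannelConfig:
    """Kernel sizes for the channel operators.

    ``scale_to_width`` rescales the disc radii and the median kernel linearly
    with ``image_width / REFERENCE_WIDTH`` — intended for small synthetic
    images; leave off for full-size fundus photographs. Line length is never
    scaled below its default so that thin vessels remain separable from
    round lesions.
    """

    asf_radii: tuple[int, ...] = (10, 20, 40)
    median_kernel: int = 25
    line_length: int = 9
    line_angles: tuple[int, ...] = DEFAULT_LINE_ANGLES
    close_radius: int = 10
    scale_to_width: bool = False

    def resolve(self, image_width: int) -> "ChannelConfig":
        """Return a config with kernel sizes resolved for *image_width*."""
        if not self.scale_to_width:
            return self
        f = image_width / REFERENCE_WIDTH
        med = int(round(self.median_kernel * f))
        if med % 2 == 0:
            med += 1
        return dataclasses.replace(
            self,
            asf_radii=tuple(max(1, int(round(r * f))) for r in self.asf_radii),
            median_kernel=max(3, med),
            close_radius=max(2, int(round(self.close_radius * f))),
            scale_to_width=False,
        )


@dataclasses.dataclass(frozen=True)
class ChannelStack:
    """The seven co-registered grayscale channels."""

    channels: tuple[np.ndarray, ...]
    names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        if len(self.channels) != 7:
            raise FormatError(f"expected 7 channels, got {len(self.channels)}")
        shapes = {ch.shape for ch in self.channels}
        if len(shapes) != 1:
            raise FormatError(f"channel shape mismatch: {shapes}")
        for name, ch in zip(self.names, self.channels):
            if not np.all(np.isfinite(ch)):
                raise FormatError(f"non-finite values in channel {name}")

    def __getitem__(self, i: int) -> np.ndarray:
        return self.channels[i]

    def __len__(self) -> int:
        return 7

    def as_array(self) -> np.ndarray:
        return np.stack(self.channels, axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.channels[0].shape)


def line_footprint(length: int, angle_deg: float) -> np.ndarray:
    """Boolean line structuring element of the given length and orientation.

    Mirrors the usual flat line strel: *length* samples along the direction,
    rounded to the pixel grid, centered on the middle pixel.
    """
    if length < 1:
        raise ParameterError(f"line length must be >= 1, got {length}")
    theta = np.deg2rad(angle_deg)
    t = np.arange(length, dtype=np.float64) - (length - 1) / 2.0
    # rows grow downward; positive angles rotate counter-clockwise
    rows = np.round(-t * np.sin(theta)).astype(int)
    cols = np.round(t * np.cos(theta)).astype(int)
    r0, c0 = rows.min(), cols.min()
    fp = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    fp[rows - r0, cols - c0] = True
    return fp


def _disk(radius: int) -> np.ndarray:
    return morphology.disk(radius)


def asf(img: np.ndarray, radii: Sequence[int]) -> np.ndarray:
    """Alternating sequential filter: closing-then-opening per scale,
    scales in the given (ascending) order."""
    out = np.asarray(img, dtype=np.float64)
    for r in radii:
        fp = _disk(r)
        out = morphology.opening(morphology.closing(out, fp), fp)
    return out


def channel_dark_enhanced(
    green_enhanced: np.ndarray, radii: Sequence[int] = (10, 20, 40)
) -> np.ndarray:
    """Background (ASF) minus image: dark structures come out positive."""
    background = asf(green_enhanced, radii)
    return np.clip(background - green_enhanced, 0.0, None)


def channel_lesions(
    green_enhanced: np.ndarray,
    median_kernel: int = 25,
    line_length: int = 9,
    line_angles: Sequence[float] = DEFAULT_LINE_ANGLES,
) -> np.ndarray:
    """Shade-correct, remove linear (vessel) structures, keep round dark ones.

    The shade-corrected image is negated so that dark structures are
    high-valued; the pixelwise maximum of the 12 line openings captures
    vessels, and its removal leaves the small round lesions.
    """
    if median_kernel % 2 == 0 or median_kernel < 3:
        raise ParameterError(f"median kernel must be odd >= 3, got {median_kernel}")
    img = np.asarray(green_enhanced, dtype=np.float64)
    background = ndi.median_filter(img, size=median_kernel, mode="reflect")
    shade_corrected = img - background            # lesions/vessels negative
    dark = -shade_corrected                       # lesions/vessels positive
    vessels = np.full_like(dark, -np.inf)
    for angle in line_angles:
        fp = line_footprint(line_length, angle)
        np.maximum(vessels, morphology.opening(dark, fp), out=vessels)
    return np.clip(dark - vessels, 0.0, None)


def channel_close(green_enhanced: np.ndarray, radius: int = 10) -> np.ndarray:
    """Grayscale closing with a disc: fills dark dots and thin dark lines."""
    if radius < 1:
        raise ParameterError(f"close radius must be >= 1, got {radius}")
    return morphology.closing(np.asarray(green_enhanced, dtype=np.float64), _disk(radius))


def channel_hue(rgb_enhanced: np.ndarray) -> np.ndarray:
    """Hue plane (HSV, angle / 360) of the enhanced RGB image."""
    rgb = np.asarray(rgb_enhanced, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise FormatError(f"expected H x W x 3, got {rgb.shape}")
    return skcolor.rgb2hsv(rgb)[..., 0]


def channel_m_cmyk(rgb_enhanced: np.ndarray) -> np.ndarray:
    """Magenta plane of the CMYK decomposition.

    ``K = 1 - max(R, G, B)``; ``M = (1 - G - K) / (1 - K)``, with ``M = 0``
    where ``K = 1`` (pure black). Dark reddish structures map high.
    """
    rgb = np.asarray(rgb_enhanced, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise FormatError(f"expected H x W x 3, got {rgb.shape}")
    k = 1.0 - rgb.max(axis=2)
    denom = 1.0 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        m = (1.0 - rgb[..., 1] - k) / denom
    m[denom <= 0.0] = 0.0
    return np.clip(m, 0.0, 1.0)


def build_channel_stack(
    pre: PreprocessedImage, config: Optional[ChannelConfig] = None
) -> ChannelStack:
    """Assemble all seven channels in their fixed order."""
    cfg = (config or ChannelConfig()).resolve(pre.shape[1])
    stack = (
        pre.green_raw.copy(),
        pre.green_enhanced.copy(),
        channel_dark_enhanced(pre.green_enhanced, cfg.asf_radii),
        channel_lesions(
            pre.green_enhanced, cfg.median_kernel, cfg.line_length, cfg.line_angles
        ),
        channel_close(pre.green_enhanced, cfg.close_radius),
        channel_hue(pre.rgb_enhanced),
        channel_m_cmyk(pre.rgb_enhanced),
    )
    return ChannelStack(channels=stack)
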