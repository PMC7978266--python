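"""Leaf image preprocessing: resize, grayscale, inverted-Otsu masking, color decomposition.

A single-leaf photograph on a bright, uniformly lit background is reduced to
a foreground mask plus ten scalar color rasters (gray, R, G, B, L*, a*, b*,
H, S, V).  The leaf is darker than the background, so the Otsu threshold on
the grayscale image separates the two classes and the *inverted* binarization
(foreground = gray strictly below the threshold) selects the leaf.

Canonical channel order, used everywhere downstream::

    gray, r, g, b, lstar, astar, bstar, h, s, v

Channels are kept in their native physical ranges (L* in [0, 100], H in
degrees [0, 360), S and V in [0, 1]); downstream feature standardization
removes scale, and native ranges keep hand-computed oracles checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from PIL import Image
from skimage.color import rgb2hsv, rgb2lab

from .errors import ConfigError, ShapeMismatchError

#: Canonical order of the ten color components.
CHANNEL_NAMES: tuple[str, ...] = (
    "gray", "r", "g", "b", "lstar", "astar", "bstar", "h", "s", "v",
)

#: Native (min, max) range of each channel, in canonical order.  a*/b* use
#: the conventional signed 8-bit Lab envelope, which covers the sRGB gamut.
CHANNEL_RANGES: tuple[tuple[float, float], ...] = (
    (0.0, 255.0),    # gray
    (0.0, 255.0),    # r
    (0.0, 255.0),    # g
    (0.0, 255.0),    # b
    (0.0, 100.0),    # lstar
    (-128.0, 127.0), # astar
    (-128.0, 127.0), # bstar
    (0.0, 360.0),    # h
    (0.0, 1.0),      # s
    (0.0, 1.0),      # v
)

# ITU-R BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class LeafImage:
    """An RGB raster of a single leaf; the unit of analysis.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` integer array with channel values in [0, 255].
    id
        Text label used to join features, scores and split membership.
    source_path
        Where the raster was read from, if it came from disk.
    """

    pixels: np.ndarray
    id: str = ""
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ConfigError(f"LeafImage needs an (H, W, 3) raster, got {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ConfigError(f"LeafImage must be at least 8x8, got {px.shape[:2]}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ConfigError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the raster."""
        return self.pixels.shape[:2]

    @classmethod
    def from_file(cls, path: str, id: str | None = None) -> "LeafImage":
        img = Image.open(path).convert("RGB")
        return cls(np.asarray(img), id=id if id is not None else str(path),
                   source_path=str(path))


@dataclass
class ForegroundMask:
    """Binary leaf mask with the threshold that produced it."""

    mask: np.ndarray
    threshold: int
    foreground_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ConfigError(f"mask must be 2-D, got shape {self.mask.shape}")
        self.foreground_fraction = float(self.mask.mean()) if self.mask.size else 0.0

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class ChannelStack:
    """The ten scalar rasters derived from one masked leaf image.

    ``data`` is a ``(10, H, W)`` float array in :data:`CHANNEL_NAMES` order.
    """

    data: np.ndarray
    names: tuple[str, ...] = CHANNEL_NAMES
    ranges: tuple[tuple[float, float], ...] = CHANNEL_RANGES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.names):
            raise ConfigError(
                f"ChannelStack needs ({len(self.names)}, H, W) data, got {self.data.shape}"
            )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]


class OtsuResult(NamedTuple):
    threshold: int
    degenerate: bool


def resize_image(img: LeafImage, width: int, height: int) -> LeafImage:
    """Bilinearly resize to exactly ``height`` rows by ``width`` columns.

    An identity resize (target equals current size) returns the raster
    unchanged.
    """
    if width < 8 or height < 8:
        raise ConfigError(f"target size must be at least 8x8, got {width}x{height}")
    if img.shape == (height, width):
        return LeafImage(img.pixels.copy(), id=img.id, source_path=img.source_path)
    out = Image.fromarray(img.pixels).resize((width, height), Image.BILINEAR)
    return LeafImage(np.asarray(out), id=img.id, source_path=img.source_path)


def to_grayscale(img: LeafImage | np.ndarray) -> np.ndarray:
    """BT.601 luma: gray = 0.299 R + 0.587 G + 0.114 B, float in [0, 255]."""
    px = img.pixels if isinstance(img, LeafImage) else np.asarray(img)
    return px[..., :3].astype(float) @ _LUMA


def otsu_threshold(gray: np.ndarray) -> OtsuResult:
    """Otsu's threshold on a 256-bin histogram of an 8-bit-quantized raster.

    For a candidate ``t`` the two classes are pixels with value ``< t`` and
    ``>= t``; the returned ``t`` maximizes the between-class variance
    ``w0(t) * w1(t) * (mu0(t) - mu1(t))**2`` (equivalently minimizes the
    intra-class variance), with ties broken toward the smallest ``t``.  A
    constant raster has a single-class histogram; it yields ``t = 0`` with
    ``degenerate=True``.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.size == 0:
        raise ConfigError("cannot threshold an empty raster")
    q = np.clip(np.round(gray), 0, 255).astype(np.intp)
    hist = np.bincount(q.ravel(), minlength=256).astype(float)
    n = hist.sum()
    if np.count_nonzero(hist) <= 1:
        return OtsuResult(0, True)

    # Cumulative class weights/means for every threshold t = 0..255, where
    # class 0 holds bins [0, t) and class 1 holds bins [t, 255].
    csum = np.concatenate([[0.0], np.cumsum(hist)])[:256]          # w0 counts
    cmoment = np.concatenate([[0.0], np.cumsum(hist * np.arange(256))])[:256]
    w0 = csum / n
    w1 = 1.0 - w0
    total_moment = float((hist * np.arange(256)).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cmoment / csum
        mu1 = (total_moment - cmoment) / (n - csum)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=0.0)
    t = int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer
    return OtsuResult(t, False)


def make_foreground_mask(gray: np.ndarray, threshold: int) -> ForegroundMask:
    """Inverted binarization: foreground = pixels with ``gray < threshold``.

    Pixels exactly at the threshold are background; the leaf is the dark
    class against the bright chamber background.
    """
    if not 0 <= threshold <= 255:
        raise ConfigError(f"threshold must be in [0, 255], got {threshold}")
    return ForegroundMask(np.asarray(gray, dtype=float) < threshold, int(threshold))


def segment_leaf(img: LeafImage) -> ForegroundMask:
    """Grayscale -> Otsu -> inverted binarization, in one call."""
    t = otsu_threshold(to_grayscale(img))
    return make_foreground_mask(to_grayscale(img), t.threshold)


def apply_mask(img: LeafImage, mask: ForegroundMask) -> LeafImage:
    """Zero out background pixels; foreground values are preserved exactly."""
    if img.shape != mask.mask.shape:
        raise ShapeMismatchError(
            f"image shape {img.shape} != mask shape {mask.mask.shape}"
        )
    out = np.where(mask.mask[..., None], img.pixels, 0).astype(np.uint8)
    return LeafImage(out, id=img.id, source_path=img.source_path)


def decompose_channels(img: LeafImage, mask: ForegroundMask) -> ChannelStack:
    """Decompose the masked image into the ten canonical color components.

    L*a*b* uses the standard sRGB -> XYZ (D65) -> CIE-Lab formulas; HSV uses
    the hexcone model with H in degrees.  Conversion is applied to the masked
    image, so background zeros convert to gray 0, L* 0, V 0.
    """
    masked = apply_mask(img, mask)
    rgb = masked.pixels.astype(float)
    rgb01 = rgb / 255.0
    lab = rgb2lab(rgb01)
    hsv = rgb2hsv(rgb01)
    data = np.stack([
        to_grayscale(masked),
        rgb[..., 0], rgb[..., 1], rgb[..., 2],
        lab[..., 0], lab[..., 1], lab[..., 2],
        hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2],
    ])
    return ChannelStack(data)
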