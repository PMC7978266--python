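"""The 30 color features: mean, min, std of each channel over foreground pixels.

Feature order is channel-major in the canonical channel order, statistic
order (mean, min, std) within each channel — ``gray_mean, gray_min,
gray_std, r_mean, ..., v_std``.  Statistics are computed over foreground
pixels only (background zeros would make every minimum trivially 0), and
std is the population standard deviation (divisor n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, ShapeMismatchError
from .segment import CHANNEL_NAMES, ChannelStack, ForegroundMask

#: The 30 feature names, canonical order.
COLOR_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{stat}" for ch in CHANNEL_NAMES for stat in ("mean", "min", "std")
)


@dataclass
class ColorFeatureVector:
    values: np.ndarray  # (30,) float
    image_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(COLOR_FEATURE_NAMES),):
            raise ShapeMismatchError(
                f"expected {len(COLOR_FEATURE_NAMES)} color features, "
                f"got shape {self.values.shape}"
            )


def channel_stats(channel: np.ndarray, mask: ForegroundMask
                  ) -> tuple[float, float, float]:
    """(mean, min, population std) over foreground pixels of one channel."""
    channel = np.asarray(channel, dtype=float)
    if channel.shape != mask.mask.shape:
        raise ShapeMismatchError(
            f"channel shape {channel.shape} != mask shape {mask.mask.shape}"
        )
    fg = channel[mask.mask]
    if fg.size == 0:
        raise EmptyMaskError("no foreground pixels")
    return float(fg.mean()), float(fg.min()), float(fg.std())


def extract_color_features(stack: ChannelStack, mask: ForegroundMask,
                           image_id: str = "") -> ColorFeatureVector:
    """All 30 color features of one image, channel-major canonical order."""
    if stack.data.shape[1:] != mask.mask.shape:
        raise ShapeMismatchError(
            f"stack shape {stack.data.shape[1:]} != mask shape {mask.mask.shape}"
        )
    values = np.empty(len(COLOR_FEATURE_NAMES))
    for c in range(stack.data.shape[0]):
        values[3 * c: 3 * c + 3] = channel_stats(stack.data[c], mask)
    return ColorFeatureVector(values, image_id=image_id)
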