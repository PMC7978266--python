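"""ORB keypoints and the 200-bin bag-of-visual-words encoding.

Per color channel, ORB keypoints (FAST corners on an 8-level pyramid with
scale factor 1.2, Harris-ranked, intensity-centroid oriented, 256-bit
steered-BRIEF described) are detected on the masked image; a 20-word visual
vocabulary is learned per channel by k-means on *training* descriptors, and
each image is encoded as the concatenation of the ten 20-bin nearest-centroid
count histograms (10 x 20 = 200 local features, channel-major).

Detection and description are backed by ``skimage.feature.ORB``;
:func:`fast_corner_test` and :func:`intensity_centroid_orientation` are
independent reference implementations of the two ORB primitives, kept here
so the detector's behavior is verifiable against first principles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from skimage.feature import ORB
from sklearn.cluster import KMeans

from .errors import ConfigError, VocabularyError
from .segment import CHANNEL_NAMES, CHANNEL_RANGES, ChannelStack, ForegroundMask

N_VISUAL_WORDS = 20
DESCRIPTOR_BITS = 256
#: The 200 local-feature names: c0_k00 .. c9_k19, channel-major.
LOCAL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"c{c}_k{k:02d}" for c in range(len(CHANNEL_NAMES)) for k in range(N_VISUAL_WORDS)
)

#: The 16 offsets (drow, dcol) of the radius-3 Bresenham circle used by the
#: FAST segment test, in clockwise order starting from the top pixel.
FAST_CIRCLE: tuple[tuple[int, int], ...] = (
    (-3, 0), (-3, 1), (-2, 2), (-1, 3), (0, 3), (1, 3), (2, 2), (3, 1),
    (3, 0), (3, -1), (2, -2), (1, -3), (0, -3), (-1, -3), (-2, -2), (-3, -1),
)


@dataclass
class Keypoint:
    """A detected corner: 0-based (x, y), Harris response, orientation, octave."""

    x: float
    y: float
    response: float
    angle: float      # degrees in [0, 360)
    octave: int


class OrientationResult(NamedTuple):
    angle: float
    degenerate: bool


def fast_corner_test(image: np.ndarray, center: tuple[int, int],
                     t: float, n_arc: int = 9) -> bool:
    """FAST segment test at ``center = (row, col)``.

    True iff at least ``n_arc`` *contiguous* pixels on the radius-3 circle
    are all brighter than ``center + t`` or all darker than ``center - t``.
    """
    image = np.asarray(image, dtype=float)
    r, c = center
    h, w = image.shape
    if r - 3 < 0 or r + 3 >= h or c - 3 < 0 or c + 3 >= w:
        raise ConfigError(f"FAST circle around {center} out of bounds for {image.shape}")
    ring = np.array([image[r + dr, c + dc] for dr, dc in FAST_CIRCLE])
    cval = image[r, c]
    for cond in (ring > cval + t, ring < cval - t):
        doubled = np.concatenate([cond, cond])
        run = 0
        for v in doubled:
            run = run + 1 if v else 0
            if run >= n_arc:
                return True
    return False


def intensity_centroid_orientation(patch: np.ndarray, radius: int | None = None
                                   ) -> OrientationResult:
    """Orientation from image moments over a centered circular patch.

    With ``m_pq = sum x^p y^q I(x, y)`` (x rightward, y downward, origin at
    the patch center), the angle is ``atan2(m01, m10)`` mapped to [0, 360)
    degrees.  A zero-mass or mass-centered patch is degenerate and returns 0.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2:
        raise ConfigError("patch must be 2-D")
    h, w = patch.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if radius is None:
        radius = int(min(cy, cx))
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    inside = dx ** 2 + dy ** 2 <= radius ** 2
    m10 = float((dx * patch)[inside].sum())
    m01 = float((dy * patch)[inside].sum())
    norm = max(np.abs(patch[inside]).sum(), 1.0)
    if math.hypot(m10, m01) < 1e-9 * norm:
        return OrientationResult(0.0, True)
    return OrientationResult(math.degrees(math.atan2(m01, m10)) % 360.0, False)


def _rescale_channel(channel: np.ndarray, channel_index: int) -> np.ndarray:
    """Affine-map a channel from its native range to integer [0, 255]."""
    lo, hi = CHANNEL_RANGES[channel_index]
    out = (np.asarray(channel, dtype=float) - lo) * (255.0 / (hi - lo))
    return np.clip(np.round(out), 0, 255)


def detect_orb(channel: np.ndarray, mask: ForegroundMask,
               channel_index: int = 0, max_keypoints: int = 500,
               fast_threshold: float = 0.08
               ) -> tuple[list[Keypoint], np.ndarray]:
    """Detect ORB keypoints on one channel and keep those inside the mask.

    The channel is rescaled to integer [0, 255] from its native range, and
    detection runs on the bounding box of the foreground mask plus a margin
    (the background is flat, so off-leaf regions contribute no corners;
    keypoints whose center falls outside the mask are discarded regardless).

    Returns ``(keypoints, descriptors)`` where descriptors is a
    ``(n, 256)`` uint8 array of bits.
    """
    if max_keypoints < 1:
        raise ConfigError(f"max_keypoints must be >= 1, got {max_keypoints}")
    empty = ([], np.zeros((0, DESCRIPTOR_BITS), dtype=np.uint8))
    m = mask.mask
    if channel.shape != m.shape:
        raise ConfigError(f"channel shape {channel.shape} != mask shape {m.shape}")
    if not m.any() or min(m.shape) < 32:
        return empty
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    margin = 40
    r0, r1 = max(rows[0] - margin, 0), min(rows[-1] + margin + 1, m.shape[0])
    c0, c1 = max(cols[0] - margin, 0), min(cols[-1] + margin + 1, m.shape[1])

    scaled = _rescale_channel(channel, channel_index)
    crop = scaled[r0:r1, c0:c1] / 255.0
    if min(crop.shape) < 32:
        return empty

    orb = ORB(n_keypoints=max_keypoints, downscale=1.2, n_scales=8,
              fast_threshold=fast_threshold)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            orb.detect_and_extract(crop)
    except (RuntimeError, IndexError):  # no features found
        return empty

    kp_rc = orb.keypoints + np.array([r0, c0])
    rr = np.clip(np.round(kp_rc[:, 0]).astype(int), 0, m.shape[0] - 1)
    cc = np.clip(np.round(kp_rc[:, 1]).astype(int), 0, m.shape[1] - 1)
    keep = m[rr, cc]

    keypoints = []
    for (y, x), resp, ang, scale in zip(
            kp_rc[keep], orb.responses[keep], orb.orientations[keep],
            orb.scales[keep]):
        octave = int(round(math.log(scale) / math.log(1.2))) if scale > 0 else 0
        keypoints.append(Keypoint(x=float(x), y=float(y), response=float(resp),
                                  angle=math.degrees(float(ang)) % 360.0,
                                  octave=octave))
    descriptors = orb.descriptors[keep].astype(np.uint8)
    return keypoints, descriptors


@dataclass
class VisualVocabulary:
    """A channel's dictionary of 20 visual words (k-means centroids)."""

    channel_index: int
    centroids: np.ndarray  # (k, 256) float
    km_seed: int
    inertia: float

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != DESCRIPTOR_BITS:
            raise VocabularyError(
                f"centroids must be (k, {DESCRIPTOR_BITS}), got {self.centroids.shape}"
            )

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def to_dict(self) -> dict:
        return {"schema": 1, "channel_index": self.channel_index,
                "km_seed": self.km_seed, "inertia": self.inertia,
                "centroids": self.centroids.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "VisualVocabulary":
        return cls(d["channel_index"], np.array(d["centroids"]),
                   d["km_seed"], d["inertia"])


def _canonical_order(centroids: np.ndarray) -> np.ndarray:
    """Order centroids by first coordinate, then lexicographically."""
    return centroids[np.lexsort(centroids.T[::-1])]


def build_vocabulary(train_descriptors: Sequence[np.ndarray],
                     k: int = N_VISUAL_WORDS, km_seed: int = 0,
                     max_train_descriptors: int = 5000,
                     n_restarts: int = 10) -> list[VisualVocabulary]:
    """Learn one k-word vocabulary per channel from training descriptors.

    ``train_descriptors[c]`` pools the channel-c descriptors of *training
    images only*.  Bits are cast to {0.0, 1.0} and clustered with seeded
    k-means (k-means++ init, ``n_restarts`` restarts by inertia).  Pools
    larger than ``max_train_descriptors`` are subsampled (seeded) before
    clustering.  Centroids are returned in canonical order.
    """
    if len(train_descriptors) != len(CHANNEL_NAMES):
        raise VocabularyError(
            f"need one descriptor pool per channel ({len(CHANNEL_NAMES)}), "
            f"got {len(train_descriptors)}"
        )
    vocabs = []
    for c, pool in enumerate(train_descriptors):
        pool = np.asarray(pool, dtype=float)
        if pool.ndim != 2 or pool.shape[1] != DESCRIPTOR_BITS:
            raise VocabularyError(f"channel {c}: descriptors must be (n, 256)")
        if pool.shape[0] < k:
            raise VocabularyError(
                f"channel {c} has {pool.shape[0]} training descriptors but "
                f"k={k}; use a larger training set or more textured images"
            )
        rng = np.random.default_rng(km_seed + 1000 * c)
        if pool.shape[0] > max_train_descriptors:
            idx = rng.choice(pool.shape[0], max_train_descriptors, replace=False)
            pool = pool[idx]
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                    random_state=int(rng.integers(2 ** 31)))
        km.fit(pool)
        vocabs.append(VisualVocabulary(
            channel_index=c, centroids=_canonical_order(km.cluster_centers_),
            km_seed=km_seed, inertia=float(km.inertia_)))
    return vocabs


def encode_bow(descriptors: np.ndarray, vocab: VisualVocabulary) -> np.ndarray:
    """Nearest-centroid count histogram of one channel's descriptors.

    Distance is Euclidean on the bit -> real cast; ties go to the lowest
    centroid index.  The histogram sums to the descriptor count (it is a
    partition); an empty descriptor set yields all zeros.
    """
    hist = np.zeros(vocab.k, dtype=int)
    d = np.asarray(descriptors, dtype=float)
    if d.size == 0:
        return hist
    if d.ndim != 2 or d.shape[1] != vocab.centroids.shape[1]:
        raise VocabularyError(
            f"descriptors shape {d.shape} incompatible with vocabulary "
            f"{vocab.centroids.shape}"
        )
    # squared Euclidean; argmin takes the first (lowest-index) minimizer
    d2 = (d ** 2).sum(1)[:, None] - 2.0 * d @ vocab.centroids.T \
        + (vocab.centroids ** 2).sum(1)[None, :]
    assign = np.argmin(d2, axis=1)
    np.add.at(hist, assign, 1)
    return hist


@dataclass
class LocalFeatureVector:
    values: np.ndarray                 # (200,) counts
    n_keypoints_per_channel: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(LOCAL_FEATURE_NAMES),):
            raise VocabularyError(
                f"expected {len(LOCAL_FEATURE_NAMES)} local features, "
                f"got shape {self.values.shape}"
            )


def extract_local_features(stack: ChannelStack, mask: ForegroundMask,
                           vocabs: Sequence[VisualVocabulary],
                           max_keypoints: int = 500,
                           image_id: str = "") -> LocalFeatureVector:
    """Concatenated per-channel BoVW histograms (10 x 20 = 200 values)."""
    if len(vocabs) != len(CHANNEL_NAMES):
        raise VocabularyError(f"need {len(CHANNEL_NAMES)} vocabularies")
    parts, counts = [], []
    for c in range(len(CHANNEL_NAMES)):
        _, desc = detect_orb(stack.data[c], mask, channel_index=c,
                             max_keypoints=max_keypoints)
        parts.append(encode_bow(desc, vocabs[c]))
        counts.append(desc.shape[0])
    return LocalFeatureVector(np.concatenate(parts).astype(float),
                              np.array(counts), image_id=image_id)
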