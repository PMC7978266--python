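"""A scikit-learn transformer that turns leaf images into 230-feature rows.

``fit`` segments each training image, detects ORB keypoints per color
channel and learns the ten 20-word visual vocabularies from *training*
descriptors only; ``transform`` maps any batch of images to the
(n_images, 230) matrix of 30 color + 200 bag-of-visual-words features.  An
audit trail of the image ids used to build the vocabularies is kept in
``vocabulary_image_ids_``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .classify import FEATURE_NAMES
from .colorfeat import extract_color_features
from .localfeat import N_VISUAL_WORDS, build_vocabulary, detect_orb, encode_bow
from .segment import (
    CHANNEL_NAMES,
    LeafImage,
    decompose_channels,
    make_foreground_mask,
    otsu_threshold,
    resize_image,
    to_grayscale,
)


def _as_leaf_image(item, index: int) -> LeafImage:
    if isinstance(item, LeafImage):
        return item
    return LeafImage(np.asarray(item), id=f"img_{index:04d}")


class FreshnessFeaturizer(TransformerMixin, BaseEstimator):
    """Segment leaf images and extract the 230 canonical features.

    Parameters
    ----------
    k
        Visual words per channel (20 in the reference configuration).
    km_seed
        Seed for vocabulary k-means (and its descriptor subsampling).
    max_keypoints
        ORB keypoint cap per channel.
    resize_width, resize_height
        Working resolution; images already at this size pass through
        unchanged.
    max_train_descriptors
        Per-channel cap on the descriptor pool clustered by k-means.

    Attributes
    ----------
    vocabularies_ : list of VisualVocabulary
        One per channel, learned in ``fit``.
    vocabulary_image_ids_ : list of str
        Ids of the images whose descriptors built the vocabularies.
    feature_names_out_ : tuple of str
        The 230 column names.
    """

    def __init__(self, k: int = N_VISUAL_WORDS, km_seed: int = 0,
                 max_keypoints: int = 500, resize_width: int = 490,
                 resize_height: int = 653, max_train_descriptors: int = 5000):
        self.k = k
        self.km_seed = km_seed
        self.max_keypoints = max_keypoints
        self.resize_width = resize_width
        self.resize_height = resize_height
        self.max_train_descriptors = max_train_descriptors

    # -- per-image processing ------------------------------------------------
    def process_image(self, item, index: int = 0):
        """Segment one image; return (image_id, color_values, descriptors).

        ``descriptors`` is a list of 10 (n_c, 256) uint8 arrays, one per
        channel in canonical order.
        """
        img = _as_leaf_image(item, index)
        img = resize_image(img, self.resize_width, self.resize_height)
        gray = to_grayscale(img)
        t = otsu_threshold(gray)
        mask = make_foreground_mask(gray, t.threshold)
        stack = decompose_channels(img, mask)
        color = extract_color_features(stack, mask, image_id=img.id)
        descs = []
        for c in range(len(CHANNEL_NAMES)):
            _, d = detect_orb(stack.data[c], mask, channel_index=c,
                              max_keypoints=self.max_keypoints)
            descs.append(d)
        return img.id, color.values, descs

    # -- estimator API -------------------------------------------------------
    def fit(self, X: Sequence, y=None):
        cached = [self.process_image(item, i) for i, item in enumerate(X)]
        self._fit_from_cache(cached)
        self._fit_cache_ = cached
        return self

    def _fit_from_cache(self, cached) -> None:
        pools = [[] for _ in CHANNEL_NAMES]
        ids = []
        for image_id, _color, descs in cached:
            ids.append(image_id)
            for c, d in enumerate(descs):
                if d.size:
                    pools[c].append(d)
        pooled = [np.concatenate(p) if p else np.zeros((0, 256), np.uint8)
                  for p in pools]
        self.vocabularies_ = build_vocabulary(
            pooled, k=self.k, km_seed=self.km_seed,
            max_train_descriptors=self.max_train_descriptors)
        self.vocabulary_image_ids_ = ids
        self.feature_names_out_ = FEATURE_NAMES

    def _encode(self, color_values: np.ndarray, descs) -> np.ndarray:
        local = np.concatenate([
            encode_bow(d, self.vocabularies_[c]) for c, d in enumerate(descs)
        ]).astype(float)
        return np.concatenate([color_values, local])

    def transform(self, X: Sequence) -> np.ndarray:
        check_is_fitted(self, "vocabularies_")
        rows = []
        for i, item in enumerate(X):
            _id, color, descs = self.process_image(item, i)
            rows.append(self._encode(color, descs))
        return np.asarray(rows)

    def fit_transform(self, X: Sequence, y=None) -> np.ndarray:
        self.fit(X)
        cached = self._fit_cache_
        del self._fit_cache_
        return np.asarray([self._encode(color, descs)
                           for _id, color, descs in cached])

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "vocabularies_")
        return np.asarray(self.feature_names_out_, dtype=object)
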