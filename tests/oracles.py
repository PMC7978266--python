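"""Independent brute-force oracles used to verify the fast implementations.

Everything here is written from first principles (exhaustive scans and
definitional sums) and deliberately shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def brute_otsu(gray: np.ndarray) -> tuple[int, np.ndarray]:
    """Exhaustive 256-threshold scan maximizing between-class variance.

    For each t, class 0 = pixels < t, class 1 = pixels >= t.  Returns the
    smallest maximizing t and the full variance curve.
    """
    q = np.clip(np.round(np.asarray(gray, float)), 0, 255).astype(int).ravel()
    n = q.size
    sigma_b = np.zeros(256)
    for t in range(256):
        c0 = q[q < t]
        c1 = q[q >= t]
        if len(c0) == 0 or len(c1) == 0:
            continue
        w0, w1 = len(c0) / n, len(c1) / n
        sigma_b[t] = w0 * w1 * (c0.mean() - c1.mean()) ** 2
    return int(np.argmax(sigma_b)), sigma_b


# radius-3 Bresenham circle, clockwise from the top — fixed published ring
RING = [(-3, 0), (-3, 1), (-2, 2), (-1, 3), (0, 3), (1, 3), (2, 2), (3, 1),
        (3, 0), (3, -1), (2, -2), (1, -3), (0, -3), (-1, -3), (-2, -2), (-3, -1)]


def brute_fast(image: np.ndarray, center: tuple[int, int], t: float,
               n_arc: int = 9) -> bool:
    """Enumerate all 16 arc start positions for both polarities."""
    r, c = center
    ring = [float(image[r + dr, c + dc]) for dr, dc in RING]
    cv = float(image[r, c])
    for start in range(16):
        arc = [ring[(start + i) % 16] for i in range(n_arc)]
        if all(v > cv + t for v in arc) or all(v < cv - t for v in arc):
            return True
    return False


def brute_nearest_centroid(descriptors: np.ndarray,
                           centroids: np.ndarray) -> np.ndarray:
    """Per-descriptor nearest centroid (Euclidean, lowest index on ties)."""
    out = []
    for d in np.asarray(descriptors, float):
        best, best_d = 0, np.inf
        for idx, cen in enumerate(np.asarray(centroids, float)):
            dist = float(np.sqrt(((d - cen) ** 2).sum()))
            if dist < best_d - 1e-12:
                best, best_d = idx, dist
        out.append(best)
    return np.array(out)


def brute_anova_partition(y: np.ndarray) -> dict:
    """Definitional sums of squares for the two-factor no-replication layout."""
    y = np.asarray(y, float)
    n_i, n_j = y.shape
    grand = y.sum() / (n_i * n_j)
    ss_total = sum((y[i, j] - grand) ** 2
                   for i in range(n_i) for j in range(n_j))
    row_means = [y[i, :].sum() / n_j for i in range(n_i)]
    col_means = [y[:, j].sum() / n_i for j in range(n_j)]
    ss_sample = n_j * sum((m - grand) ** 2 for m in row_means)
    ss_panel = n_i * sum((m - grand) ** 2 for m in col_means)
    ss_error = sum(
        (y[i, j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n_i) for j in range(n_j))
    return {"ss_total": ss_total, "ss_sample": ss_sample,
            "ss_panel": ss_panel, "ss_error": ss_error}
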