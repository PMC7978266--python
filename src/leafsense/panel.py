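"""Panel-score aggregation, coarsening, and panel-agreement statistics.

The supervised target is the per-image mean of the panel scores, rounded
half-up to the nearest level (the "true label").  Four-level labels are
coarsened to three levels by merging {3, 4} ("fresh") and to two levels by
further merging {1, 2} ("not fresh").

Panel agreement is summarized by the per-image between-subject standard
deviation sigma_i (population form, divisor n_j) and its mean sigma-bar, a
randomized-block ANOVA (panels as blocks, images as the sample factor) with
Cohen's f-squared effect sizes, Pearson correlations between image features
and the unrounded mean score, and per-panel classification accuracies
against the true label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ShapeMismatchError

#: 4-level -> 3-level map: {3, 4} merge to "fresh" (3).
LEVEL3_MAP = {1: 1, 2: 2, 3: 3, 4: 3}
#: 4-level -> 2-level map: {1, 2} not fresh (1), {3, 4} fresh (2).
LEVEL2_MAP = {1: 1, 2: 1, 3: 2, 4: 2}


def coarsen(labels4: np.ndarray, level: int) -> np.ndarray:
    """Map 4-level labels to the requested level set (4, 3 or 2)."""
    labels4 = np.asarray(labels4, dtype=int)
    if level == 4:
        return labels4.copy()
    mapping = {4: None, 3: LEVEL3_MAP, 2: LEVEL2_MAP}.get(level)
    if mapping is None:
        raise ConfigError(f"level must be 4, 3 or 2, got {level}")
    lut = np.zeros(5, dtype=int)
    for k, v in mapping.items():
        lut[k] = v
    return lut[labels4]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass
class PanelTable:
    """n_images x n_panels integer scores in {1, 2, 3, 4}."""

    scores: np.ndarray
    image_ids: list[str] | None = None
    panel_ids: list[str] | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.ndim != 2:
            raise ConfigError(f"scores must be 2-D, got shape {s.shape}")
        bad = np.argwhere((s < 1) | (s > 4) | (s != np.round(s)))
        if bad.size:
            cells = ", ".join(f"({i},{j})={s[i, j]}" for i, j in bad[:10])
            raise ConfigError(f"scores outside {{1..4}} at cells: {cells}")
        self.scores = s.astype(int)
        n_i, n_j = s.shape
        if self.image_ids is None:
            self.image_ids = [f"img_{i:04d}" for i in range(n_i)]
        if self.panel_ids is None:
            self.panel_ids = [f"panel_{j + 1:02d}" for j in range(n_j)]
        if len(self.image_ids) != n_i or len(self.panel_ids) != n_j:
            raise ShapeMismatchError("id lists do not match the score matrix")

    @property
    def n_images(self) -> int:
        return self.scores.shape[0]

    @property
    def n_panels(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PanelTable":
        df = pd.read_csv(path, sep="\t")
        panel_cols = [c for c in df.columns if c.startswith("panel_")]
        if not panel_cols:
            raise ConfigError(f"{path}: no panel_* columns found")
        return cls(df[panel_cols].to_numpy(),
                   image_ids=[str(x) for x in df["image_id"]],
                   panel_ids=panel_cols)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.panel_ids)
        df.insert(0, "image_id", self.image_ids)
        return df


@dataclass
class TrueLabels:
    """Aggregated targets at the three granularities."""

    mean_score: np.ndarray  # unrounded per-image mean
    label4: np.ndarray
    label3: np.ndarray
    label2: np.ndarray

    def at_level(self, level: int) -> np.ndarray:
        return {4: self.label4, 3: self.label3, 2: self.label2}[level]


def aggregate_true_labels(table: PanelTable) -> TrueLabels:
    """Mean over panels, rounded half-up; plus the fixed coarsenings."""
    mean = table.scores.mean(axis=1)
    label4 = _round_half_up(mean)
    return TrueLabels(mean_score=mean, label4=label4,
                      label3=coarsen(label4, 3), label2=coarsen(label4, 2))


def panel_sd(table: PanelTable) -> tuple[np.ndarray, float]:
    """Per-image between-subject SD (population divisor) and its mean.

    sigma_i = sqrt((1/n_j) * sum_j (y_ij - mean_i)^2); sigma-bar is the mean
    of sigma_i over images.
    """
    sigma_i = table.scores.std(axis=1)  # ddof=0: population form
    return sigma_i, float(sigma_i.mean())


@dataclass
class AnovaFactor:
    ss: float
    df: int
    ms: float
    f: float
    p: float
    f2: float


@dataclass
class AnovaResult:
    """Randomized-block partition: samples (rows) + panels (columns) + error."""

    sample: AnovaFactor
    panel: AnovaFactor
    ss_error: float
    df_error: int
    ms_error: float
    ss_total: float

    def to_dict(self) -> dict:
        return {
            "sample": vars(self.sample), "panel": vars(self.panel),
            "error": {"ss": self.ss_error, "df": self.df_error,
                      "ms": self.ms_error},
            "ss_total": self.ss_total,
        }


def anova_random_blocks(table: PanelTable) -> AnovaResult:
    """Two-factor ANOVA without replication on the complete score matrix.

    SS_total is partitioned into SS_sample (image rows), SS_panel (rater
    columns) and SS_error (residual); F = MS_factor / MS_error with the
    repeated-measures degrees of freedom, and Cohen's f^2 = SS_factor /
    SS_error.
    """
    y = table.scores.astype(float)
    n_i, n_j = y.shape
    if n_i < 2 or n_j < 2:
        raise ConfigError(f"ANOVA needs at least a 2x2 table, got {y.shape}")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_sample = float(n_j * ((y.mean(axis=1) - grand) ** 2).sum())
    ss_panel = float(n_i * ((y.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_sample - ss_panel
    df_s, df_p = n_i - 1, n_j - 1
    df_e = df_s * df_p
    ms_e = ss_error / df_e

    def factor(ss: float, df: int) -> AnovaFactor:
        ms = ss / df
        if ms_e > 0:
            f = ms / ms_e
        else:  # no residual variation: a zero-SS factor has no effect at all
            f = 0.0 if ms == 0 else np.inf
        p = float(stats.f.sf(f, df, df_e)) if np.isfinite(f) else 0.0
        if ss_error > 0:
            f2 = ss / ss_error
        else:
            f2 = 0.0 if ss == 0 else np.inf
        return AnovaFactor(ss=ss, df=df, ms=ms, f=f, p=p, f2=f2)

    return AnovaResult(sample=factor(ss_sample, df_s),
                       panel=factor(ss_panel, df_p),
                       ss_error=float(ss_error), df_error=df_e,
                       ms_error=float(ms_e), ss_total=ss_total)


@dataclass
class CorrelationReport:
    r: dict[str, float]
    undefined: set[str]


def feature_score_correlations(features: pd.DataFrame | np.ndarray,
                               mean_score: np.ndarray,
                               names: Sequence[str] | None = None
                               ) -> CorrelationReport:
    """Pearson r of every feature column against the unrounded mean score.

    Zero-variance columns are reported as undefined (flagged), not as 0 or
    NaN.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if names is None:
            names = [f"f{i}" for i in range(x.shape[1])]
    y = np.asarray(mean_score, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ShapeMismatchError(
            f"{x.shape[0]} feature rows but {y.shape[0]} scores"
        )
    if x.shape[0] < 3:
        raise ConfigError("need at least 3 images for correlation")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom_x = np.sqrt((xc ** 2).sum(axis=0))
    denom_y = float(np.sqrt((yc ** 2).sum()))
    r: dict[str, float] = {}
    undefined: set[str] = set()
    for j, name in enumerate(names):
        if denom_x[j] == 0.0 or denom_y == 0.0:
            undefined.add(name)
        else:
            r[name] = float((xc[:, j] * yc).sum() / (denom_x[j] * denom_y))
    return CorrelationReport(r=r, undefined=undefined)


def panel_accuracy(table: PanelTable, labels: TrueLabels, level: int,
                   subset: Sequence[int] | None = None) -> np.ndarray:
    """Per-panel accuracy (%) against the coarsened true label.

    Each panel's raw scores are coarsened by the same maps as the labels and
    compared on ``subset`` (default: all images; the study uses the test
    split).
    """
    idx = np.arange(table.n_images) if subset is None else np.asarray(subset, int)
    if idx.size == 0:
        raise ConfigError("subset must be non-empty")
    truth = labels.at_level(level)[idx]
    out = np.empty(table.n_panels)
    for j in range(table.n_panels):
        pred = coarsen(table.scores[idx, j], level)
        out[j] = 100.0 * float((pred == truth).mean())
    return out


def panel_stats_report(table: PanelTable,
                       features: pd.DataFrame | None = None) -> dict:
    """JSON-ready summary: sigma, ANOVA (+f^2), optional correlations."""
    labels = aggregate_true_labels(table)
    sigma_i, sigma_bar = panel_sd(table)
    report = {
        "n_images": table.n_images,
        "n_panels": table.n_panels,
        "sigma_bar": sigma_bar,
        "sigma_i_quartiles": [float(q) for q in
                              np.percentile(sigma_i, [0, 25, 50, 75, 100])],
        "label4_counts": {str(k): int((labels.label4 == k).sum())
                          for k in (1, 2, 3, 4)},
        "anova": anova_random_blocks(table).to_dict(),
    }
    if features is not None:
        corr = feature_score_correlations(features, labels.mean_score)
        report["correlations"] = corr.r
        report["correlations_undefined"] = sorted(corr.undefined)
    return report
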