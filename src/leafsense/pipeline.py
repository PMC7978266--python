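"""End-to-end orchestration: images -> features -> labels -> models -> report.

A run consumes either a directory of real leaf photographs plus a panel
score table, or a seeded synthetic configuration.  It produces a run
directory with the feature table, labels, visual vocabularies, evaluation
reports for the SVM and the MLP at 4/3/2 levels, panel statistics, and a
panel-versus-model comparison (the model accuracies placed against the
per-panel accuracy distribution).

Heavy extraction output is cached in the run directory keyed by a content
hash of the relevant configuration, so re-running with an unchanged config
skips the expensive stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify
from .errors import ConfigError, PipelineError
from .featurize import FreshnessFeaturizer
from .localfeat import DESCRIPTOR_BITS, VisualVocabulary, build_vocabulary, encode_bow
from .panel import (
    PanelTable,
    TrueLabels,
    aggregate_true_labels,
    panel_accuracy,
    panel_stats_report,
)
from .segment import CHANNEL_NAMES, LeafImage
from .synthesize import SynthConfig, iter_samples

_N_CH = len(CHANNEL_NAMES)


@dataclass
class RunConfig:
    """Everything a reproducible run needs; fully serializable."""

    out_dir: str
    synth: SynthConfig | None = None
    images_dir: str | None = None
    scores_path: str | None = None
    k: int = 20
    km_seed: int = 0
    max_keypoints: int = 500
    max_train_descriptors: int = 5000
    split_seed: int = 0
    test_fraction: float = 0.2
    ann_seed: int = 0
    cv_folds: int = 5
    levels: tuple[int, ...] = (4, 3, 2)
    resize_width: int = 490
    resize_height: int = 653

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synth is not None:
            d["synth"] = asdict(self.synth)
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory view of a finished run (everything is also on disk)."""

    report: dict
    features: pd.DataFrame          # image_id + 230 columns
    panel_table: PanelTable
    labels: TrueLabels
    split: classify.SplitPlan
    vocabularies: list[VisualVocabulary]
    svm_report: classify.EvalReport
    ann_report: classify.EvalReport
    X: np.ndarray = field(repr=False, default=None)
    mean_iou: float | None = None
    latent: np.ndarray | None = None


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0


class _DescriptorStore:
    """Packed per-image per-channel ORB descriptors (memory-lean)."""

    def __init__(self) -> None:
        self.packed: list[list[np.ndarray]] = [[] for _ in range(_N_CH)]

    def add(self, descs: list[np.ndarray]) -> None:
        for c, d in enumerate(descs):
            self.packed[c].append(np.packbits(d.astype(np.uint8), axis=1)
                                  if d.size else np.zeros((0, 32), np.uint8))

    def get(self, image_index: int, channel: int) -> np.ndarray:
        p = self.packed[channel][image_index]
        if p.size == 0:
            return np.zeros((0, DESCRIPTOR_BITS), np.uint8)
        return np.unpackbits(p, axis=1)[:, :DESCRIPTOR_BITS]

    def pooled(self, channel: int, image_indices: np.ndarray) -> np.ndarray:
        parts = [self.get(i, channel) for i in image_indices]
        parts = [p for p in parts if p.size]
        return np.concatenate(parts) if parts \
            else np.zeros((0, DESCRIPTOR_BITS), np.uint8)

    @property
    def n_images(self) -> int:
        return len(self.packed[0])


def _extract_stage(cfg: RunConfig):
    """Stream images through segmentation + detection.

    Returns (image_ids, color matrix, descriptor store, panel table or None,
    mean IoU or None, latent or None).
    """
    feat = FreshnessFeaturizer(
        k=cfg.k, km_seed=cfg.km_seed, max_keypoints=cfg.max_keypoints,
        resize_width=cfg.resize_width, resize_height=cfg.resize_height,
        max_train_descriptors=cfg.max_train_descriptors)
    ids, colors = [], []
    store = _DescriptorStore()
    ious: list[float] = []
    latent: list[float] = []
    scores = []

    if cfg.synth is not None:
        for i, sample in enumerate(iter_samples(cfg.synth)):
            image_id, color, descs = feat.process_image(
                LeafImage(sample.image, id=sample.image_id), i)
            # recompute the mask the featurizer used, for IoU bookkeeping
            from .segment import make_foreground_mask, otsu_threshold, to_grayscale
            gray = to_grayscale(sample.image.astype(float))
            t = otsu_threshold(gray)
            ious.append(_iou(make_foreground_mask(gray, t.threshold).mask,
                             sample.true_mask))
            ids.append(image_id)
            colors.append(color)
            store.add(descs)
            latent.append(sample.latent_freshness)
            scores.append(sample.panel_scores)
        table = PanelTable(np.stack(scores), image_ids=list(ids)) if scores else None
        mean_iou = float(np.mean(ious)) if ious else None
        return ids, np.asarray(colors), store, table, mean_iou, np.asarray(latent)

    if cfg.images_dir is None:
        raise ConfigError("RunConfig needs either synth or images_dir")
    img_dir = Path(cfg.images_dir)
    paths = sorted(p for p in img_dir.iterdir()
                   if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
    if not paths:
        raise PipelineError(f"extract stage: no images found in {img_dir}")
    for i, p in enumerate(paths):
        image_id, color, descs = feat.process_image(
            LeafImage.from_file(str(p), id=p.stem), i)
        ids.append(image_id)
        colors.append(color)
        store.add(descs)
    return ids, np.asarray(colors), store, None, None, None


def _load_panel_table(cfg: RunConfig, ids: list[str],
                      table: PanelTable | None) -> PanelTable:
    if table is not None:
        return table
    if cfg.scores_path is None or not Path(cfg.scores_path).exists():
        raise PipelineError(
            f"labels stage: panel score table not found at {cfg.scores_path!r}")
    table = PanelTable.read_tsv(cfg.scores_path)
    order = {iid: i for i, iid in enumerate(table.image_ids)}
    missing = [iid for iid in ids if iid not in order]
    if missing:
        raise PipelineError(
            f"labels stage: no panel scores for image id(s) {missing[:5]}")
    rows = [order[iid] for iid in ids]
    return PanelTable(table.scores[rows], image_ids=list(ids),
                      panel_ids=table.panel_ids)


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline and write all artifacts to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.content_hash()

    # -- stage 1: extraction (cached by config hash) ------------------------
    cache = out / "extraction.npz"
    manifest_path = out / "manifest.json"
    cached_ok = False
    if cache.exists() and manifest_path.exists():
        try:
            prev = json.loads(manifest_path.read_text())
            cached_ok = prev.get("config_hash") == chash
        except (json.JSONDecodeError, OSError):
            cached_ok = False
    if cached_ok:
        ids, colors, store, table, mean_iou, latent = _load_extraction(cache, cfg)
    else:
        ids, colors, store, table, mean_iou, latent = _extract_stage(cfg)
        _save_extraction(cache, ids, colors, store, table, mean_iou, latent)

    if len(ids) == 0:
        raise PipelineError("extract stage: produced zero images")

    # -- stage 2: labels and panel statistics -------------------------------
    table = _load_panel_table(cfg, ids, table)
    labels = aggregate_true_labels(table)

    # -- stage 3: split, vocabulary (train only), encode, train, evaluate ---
    split = classify.stratified_split(labels.label4, cfg.test_fraction,
                                      seed=cfg.split_seed, image_ids=ids)
    pooled = [store.pooled(c, split.train_idx) for c in range(_N_CH)]
    vocabs = build_vocabulary(pooled, k=cfg.k, km_seed=cfg.km_seed,
                              max_train_descriptors=cfg.max_train_descriptors)
    local = np.asarray([
        np.concatenate([encode_bow(store.get(i, c), vocabs[c])
                        for c in range(_N_CH)])
        for i in range(len(ids))], dtype=float)
    X = np.hstack([colors, local])
    features = pd.DataFrame(X, columns=list(classify.FEATURE_NAMES))
    features.insert(0, "image_id", ids)

    scaler = classify.fit_standardizer(X[split.train_idx])
    Xtr = classify.apply_standardizer(scaler, X[split.train_idx])
    Xte = classify.apply_standardizer(scaler, X[split.test_idx])
    ytr = labels.label4[split.train_idx]
    yte = labels.label4[split.test_idx]

    svm = classify.train_svm(Xtr, ytr)
    ann = classify.train_ann(Xtr, ytr, seed=cfg.ann_seed)
    svm_report = classify.evaluate(svm, Xte, yte, model_tag="svm")
    ann_report = classify.evaluate(ann, Xte, yte, model_tag="ann")
    cv = classify.cross_validate(X[split.train_idx], ytr, "svm",
                                 folds=cfg.cv_folds, seed=cfg.split_seed)

    # -- panel comparison ---------------------------------------------------
    pstats = panel_stats_report(table, features=features.drop(columns="image_id"))
    comparison = {}
    for level in cfg.levels:
        accs = panel_accuracy(table, labels, level, subset=split.test_idx)
        q = np.percentile(accs, [0, 25, 50, 75, 100])
        comparison[str(level)] = {
            "panel_accuracies": [float(a) for a in accs],
            "panel_min": float(q[0]), "panel_q1": float(q[1]),
            "panel_median": float(q[2]), "panel_q3": float(q[3]),
            "panel_max": float(q[4]),
            "svm": svm_report.overall_accuracy[level],
            "ann": ann_report.overall_accuracy[level],
        }

    report = {
        "config_hash": chash,
        "config": cfg.to_dict(),
        "n_images": len(ids),
        "n_train": int(split.train_idx.size),
        "n_test": int(split.test_idx.size),
        "mean_mask_iou": mean_iou,
        "cv": {"mean_accuracy": cv.best_score, "n_folds": cv.n_folds,
               "fold_scores": cv.fold_scores[0]},
        "models": {"svm": svm_report.to_dict(), "ann": ann_report.to_dict()},
        "panel_stats": pstats,
        "panel_vs_model": comparison,
    }

    # -- artifacts ----------------------------------------------------------
    features.to_csv(out / "features.tsv", sep="\t", index=False)
    labels_df = pd.DataFrame({
        "image_id": ids, "mean_score": labels.mean_score,
        "label4": labels.label4, "label3": labels.label3,
        "label2": labels.label2,
        "split": ["test" if i in set(split.test_idx) else "train"
                  for i in range(len(ids))],
    })
    labels_df.to_csv(out / "labels.tsv", sep="\t", index=False)
    (out / "vocabularies.json").write_text(json.dumps(
        {"schema": 1, "vocabularies": [v.to_dict() for v in vocabs]}))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    manifest_path.write_text(json.dumps({
        "config_hash": chash, "config": cfg.to_dict(),
        "artifacts": ["features.tsv", "labels.tsv", "vocabularies.json",
                      "report.json", "extraction.npz"],
    }, indent=2, default=str))

    return RunResult(report=report, features=features, panel_table=table,
                     labels=labels, split=split, vocabularies=vocabs,
                     svm_report=svm_report, ann_report=ann_report, X=X,
                     mean_iou=mean_iou, latent=latent)


def _save_extraction(path: Path, ids, colors, store: _DescriptorStore,
                     table, mean_iou, latent) -> None:
    arrays = {
        "ids": np.asarray(ids, dtype=object).astype(str),
        "colors": colors,
        "counts": np.array([[store.packed[c][i].shape[0]
                             for c in range(_N_CH)]
                            for i in range(store.n_images)], dtype=int),
    }
    for c in range(_N_CH):
        arrays[f"packed_{c}"] = (np.concatenate(store.packed[c])
                                 if store.packed[c]
                                 else np.zeros((0, 32), np.uint8))
    if table is not None:
        arrays["scores"] = table.scores
    if mean_iou is not None:
        arrays["mean_iou"] = np.array(mean_iou)
    if latent is not None:
        arrays["latent"] = latent
    np.savez_compressed(path, **arrays)


def _load_extraction(path: Path, cfg: RunConfig):
    z = np.load(path, allow_pickle=False)
    ids = [str(s) for s in z["ids"]]
    counts = z["counts"]
    store = _DescriptorStore()
    offsets = np.zeros(_N_CH, dtype=int)
    for i in range(len(ids)):
        descs = []
        for c in range(_N_CH):
            k = int(counts[i, c])
            p = z[f"packed_{c}"][offsets[c]:offsets[c] + k]
            offsets[c] += k
            descs.append(np.unpackbits(p, axis=1)[:, :DESCRIPTOR_BITS]
                         if k else np.zeros((0, DESCRIPTOR_BITS), np.uint8))
        store.add(descs)
    table = PanelTable(z["scores"], image_ids=list(ids)) if "scores" in z else None
    mean_iou = float(z["mean_iou"]) if "mean_iou" in z else None
    latent = z["latent"] if "latent" in z else None
    return ids, z["colors"], store, table, mean_iou, latent
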