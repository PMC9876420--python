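"""Negative sampling, leakage-safe cross-validation, and the metric suite.

Known drug–target interactions are the positive class; an equal number of
negatives is drawn uniformly from the unobserved drug–target pairs.  The
labeled set is partitioned into five folds: each fold holds out a disjoint
20% test split, and the remaining 80% is divided 7:1 into train:validation
(so the overall ratio is 7:1:2), stratified by label.

Within every fold the test interactions are removed from the graph before
meta-path walks are generated — walk sentences can therefore never leak a
test edge into the structure embeddings — and the train/test pair sets are
asserted disjoint.  Metrics: accuracy, precision, sensitivity, F1, Matthews
correlation, and ROC-AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data import DTIDataset
from .fusion import assemble_pair, predict_ensemble, train_ensemble
from .hetnet import mask_edges
from .pipeline import PipelineConfig, build_store, sequence_features, similarity_features

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("Acc", "Prec", "Sen", "F1", "MCC", "AUC")


def sample_negatives(
    positives: Sequence[tuple[str, str]],
    drugs: Sequence[str],
    targets: Sequence[str],
    n: int | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniform sample of n unobserved (drug, target) pairs, disjoint from positives."""
    pos = set(map(tuple, positives))
    if n is None:
        n = len(pos)
    candidates = [
        (d, t) for d in sorted(drugs) for t in sorted(targets) if (d, t) not in pos
    ]
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} candidate negative pairs available, need {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]


@dataclass
class FoldSplit:
    """Index sets of one cross-validation fold (into the labeled pair list)."""

    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def make_folds(
    labels: Sequence[int], k: int = 5, ratio: tuple[int, int, int] = (7, 1, 2), seed: int = 0
) -> list[FoldSplit]:
    """Stratified k-fold splits at a train:validation:test ratio.

    Each pair lands in the test split of exactly one fold; the remaining
    pairs are split train:validation at ratio[0]:ratio[1] per fold.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) < 2 * k:
        raise ValueError(f"need at least {2 * k} pairs for {k} folds")
    if min(np.bincount(y, minlength=2)) < k:
        raise ValueError("too few pairs in one class to stratify the folds")
    r_train, r_val, r_test = ratio
    if r_test / sum(ratio) != 1 / k:
        logger.warning(
            "make_folds: test share %s differs from 1/k; using k disjoint test folds",
            r_test / sum(ratio),
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for f, (rest_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        val_share = r_val / (r_train + r_val)
        train_idx, val_idx = train_test_split(
            rest_idx,
            test_size=val_share,
            stratify=y[rest_idx],
            random_state=seed * 1000 + f,
        )
        folds.append(
            FoldSplit(
                fold=f,
                train_idx=np.sort(train_idx),
                val_idx=np.sort(val_idx),
                test_idx=np.sort(test_idx),
            )
        )
    return folds


def confusion_counts(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with predictions = score >= threshold."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(s):
        raise ValueError("labels and scores differ in length")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return tp, tn, fp, fn


@dataclass
class MetricsBundle:
    """Confusion counts plus the six evaluation criteria."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    prec: float
    sen: float
    f1: float
    mcc: float
    auc: float | None = None

    def as_row(self) -> dict[str, float]:
        return {
            "Acc": self.acc,
            "Prec": self.prec,
            "Sen": self.sen,
            "F1": self.f1,
            "MCC": self.mcc,
            "AUC": self.auc if self.auc is not None else float("nan"),
        }


def compute_metrics(counts: tuple[int, int, int, int]) -> MetricsBundle:
    """Accuracy, precision, sensitivity, F1 and MCC from confusion counts.

    Conventions for degenerate denominators (documented, not errors):
    precision and sensitivity are 0 when undefined, F1 is 0 when
    precision + sensitivity = 0, and MCC is 0 when its denominator is 0.
    """
    tp, tn, fp, fn = counts
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("negative confusion counts")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("no evaluated pairs")
    acc = (tp + tn) / total
    prec = tp / (tp + fp) if tp + fp else 0.0
    sen = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * sen / (prec + sen) if prec + sen else 0.0
    denom = math.sqrt((tp + fp) * (tn + fn) * (tn + fp) * (tp + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return MetricsBundle(tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, prec=prec, sen=sen, f1=f1, mcc=mcc)


def f1_score(prec: float, sen: float) -> float:
    """Harmonic mean of precision and sensitivity."""
    return 2 * prec * sen / (prec + sen) if prec + sen else 0.0


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (rank/Mann–Whitney form)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: single-class labels")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class CVReport:
    """Per-fold metrics with mean ± sample standard deviation."""

    folds: list[MetricsBundle]
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [m.as_row() for m in self.folds]
        df = pd.DataFrame(rows, index=[f"{i + 1}" for i in range(len(rows))])
        df.index.name = "Fold"
        return df

    def mean(self, metric: str) -> float:
        return float(self.to_frame()[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.to_frame()[metric].std(ddof=1))

    def summary_frame(self) -> pd.DataFrame:
        df = self.to_frame()
        avg = df.mean()
        sd = df.std(ddof=1)
        out = df.copy().astype(object)
        out.loc["Average"] = [
            f"{avg[c]:.4f} ± {sd[c]:.4f}" for c in df.columns
        ]
        return out

    def write_csv(self, path) -> None:
        self.summary_frame().to_csv(path)


def _leakage_audit(corpus, masked_pairs: set[frozenset]) -> None:
    """Assert no masked drug-target pair appears as consecutive walk tokens."""
    if corpus is None or not masked_pairs:
        return
    for walk in corpus.walks:
        toks = walk.tokens
        for u, v in zip(toks, toks[1:]):
            pair = frozenset((u, v))
            if pair in masked_pairs:
                raise AssertionError(
                    f"leakage: masked pair {sorted(pair)} appears in a walk"
                )


def _center_scale(train_x: np.ndarray, all_x: np.ndarray) -> np.ndarray:
    """Center on the train mean; scale by the mean train row norm.

    Scaling whole branches (rather than per-feature z-scores) equalizes the
    branches' input magnitudes without inflating near-constant feature
    dimensions, preserving each modality's covariance shape.
    """
    mu = train_x.mean(axis=0)
    scale = np.linalg.norm(train_x - mu, axis=1).mean()
    return (all_x - mu) / max(scale, 1e-12)


def cross_validate(
    dataset: DTIDataset,
    config: PipelineConfig,
    seed: int = 0,
    negatives: list[tuple[str, str]] | None = None,
) -> CVReport:
    """Leakage-safe k-fold cross-validation of the full pipeline.

    Negative pairs are sampled once for the dataset (unless supplied), folds
    are stratified, and for every fold the test interactions are masked from
    the graph before walk generation.  Fold-independent modalities (sequence,
    similarity) are computed once and shared across folds.
    """
    positives = dataset.positives
    if not positives:
        raise ValueError("dataset has no positive interactions")
    if negatives is None:
        negatives = sample_negatives(
            positives, dataset.drugs, dataset.targets, n=len(positives), seed=seed
        )
    pairs: list[tuple[str, str]] = list(positives) + list(negatives)
    labels = np.array([1] * len(positives) + [0] * len(negatives))

    folds = make_folds(labels, k=config.n_folds, ratio=config.split_ratio, seed=seed)

    fixed: dict[str, dict[str, np.ndarray]] = {}
    if "sequence" in config.modalities:
        fixed["sequence"] = sequence_features(dataset, config, seed=seed)
    if "similarity" in config.modalities:
        fixed["similarity"] = similarity_features(dataset, config)

    results: list[MetricsBundle] = []
    for split in folds:
        test_pairs = [pairs[i] for i in split.test_idx]
        train_pairs = [pairs[i] for i in split.train_idx]
        val_pairs = [pairs[i] for i in split.val_idx]
        # train/validation must never contain a test pair
        overlap = (set(train_pairs) | set(val_pairs)) & set(test_pairs)
        if overlap:
            raise AssertionError(f"fold {split.fold}: split overlap {sorted(overlap)[:3]}")

        test_pos = [pairs[i] for i in split.test_idx if labels[i] == 1]
        masked_graph = mask_edges(dataset.graph, test_pos)
        masked_set = {frozenset(p) for p in test_pos}
        for pair in masked_set:
            d, t = sorted(pair)
            if masked_graph.has_edge(d, t):
                raise AssertionError(f"fold {split.fold}: masked edge {d}-{t} survived")

        store, corpus = build_store(
            dataset,
            config,
            graph=masked_graph,
            seed=seed * 100 + split.fold,
            fixed=fixed,
        )
        _leakage_audit(corpus, masked_set)

        mods = config.modalities
        branch = [
            np.vstack(cols)
            for cols in zip(*(assemble_pair(d, t, store, mods) for d, t in pairs))
        ]
        branch = [
            _center_scale(x[split.train_idx], x) for x in branch
        ]
        fusion_cfg = replace(config.fusion, seed=config.fusion.seed + seed * 100 + split.fold)
        models = train_ensemble(
            fusion_cfg,
            [x[split.train_idx] for x in branch],
            labels[split.train_idx],
            [x[split.val_idx] for x in branch],
            labels[split.val_idx],
        )
        scores = predict_ensemble(models, [x[split.test_idx] for x in branch])
        y_test = labels[split.test_idx]
        bundle = compute_metrics(confusion_counts(y_test, scores))
        bundle.auc = roc_auc(y_test, scores)
        results.append(bundle)
        logger.info(
            "fold %d: Acc=%.4f AUC=%.4f (best epoch %s)",
            split.fold,
            bundle.acc,
            bundle.auc,
            models[0].best_epoch,
        )
    provenance = {
        "seed": seed,
        "n_positives": len(positives),
        "n_negatives": len(negatives),
        "modalities": list(config.modalities),
        "n_folds": config.n_folds,
        "ratio": list(config.split_ratio),
    }
    return CVReport(folds=results, provenance=provenance)
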