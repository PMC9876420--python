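"""Fit-once predictor: the full pipeline wrapped for scoring and ranking.

Unlike cross-validation (which masks test interactions fold by fold), a
deployed predictor trains on all known interactions: balanced negatives are
sampled, a stratified train/validation split (7:1) drives early stopping,
and the fusion network is fit on features built from the complete graph.
The fitted object scores arbitrary drug–target pairs and ranks candidate
drugs for a protein, as in a drug-repositioning screen.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .data import DTIDataset
from .evaluation import sample_negatives
from .fusion import (
    JointModel,
    ModalityStore,
    assemble_pair,
    predict_ensemble,
    train_ensemble,
)
from .pipeline import PipelineConfig, build_store

logger = logging.getLogger(__name__)


@dataclass
class Predictor:
    """Trained fusion models plus the feature store and branch scalers."""

    models: list[JointModel]
    store: ModalityStore
    scalers: list[tuple[np.ndarray, float]]  # per-branch (mean, row-norm scale)
    config: PipelineConfig
    seed: int

    @property
    def model(self) -> JointModel:
        return self.models[0]

    def _branches(self, pairs) -> list[np.ndarray]:
        mods = self.config.modalities
        cols = zip(*(assemble_pair(d, t, self.store, mods) for d, t in pairs))
        return [
            (np.vstack(c) - mu) / sd for c, (mu, sd) in zip(cols, self.scalers)
        ]

    def score(self, pairs) -> np.ndarray:
        """Interaction probability per (drug, target) pair, order-preserving."""
        if not pairs:
            raise ValueError("no pairs to score")
        return predict_ensemble(self.models, self._branches(list(pairs)))

    def rank(self, target: str, drugs=None, top: int | None = None):
        """Candidate drugs for *target*, descending by score (ties by id)."""
        if drugs is None:
            drugs = sorted(self.store.vectors[self.config.modalities[0]])
            drugs = [d for d in drugs if d.startswith("dr:")]
        if not drugs:
            raise ValueError("empty candidate drug list")
        scores = self.score([(d, target) for d in drugs])
        ranked = sorted(zip(drugs, scores), key=lambda t: (-t[1], t[0]))
        ranked = [(d, float(s)) for d, s in ranked]
        return ranked[:top] if top else ranked

    def save_weights(self, path) -> None:
        """First ensemble member's weights + branch scalers.

        Features are rebuilt from the dataset (same seed) rather than stored;
        the checkpoint exists for provenance and warm restarts.
        """
        np.savez(
            path,
            __meta__=np.frombuffer(
                json.dumps({"seed": self.seed}).encode(), dtype=np.uint8
            ),
            __dims__=np.asarray(self.model.input_dims),
            **{f"p{i}": p for i, p in enumerate(self.model.parameters())},
            **{f"mu{i}": mu for i, (mu, _) in enumerate(self.scalers)},
            **{f"sd{i}": sd for i, (_, sd) in enumerate(self.scalers)},
        )


def fit_predictor(
    dataset: DTIDataset, config: PipelineConfig, seed: int = 0
) -> Predictor:
    """Train the fusion model on the full dataset and return a Predictor."""
    positives = dataset.positives
    if not positives:
        raise ValueError("dataset has no positive interactions")
    negatives = sample_negatives(
        positives, dataset.drugs, dataset.targets, n=len(positives), seed=seed
    )
    pairs = list(positives) + list(negatives)
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    store, _ = build_store(dataset, config, graph=dataset.graph, seed=seed)

    mods = config.modalities
    branch = [
        np.vstack(c) for c in zip(*(assemble_pair(d, t, store, mods) for d, t in pairs))
    ]
    idx = np.arange(len(pairs))
    r_train, r_val, _ = config.split_ratio
    train_idx, val_idx = train_test_split(
        idx, test_size=r_val / (r_train + r_val), stratify=labels, random_state=seed
    )
    scalers = []
    scaled = []
    for x in branch:
        mu = x[train_idx].mean(axis=0)
        s = float(np.linalg.norm(x[train_idx] - mu, axis=1).mean())
        s = max(s, 1e-12)
        scalers.append((mu, s))
        scaled.append((x - mu) / s)
    from dataclasses import replace

    fusion_cfg = replace(config.fusion, seed=config.fusion.seed + seed)
    models = train_ensemble(
        fusion_cfg,
        [x[train_idx] for x in scaled],
        labels[train_idx],
        [x[val_idx] for x in scaled],
        labels[val_idx],
    )
    logger.info("fit_predictor: best epoch %s", models[0].best_epoch)
    return Predictor(models=models, store=store, scalers=scalers, config=config, seed=seed)
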