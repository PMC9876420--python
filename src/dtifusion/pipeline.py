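"""Modality feature builders tying the stages together.

Three modalities per entity:

* **sequence** — drugs: CBOW symbol embeddings of the SMILES corpus, mean-
  pooled per drug (343-dim, window 5); targets: conjoint-triad SVD vectors
  (343-dim).
* **structure** — 64-dim CBOW embeddings of node ids from the meta-path walk
  corpus.  This is the only fold-dependent modality: walks are generated on
  a graph with the test-fold interactions masked out.
* **similarity** — each entity's row of its similarity matrix (Jaccard over
  drug substructures; normalized Smith–Waterman over proteins), loaded from
  file when precomputed matrices are supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import proteins as prot
from .data import DTIDataset
from .embedding import EmbeddingTable, TokenCorpus, embed_mean, tokenize_smiles, train_cbow
from .fusion import FusionConfig, ModalityStore
from .hetnet import DEFAULT_SCHEMAS, HeteroGraph, WalkCorpus, build_corpus
from .similarity import drug_similarity, protein_similarity

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters with the framework's standard constants.

    Defaults: 343-dim SMILES/protein vectors, window 5; 64-dim meta-path
    embeddings from 64-instance walks with 500 restart walks per schema;
    dropout-0.3 fusion network; five folds at a 7:1:2 train:validation:test
    ratio with balanced negative sampling.
    """

    smiles_dim: int = 343
    smiles_window: int = 5
    smiles_mode: str = "char"
    walk_dim: int = 64
    walk_window: int = 10
    n_instances: int = 64
    restarts: int = 500
    cbow_epochs: int = 3
    protein_partition: str = "default"
    protein_method: str = "svd"
    substructure_method: str = "auto"
    fusion: FusionConfig = field(default_factory=FusionConfig)
    n_folds: int = 5
    split_ratio: tuple[int, int, int] = (7, 1, 2)

    @property
    def modalities(self) -> tuple[str, ...]:
        return self.fusion.modalities

    def with_modalities(self, modalities) -> "PipelineConfig":
        return replace(self, fusion=replace(self.fusion, modalities=tuple(modalities)))


def benchmark_config(**overrides) -> PipelineConfig:
    """Configuration sized for the synthetic benchmark (minutes on one CPU).

    Restarts are reduced to 50 per schema — the fixture graph has ~90 nodes,
    so 50 restarts on top of full coverage already revisit every node many
    times.  The fusion network keeps batch size 32 and adds the small-sample
    regularization the fixture needs: decoupled weight decay, patience 50,
    and a 3-model score-averaged ensemble per fold.
    """
    overrides.setdefault("restarts", 50)
    overrides.setdefault(
        "fusion", FusionConfig(weight_decay=1.0, patience=50, n_models=3)
    )
    return PipelineConfig(**overrides)


def sequence_features(
    dataset: DTIDataset, config: PipelineConfig, seed: int = 0
) -> dict[str, np.ndarray]:
    """Sequence-modality vectors: SMILES CBOW means + conjoint-triad SVD."""
    out: dict[str, np.ndarray] = {}
    if dataset.smiles:
        sentences = {
            d: tokenize_smiles(s, mode=config.smiles_mode)
            for d, s in dataset.smiles.items()
        }
        corpus = TokenCorpus.from_sentences(sentences.values())
        table = train_cbow(
            corpus,
            dim=config.smiles_dim,
            window=config.smiles_window,
            epochs=config.cbow_epochs,
            seed=seed,
        )
        for drug, toks in sentences.items():
            out[drug] = embed_mean(toks, table)
    for pid, seq in dataset.proteins.items():
        out[pid] = prot.protein_vector(
            seq, partition=config.protein_partition, method=config.protein_method
        )
    return out


def structure_features(
    graph: HeteroGraph, config: PipelineConfig, seed: int = 0
) -> tuple[dict[str, np.ndarray], WalkCorpus]:
    """Meta-path CBOW node embeddings from walks on *graph*.

    Nodes never visited by any walk (isolated under every schema) receive a
    zero vector so downstream assembly never fails.  Returns the corpus too
    so callers can audit the walks (leakage checks).
    """
    corpus = build_corpus(
        graph,
        schemas=DEFAULT_SCHEMAS,
        n_instances=config.n_instances,
        restarts=config.restarts,
        seed=seed,
    )
    token_corpus = TokenCorpus.from_sentences(corpus.sentences())
    table = train_cbow(
        token_corpus,
        dim=config.walk_dim,
        window=config.walk_window,
        epochs=config.cbow_epochs,
        seed=seed,
    )
    out: dict[str, np.ndarray] = {}
    n_missing = 0
    for node in graph.nodes:
        if node in table:
            out[node] = table[node]
        else:
            out[node] = np.zeros(config.walk_dim)
            n_missing += 1
    if n_missing:
        logger.warning("structure_features: %d nodes unseen by walks (zero vectors)", n_missing)
    return out, corpus


def similarity_features(
    dataset: DTIDataset, config: PipelineConfig
) -> dict[str, np.ndarray]:
    """Similarity-modality vectors: rows of the two similarity matrices."""
    out: dict[str, np.ndarray] = {}
    dsim = dataset.drug_similarity
    if dsim is None and dataset.smiles:
        dsim = drug_similarity(dataset.smiles, method=config.substructure_method)
    if dsim is not None:
        for drug in dsim.ids:
            out[drug] = dsim.row(drug)
    psim = dataset.protein_similarity
    if psim is None and dataset.proteins:
        psim = protein_similarity(dataset.proteins)
    if psim is not None:
        for pid in psim.ids:
            out[pid] = psim.row(pid)
    return out


def build_store(
    dataset: DTIDataset,
    config: PipelineConfig,
    graph: HeteroGraph | None = None,
    seed: int = 0,
    fixed: dict[str, dict[str, np.ndarray]] | None = None,
) -> tuple[ModalityStore, WalkCorpus | None]:
    """Assemble the enabled modalities into a ModalityStore.

    ``graph`` is the (possibly edge-masked) graph used for structure walks;
    ``fixed`` optionally carries precomputed fold-independent modalities
    (sequence / similarity) so cross-validation does not recompute them.
    """
    store = ModalityStore()
    corpus = None
    fixed = fixed or {}
    for modality in config.modalities:
        if modality in fixed:
            store.add(modality, fixed[modality])
        elif modality == "sequence":
            store.add(modality, sequence_features(dataset, config, seed=seed))
        elif modality == "similarity":
            store.add(modality, similarity_features(dataset, config))
        elif modality == "structure":
            vectors, corpus = structure_features(
                graph if graph is not None else dataset.graph, config, seed=seed
            )
            store.add(modality, vectors)
    return store, corpus
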