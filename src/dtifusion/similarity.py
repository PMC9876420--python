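"""Similarity-modality features.

Drugs are compared by the Jaccard index over discrete substructure sets
(hashed circular fingerprints when RDKit can parse the SMILES, character
n-grams otherwise, or a precomputed similarity matrix loaded from file).
Proteins are compared by normalized Smith–Waterman local alignment:

    S_g(i, j) = SW(p_i, p_j) / (sqrt(SW(p_i, p_i)) * sqrt(SW(p_j, p_j)))

which is symmetric, 1 on the diagonal, and bounded by [0, 1] in practice.
Each entity's similarity feature vector is its row of the similarity matrix,
so the feature dimension equals the number of entities in the dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)


@dataclass
class ScoringScheme:
    """Smith–Waterman scoring: substitution source plus affine gap penalties.

    ``matrix`` names a Biopython substitution matrix (e.g. ``"BLOSUM62"``);
    when None, a simple match/mismatch scheme is used.  Gap penalties are
    positive costs: opening a gap costs ``gap_open``, each further gapped
    position costs ``gap_extend``.
    """

    matrix: str | None = "BLOSUM62"
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        if self.matrix is not None:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCHEME = ScoringScheme()


def smith_waterman(p: str, q: str, scoring: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Optimal local-alignment score; 0 when no positive-scoring alignment exists."""
    if not p or not q:
        raise ValueError("sequences must be nonempty")
    aligner = scoring.aligner()
    if scoring.matrix is not None:
        alphabet = set(str(aligner.substitution_matrix.alphabet))
        bad = (set(p) | set(q)) - alphabet
        if bad:
            raise ValueError(f"residues {sorted(bad)} absent from {scoring.matrix}")
    try:
        return float(aligner.score(p, q))
    except ValueError as exc:  # residue outside the substitution table
        raise ValueError(f"alignment failed for pair: {exc}") from exc


def normalized_sw(p: str, q: str, scoring: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Self-score-normalized Smith–Waterman similarity in [0, 1]."""
    spp = smith_waterman(p, p, scoring)
    sqq = smith_waterman(q, q, scoring)
    if spp <= 0 or sqq <= 0:
        raise ValueError("zero self-alignment score; cannot normalize")
    return smith_waterman(p, q, scoring) / (np.sqrt(spp) * np.sqrt(sqq))


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """|a ∩ b| / |a ∪ b| over substructure sets."""
    if not a or not b:
        raise ValueError("substructure sets must be nonempty")
    return len(a & b) / len(a | b)


def _morgan_set(smiles: str, radius: int = 2, n_bits: int = 2048) -> frozenset | None:
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import rdFingerprintGenerator

        RDLogger.DisableLog("rdApp.*")
    except ImportError:
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return frozenset(fp.GetOnBits())


def _ngram_set(smiles: str, n: int = 3) -> frozenset:
    if len(smiles) < n:
        return frozenset({smiles})
    return frozenset(smiles[i : i + n] for i in range(len(smiles) - n + 1))


def substructure_sets(
    smiles: Mapping[str, str], method: str = "auto"
) -> dict[str, frozenset]:
    """Discrete substructure sets per drug.

    ``morgan`` hashes circular environments (radius 2, 2048 bits) via RDKit;
    ``ngram`` falls back to character 3-grams of the SMILES string; ``auto``
    uses Morgan fingerprints when every SMILES parses, n-grams otherwise, so
    all drugs in a dataset share one feature space.
    """
    if method in ("auto", "morgan"):
        sets = {d: _morgan_set(s) for d, s in smiles.items()}
        if all(v is not None for v in sets.values()):
            return {d: v for d, v in sets.items()}  # type: ignore[misc]
        if method == "morgan":
            bad = sorted(d for d, v in sets.items() if v is None)
            raise ValueError(f"unparseable SMILES (or RDKit missing) for {bad[:5]}")
        logger.info("substructure_sets: falling back to character n-grams")
    return {d: _ngram_set(s) for d, s in smiles.items()}


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with unit diagonal over ordered ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("similarity matrix diagonal is not 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise ValueError("similarity values outside [0, 1]")
        self.values = v
        self._index = {e: i for i, e in enumerate(self.ids)}

    def row(self, entity: str) -> np.ndarray:
        """The entity's feature vector: its row in the fixed id order."""
        return self.values[self._index[entity]].copy()

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )

    @classmethod
    def read_tsv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column ids differ")
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(dtype=float))


def build_similarity_matrix(
    entities: Mapping[str, object] | Sequence[str],
    scorer: Callable[[object, object], float],
    payload: Mapping[str, object] | None = None,
) -> SimilarityMatrix:
    """Pairwise similarity matrix; diagonal forced to exactly 1.

    ``entities`` maps id -> object to score (or is a list of ids with a
    separate ``payload`` map).  The scorer is called once per unordered pair;
    failures are re-raised naming the pair.
    """
    if payload is None:
        payload = dict(entities)  # type: ignore[arg-type]
        ids = sorted(payload)
    else:
        ids = list(entities)  # type: ignore[arg-type]
    if len(ids) < 2:
        raise ValueError("need at least two entities")
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = float(scorer(payload[ids[i]], payload[ids[j]]))
            except Exception as exc:
                raise RuntimeError(
                    f"similarity scorer failed on pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(ids=ids, values=values)


def drug_similarity(smiles: Mapping[str, str], method: str = "auto") -> SimilarityMatrix:
    """Jaccard substructure similarity matrix over all drugs."""
    sets = substructure_sets(smiles, method=method)
    return build_similarity_matrix(sets, jaccard)


def protein_similarity(
    sequences: Mapping[str, str], scoring: ScoringScheme = DEFAULT_SCHEME
) -> SimilarityMatrix:
    """Normalized Smith–Waterman similarity matrix over all proteins.

    Self-scores are computed once per protein rather than per pair.
    """
    ids = sorted(sequences)
    if len(ids) < 2:
        raise ValueError("need at least two proteins")
    self_scores = {}
    for pid in ids:
        s = smith_waterman(sequences[pid], sequences[pid], scoring)
        if s <= 0:
            raise ValueError(f"protein {pid}: zero self-alignment score")
        self_scores[pid] = np.sqrt(s)
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = smith_waterman(sequences[ids[i]], sequences[ids[j]], scoring)
            values[i, j] = values[j, i] = s / (self_scores[ids[i]] * self_scores[ids[j]])
    return SimilarityMatrix(ids=ids, values=values)
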