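"""Conjoint-triad protein encoding with SVD reduction.

The 20 amino acids are reduced to 7 physicochemical classes (grouped by
dipole moment and side-chain volume).  A protein of reduced length n is then
written as a sparse indicator matrix L of shape (343, n-2): column j carries
a single 1 in the row indexing the class triad at positions (j, j+1, j+2),
with row index c_j*49 + c_{j+1}*7 + c_{j+2}.  The 343-dimensional protein
vector is the leading left singular vector of L scaled by its singular
value — a rank-1 summary living in triad space whose norm equals the top
singular value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

#: Default 7-class partition: every one of the 20 standard amino acids
#: appears exactly once (class 2 is Y/M/T/S).
CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "DE", "RK", "C")

#: As-printed variant that writes class 2 as T/M/T/S (no Y).  Y is then an
#: unknown residue and is skipped.  Kept for comparability, not recommended.
CLASSES_LITERAL: tuple[str, ...] = ("AGV", "ILFP", "TMTS", "HNQW", "DE", "RK", "C")

AMBIGUOUS = set("BJXZUO")


def _class_map(partition: str) -> dict[str, int]:
    groups = CLASSES if partition == "default" else CLASSES_LITERAL
    if partition not in ("default", "literal"):
        raise ValueError(f"unknown partition {partition!r}")
    return {aa: i for i, group in enumerate(groups) for aa in group}


@dataclass
class ReducedSequence:
    """Per-residue class indices (0..6) after alphabet reduction."""

    classes: list[int]
    source_length: int
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.classes)


def reduce_alphabet(sequence: str, partition: str = "default") -> ReducedSequence:
    """Map each residue to its 7-class index; unknown residues are skipped.

    A sequence may reduce to fewer than 3 residues; it is the triad stage
    that rejects such sequences (no window of length 3 exists).
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    cmap = _class_map(partition)
    classes: list[int] = []
    skipped = 0
    for aa in sequence.upper():
        idx = cmap.get(aa)
        if idx is None:
            skipped += 1
            continue
        classes.append(idx)
    if skipped:
        logger.warning("reduce_alphabet: skipped %d unknown residues", skipped)
    return ReducedSequence(classes=classes, source_length=len(sequence), n_skipped=skipped)


def triad_index(c1: int, c2: int, c3: int) -> int:
    """Base-7 row index of a class triad; inverse of :func:`triad_classes`."""
    return c1 * 49 + c2 * 7 + c3


def triad_classes(index: int) -> tuple[int, int, int]:
    """Inverse of :func:`triad_index`."""
    if not 0 <= index < 343:
        raise ValueError("triad index out of range")
    return index // 49, (index // 7) % 7, index % 7


def triad_matrix(reduced: ReducedSequence, k: int = 3) -> sparse.csc_matrix:
    """Sparse indicator matrix of shape (7**k, n - k + 1); one 1 per column."""
    if k != 3:
        raise ValueError("only k=3 (conjoint triads) is supported")
    n = len(reduced)
    if n < k:
        raise ValueError(f"reduced length {n} < k={k}")
    c = np.asarray(reduced.classes)
    rows = c[:-2] * 49 + c[1:-1] * 7 + c[2:]
    cols = np.arange(n - 2)
    data = np.ones(n - 2)
    return sparse.csc_matrix((data, (rows, cols)), shape=(343, n - 2))


def svd_vector(matrix: sparse.spmatrix) -> np.ndarray:
    """Leading left singular vector scaled by its singular value.

    The sign is fixed so the largest-magnitude component is positive, making
    the output deterministic.  The result has length 343 and Euclidean norm
    equal to the top singular value.
    """
    if matrix.nnz == 0:
        raise ValueError("zero matrix has no informative singular vector")
    # dense LAPACK SVD: deterministic even when the leading singular value is
    # degenerate (common for short sequences), where iterative solvers return
    # an arbitrary vector from the leading subspace
    u_full, s_full, _ = np.linalg.svd(matrix.toarray(), full_matrices=False)
    u, s = u_full[:, 0], s_full[0]
    pivot = np.argmax(np.abs(u))
    if u[pivot] < 0:
        u = -u
    return s * u


def triad_counts(reduced: ReducedSequence) -> np.ndarray:
    """Alternative featurizer: raw triad occurrence counts (row sums of L)."""
    m = triad_matrix(reduced)
    return np.asarray(m.sum(axis=1)).ravel()


def protein_vector(
    sequence: str, partition: str = "default", method: str = "svd"
) -> np.ndarray:
    """343-dim conjoint-triad vector of a protein sequence."""
    reduced = reduce_alphabet(sequence, partition=partition)
    if method == "svd":
        return svd_vector(triad_matrix(reduced))
    if method == "counts":
        return triad_counts(reduced)
    raise ValueError(f"unknown method {method!r}")
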