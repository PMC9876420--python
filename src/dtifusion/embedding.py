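"""CBOW token embeddings shared by SMILES corpora and meta-path walk corpora.

A continuous-bag-of-words model predicts a center token from the arithmetic
average of its context tokens' input vectors.  With context indices
``x_1..x_c`` inside a window of size ``c`` the hidden state is

    h = (1/c) * sum_k W_in[x_k]

and the loss for center token j is the full-softmax negative log-likelihood

    E = log sum_i exp(W_out_i . h) - W_out_j . h.

Full softmax is the default here (not negative sampling): vocabularies are a
few thousand node ids or a few dozen SMILES symbols, so the exact objective
is affordable and unambiguous.

The same trainer serves both corpora: SMILES sentences are symbol sequences
(dim 343, window 5 by convention downstream), walk sentences are node-id
sequences (dim 64).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_ATOMWISE_RE = re.compile(r"\[[^\]]*\]|Br|Cl|.")


def tokenize_smiles(smiles: str, mode: str = "char") -> list[str]:
    """Split a SMILES string into symbol tokens.

    ``char`` (default) emits one token per character.  ``atomwise`` keeps
    two-character element symbols (Cl, Br) and bracket atoms ``[...]`` as
    single tokens.
    """
    if not smiles:
        raise ValueError("cannot tokenize an empty SMILES string")
    if mode == "char":
        return list(smiles)
    if mode == "atomwise":
        return _ATOMWISE_RE.findall(smiles)
    raise ValueError(f"unknown tokenization mode {mode!r}")


@dataclass
class TokenCorpus:
    """Sentences of tokens plus a deterministic token -> index vocabulary."""

    sentences: list[list[str]]
    vocab: dict[str, int]

    @classmethod
    def from_sentences(cls, sentences: Iterable[Sequence[str]]) -> "TokenCorpus":
        sents = [list(s) for s in sentences]
        tokens = sorted({tok for s in sents for tok in s})
        if not tokens:
            raise ValueError("corpus has an empty vocabulary")
        return cls(sentences=sents, vocab={t: i for i, t in enumerate(tokens)})


@dataclass
class EmbeddingTable:
    """Token -> fixed-length vector map with its training metadata."""

    dim: int
    vectors: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for token in sorted(self.vectors):
                vals = " ".join(repr(float(x)) for x in self.vectors[token])
                fh.write(f"{token}\t{vals}\n")

    @classmethod
    def read_tsv(cls, path) -> "EmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        with open(path) as fh:
            for line in fh:
                token, vals = line.rstrip("\n").split("\t")
                vectors[token] = np.array([float(x) for x in vals.split()])
        if not vectors:
            raise ValueError(f"empty embedding table at {path}")
        dims = {v.shape[0] for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError("inconsistent vector lengths in embedding table")
        return cls(dim=dims.pop(), vectors=vectors)


def _context_pairs(
    encoded: list[np.ndarray], window: int, pad: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (padded context, center) training pairs of the corpus."""
    contexts: list[list[int]] = []
    centers: list[int] = []
    width = 2 * window
    for sent in encoded:
        n = len(sent)
        if n < 2:
            continue
        for t in range(n):
            lo, hi = max(0, t - window), min(n, t + window + 1)
            ctx = [int(sent[i]) for i in range(lo, hi) if i != t]
            if not ctx:
                continue
            contexts.append(ctx + [pad] * (width - len(ctx)))
            centers.append(int(sent[t]))
    if not centers:
        raise ValueError("corpus yields no training pairs (sentences too short)")
    return np.asarray(contexts, dtype=np.int64), np.asarray(centers, dtype=np.int64)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cbow_loss_and_grads(
    w_in: np.ndarray, w_out: np.ndarray, context: Sequence[int], center: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Single-example CBOW loss and exact gradients (reference path).

    Returns ``(loss, grad_w_in, grad_w_out)`` for input matrix ``w_in``
    (V x dim) and output matrix ``w_out`` (dim x V).  Used by the trainer's
    correctness checks; the batched trainer computes the same quantities
    vectorised.
    """
    context = np.asarray(context, dtype=np.int64)
    h = w_in[context].mean(axis=0)
    logits = h @ w_out
    p = _softmax(logits)
    loss = float(np.log(np.exp(logits - logits.max()).sum()) + logits.max() - logits[center])
    dlogits = p.copy()
    dlogits[center] -= 1.0
    grad_w_out = np.outer(h, dlogits)
    dh = w_out @ dlogits
    grad_w_in = np.zeros_like(w_in)
    np.add.at(grad_w_in, context, dh / len(context))
    return loss, grad_w_in, grad_w_out


def train_cbow(
    corpus: TokenCorpus,
    dim: int,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    learning_rate: float = 0.025,
    min_learning_rate: float = 1e-4,
    batch_size: int = 128,
) -> EmbeddingTable:
    """Train CBOW embeddings with full-softmax mini-batch gradient descent.

    Deterministic for a fixed seed (single-threaded NumPy).  The learning
    rate decays linearly from ``learning_rate`` to ``min_learning_rate``
    over the training run, following the usual word2vec schedule.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if window < 1:
        raise ValueError("window must be >= 1")
    if not corpus.sentences:
        raise ValueError("corpus is empty")
    vocab = corpus.vocab
    V = len(vocab)
    if V == 0:
        raise ValueError("vocabulary is empty")
    encoded = [
        np.array([vocab[t] for t in sent], dtype=np.int64) for sent in corpus.sentences
    ]
    contexts, centers = _context_pairs(encoded, window, pad=V)
    counts = (contexts != V).sum(axis=1)

    rng = np.random.default_rng(seed)
    w_in = (rng.random((V + 1, dim)) - 0.5) / dim  # row V is the padding row
    w_in[V] = 0.0
    w_out = np.zeros((dim, V))

    n_pairs = len(centers)
    n_batches = int(np.ceil(n_pairs / batch_size))
    total_steps = max(1, epochs * n_batches)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for b in range(n_batches):
            idx = order[b * batch_size : (b + 1) * batch_size]
            lr = learning_rate + (min_learning_rate - learning_rate) * (step / total_steps)
            step += 1
            ctx = contexts[idx]
            cnt = counts[idx].astype(float)
            h = w_in[ctx].sum(axis=1) / cnt[:, None]
            p = _softmax(h @ w_out)
            # summed (not averaged) batch gradient: each pair contributes a
            # full step at lr, matching sequential word2vec SGD magnitude
            dlogits = p
            dlogits[np.arange(len(idx)), centers[idx]] -= 1.0
            dh = dlogits @ w_out.T
            w_out -= lr * (h.T @ dlogits)
            # each (non-pad) context row of w_in receives dh / context-count
            contrib = np.repeat(-lr * dh / cnt[:, None], ctx.shape[1], axis=0)
            np.add.at(w_in, ctx.ravel(), contrib)
            w_in[V] = 0.0  # padding row must stay zero

    inv = {i: t for t, i in vocab.items()}
    vectors = {inv[i]: w_in[i].copy() for i in range(V)}
    meta = {"window": window, "epochs": epochs, "seed": seed, "lr": learning_rate}
    return EmbeddingTable(dim=dim, vectors=vectors, meta=meta)


def embed_mean(tokens: Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """Arithmetic mean of the tokens' vectors; OOV tokens skipped with warning."""
    known = [t for t in tokens if t in table]
    missing = len(tokens) - len(known)
    if missing:
        logger.warning("embed_mean: %d/%d tokens out of vocabulary", missing, len(tokens))
    if not known:
        raise ValueError("no in-vocabulary token to average")
    return np.mean([table[t] for t in known], axis=0)
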