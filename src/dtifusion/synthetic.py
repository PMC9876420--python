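"""Seeded synthetic benchmark: a tripartite network with planted signal.

Drugs, targets and diseases are assigned to latent blocks (communities).
Drug–target edges are drawn Bernoulli(p_in) within a block and
Bernoulli(p_out) across blocks, so block membership is the ground-truth
interaction signal; drug–drug and drug–disease edges are block-correlated
the same way, which makes meta-path walks informative.  SMILES-like strings
and protein sequences carry the same block signal as weak symbol-frequency
biases, so the sequence and similarity modalities are each independently
(weakly) predictive and every ablation arm is testable.

The strings are *not* chemically valid molecules; they are syntactically
well-formed token streams (balanced parentheses, matched ring digits) over a
small SMILES alphabet.  Everything is bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DTIDataset
from .hetnet import HeteroGraph, build_graph

#: atoms the SMILES-like generator emits (ring digits / parens added on top)
SMILES_ATOMS = ("C", "N", "O", "S", "c", "n")
SMILES_ALPHABET = set(SMILES_ATOMS) | {"(", ")", "=", "1", "2"}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "DE", "RK", "C")

#: weight multiplier for a block's preferred symbol/class (weak signal)
_BIAS = 3.0


@dataclass
class SyntheticSpec:
    """Study conditions of the synthetic benchmark."""

    n_drugs: int = 40
    n_targets: int = 30
    n_diseases: int = 20
    n_blocks: int = 4
    p_in: float = 0.3  # within-block drug-target edge probability
    p_out: float = 0.01  # cross-block drug-target edge probability
    ddi_in: float = 0.3
    ddi_out: float = 0.02
    dda_in: float = 0.3
    dda_out: float = 0.02
    smiles_length: tuple[int, int] = (20, 60)
    protein_length: tuple[int, int] = (60, 120)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_targets, self.n_diseases, self.n_blocks) < 1:
            raise ValueError("entity and block counts must be positive")
        for lo, hi in (self.smiles_length, self.protein_length):
            if not 1 <= lo <= hi:
                raise ValueError("invalid length range")
        if self.protein_length[0] < 3:
            raise ValueError("protein min length must be >= 3")
        for p_hi, p_lo in ((self.p_in, self.p_out), (self.ddi_in, self.ddi_out),
                           (self.dda_in, self.dda_out)):
            if not 0 <= p_lo <= p_hi <= 1:
                raise ValueError("edge probabilities need 0 <= p_out <= p_in <= 1")


def _block_labels(n: int, prefix: str, n_blocks: int) -> dict[str, int]:
    # cyclic assignment: deterministic and balanced
    return {f"{prefix}{i}": i % n_blocks for i in range(n)}


def gen_hetnet(spec: SyntheticSpec) -> tuple[HeteroGraph, dict[str, int]]:
    """Planted-block tripartite graph plus the ground-truth block labels."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    drugs = _block_labels(spec.n_drugs, "dr:", spec.n_blocks)
    targets = _block_labels(spec.n_targets, "t:", spec.n_blocks)
    diseases = _block_labels(spec.n_diseases, "di:", spec.n_blocks)

    n_in = sum(
        1 for bd in drugs.values() for bt in targets.values() if bd == bt
    )
    n_total = spec.n_drugs * spec.n_targets
    expected = n_in * spec.p_in + (n_total - n_in) * spec.p_out
    if expected < 10:
        raise ValueError(
            f"expected {expected:.1f} positive interactions (< 10): fixture untrainable"
        )

    records: list[tuple[str, str, str]] = []

    def bernoulli_edges(a_labels, b_labels, p_same, p_diff, etype):
        a_ids, b_ids = sorted(a_labels), sorted(b_labels)
        for i, u in enumerate(a_ids):
            for v in b_ids if etype != "DDI" else b_ids[i + 1 :]:
                if u == v:
                    continue
                p = p_same if a_labels[u] == b_labels[v] else p_diff
                if rng.random() < p:
                    records.append((u, v, etype))

    bernoulli_edges(drugs, targets, spec.p_in, spec.p_out, "DTI")
    bernoulli_edges(drugs, drugs, spec.ddi_in, spec.ddi_out, "DDI")
    bernoulli_edges(drugs, diseases, spec.dda_in, spec.dda_out, "DDA")

    graph = build_graph(records)
    for node in (*drugs, *targets, *diseases):  # isolated nodes still exist
        graph.add_node(node)
    labels = {**drugs, **targets, **diseases}
    return graph, labels


def gen_smiles(
    n: int,
    length_range: tuple[int, int] = (20, 60),
    seed: int = 0,
    block_labels: dict[str, int] | None = None,
) -> dict[str, str]:
    """SMILES-like strings with balanced parentheses and matched ring digits.

    When ``block_labels`` is given (drug id -> block), each block prefers one
    atom symbol, planting a weak, chi-squared-detectable frequency signal.
    """
    lo, hi = length_range
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= lo <= hi:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    ids = sorted(block_labels) if block_labels else [f"dr:{i}" for i in range(n)]
    out: dict[str, str] = {}
    for drug in ids[:n] if block_labels is None else ids:
        block = 0 if block_labels is None else block_labels[drug]
        weights = np.ones(len(SMILES_ATOMS))
        weights[block % len(SMILES_ATOMS)] = _BIAS
        weights /= weights.sum()
        target_len = int(rng.integers(lo, hi + 1))
        chars: list[str] = []
        open_parens = 0
        open_rings: list[str] = []
        unused_rings = ["1", "2"]

        def pending() -> int:
            return open_parens + len(open_rings)

        while len(chars) + pending() < target_len:
            last_atom = bool(chars) and chars[-1] in SMILES_ATOMS
            room = target_len - len(chars) - pending()
            r = rng.random()
            if last_atom and r < 0.06 and unused_rings and room >= 3:
                digit = unused_rings.pop(0)
                open_rings.append(digit)
                chars.append(digit)
            elif last_atom and r < 0.12 and open_rings:
                chars.append(open_rings.pop(0))
            elif last_atom and r < 0.20 and room >= 3:
                open_parens += 1
                chars.append("(")
            elif last_atom and r < 0.28 and open_parens > 0:
                open_parens -= 1
                chars.append(")")
            elif last_atom and r < 0.36:
                chars.append("=")
            else:
                chars.append(SMILES_ATOMS[int(rng.choice(len(SMILES_ATOMS), p=weights))])
        chars.extend(open_rings)  # close remaining rings, then parens
        chars.extend(")" * open_parens)
        out[drug] = "".join(chars)
    return out


def gen_proteins(
    n: int,
    length_range: tuple[int, int] = (60, 120),
    seed: int = 0,
    block_labels: dict[str, int] | None = None,
) -> dict[str, str]:
    """Random amino-acid sequences with block-biased 7-class composition."""
    lo, hi = length_range
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 3 <= lo <= hi:
        raise ValueError("invalid length range (min length >= 3)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    ids = sorted(block_labels) if block_labels else [f"t:{i}" for i in range(n)]
    out: dict[str, str] = {}
    for pid in ids[:n] if block_labels is None else ids:
        block = 0 if block_labels is None else block_labels[pid]
        weights = np.ones(len(_AA_CLASSES))
        weights[block % len(_AA_CLASSES)] = _BIAS
        weights /= weights.sum()
        length = int(rng.integers(lo, hi + 1))
        classes = rng.choice(len(_AA_CLASSES), size=length, p=weights)
        seq = [
            _AA_CLASSES[c][int(rng.integers(len(_AA_CLASSES[c])))] for c in classes
        ]
        out[pid] = "".join(seq)
    return out


def gen_dataset(spec: SyntheticSpec) -> tuple[DTIDataset, dict[str, int]]:
    """Full synthetic dataset (graph + SMILES + proteins) and block labels."""
    graph, labels = gen_hetnet(spec)
    drug_labels = {k: v for k, v in labels.items() if k.startswith("dr:")}
    target_labels = {k: v for k, v in labels.items() if k.startswith("t:")}
    smiles = gen_smiles(
        spec.n_drugs, spec.smiles_length, seed=spec.seed, block_labels=drug_labels
    )
    proteins = gen_proteins(
        spec.n_targets, spec.protein_length, seed=spec.seed, block_labels=target_labels
    )
    ds = DTIDataset(graph=graph, smiles=smiles, proteins=proteins)
    ds.meta["synthetic_spec"] = spec
    ds.meta["block_labels"] = labels
    return ds, labels
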