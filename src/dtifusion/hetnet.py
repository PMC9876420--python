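"""Tripartite drug/target/disease heterogeneous network and meta-path walks.

The network has three node types — drugs (``dr:``), protein targets (``t:``)
and diseases (``di:``) — and three undirected edge relations:

* ``DTI`` — drug–target interactions (the links being predicted),
* ``DDI`` — drug–drug interactions,
* ``DDA`` — drug–disease associations.

Semantics are extracted by schema-constrained random walks.  A *meta-path
schema* is an ordered template of node types (e.g. drug–target–drug); a walk
chains many instances of one schema head-to-tail, producing a "sentence" of
node ids whose co-occurrence statistics encode network structure.  At each
step the walker moves uniformly at random among the current node's neighbors
of the type the schema requires next.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DRUG = "drug"
TARGET = "target"
DISEASE = "disease"

NODE_TYPES = (DRUG, TARGET, DISEASE)

#: id prefix -> node type
PREFIXES = {"dr:": DRUG, "t:": TARGET, "di:": DISEASE}

#: edge relation -> unordered endpoint-type pair
EDGE_TYPES = {
    "DTI": frozenset({DRUG, TARGET}),
    "DDI": frozenset({DRUG}),
    "DDA": frozenset({DRUG, DISEASE}),
}

_SHORT = {"dr": DRUG, "t": TARGET, "di": DISEASE}


class SchemaViolation(ValueError):
    """An edge or walk step is incompatible with the typed-graph rules."""


def node_type(node_id: str) -> str:
    """Infer a node's type from its id prefix (``dr:``, ``t:`` or ``di:``)."""
    for prefix, ntype in PREFIXES.items():
        if node_id.startswith(prefix):
            return ntype
    raise SchemaViolation(f"node id {node_id!r} lacks a recognised type prefix")


def edge_type_for(u: str, v: str) -> str:
    """The unique edge relation joining the endpoint types of (u, v)."""
    pair = frozenset({node_type(u), node_type(v)})
    for etype, types in EDGE_TYPES.items():
        if pair == types:
            return etype
    raise SchemaViolation(f"no edge relation joins {sorted(pair)} ({u!r}, {v!r})")


@dataclass(frozen=True)
class MetaPathSchema:
    """Ordered node-type template constraining walks.

    ``types`` has length 2–5; consecutive types must correspond to a legal
    edge relation, and the first and last type must coincide so instances
    chain head-to-tail.
    """

    name: str
    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 2 <= len(self.types) <= 5:
            raise ValueError(f"schema {self.name}: length must be in 2..5")
        if self.types[0] != self.types[-1]:
            raise ValueError(f"schema {self.name}: must start and end on the same type")
        if self.types[0] not in (DRUG, TARGET):
            raise ValueError(f"schema {self.name}: head type must be drug or target")
        for a, b in zip(self.types, self.types[1:]):
            pair = frozenset({a, b})
            if pair not in EDGE_TYPES.values():
                raise ValueError(f"schema {self.name}: illegal step {a}->{b}")

    @property
    def length(self) -> int:
        return len(self.types)

    @classmethod
    def from_string(cls, text: str) -> "MetaPathSchema":
        """Parse shorthand like ``"dr-t-dr"`` into a schema."""
        parts = text.split("-")
        try:
            types = tuple(_SHORT[p] for p in parts)
        except KeyError as exc:
            raise ValueError(f"unknown node-type code in {text!r}") from exc
        return cls(name=text, types=types)


#: The six shipped meta-path schemas.  Each captures one relational
#: semantics: e.g. t-dr-t links targets sharing a drug, dr-di-dr links drugs
#: treating the same disease.
DEFAULT_SCHEMAS: tuple[MetaPathSchema, ...] = tuple(
    MetaPathSchema.from_string(s)
    for s in ("t-dr-t", "t-dr-di-dr-t", "dr-dr", "dr-t-dr", "dr-di-dr", "t-dr-dr-t")
)


class HeteroGraph:
    """Simple undirected typed graph over drugs, targets and diseases.

    Adjacency is stored per neighbor type with deterministically sorted
    neighbor lists so that seeded walks are reproducible.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, str] = {}
        # node -> neighbor type -> sorted tuple of neighbors
        self._adj: dict[str, dict[str, list[str]]] = {}
        self.edges: set[tuple[str, str, str]] = set()  # canonical (etype, u, v), u < v

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: str) -> None:
        ntype = node_type(node_id)
        self.nodes.setdefault(node_id, ntype)
        self._adj.setdefault(node_id, {})

    def add_edge(self, u: str, v: str, etype: str | None = None) -> bool:
        """Add an undirected edge; returns False if it was a duplicate.

        Raises :class:`SchemaViolation` when endpoint types do not match the
        declared relation.  Self-loops are dropped with a warning (only DDI
        could form one; a self-transition carries no walk semantics).
        """
        inferred = edge_type_for(u, v)
        if etype is not None and etype != inferred:
            raise SchemaViolation(
                f"edge ({u!r}, {v!r}) declared {etype} but endpoint types imply {inferred}"
            )
        if u == v:
            logger.warning("dropping self-loop on %s", u)
            return False
        self.add_node(u)
        self.add_node(v)
        key = (inferred, *sorted((u, v)))
        if key in self.edges:
            return False
        self.edges.add(key)
        for a, b in ((u, v), (v, u)):
            bucket = self._adj[a].setdefault(self.nodes[b], [])
            bucket.append(b)
            bucket.sort()
        return True

    # -- queries -----------------------------------------------------------

    def has_edge(self, u: str, v: str) -> bool:
        try:
            key = (edge_type_for(u, v), *sorted((u, v)))
        except SchemaViolation:
            return False
        return key in self.edges

    def neighbors(self, node_id: str, ntype: str | None = None) -> list[str]:
        if node_id not in self._adj:
            raise KeyError(f"unknown node {node_id!r}")
        if ntype is None:
            out: list[str] = []
            for bucket in self._adj[node_id].values():
                out.extend(bucket)
            return sorted(out)
        return list(self._adj[node_id].get(ntype, ()))

    def nodes_of_type(self, ntype: str) -> list[str]:
        return sorted(n for n, t in self.nodes.items() if t == ntype)

    def edge_count(self, etype: str | None = None) -> int:
        if etype is None:
            return len(self.edges)
        return sum(1 for e in self.edges if e[0] == etype)

    def edges_of_type(self, etype: str) -> list[tuple[str, str]]:
        return sorted((u, v) for t, u, v in self.edges if t == etype)

    def summary(self) -> dict[str, int]:
        out = {f"n_{t}": len(self.nodes_of_type(t)) for t in NODE_TYPES}
        out.update({f"n_{e}": self.edge_count(e) for e in EDGE_TYPES})
        return out

    def copy(self) -> "HeteroGraph":
        g = HeteroGraph()
        g.nodes = dict(self.nodes)
        g._adj = {n: {t: list(b) for t, b in d.items()} for n, d in self._adj.items()}
        g.edges = set(self.edges)
        return g


def build_graph(edges: Iterable[tuple[str, str, str]]) -> HeteroGraph:
    """Build a :class:`HeteroGraph` from (u, v, etype) records.

    Duplicate records collapse to a single undirected edge.  A record whose
    endpoint types are incompatible with its declared relation raises
    :class:`SchemaViolation` naming the record.
    """
    g = HeteroGraph()
    n_dup = 0
    for rec in edges:
        u, v, etype = rec
        if etype not in EDGE_TYPES:
            raise SchemaViolation(f"unknown edge relation {etype!r} in record {rec!r}")
        try:
            if not g.add_edge(u, v, etype):
                n_dup += 1
        except SchemaViolation as exc:
            raise SchemaViolation(f"record {rec!r}: {exc}") from exc
    if n_dup:
        logger.info("collapsed %d duplicate edge records", n_dup)
    logger.info("built graph: %s", g.summary())
    return g


def mask_edges(graph: HeteroGraph, pairs: Sequence[tuple[str, str]]) -> HeteroGraph:
    """Return a copy of *graph* with the given DTI (drug, target) edges removed.

    The input graph is untouched.  Pairs absent from the graph are ignored
    with a warning, so masking is idempotent.
    """
    g = graph.copy()
    for drug, target in pairs:
        key = ("DTI", *sorted((drug, target)))
        if key not in g.edges:
            logger.warning("mask_edges: pair (%s, %s) not in graph; ignored", drug, target)
            continue
        g.edges.remove(key)
        for a, b in ((drug, target), (target, drug)):
            bucket = g._adj[a].get(g.nodes[b], [])
            if b in bucket:
                bucket.remove(b)
    return g


def transition_distribution(
    graph: HeteroGraph, current: str, required_type: str
) -> dict[str, float]:
    """Uniform next-step distribution over neighbors of the required type.

    Returns an empty mapping when the node has no neighbor of that type
    (a dead end for the walk).
    """
    nbrs = graph.neighbors(current, required_type)
    if not nbrs:
        return {}
    p = 1.0 / len(nbrs)
    return {n: p for n in nbrs}


@dataclass
class Walk:
    """A schema-constrained walk: chained meta-path instances."""

    tokens: list[str]
    schema: MetaPathSchema
    n_instances: int
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.tokens)


def generate_walk(
    graph: HeteroGraph,
    schema: MetaPathSchema,
    start: str,
    n_instances: int = 64,
    rng: np.random.Generator | None = None,
) -> Walk:
    """Chain ``n_instances`` instances of *schema* head-to-tail from *start*.

    The terminal node of instance k is the start node of instance k+1 and is
    emitted once, so a complete walk has ``n_instances * (L - 1) + 1`` tokens
    for a schema of length L.  A dead end truncates the walk, which is then
    flagged.
    """
    if rng is None:
        rng = np.random.default_rng()
    if graph.nodes.get(start) != schema.types[0]:
        raise SchemaViolation(
            f"start node {start!r} ({graph.nodes.get(start)}) does not match "
            f"schema head type {schema.types[0]}"
        )
    tokens = [start]
    current = start
    for _ in range(n_instances):
        for required in schema.types[1:]:
            nbrs = graph.neighbors(current, required)
            if not nbrs:
                return Walk(tokens, schema, n_instances, truncated=True)
            current = nbrs[int(rng.integers(len(nbrs)))]
            tokens.append(current)
    return Walk(tokens, schema, n_instances)


@dataclass
class WalkCorpus:
    """A bag of walks with its vocabulary and generation provenance."""

    walks: list[Walk]
    vocabulary: set[str] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def sentences(self) -> list[list[str]]:
        return [w.tokens for w in self.walks]

    def write(self, path) -> None:
        """One walk per line, space-separated tokens (word2vec plain text)."""
        with open(path, "w") as fh:
            for walk in self.walks:
                fh.write(" ".join(walk.tokens) + "\n")


def build_corpus(
    graph: HeteroGraph,
    schemas: Sequence[MetaPathSchema] = DEFAULT_SCHEMAS,
    n_instances: int = 64,
    restarts: int = 500,
    seed: int | np.random.SeedSequence = 0,
    keep_truncated: bool = True,
) -> WalkCorpus:
    """Generate the walk corpus over all schemas.

    For each schema every node of the head type is used once as a start
    (coverage), then ``restarts`` additional starts are drawn uniformly from
    the head-type nodes (diversity).  Walks shorter than two tokens are
    discarded.  Each schema gets an independent RNG stream derived from the
    master seed, so corpora are reproducible and schema order-independent.
    """
    if not graph.nodes:
        raise ValueError("cannot build a corpus from an empty graph")
    master = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    streams = master.spawn(len(schemas))
    walks: list[Walk] = []
    for schema, stream in zip(schemas, streams):
        rng = np.random.default_rng(stream)
        starts = graph.nodes_of_type(schema.types[0])
        if not starts:
            logger.warning("schema %s: no eligible start node; skipped", schema.name)
            continue
        queue = list(starts)
        queue.extend(starts[int(rng.integers(len(starts)))] for _ in range(restarts))
        for start in queue:
            walk = generate_walk(graph, schema, start, n_instances=n_instances, rng=rng)
            if len(walk) < 2:
                continue
            if walk.truncated and not keep_truncated:
                continue
            walks.append(walk)
    vocab = {tok for w in walks for tok in w.tokens}
    provenance = {
        "schemas": [s.name for s in schemas],
        "n_instances": n_instances,
        "restarts": restarts,
        "seed": repr(seed),
    }
    return WalkCorpus(walks=walks, vocabulary=vocab, provenance=provenance)
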