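"""Typed-graph construction, meta-path schemas and walk generation."""

import numpy as np
import pytest

from dtifusion.hetnet import (
    DEFAULT_SCHEMAS,
    MetaPathSchema,
    SchemaViolation,
    build_corpus,
    build_graph,
    generate_walk,
    mask_edges,
    transition_distribution,
)


class TestBuildGraph:
    def test_counts_after_dedup(self, toy_graph):
        assert len(toy_graph.nodes) == 6
        assert toy_graph.edge_count() == 6  # 3 DTI + 1 DDI (dup collapsed) + 2 DDA
        assert toy_graph.edge_count("DTI") == 3
        assert toy_graph.edge_count("DDI") == 1
        assert toy_graph.edge_count("DDA") == 2

    def test_empty_records(self):
        g = build_graph([])
        assert len(g.nodes) == 0 and g.edge_count() == 0

    def test_type_incompatible_edge_rejected(self):
        with pytest.raises(SchemaViolation, match="di:p"):
            build_graph([("di:p", "di:q", "DDA")])

    def test_declared_type_must_match_endpoints(self):
        with pytest.raises(SchemaViolation):
            build_graph([("dr:a", "t:x", "DDI")])

    def test_edges_are_undirected(self, toy_graph):
        assert toy_graph.has_edge("dr:a", "t:x") and toy_graph.has_edge("t:x", "dr:a")


class TestMaskEdges:
    def test_mask_one_of_three(self, toy_graph):
        g = mask_edges(toy_graph, [("dr:a", "t:x")])
        assert g.edge_count("DTI") == 2
        assert not g.has_edge("dr:a", "t:x")

    def test_mask_nothing_is_identity(self, toy_graph):
        g = mask_edges(toy_graph, [])
        assert g.edges == toy_graph.edges

    def test_mask_all_dti_leaves_other_relations(self, toy_graph):
        pairs = [("dr:a", "t:x"), ("dr:a", "t:y"), ("dr:b", "t:y")]
        g = mask_edges(toy_graph, pairs)
        assert g.edge_count("DTI") == 0
        assert g.edge_count("DDI") == 1 and g.edge_count("DDA") == 2

    def test_input_graph_unmodified(self, toy_graph):
        before = set(toy_graph.edges)
        mask_edges(toy_graph, [("dr:a", "t:x")])
        assert toy_graph.edges == before

    def test_absent_pair_ignored(self, toy_graph):
        g = mask_edges(toy_graph, [("dr:zzz", "t:zzz")])
        assert g.edges == toy_graph.edges


class TestTransitionDistribution:
    def test_uniform_over_required_type(self, star_graph):
        dist = transition_distribution(star_graph, "dr:hub", "target")
        assert len(dist) == 4
        assert all(p == pytest.approx(0.25) for p in dist.values())

    def test_other_types_excluded(self, star_graph):
        dist = transition_distribution(star_graph, "dr:hub", "disease")
        assert set(dist) == {"di:0", "di:1", "di:2"}
        assert all(p == pytest.approx(1 / 3) for p in dist.values())

    def test_dead_end_gives_empty_map(self, star_graph):
        assert transition_distribution(star_graph, "t:0", "disease") == {}

    def test_unknown_node_raises(self, star_graph):
        with pytest.raises(KeyError):
            transition_distribution(star_graph, "dr:ghost", "target")

    def test_normalization(self, small_dataset):
        dataset, _ = small_dataset
        g = dataset.graph
        for node in list(g.nodes)[:20]:
            for ntype in ("drug", "target", "disease"):
                dist = transition_distribution(g, node, ntype)
                if dist:
                    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empirical_frequencies_match_uniform(self, star_graph):
        """Sampled steps hit each eligible neighbor at rate 1/|N| within 3 sigma."""
        rng = np.random.default_rng(123)
        schema = MetaPathSchema.from_string("dr-t-dr")
        counts = {f"t:{i}": 0 for i in range(4)}
        n = 10_000
        for _ in range(n):
            walk = generate_walk(star_graph, schema, "dr:hub", n_instances=1, rng=rng)
            counts[walk.tokens[1]] += 1
        p = 0.25
        se = np.sqrt(p * (1 - p) / n)
        for c in counts.values():
            assert abs(c / n - p) < 3 * se


class TestGenerateWalk:
    def test_complete_walk_token_count_and_types(self, small_dataset):
        dataset, _ = small_dataset
        schema = MetaPathSchema.from_string("dr-t-dr")
        rng = np.random.default_rng(1)
        start = dataset.drugs[0]
        walk = generate_walk(dataset.graph, schema, start, n_instances=64, rng=rng)
        if not walk.truncated:
            assert len(walk) == 64 * 2 + 1
            types = [dataset.graph.nodes[t] for t in walk.tokens]
            assert all(
                t == ("drug" if i % 2 == 0 else "target") for i, t in enumerate(types)
            )

    def test_immediate_dead_end(self):
        g = build_graph([("dr:lone", "t:x", "DTI")])
        schema = MetaPathSchema.from_string("dr-dr")
        walk = generate_walk(g, schema, "dr:lone", rng=np.random.default_rng(0))
        assert walk.truncated and len(walk) == 1

    def test_seed_determinism(self, small_dataset):
        dataset, _ = small_dataset
        schema = MetaPathSchema.from_string("t-dr-t")
        start = dataset.targets[0]
        w1 = generate_walk(dataset.graph, schema, start, rng=np.random.default_rng(42))
        w2 = generate_walk(dataset.graph, schema, start, rng=np.random.default_rng(42))
        assert w1.tokens == w2.tokens

    def test_type_mismatched_start_rejected(self, star_graph):
        schema = MetaPathSchema.from_string("dr-t-dr")
        with pytest.raises(SchemaViolation):
            generate_walk(star_graph, schema, "t:0", rng=np.random.default_rng(0))

    def test_walk_validity_replay(self, small_dataset):
        """Every consecutive token pair is a graph edge; types tile the schema."""
        dataset, _ = small_dataset
        g = dataset.graph
        corpus = build_corpus(g, restarts=5, n_instances=8, seed=3)
        assert corpus.walks
        for walk in corpus.walks:
            L = walk.schema.length
            cycle = walk.schema.types[:-1]
            for i, (u, v) in enumerate(zip(walk.tokens, walk.tokens[1:])):
                assert g.has_edge(u, v)
                assert g.nodes[u] == cycle[i % (L - 1)]


class TestBuildCorpus:
    def test_coverage_plus_restart_counts(self):
        records = [(f"dr:{i}", f"t:{i % 2}", "DTI") for i in range(3)]
        g = build_graph(records)
        schema = MetaPathSchema.from_string("dr-t-dr")
        corpus = build_corpus(g, schemas=[schema], restarts=10, n_instances=4, seed=0)
        assert len(corpus.walks) == 3 + 10

    def test_zero_restarts_is_one_walk_per_start(self, small_dataset):
        """One coverage walk per head-type node; isolated starts are dropped
        because a dead-ended single-token walk carries no context."""
        dataset, _ = small_dataset
        schema = MetaPathSchema.from_string("t-dr-t")
        corpus = build_corpus(
            dataset.graph, schemas=[schema], restarts=0, n_instances=4, seed=0
        )
        connected = [
            t for t in dataset.targets if dataset.graph.neighbors(t, "drug")
        ]
        assert len(corpus.walks) == len(connected)
        assert {w.tokens[0] for w in corpus.walks} == set(connected)

    def test_vocabulary_subset_of_nodes(self, small_dataset):
        dataset, _ = small_dataset
        corpus = build_corpus(dataset.graph, restarts=3, n_instances=4, seed=1)
        assert corpus.vocabulary <= set(dataset.graph.nodes)

    def test_reproducible_per_seed(self, small_dataset):
        dataset, _ = small_dataset
        c1 = build_corpus(dataset.graph, restarts=3, n_instances=4, seed=5)
        c2 = build_corpus(dataset.graph, restarts=3, n_instances=4, seed=5)
        assert [w.tokens for w in c1.walks] == [w.tokens for w in c2.walks]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            build_corpus(build_graph([]), restarts=1)


class TestSchemas:
    def test_six_default_schemas(self):
        names = {s.name for s in DEFAULT_SCHEMAS}
        assert names == {"t-dr-t", "t-dr-di-dr-t", "dr-dr", "dr-t-dr", "dr-di-dr", "t-dr-dr-t"}

    def test_head_equals_tail(self):
        for s in DEFAULT_SCHEMAS:
            assert s.types[0] == s.types[-1]

    def test_illegal_step_rejected(self):
        with pytest.raises(ValueError):
            MetaPathSchema.from_string("t-di-t")  # no target-disease relation

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            MetaPathSchema.from_string("dr-t-dr-t-dr-t-dr")
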