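"""The Y-shaped fusion network: assembly, architecture, training, scoring."""

import numpy as np
import pytest

from dtifusion.fusion import (
    FusionConfig,
    ModalityStore,
    assemble_pair,
    bce_loss,
    build_model,
    predict_ensemble,
    rank_candidates,
    score_pairs,
    train,
    train_ensemble,
)


@pytest.fixture
def store(rng):
    s = ModalityStore()
    drugs = [f"dr:{i}" for i in range(6)]
    targets = [f"t:{i}" for i in range(4)]
    s.add("sequence", {e: rng.normal(size=8) for e in drugs + targets})
    s.add("structure", {e: rng.normal(size=4) for e in drugs + targets})
    s.add("similarity", {e: rng.normal(size=6) for e in drugs + targets})
    return s


class TestAssemblePair:
    def test_six_vectors_in_branch_order(self, store):
        vecs = assemble_pair("dr:0", "t:0", store)
        assert len(vecs) == 6
        # (drug-seq, target-seq, drug-struct, target-struct, drug-sim, target-sim)
        assert vecs[0].shape == (8,) and vecs[1].shape == (8,)
        assert vecs[2].shape == (4,) and vecs[3].shape == (4,)
        assert vecs[4].shape == (6,) and vecs[5].shape == (6,)

    def test_disabled_modality_omitted(self, store):
        vecs = assemble_pair("dr:0", "t:0", store, modalities=("sequence", "similarity"))
        assert len(vecs) == 4
        assert vecs[0].shape == (8,) and vecs[2].shape == (6,)

    def test_deterministic(self, store):
        v1 = assemble_pair("dr:1", "t:2", store)
        v2 = assemble_pair("dr:1", "t:2", store)
        assert all(np.array_equal(a, b) for a, b in zip(v1, v2))

    def test_missing_vector_names_entity_and_modality(self, store):
        with pytest.raises(KeyError, match="dr:99.*sequence"):
            assemble_pair("dr:99", "t:0", store)


class TestBuildModel:
    def test_concat_width_six_branches(self):
        model = build_model(FusionConfig(), [8, 8, 4, 4, 6, 6])
        assert model.concat_width == 6 * 64 == 384
        assert model.w1.shape == (384, 128)
        assert model.w2.shape == (128, 32)
        assert model.w3.shape == (32, 1)

    def test_forward_scores_in_unit_interval(self, rng):
        model = build_model(FusionConfig(), [8, 8, 4, 4, 6, 6])
        xs = [rng.normal(size=(10, d)) for d in (8, 8, 4, 4, 6, 6)]
        p = model.predict(xs)
        assert p.shape == (10,)
        assert np.all((p > 0) & (p < 1))

    def test_same_seed_identical_init(self):
        cfg = FusionConfig(seed=9, modalities=("structure",))
        m1 = build_model(cfg, [4, 4])
        m2 = build_model(cfg, [4, 4])
        assert all(np.array_equal(a, b) for a, b in zip(m1.parameters(), m2.parameters()))

    def test_branch_count_must_match_modalities(self):
        with pytest.raises(ValueError):
            build_model(FusionConfig(), [8, 8])  # 3 modalities need 6 branches

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FusionConfig(modalities=())
        with pytest.raises(ValueError):
            FusionConfig(dropout=1.0)
        with pytest.raises(ValueError):
            FusionConfig(monitor="accuracy")


def _separable_problem(rng, n=120, d=6):
    y = rng.integers(0, 2, size=n).astype(float)
    xs = [rng.normal(size=(n, d)) + 2.0 * y[:, None] * (k + 1) / 2 for k in range(2)]
    return xs, y


class TestTrain:
    def test_fits_linearly_separable_features(self, rng):
        xs, y = _separable_problem(rng)
        cfg = FusionConfig(modalities=("structure",), seed=0, max_epochs=60, patience=60)
        model = build_model(cfg, [x.shape[1] for x in xs])
        train(model, xs, y, xs, y)
        assert model.history[-1]["train_loss"] < 0.1

    def test_constant_features_stagnate_at_ln2(self, rng):
        n = 100
        y = np.array([0, 1] * (n // 2), dtype=float)
        xs = [np.zeros((n, 4)), np.zeros((n, 4))]
        cfg = FusionConfig(modalities=("structure",), seed=0, max_epochs=30, patience=30)
        model = build_model(cfg, [4, 4])
        train(model, xs, y, xs, y)
        assert model.history[-1]["train_loss"] == pytest.approx(np.log(2), abs=0.02)

    def test_single_class_labels_rejected(self, rng):
        xs = [rng.normal(size=(10, 4)), rng.normal(size=(10, 4))]
        cfg = FusionConfig(modalities=("structure",))
        model = build_model(cfg, [4, 4])
        with pytest.raises(ValueError):
            train(model, xs, np.ones(10), xs, np.ones(10))

    def test_reproducible_for_fixed_seed(self, rng):
        xs, y = _separable_problem(rng)
        losses = []
        for _ in range(2):
            cfg = FusionConfig(modalities=("structure",), seed=4, max_epochs=20, patience=20)
            model = build_model(cfg, [x.shape[1] for x in xs])
            train(model, xs, y, xs, y)
            losses.append(model.history[-1]["train_loss"])
        assert losses[0] == losses[1]


class TestScoring:
    @pytest.fixture
    def trained(self, store, rng):
        pairs = [(f"dr:{i}", f"t:{j}") for i in range(6) for j in range(4)]
        y = np.array([(i + j) % 2 for i, j in [(int(d[3:]), int(t[2:])) for d, t in pairs]], dtype=float)
        cfg = FusionConfig(seed=0, max_epochs=15, patience=15)
        xs = [np.vstack(c) for c in zip(*(assemble_pair(d, t, store) for d, t in pairs))]
        model = build_model(cfg, [x.shape[1] for x in xs])
        train(model, xs, y, xs, y)
        return model

    def test_order_preserving_and_duplicates_identical(self, trained, store):
        pairs = [("dr:0", "t:0"), ("dr:1", "t:1"), ("dr:0", "t:0")]
        s = score_pairs(trained, pairs, store)
        assert len(s) == 3
        assert s[0] == s[2]

    def test_batch_size_invariance(self, trained, store):
        pairs = [(f"dr:{i}", "t:0") for i in range(6)]
        full = score_pairs(trained, pairs, store)
        singles = np.array([score_pairs(trained, [p], store)[0] for p in pairs])
        assert np.allclose(full, singles, atol=1e-6)

    def test_repeated_inference_identical(self, trained, store):
        """Dropout must be disabled outside training."""
        pairs = [("dr:2", "t:3")] * 4
        s1 = score_pairs(trained, pairs, store)
        s2 = score_pairs(trained, pairs, store)
        assert np.array_equal(s1, s2)

    def test_empty_pairs_rejected(self, trained, store):
        with pytest.raises(ValueError):
            score_pairs(trained, [], store)


class TestRankCandidates:
    def test_output_shape_and_sorting(self, store, rng):
        pairs = [(f"dr:{i}", f"t:{j}") for i in range(6) for j in range(4)]
        y = rng.integers(0, 2, size=len(pairs)).astype(float)
        y[0] = 1 - y[1] if y[0] == y[1] else y[0]  # ensure both classes
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
        cfg = FusionConfig(seed=1, max_epochs=5, patience=5)
        xs = [np.vstack(c) for c in zip(*(assemble_pair(d, t, store) for d, t in pairs))]
        model = build_model(cfg, [x.shape[1] for x in xs])
        train(model, xs, y, xs, y)
        drugs = [f"dr:{i}" for i in range(6)]
        ranked = rank_candidates(model, "t:1", drugs, store)
        assert len(ranked) == 6
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_empty_drug_list_rejected(self, store):
        model = build_model(FusionConfig(), [8, 8, 4, 4, 6, 6])
        with pytest.raises(ValueError):
            rank_candidates(model, "t:0", [], store)


class TestArchitectureSymmetry:
    def test_swapping_branches_with_weights_preserves_scores(self, rng):
        """Branch identity lives only in its weights: swapping a branch's
        weight matrices together with its inputs leaves scores unchanged,
        once the concatenation-facing rows of the first hidden layer move too."""
        cfg = FusionConfig(modalities=("sequence", "structure"), seed=2)
        model = build_model(cfg, [5, 5, 5, 5])
        xs = [rng.normal(size=(7, 5)) for _ in range(4)]
        base = model.predict(xs)
        bw = cfg.branch_width
        # swap branches 0 and 2 entirely
        model.branch_w[0], model.branch_w[2] = model.branch_w[2], model.branch_w[0]
        model.branch_b[0], model.branch_b[2] = model.branch_b[2], model.branch_b[0]
        w1 = model.w1.copy()
        model.w1[0:bw], model.w1[2 * bw : 3 * bw] = w1[2 * bw : 3 * bw], w1[0:bw]
        swapped = model.predict([xs[2], xs[1], xs[0], xs[3]])
        assert np.allclose(base, swapped, atol=1e-12)


class TestEnsemble:
    def test_members_differ_but_average_is_deterministic(self, rng):
        xs, y = _separable_problem(rng)
        cfg = FusionConfig(
            modalities=("structure",), seed=0, n_models=3, max_epochs=10, patience=10
        )
        models = train_ensemble(cfg, xs, y, xs, y)
        assert len(models) == 3
        p1 = predict_ensemble(models, xs)
        p2 = predict_ensemble(models, xs)
        assert np.array_equal(p1, p2)
        assert not np.array_equal(models[0].predict(xs), models[1].predict(xs))


def test_bce_loss_matches_formula():
    y = np.array([1.0, 0.0, 1.0])
    p = np.array([0.9, 0.2, 0.6])
    expected = -np.mean([np.log(0.9), np.log(0.8), np.log(0.6)])
    assert bce_loss(y, p) == pytest.approx(expected)
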