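import math

import numpy as np
import pytest

from dssmreg.dssm_core import (
    DSSMConfig,
    bce_loss,
    build_towers,
    cosine_score,
    edge_probability,
    load_model,
    make_training_set,
    predict_pairs,
    save_model,
    score_all_pairs,
    tower_forward,
    train_dssm,
)
from dssmreg.gene_embeddings import FeatureSet, GeneFeatureVector
from dssmreg.types import EdgeList


def _features(genes, dim=10, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureSet(
        {g: GeneFeatureVector(g, rng.random(dim), rng.random(dim)) for g in genes}
    )


def _small_cfg(**kw):
    defaults = dict(layer_widths=(16, 16, 8), epochs=5, batch_size=16,
                    learning_rate=1e-3, seed=0)
    defaults.update(kw)
    return DSSMConfig(**defaults)


class TestMakeTrainingSet:
    def test_balance_rule(self):
        pos = EdgeList([("A", "g1")])
        pairs = make_training_set(pos, {"A"}, {"g1", "g2", "g3", "g4"}, _small_cfg())
        negs = [p for p in pairs if p.label == 0]
        assert len(negs) == 1
        assert negs[0].tg_id in {"g2", "g3", "g4"}

    def test_negatives_never_positive(self):
        pos = EdgeList([("A", f"g{i}") for i in range(10)])
        universe = {f"g{i}" for i in range(30)} | {"A"}
        pairs = make_training_set(pos, {"A"}, universe, _small_cfg())
        pos_set = pos.as_set()
        for p in pairs:
            if p.label == 0:
                assert (p.tf_id, p.tg_id) not in pos_set
                assert p.tg_id != p.tf_id

    def test_stratified_split_counts(self):
        # 100 positives + 100 negatives at train_fraction 0.8
        pos = EdgeList([(f"T{i}", f"g{i}_{j}") for i in range(5) for j in range(20)])
        universe = {f"g{i}_{j}" for i in range(5) for j in range(20)}
        universe |= {f"x{k}" for k in range(100)}
        tfs = {f"T{i}" for i in range(5)}
        pairs = make_training_set(pos, tfs, universe | tfs, _small_cfg())
        assert len(pairs) == 200
        train = [p for p in pairs if p.split == "train"]
        test = [p for p in pairs if p.split == "test"]
        assert len(train) == 160 and len(test) == 40
        assert sum(p.label for p in train) == 80
        assert sum(p.label for p in test) == 20

    def test_deficit_pool_logged(self, caplog):
        pos = EdgeList([("A", "g1"), ("A", "g2")])
        with caplog.at_level("WARNING", logger="dssmreg.dssm_core"):
            pairs = make_training_set(pos, {"A"}, {"g1", "g2", "g3"}, _small_cfg())
        assert sum(p.label == 0 for p in pairs) == 1  # pool exhausted
        assert any("whole pool" in r.message for r in caplog.records)

    def test_unknown_tf_rejected(self):
        pos = EdgeList([("A", "g1")])
        with pytest.raises(ValueError, match="tf_universe"):
            make_training_set(pos, {"B"}, {"g1", "g2"}, _small_cfg())


class TestTowerForward:
    def test_output_length(self):
        cfg = DSSMConfig(seed=0)
        rng = np.random.default_rng(0)
        tf_tower, _ = build_towers(cfg, 100, rng)
        out = tower_forward(tf_tower, np.ones(100))
        assert out.shape == (128,)

    def test_deterministic(self):
        cfg = _small_cfg()
        rng = np.random.default_rng(0)
        tower, _ = build_towers(cfg, 10, rng)
        v = np.linspace(-1, 1, 10)
        np.testing.assert_array_equal(tower_forward(tower, v), tower_forward(tower, v))

    def test_wrong_input_length(self):
        cfg = _small_cfg()
        rng = np.random.default_rng(0)
        tower, _ = build_towers(cfg, 10, rng)
        with pytest.raises(ValueError, match="width"):
            tower_forward(tower, np.ones(7))

    def test_linearity_with_activations_disabled(self, monkeypatch):
        from dssmreg.nn import MLP

        cfg = _small_cfg()
        rng = np.random.default_rng(0)
        tower, _ = build_towers(cfg, 10, rng)
        monkeypatch.setattr(MLP, "_is_relu", lambda self, layer: False)
        tower.biases = [np.zeros_like(b) for b in tower.biases]
        v = np.linspace(-1, 1, 10)
        np.testing.assert_allclose(
            tower_forward(tower, 3.0 * v), 3.0 * tower_forward(tower, v), rtol=1e-10
        )


class TestCosineScore:
    def test_orthogonal(self):
        a = np.zeros(8); a[0] = 1.0
        b = np.zeros(8); b[1] = 1.0
        assert cosine_score(a, b) == 0.0

    def test_colinear(self):
        v = np.arange(1.0, 9.0)
        assert cosine_score(v, 2.0 * v) == pytest.approx(1.0, abs=1e-12)

    def test_hand_value(self):
        # dot = 32, |a| = sqrt(14), |b| = sqrt(77)
        a = np.array([1.0, 2.0, 3.0, 0.0, 0.0])
        b = np.array([4.0, 5.0, 6.0, 0.0, 0.0])
        expected = 32.0 / (math.sqrt(14.0) * math.sqrt(77.0))
        assert cosine_score(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9746318461970762, abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_score(np.zeros(3), np.ones(3))


class TestEdgeProbability:
    def test_zero(self):
        assert edge_probability(0.0) == 0.5

    def test_one(self):
        assert edge_probability(1.0) == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)
        assert edge_probability(1.0) == pytest.approx(0.7310585786300049, abs=1e-12)

    @pytest.mark.parametrize("s", [-5.0, -0.3, 0.0, 0.7, 3.2])
    def test_symmetry(self, s):
        assert edge_probability(s) + edge_probability(-s) == pytest.approx(1.0, abs=1e-12)

    def test_monotone(self):
        grid = np.linspace(-4, 4, 30)
        probs = [edge_probability(s) for s in grid]
        assert all(p1 < p2 for p1, p2 in zip(probs, probs[1:]))


class TestBCELoss:
    def test_ln2(self):
        assert bce_loss([0.5, 0.5], [1, 0]) == pytest.approx(math.log(2.0), abs=1e-12)

    def test_perfect_prediction_limit(self):
        assert bce_loss([1.0 - 1e-9], [1]) < 1e-8

    def test_permutation_symmetry(self):
        p = [0.3, 0.8, 0.6]
        y = [0, 1, 1]
        assert bce_loss(p, y) == pytest.approx(bce_loss(p[::-1], y[::-1]), abs=1e-15)

    def test_clamps_extremes(self, caplog):
        with caplog.at_level("WARNING", logger="dssmreg.dssm_core"):
            loss = bce_loss([0.0, 1.0], [0, 1])
        assert np.isfinite(loss)
        assert any("clamped" in r.message for r in caplog.records)


@pytest.fixture
def trained_setup():
    pos = EdgeList([(f"T{i}", f"g{i}_{j}") for i in range(2) for j in range(8)])
    genes = {f"g{i}_{j}" for i in range(2) for j in range(8)} | {f"x{k}" for k in range(20)}
    tfs = {"T0", "T1"}
    features = _features(sorted(genes | tfs))
    cfg = _small_cfg()
    pairs = make_training_set(pos, tfs, genes | tfs, cfg)
    model = train_dssm(pairs, features, cfg)
    return pos, genes, tfs, features, cfg, pairs, model


class TestTrainDSSM:
    def test_loss_trajectory(self, trained_setup):
        *_, model = trained_setup
        assert model.epoch_losses[-1] < model.epoch_losses[0]

    def test_seeded_determinism(self, trained_setup):
        pos, genes, tfs, features, cfg, pairs, model = trained_setup
        model2 = train_dssm(pairs, features, cfg)
        for a, b in zip(model.tf_tower.parameters(), model2.tf_tower.parameters()):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(model.tg_tower.parameters(), model2.tg_tower.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_test_split_isolated(self, trained_setup):
        pos, genes, tfs, features, cfg, pairs, model = trained_setup
        train_only = [p for p in pairs if p.split == "train"]
        model2 = train_dssm(train_only, features, cfg)
        for a, b in zip(model.tf_tower.parameters(), model2.tf_tower.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_missing_vector_rejected(self, trained_setup):
        pos, genes, tfs, features, cfg, pairs, _ = trained_setup
        broken = FeatureSet({g: v for g, v in features.vectors.items() if g != "T0"})
        with pytest.raises(ValueError, match="T0"):
            train_dssm(pairs, broken, cfg)

    def test_checkpoint_round_trip(self, trained_setup, tmp_path):
        pos, genes, tfs, features, cfg, pairs, model = trained_setup
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        p1, _ = predict_pairs(model, pairs, features, "test")
        p2, _ = predict_pairs(back, pairs, features, "test")
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestScoreAllPairs:
    def test_cardinality(self, trained_setup):
        pos, genes, tfs, features, cfg, pairs, model = trained_setup
        tgs = {f"g0_{j}" for j in range(8)} | {"x0", "x1"}
        table = score_all_pairs(model, features, tfs, tgs, "ct")
        assert len(table) == len(tfs) * len(tgs)

    def test_score_prob_invariants(self, trained_setup):
        pos, genes, tfs, features, cfg, pairs, model = trained_setup
        table = score_all_pairs(model, features, tfs, genes, "ct")
        assert ((table["score"] >= -1.0) & (table["score"] <= 1.0)).all()
        np.testing.assert_allclose(
            table["prob"], 1.0 / (1.0 + np.exp(-table["score"])), atol=1e-12
        )

    def test_empty_sets_rejected(self, trained_setup):
        *_, model = trained_setup
        features = _features(["a"])
        with pytest.raises(ValueError, match="empty"):
            score_all_pairs(model, features, set(), {"a"}, "ct")

    def test_direction_aware(self, trained_setup):
        pos, genes, tfs, features, cfg, pairs, model = trained_setup
        fwd = score_all_pairs(model, features, {"T0"}, {"g0_0"}, "ct")["score"].iloc[0]
        rev = score_all_pairs(model, features, {"g0_0"}, {"T0"}, "ct")["score"].iloc[0]
        assert fwd != rev


class TestTowerIndependence:
    def test_perturbing_tf_tower_leaves_tg_hidden_unchanged(self, trained_setup):
        pos, genes, tfs, features, cfg, pairs, model = trained_setup
        v = features.vectors["g0_0"].full_vec
        before = tower_forward(model.tg_tower, v)
        model.tf_tower.weights[0] += 1.0
        after = tower_forward(model.tg_tower, v)
        np.testing.assert_array_equal(before, after)

    def test_no_shared_parameters(self, trained_setup):
        *_, model = trained_setup
        for a in model.tf_tower.parameters():
            for b in model.tg_tower.parameters():
                assert a is not b
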