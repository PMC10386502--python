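"""Forest minimal depth / OOB permutation importance and XGBoost gain ranking."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import metaborank as mb
from metaborank.containers import AbundanceMatrix, SampleMetadata
from metaborank.trees import BoostedModel, ForestModel, _oob_mask, _tree_min_depths


def _dataset(n=300, p=20, signal=None, seed=0, noise=0.0):
    """Binary outcome driven by column 0 when signal='strong'; pure noise otherwise."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if signal == "strong":
        y = (X[:, 0] + noise * rng.standard_normal(n) > 0).astype(int)
    else:
        y = (rng.random(n) < 0.5).astype(int)
    m = AbundanceMatrix(X, [f"S{i}" for i in range(n)],
                        [f"M{j:03d}" for j in range(p)], stage="scaled")
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": m.sample_ids, "outcome": y,
        "age": rng.normal(52, 10, n).clip(20, 90),
        "sex": np.where(rng.random(n) < 0.7, "F", "M"),
        "batch": ["B1"] * n,
    }))
    return m, meta


def _stub_tree(children_left, children_right, feature):
    return SimpleNamespace(tree_=SimpleNamespace(
        children_left=np.array(children_left),
        children_right=np.array(children_right),
        feature=np.array(feature),
        node_count=len(feature),
    ))


def _stub_forest(trees, p):
    forest = SimpleNamespace(estimators_=trees, n_features_in_=p)
    return ForestModel(forest, mtry=1, nodesize=1, oob_error=0.0, seed=0)


# depth-1 stump splitting on feature 0
STUMP = ([1, -1, -1], [2, -1, -1], [0, -2, -2])
# depth-3 chain: features 1 (root), 2, 3
CHAIN = ([1, 3, -1, 5, -1, -1, -1], [2, 4, -1, 6, -1, -1, -1],
         [1, 2, -2, 3, -2, -2, -2])


class TestMinimalDepth:
    def test_single_tree_depths(self):
        d, dmax = _tree_min_depths(_stub_tree(*CHAIN), 5)
        assert dmax == 3
        assert list(d[[1, 2, 3]]) == [0.0, 1.0, 2.0]
        assert np.isinf(d[0]) and np.isinf(d[4])

    def test_root_split_everywhere_gives_zero(self):
        model = _stub_forest([_stub_tree(*STUMP)] * 3, 4)
        assert mb.minimal_depth(model)[0] == 0.0

    def test_absent_feature_penalized_at_max_depth_plus_one(self):
        model = _stub_forest([_stub_tree(*CHAIN)] * 2, 5)
        assert mb.minimal_depth(model)[4] == 4.0       # uniform depth 3 -> 3 + 1

    def test_hand_walked_average(self):
        # feature 0: root (depth 0) in the stump, absent from the depth-3 chain
        model = _stub_forest([_stub_tree(*STUMP), _stub_tree(*CHAIN)], 5)
        assert mb.minimal_depth(model)[0] == pytest.approx((0 + 4) / 2)

    def test_empty_forest_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mb.minimal_depth(_stub_forest([], 3))


class TestForestFit:
    def test_pure_noise_oob_near_majority_rate(self):
        m, meta = _dataset(n=400, p=10, seed=1)
        model = mb.tune_and_fit_forest(m, meta, mtry_grid=(3,), nodesize_grid=(15,),
                                       n_trees=100, seed=0)
        majority = max(meta.outcome.mean(), 1 - meta.outcome.mean())
        assert abs(model.oob_error - (1 - majority)) <= 0.05

    def test_dominant_feature_low_oob_error(self):
        m, meta = _dataset(n=1000, p=10, signal="strong", seed=2)
        model = mb.tune_and_fit_forest(m, meta, mtry_grid=(3,), nodesize_grid=(5,),
                                       n_trees=100, seed=0)
        assert model.oob_error < 0.1

    def test_same_seed_identical_forests(self):
        m, meta = _dataset(n=200, p=8, signal="strong", noise=0.5, seed=3)
        f1 = mb.tune_and_fit_forest(m, meta, mtry_grid=(2, 4), nodesize_grid=(5,),
                                    n_trees=60, seed=9)
        f2 = mb.tune_and_fit_forest(m, meta, mtry_grid=(2, 4), nodesize_grid=(5,),
                                    n_trees=60, seed=9)
        assert f1.mtry == f2.mtry and f1.nodesize == f2.nodesize
        assert f1.oob_error == f2.oob_error
        for a, b in zip(f1.forest.estimators_, f2.forest.estimators_):
            assert a.tree_.node_count == b.tree_.node_count
            assert np.array_equal(a.tree_.feature, b.tree_.feature)

    def test_tuning_tie_prefers_regularized(self):
        m, meta = _dataset(n=150, p=5, signal="strong", seed=4)
        model = mb.tune_and_fit_forest(m, meta, mtry_grid=(2,), nodesize_grid=(5, 15),
                                       n_trees=60, seed=0)
        assert len(model.tuning_trace) == 2

    def test_oob_mask_matches_sklearn_aggregation(self):
        m, meta = _dataset(n=150, p=6, signal="strong", noise=0.8, seed=5)
        model = mb.tune_and_fit_forest(m, meta, mtry_grid=(2,), nodesize_grid=(5,),
                                       n_trees=80, seed=1)
        n = m.n_samples
        agg = np.zeros((n, 2))
        cnt = np.zeros(n)
        for est in model.forest.estimators_:
            oob = _oob_mask(est.random_state, n)
            agg[oob] += est.predict_proba(m.values[oob])
            cnt[oob] += 1
        seen = cnt > 0
        np.testing.assert_allclose(agg[seen] / cnt[seen, None],
                                   model.forest.oob_decision_function_[seen])


class TestForestImportance:
    def test_null_importance_near_zero_and_causal_dominates(self):
        wins = 0
        for seed in range(10):
            m, meta = _dataset(n=300, p=15, signal="strong", noise=1.0,
                               seed=100 + seed)
            model = mb.tune_and_fit_forest(m, meta, mtry_grid=(4,),
                                           nodesize_grid=(5,), n_trees=150, seed=seed)
            imp = mb.forest_importance(model, m, meta)
            assert np.abs(imp[1:]).max() < 0.05      # noise features near zero
            if np.argmax(imp) == 0 and imp[0] > 0:
                wins += 1
        assert wins >= 9

    def test_seeded_importance_reproducible(self):
        m, meta = _dataset(n=200, p=8, signal="strong", noise=0.5, seed=6)
        model = mb.tune_and_fit_forest(m, meta, mtry_grid=(3,), nodesize_grid=(5,),
                                       n_trees=100, seed=2)
        i1 = mb.forest_importance(model, m, meta)
        i2 = mb.forest_importance(model, m, meta)
        assert np.array_equal(i1, i2)


class TestRankForest:
    def test_importance_order(self):
        r = mb.rank_forest([1.0, 1.0, 1.0], [0.2, 0.0, 0.1], ["A", "B", "C"])
        assert list(r.rank) == [1, 3, 2]

    def test_depth_breaks_importance_ties(self):
        r = mb.rank_forest([1.0, 0.5], [0.1, 0.1], ["A", "B"])
        assert list(r.rank) == [2, 1]

    def test_selection_imputes_deep_features(self):
        r = mb.rank_forest([1.0, 1.0, 10.0], [0.3, 0.2, 0.1], ["A", "B", "C"],
                           selection=True)
        assert r.imputed[2] and not r.imputed[0]
        assert r.rank[2] == 3

    def test_rank_by_minimal_depth_mode(self):
        r = mb.rank_forest([2.0, 0.5, 1.0], [0.0, 0.0, 0.0], ["A", "B", "C"],
                           by="minimal_depth")
        assert list(r.rank) == [3, 1, 2]


class TestXgb:
    def test_pure_noise_cv_error_near_majority(self):
        m, meta = _dataset(n=600, p=10, seed=7)
        model = mb.tune_and_fit_xgb(m, meta,
                                    param_grid=({"max_depth": 3, "learning_rate": 0.1},),
                                    folds=5, seed=0)
        majority = max(meta.outcome.mean(), 1 - meta.outcome.mean())
        assert abs(model.cv_error - (1 - majority)) <= 0.05

    def test_strong_signal_concentrates_gain(self):
        for seed in range(5):
            m, meta = _dataset(n=500, p=10, signal="strong", seed=200 + seed)
            model = mb.tune_and_fit_xgb(
                m, meta, param_grid=({"max_depth": 3, "learning_rate": 0.1},),
                folds=5, seed=seed)
            frac = model.total_gain / model.total_gain.sum()
            assert frac[0] > 0.5

    def test_same_seed_same_choice(self):
        m, meta = _dataset(n=200, p=8, signal="strong", noise=0.5, seed=8)
        grid = ({"max_depth": 2, "learning_rate": 0.1},
                {"max_depth": 4, "learning_rate": 0.3})
        m1 = mb.tune_and_fit_xgb(m, meta, param_grid=grid, folds=5, seed=4)
        m2 = mb.tune_and_fit_xgb(m, meta, param_grid=grid, folds=5, seed=4)
        assert (m1.max_depth, m1.learning_rate, m1.rounds) == \
               (m2.max_depth, m2.learning_rate, m2.rounds)
        assert np.array_equal(m1.total_gain, m2.total_gain)


class TestRankXgbGain:
    def _model(self, gains):
        return BoostedModel(booster=None, rounds=10, learning_rate=0.1, max_depth=3,
                            total_gain=np.array(gains, dtype=float), cv_error=0.1,
                            seed=0)

    def test_fractional_gains(self):
        r = mb.rank_xgb_gain(self._model([30.0, 70.0]), ["A", "B"])
        np.testing.assert_allclose(r.score, [0.3, 0.7])
        assert list(r.rank) == [2, 1]

    def test_single_used_feature(self):
        r = mb.rank_xgb_gain(self._model([0.0, 5.0, 0.0]), ["A", "B", "C"])
        assert r.score[1] == 1.0 and r.rank[1] == 1
        assert r.imputed[0] and r.imputed[2]
        assert r.rank[0] == r.rank[2] == 3

    def test_equal_gains_id_order(self):
        r = mb.rank_xgb_gain(self._model([1.0, 1.0, 1.0]), ["C", "A", "B"])
        assert list(r.rank) == [3, 1, 2]
        np.testing.assert_allclose(r.score, [1 / 3] * 3)
        assert r.score[~r.imputed].sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_splits_rejected(self):
        with pytest.raises(ValueError, match="splits"):
            mb.rank_xgb_gain(self._model([0.0, 0.0]), ["A", "B"])


def test_forest_spreads_over_blocks_while_xgb_concentrates():
    """On block-correlated data the forest's top list includes more members
    per signal block than XGBoost's gain ranking (convergent vs divergent)."""
    forest_members, xgb_members = [], []
    for seed in range(20):
        cfg = mb.SyntheticConfig(n_samples=250, n_blocks=8, block_size=20, rho=0.7,
                                 n_signal_blocks=4, beta_signal=1.2, seed=3000 + seed)
        raw, meta = mb.generate_dataset(cfg)
        Xs = mb.preprocess(raw, meta)
        meta = meta.aligned_to(Xs)
        fm = mb.tune_and_fit_forest(Xs, meta, mtry_grid=(12,), nodesize_grid=(5,),
                                    n_trees=120, seed=seed)
        imp = mb.forest_importance(fm, Xs, meta)
        rf = mb.rank_forest(mb.minimal_depth(fm), imp, Xs.feature_ids)
        bm = mb.tune_and_fit_xgb(Xs, meta,
                                 param_grid=({"max_depth": 3, "learning_rate": 0.1},),
                                 folds=5, seed=seed)
        rx = mb.rank_xgb_gain(bm, Xs.feature_ids)

        def members_per_block(r):
            top = r.top_ids(min(50, r.n_scored))
            # block index of feature id "Mxxxxxx" (ids are 1-based)
            blocks = [(int(t[1:]) - 1) // cfg.block_size for t in top]
            signal = [b for b in blocks if b < cfg.n_signal_blocks]
            return len(signal) / cfg.n_signal_blocks
        forest_members.append(members_per_block(rf))
        xgb_members.append(members_per_block(rx))
    assert np.mean(forest_members) > np.mean(xgb_members)
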