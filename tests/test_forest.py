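import json

import numpy as np
import pytest

from sauronrf import (
    Dataset,
    ForestParams,
    SauronForest,
    binarize,
    distance_sample_weights,
    fit_forest,
    simple_sample_weights,
    uniform_sample_weights,
)
from conftest import single_leaf_tree
from helpers_oracle import best_split_partitions, fitted_tree_partitions


def weight_schemes(ds):
    return {
        "uniform": uniform_sample_weights(ds.n_samples),
        "simple": simple_sample_weights(ds.Y),
        "linear": distance_sample_weights(ds.y, ds.Y, ds.t, d=1),
        "quadratic": distance_sample_weights(ds.y, ds.Y, ds.t, d=2),
    }


class TestSplitOracle:
    @pytest.mark.parametrize("scheme", ["uniform", "simple", "linear", "quadratic"])
    def test_every_split_is_exhaustive_argmin(self, toy, scheme):
        """Each split chosen during fitting equals the brute-force argmin of
        the weighted child error over all (feature, midpoint) candidates,
        under all four sample-weight schemes."""
        weights = weight_schemes(toy)[scheme]
        params = ForestParams(B=3, m=3, min_samples_leaf=2, seed=101)
        forest = fit_forest(toy, weights, params)
        checked = 0
        for tree in forest.trees:
            Xb = toy.X[tree.bootstrap_idx]
            wb = weights.w_star[tree.bootstrap_idx]
            yb = toy.y[tree.bootstrap_idx]
            for members, left in fitted_tree_partitions(tree, Xb):
                members = np.array(members)
                best = best_split_partitions(
                    Xb[members], yb[members], wb[members], params.min_samples_leaf
                )
                local_left = tuple(
                    int(np.searchsorted(members, i)) for i in left
                )
                assert local_left in best
                checked += 1
        assert checked >= 3  # at least one split per tree

    def test_plateau_split_point_and_leaf_means(self):
        """1-D response with two plateaus: the single split must separate
        them and the leaves reproduce the plateau values."""
        X = np.arange(10, dtype=float).reshape(-1, 1)
        y = np.array([1.0] * 5 + [5.0] * 5)
        ds = Dataset(
            [f"s{i}" for i in range(10)], ["g"], X, y, binarize(y, 3.0), 3.0
        )
        forest = fit_forest(
            ds, uniform_sample_weights(10), ForestParams(B=1, m=1, min_samples_leaf=2, seed=0)
        )
        tree = forest.trees[0]
        assert 4.0 <= tree.threshold[0] < 5.0
        leaf_vals = sorted(tree.leaf_value[tree.leaf_ids()])
        assert leaf_vals == pytest.approx([1.0, 5.0])

    def test_single_class_training_forces_constant_class(self, toy):
        idx = np.flatnonzero(toy.Y == 0)
        sub = toy.subset(idx)
        forest = fit_forest(
            sub, uniform_sample_weights(sub.n_samples), ForestParams(B=5, m=3, min_samples_leaf=2, seed=1)
        )
        for tree in forest.trees:
            assert np.all(tree.leaf_class[tree.leaf_ids()] == 0)
        assert np.all(forest.predict_class(toy.X) == 0)

    def test_fit_validation_errors(self, toy):
        with pytest.raises(ValueError, match="m="):
            fit_forest(toy, params=ForestParams(B=1, m=7, min_samples_leaf=2))
        with pytest.raises(ValueError, match="at least"):
            fit_forest(toy, params=ForestParams(B=1, m=2, min_samples_leaf=8))


class TestVoting:
    def make_forest(self, classes, values, masses=None):
        trees = []
        for i, (c, v) in enumerate(zip(classes, values)):
            if masses is None:
                m0, m1 = (2.0, 1.0) if c == 0 else (1.0, 2.0)
            else:
                m0, m1 = masses[i]
            trees.append(single_leaf_tree(v, c, m0, m1))
        params = ForestParams(B=len(trees), m=1, min_samples_leaf=1, seed=0)
        return SauronForest(trees, params, ["g"], "uniform")

    def test_majority_vote(self):
        f = self.make_forest([1, 1, 0], [0.0, 0.0, 0.0])
        assert f.predict_class([[0.0]])[0] == 1

    def test_unanimous_vote_all_indicators_one(self):
        f = self.make_forest([1, 1, 1], [0.0, 0.0, 0.0])
        w = f.tree_weights([[0.0]], "binary")[0]
        assert np.allclose(w, 1 / 3)

    def test_tie_goes_to_resistant(self):
        f = self.make_forest([1, 0], [0.0, 0.0])
        assert f.predict_class([[0.0]])[0] == 0

    def test_feature_length_mismatch_rejected(self):
        f = self.make_forest([1, 0], [0.0, 0.0])
        with pytest.raises(ValueError, match="features"):
            f.predict_class([[0.0, 1.0]])


class TestTreeWeights:
    def test_binary_weights_from_agreeing_trees(self):
        f = TestVoting().make_forest([1, 1, 1, 0], [0.0] * 4)
        w = f.tree_weights([[0.0]], "binary")[0]
        assert w == pytest.approx([1 / 3, 1 / 3, 1 / 3, 0.0])

    def test_binary_sens_uniform_when_resistant_predicted(self):
        f = TestVoting().make_forest([0, 0, 0, 1], [0.0] * 4)
        w = f.tree_weights([[0.0]], "binary_sens")[0]
        assert w == pytest.approx([0.25] * 4)

    def test_majority_weights_from_agree_fractions(self):
        """Leaf agree-fractions 1.0 and 0.5 for the forest's class give
        weights 2/3 and 1/3."""
        f = TestVoting().make_forest(
            [1, 1], [2.0, 5.0], masses=[(0.0, 2.0), (1.0, 1.0)]
        )
        w = f.tree_weights([[0.0]], "majority")[0]
        assert w == pytest.approx([2 / 3, 1 / 3])
        assert f.predict_value([[0.0]], "majority")[0] == pytest.approx(3.0)

    def test_majority_sens_uniform_when_resistant_predicted(self):
        f = TestVoting().make_forest(
            [0, 0, 1], [1.0, 2.0, 3.0], masses=[(2.0, 0.0), (1.5, 0.5), (0.5, 1.5)]
        )
        w = f.tree_weights([[0.0]], "majority_sens")[0]
        assert w == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_unknown_scheme_rejected(self):
        f = TestVoting().make_forest([1, 0], [0.0, 0.0])
        with pytest.raises(ValueError, match="scheme"):
            f.tree_weights([[0.0]], "harmonic")

    def test_all_schemes_sum_to_one_random_forests(self, small_imbalanced):
        ds = small_imbalanced
        forest = fit_forest(
            ds,
            simple_sample_weights(ds.Y),
            ForestParams(B=20, m=8, min_samples_leaf=3, seed=5),
        )
        rng = np.random.default_rng(0)
        Xq = rng.standard_normal((40, ds.n_genes))
        for scheme in ("uniform", "binary", "binary_sens", "majority", "majority_sens"):
            w = forest.tree_weights(Xq, scheme)
            assert np.allclose(w.sum(axis=1), 1.0, atol=1e-12)


class TestPredictValue:
    def test_binary_weighting_hand_example(self):
        """Three trees with leaf means 2, 4, 10 and classes (1,1,0): the
        forest predicts class 1 and the binary-weighted value (2+4)/2 = 3."""
        f = TestVoting().make_forest([1, 1, 0], [2.0, 4.0, 10.0])
        assert f.predict_class([[0.0]])[0] == 1
        assert f.predict_value([[0.0]], "binary")[0] == pytest.approx(3.0)

    def test_uniform_equals_conventional_rf(self, small_imbalanced):
        ds = small_imbalanced
        forest = fit_forest(
            ds, uniform_sample_weights(ds.n_samples), ForestParams(B=10, m=8, min_samples_leaf=5, seed=2)
        )
        vals = forest.tree_values(ds.X[:20])
        assert forest.predict_value(ds.X[:20], "uniform") == pytest.approx(
            vals.mean(axis=1)
        )

    def test_unanimous_forest_binary_equals_uniform(self):
        f = TestVoting().make_forest([1, 1, 1], [1.0, 2.0, 6.0])
        assert f.predict_value([[0.0]], "binary")[0] == pytest.approx(
            f.predict_value([[0.0]], "uniform")[0]
        )

    def test_single_class_all_schemes_identical(self, toy):
        """With uniform weights and one-class data every scheme reduces to
        the conventional regression forest."""
        sub = toy.subset(np.flatnonzero(toy.Y == 0))
        forest = fit_forest(
            sub, uniform_sample_weights(sub.n_samples), ForestParams(B=6, m=3, min_samples_leaf=2, seed=3)
        )
        ref = forest.predict_value(toy.X, "uniform")
        for scheme in ("binary", "binary_sens", "majority", "majority_sens"):
            assert forest.predict_value(toy.X, scheme) == pytest.approx(ref)

    def test_prediction_result_contract(self, toy):
        forest = fit_forest(
            toy, simple_sample_weights(toy.Y), ForestParams(B=4, m=2, min_samples_leaf=2, seed=9, tree_weighting="binary_sens")
        )
        for pr in forest.predict(toy.X):
            assert pr.tree_weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert pr.predicted_value == pytest.approx(
                float(pr.tree_weights @ pr.tree_values)
            )
            assert pr.predicted_class in (0, 1)


class TestLeafAnnotations:
    def test_resubstitution_weighted_means(self, toy):
        """Each leaf's stored value equals the weighted mean of its
        bootstrap members, recomputed from scratch."""
        weights = distance_sample_weights(toy.y, toy.Y, toy.t, d=1)
        forest = fit_forest(toy, weights, ForestParams(B=4, m=3, min_samples_leaf=2, seed=21))
        for tree in forest.trees:
            Xb = toy.X[tree.bootstrap_idx]
            yb = toy.y[tree.bootstrap_idx]
            wb = weights.w_star[tree.bootstrap_idx]
            leaves = tree.apply(Xb)
            for leaf in tree.leaf_ids():
                mask = leaves == leaf
                assert mask.any()
                expected = float((wb[mask] * yb[mask]).sum() / wb[mask].sum())
                assert tree.leaf_value[leaf] == pytest.approx(expected, rel=1e-12)
                assert tree.mass1[leaf] == pytest.approx(wb[mask][toy.Y[tree.bootstrap_idx][mask] == 1].sum())

    def test_min_samples_leaf_respected(self, toy):
        forest = fit_forest(toy, params=ForestParams(B=5, m=2, min_samples_leaf=3, seed=4))
        for tree in forest.trees:
            counts = tree.count0 + tree.count1
            assert np.all(counts[tree.leaf_ids()] >= 3)


class TestFeatureImportances:
    def test_stump_forest_concentrates_on_split_gene(self):
        X = np.column_stack([np.arange(10, dtype=float), np.ones(10)])
        y = np.array([0.0] * 5 + [4.0] * 5)
        ds = Dataset([f"s{i}" for i in range(10)], ["gA", "gB"], X, y, binarize(y, 2.0), 2.0)
        forest = fit_forest(ds, params=ForestParams(B=10, m=2, min_samples_leaf=5, seed=0))
        imp = forest.feature_importances()
        assert imp[0] == pytest.approx(1.0)
        assert imp[1] == pytest.approx(0.0)

    def test_importances_sum_to_one(self, small_imbalanced):
        forest = fit_forest(
            small_imbalanced, params=ForestParams(B=10, m=8, min_samples_leaf=5, seed=1)
        )
        assert forest.feature_importances().sum() == pytest.approx(1.0)


class TestSerialization:
    def test_roundtrip_replays_predictions_exactly(self, toy, tmp_path):
        forest = fit_forest(
            toy,
            simple_sample_weights(toy.Y),
            ForestParams(B=5, m=2, min_samples_leaf=2, seed=8, tree_weighting="majority"),
        )
        path = tmp_path / "forest.json"
        forest.save(path)
        loaded = SauronForest.load(path)
        rng = np.random.default_rng(1)
        Xq = rng.standard_normal((15, toy.n_genes))
        for scheme in ("uniform", "binary", "binary_sens", "majority", "majority_sens"):
            assert np.array_equal(
                forest.predict_value(Xq, scheme), loaded.predict_value(Xq, scheme)
            )
        assert np.array_equal(forest.predict_class(Xq), loaded.predict_class(Xq))
        # the serialized form is valid documented JSON
        d = json.loads(path.read_text())
        assert d["format"] == "sauronrf-forest-v1"
        assert len(d["trees"]) == 5
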