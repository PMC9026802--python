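"""CART growing, prediction, importance and the published fixed-cutoff trees."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pmtperf.cart import (
    CartModel,
    DecisionTree,
    TreeNode,
    _best_split,
    gini,
    grow_tree,
    published_tree,
    variable_importance,
    PMT3_CUTOFFS,
    LYMPHOMA_VOLUME_CUTOFF,
    INVASIVENESS_CUTOFFS,
)


def brute_force_best_split(X, y_codes, n_classes, min_leaf=1):
    """Naive double loop over every feature and candidate midpoint, same
    tie-break rules (impurity, then feature order, then threshold)."""
    n, p = X.shape
    best = None
    for j in range(p):
        vals = np.sort(np.unique(X[:, j]))
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            left = X[:, j] <= thr
            nl, nr = left.sum(), (~left).sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            cl = np.bincount(y_codes[left], minlength=n_classes).astype(float)
            cr = np.bincount(y_codes[~left], minlength=n_classes).astype(float)
            g = (nl * gini(cl) + nr * gini(cr)) / n
            if best is None or g < best[2] or (g == best[2] and (j, thr) < (best[0], best[1])):
                best = (j, thr, g)
    return best


class TestSplitSearch:
    def test_perfectly_separable_1d(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 8.0, 9.0]})
        y = ["A", "A", "B", "B"]
        res = grow_tree(X, y, max_depth=5, min_samples_split=2, min_samples_leaf=1)
        root = res.tree.root
        assert root.feature == "x" and root.threshold == 5.0
        assert root.left.is_leaf and root.right.is_leaf
        assert res.training_accuracy() == 1.0

    @given(st.data())
    @settings(max_examples=120, deadline=None, derandomize=True)
    def test_split_matches_exhaustive_oracle(self, data):
        n = data.draw(st.integers(2, 12))
        p = data.draw(st.integers(1, 3))
        X = np.array(
            [[data.draw(st.integers(0, 8)) for _ in range(p)] for _ in range(n)],
            dtype=float,
        )
        y = np.array([data.draw(st.integers(0, 2)) for _ in range(n)])
        got = _best_split(X, y, n_classes=3, min_samples_leaf=1)
        want = brute_force_best_split(X, y, n_classes=3, min_leaf=1)
        if want is None:
            assert got is None
        else:
            assert got[0] == want[0] and got[1] == want[1]
            assert got[2] == pytest.approx(want[2], abs=1e-12)

    def test_constant_features_skipped(self):
        X = pd.DataFrame({"c": [1.0] * 6, "x": [1, 2, 3, 7, 8, 9.0]})
        y = ["A"] * 3 + ["B"] * 3
        res = grow_tree(X, y, min_samples_split=2, min_samples_leaf=1)
        assert res.tree.root.feature == "x"

    def test_single_class_gives_single_leaf(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        res = grow_tree(X, ["A"] * 4)
        assert res.tree.root.is_leaf

    def test_zero_training_error_when_unbounded(self, rng):
        # no conflicting duplicate rows -> unlimited tree is exact
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.choice(["u", "v", "w"], size=40)
        res = grow_tree(X, y, max_depth=64, min_samples_split=2, min_samples_leaf=1)
        assert res.training_accuracy() == 1.0

    def test_depth_limit_respected(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)))
        y = rng.choice(["a", "b"], size=60)
        res = grow_tree(X, y, max_depth=2, min_samples_split=2, min_samples_leaf=1)
        assert res.tree.depth <= 2

    def test_missing_values_rejected(self):
        X = pd.DataFrame({"x": [1.0, np.nan, 3.0, 4.0]})
        with pytest.raises(ValueError):
            CartModel(X, ["A", "A", "B", "B"])

    def test_root_split_agrees_with_sklearn(self, rng):
        # independent implementation cross-check on a clean two-class problem
        sklearn_tree = pytest.importorskip("sklearn.tree")
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = np.where(X["b"] + 0.3 * rng.normal(size=50) > 0, "pos", "neg")
        ours = grow_tree(X, y, max_depth=1, min_samples_split=2, min_samples_leaf=1)
        sk = sklearn_tree.DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        assert ours.tree.root.feature == X.columns[sk.tree_.feature[0]]
        # sklearn casts features to float32 before computing midpoints
        assert ours.tree.root.threshold == pytest.approx(sk.tree_.threshold[0], rel=1e-6)


class TestPredict:
    def test_boundary_value_goes_left(self):
        tree = published_tree("pmt3")
        row = {"age_yr": 32.0, "ktrans": 1, "kep": 1, "vp": 1, "ve": 1,
               "ttp_s": 1, "cmax": 1, "volume_mm3": 1, "surface_mm2": 1, "maxdiam_mm": 1}
        assert tree.predict_row(row) == "lymphoma"

    def test_missing_feature_rejected(self):
        tree = published_tree("pmt3")
        with pytest.raises(KeyError):
            tree.predict_row({"ktrans": 1.0})

    def test_agrees_with_naive_recursive_evaluator(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = rng.choice(["p", "q"], size=30)
        tree = grow_tree(X, y, max_depth=4, min_samples_split=2, min_samples_leaf=1).tree

        def naive(node, row):
            if node.is_leaf:
                return node.prediction
            return naive(node.left if row[node.feature] <= node.threshold else node.right, row)

        rows = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        got = tree.predict(rows)
        want = [naive(tree.root, r) for _, r in rows.iterrows()]
        assert list(got) == want


class TestImportance:
    def test_single_split_tree(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 8.0, 9.0], "z": [5.0, 5.0, 5.0, 5.0]})
        res = grow_tree(X, ["A", "A", "B", "B"], min_samples_split=2, min_samples_leaf=1)
        imp = res.importance().set_index("feature")
        assert imp.loc["x", "normalized"] == 100.0
        assert imp.loc["z", "normalized"] == 0.0

    def test_duplicate_feature_tie_break_deterministic(self):
        X = pd.DataFrame({"x1": [1.0, 2.0, 8.0, 9.0], "x2": [1.0, 2.0, 8.0, 9.0]})
        res = grow_tree(X, ["A", "A", "B", "B"], min_samples_split=2, min_samples_leaf=1)
        imp = res.importance().set_index("feature")
        # earlier column wins the tie and takes all the importance
        assert imp.loc["x1", "normalized"] == 100.0
        assert imp.loc["x2", "normalized"] == 0.0

    def test_hand_computed_impurity_decrease(self):
        # 6 samples, one split at x<=4: parent gini 0.5 -> children (pure, pure)
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 6.0, 7.0, 8.0]})
        y = ["A"] * 3 + ["B"] * 3
        res = grow_tree(X, y, min_samples_split=2, min_samples_leaf=1)
        imp = res.importance().set_index("feature")
        assert imp.loc["x", "raw"] == pytest.approx(0.5)  # (1.0)*(0.5 - 0)

    def test_stump_free_tree_all_zero(self):
        X = pd.DataFrame({"x": [1.0, 2.0]})
        res = grow_tree(X, ["A", "A"])
        assert (res.importance()["raw"] == 0).all()

    def test_max_normalized_is_100_when_split_exists(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        y = rng.choice(["a", "b"], 30)
        res = grow_tree(X, y, max_depth=3, min_samples_split=2, min_samples_leaf=1)
        if not res.tree.root.is_leaf:
            assert res.importance()["normalized"].max() == 100.0


class TestPublishedTrees:
    def test_pmt3_thresholds(self):
        tree = published_tree("pmt3")
        root = tree.root
        assert root.feature == "age_yr" and root.threshold == 32.0
        ve_node = root.right
        assert ve_node.feature == "ve" and ve_node.threshold == 0.175
        kep_node = ve_node.right
        assert kep_node.feature == "kep" and kep_node.threshold == 2.649

    def test_lymphoma_volume_threshold(self):
        tree = published_tree("lymphoma_subtype")
        assert tree.root.feature == "volume_mm3"
        assert tree.root.threshold == 45183.50 == LYMPHOMA_VOLUME_CUTOFF

    def test_invasiveness_thresholds(self):
        tree = published_tree("thymoma_invasiveness")
        assert tree.root.feature == "kep" and tree.root.threshold == 2.1489
        assert tree.root.left.feature == "kep" and tree.root.left.threshold == 1.009

    def test_young_patient_routed_to_lymphoma(self, feature_row):
        row = dict(feature_row, age_yr=25.0)
        assert published_tree("pmt3").predict_row(row) == "lymphoma"

    def test_orientation_override(self, feature_row):
        tree = published_tree("pmt3", orientation={"young": "thymoma"})
        assert tree.predict_row(dict(feature_row, age_yr=25.0)) == "thymoma"
        with pytest.raises(ValueError):
            published_tree("pmt3", orientation={"nonsense": "x"})

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            published_tree("not_a_tree")

    def test_depths_match_published_settings(self):
        assert published_tree("pmt3").depth == 3
        assert published_tree("lymphoma_subtype").depth == 1
        assert published_tree("thymoma_invasiveness").depth == 2


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.choice(["u", "v"], 40)
        tree = grow_tree(X, y, max_depth=3, min_samples_split=2, min_samples_leaf=1).tree
        path = tmp_path / "tree.json"
        tree.to_json(path)
        back = DecisionTree.from_json(path)
        rows = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        assert list(tree.predict(rows)) == list(back.predict(rows))

    def test_dot_export_contains_rules(self):
        dot = published_tree("pmt3").to_dot()
        assert "digraph" in dot and "age_yr" in dot and "lymphoma" in dot
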