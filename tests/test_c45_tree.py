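"""Gain-ratio tree induction: split selection, pruning, text round trip."""

import math

import numpy as np
import pytest

from metabroscreen.c45_tree import (
    TreeConfig,
    best_split,
    build_tree,
    entropy,
    gain_ratio,
    parse_text,
    predict,
    predict_matrix,
    to_text,
    tree_from_json,
    tree_size,
    tree_to_json,
)


def _gain_ratio_oracle(parent, children):
    """Direct textbook evaluation, independent of the package formulas."""
    def h(counts):
        tot = sum(counts)
        return -sum(c / tot * math.log2(c / tot) for c in counts if c) if tot else 0.0

    tot = sum(parent)
    gain = h(parent) - sum(sum(c) / tot * h(c) for c in children)
    split = -sum(
        sum(c) / tot * math.log2(sum(c) / tot) for c in children if sum(c)
    )
    return gain / split if split else 0.0


class TestEntropyGainRatio:
    def test_balanced_binary_entropy_is_one_bit(self):
        assert entropy((2, 2)) == pytest.approx(1.0)

    def test_pure_node_entropy_zero(self):
        assert entropy((5, 0)) == 0.0

    def test_perfect_split_has_unit_gain_ratio(self):
        assert gain_ratio((2, 2), [(2, 0), (0, 2)]) == pytest.approx(1.0)

    def test_matches_independent_formula_on_random_tables(self, rng):
        for _ in range(50):
            left = rng.integers(0, 8, size=2)
            right = rng.integers(0, 8, size=2)
            parent = left + right
            if parent.sum() == 0:
                continue
            got = gain_ratio(parent, [left, right])
            want = _gain_ratio_oracle(parent.tolist(), [left.tolist(), right.tolist()])
            assert got == pytest.approx(want, abs=1e-12)
            assert 0.0 <= got <= 1.0 + 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            entropy((-1, 2))
        with pytest.raises(ValueError):
            gain_ratio((1, 1), [(2, 0), (-1, 1)])


class TestBestSplit:
    CFG = TreeConfig(min_leaf=1)

    def test_unique_perfect_split_midpoint(self):
        res = best_split([1, 2, 3, 4], ["case", "case", "control", "control"], self.CFG)
        assert res is not None
        assert res[0] == pytest.approx(2.5)
        assert res[1] == pytest.approx(1.0)

    def test_pure_node_has_no_split(self):
        assert best_split([1, 2, 3], ["case", "case", "case"], self.CFG) is None

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            v = np.round(rng.normal(size=n), 1)  # duplicates likely
            y = np.where(rng.random(n) < 0.5, "case", "control")
            if len(set(y)) < 2:
                continue
            got = best_split(v, y, self.CFG)
            # brute force over all midpoints with the independent formula
            sv = np.sort(np.unique(v))
            entries = []
            for a, b in zip(sv[:-1], sv[1:]):
                thr = (a + b) / 2
                lm = v <= thr
                left = [(y[lm] == "case").sum(), (y[lm] == "control").sum()]
                right = [(y[~lm] == "case").sum(), (y[~lm] == "control").sum()]
                parent = [left[0] + right[0], left[1] + right[1]]
                tot = sum(parent)

                def hh(c):
                    t = sum(c)
                    return -sum(x / t * math.log2(x / t) for x in c if x) if t else 0.0

                gain = (hh(parent) - (sum(left) / tot) * hh(left)
                        - (sum(right) / tot) * hh(right))
                entries.append((thr, gain, _gain_ratio_oracle(parent, [left, right])))
            mean_gain = np.mean([e[1] for e in entries])
            admissible = [e for e in entries if e[1] >= mean_gain - 1e-12]
            best = max(admissible, key=lambda e: (e[2], -e[0])) if admissible else None
            if got is None:
                assert best is None or best[1] <= 0
            else:
                assert got[1] == pytest.approx(best[2], abs=1e-12)
                assert got[0] == pytest.approx(best[0])


class TestBuildTree:
    def test_linearly_separable_gives_depth_one_perfect_tree(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        y = np.array(["control", "control", "case", "case"])
        tree = build_tree(X, y, ["ion_a"], TreeConfig(min_leaf=1, prune=False))
        assert tree_size(tree) == 3
        pred = predict_matrix(tree, X, ["ion_a"])
        assert (pred == y).all()

    def test_unpruned_tree_memorises_consistent_data(self, rng):
        cfg = TreeConfig(min_leaf=1, prune=False)
        for _ in range(20):
            n = int(rng.integers(8, 40))
            X = rng.normal(size=(n, 3))
            # labels a deterministic function of X => consistent, tie-free
            y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0, "case", "control")
            if len(set(y)) < 2:
                continue
            tree = build_tree(X, y, ["a", "b", "c"], cfg)
            pred = predict_matrix(tree, X, ["a", "b", "c"])
            assert (pred == y).all()

    def test_pruned_never_larger_and_never_better_on_train(self, rng):
        for _ in range(15):
            n = 40
            X = rng.normal(size=(n, 4))
            y = np.where(
                (X[:, 0] > 0) ^ (rng.random(n) < 0.25), "case", "control"
            )
            if len(set(y)) < 2:
                continue
            ions = list("abcd")
            unpruned = build_tree(X, y, ions, TreeConfig(min_leaf=1, prune=False))
            pruned = build_tree(X, y, ions, TreeConfig(min_leaf=1, prune=True))
            assert tree_size(pruned) <= tree_size(unpruned)
            err_u = (predict_matrix(unpruned, X, ions) != y).sum()
            err_p = (predict_matrix(pruned, X, ions) != y).sum()
            assert err_p >= err_u

    def test_invariant_under_monotone_transformation(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.where(X[:, 0] - X[:, 2] > 0.3, "case", "control")
        ions = list("abc")
        cfg = TreeConfig(min_leaf=2, prune=True)
        t1 = build_tree(X, y, ions, cfg)
        Xm = X.copy()
        Xm[:, 1] = np.exp(Xm[:, 1])  # strictly monotone on one ion
        t2 = build_tree(Xm, y, ions, cfg)
        Xtest = rng.normal(size=(50, 3))
        Xtest_m = Xtest.copy()
        Xtest_m[:, 1] = np.exp(Xtest_m[:, 1])
        assert (predict_matrix(t1, Xtest, ions) == predict_matrix(t2, Xtest_m, ions)).all()

    def test_single_class_or_empty_raises(self):
        with pytest.raises(ValueError):
            build_tree(np.ones((3, 1)), np.array(["case"] * 3), ["a"])
        with pytest.raises(ValueError):
            build_tree(np.empty((0, 1)), np.array([]), ["a"])


class TestPredictAndText:
    @staticmethod
    def _toy_tree():
        X = np.array([[1.0, 5.0], [2.0, 6.0], [10.0, 5.5], [11.0, 7.0],
                      [1.5, 9.0], [10.5, 9.5]])
        y = np.array(["control", "control", "case", "case", "control", "case"])
        return build_tree(X, y, ["ion_a", "ion_b"], TreeConfig(min_leaf=1, prune=False))

    def test_routing_below_threshold_goes_left(self):
        tree = self._toy_tree()
        assert predict(tree, {"ion_a": 0.0, "ion_b": 0.0}) == "control"
        assert predict(tree, {"ion_a": 100.0, "ion_b": 0.0}) == "case"

    def test_missing_ion_error_names_ion(self):
        tree = self._toy_tree()
        with pytest.raises(KeyError, match="ion_a"):
            predict(tree, {"ion_b": 1.0})

    def test_text_round_trip_predicts_identically(self, rng):
        tree = self._toy_tree()
        text = to_text(tree)
        back = parse_text(text)
        for _ in range(50):
            sample = {"ion_a": float(rng.uniform(0, 12)),
                      "ion_b": float(rng.uniform(4, 10))}
            assert predict(tree, sample) == predict(back, sample)

    def test_text_lists_both_branches_with_thresholds(self):
        tree = self._toy_tree()
        lines = to_text(tree).splitlines()
        assert sum("<=" in ln for ln in lines) == sum(">" in ln and "<=" not in ln for ln in lines)
        assert any(ln.lstrip("| ").startswith(":") for ln in lines)

    def test_json_round_trip(self, tmp_path):
        tree = self._toy_tree()
        tree_to_json(tree, tmp_path / "t.json")
        back = tree_from_json(tmp_path / "t.json")
        assert to_text(back) == to_text(tree)
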