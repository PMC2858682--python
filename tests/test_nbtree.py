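"""Classifier core: MDL discretization, Naive-Bayes leaves, tree
induction, routing, and model serialization."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from cnvtriage.nbtree import (
    CLASSES,
    Discretization,
    ModelFormatError,
    NaiveBayesLeaf,
    NbTreeParams,
    classify,
    classify_table,
    load_model,
    mdl_cut_points,
    nb_posterior,
    save_model,
    train_nb_leaf,
    train_nbtree,
)


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation's code paths)
# ---------------------------------------------------------------------------

def _entropy(counts):
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    return -sum(c / n * math.log2(c / n) for c in counts)


def _oracle_mdl(values, labels01):
    """Exhaustive recursive MDL partitioning: every distinct-value
    midpoint is scored; the best-gain cut is kept iff it passes the MDL
    criterion."""
    pairs = sorted(zip(values, labels01))
    v = [p[0] for p in pairs]
    y = [p[1] for p in pairs]

    def recurse(v, y, out):
        n = len(v)
        if n < 2 or len(set(y)) < 2:
            return
        e_all = _entropy([y.count(0), y.count(1)])
        best = None
        for i in range(1, n):
            if v[i] <= v[i - 1]:
                continue
            l, r = y[:i], y[i:]
            el = _entropy([l.count(0), l.count(1)])
            er = _entropy([r.count(0), r.count(1)])
            gain = e_all - (i / n) * el - ((n - i) / n) * er
            if best is None or gain > best[0]:
                best = (gain, i, el, er)
        if best is None:
            return
        gain, i, el, er = best
        l, r = y[:i], y[i:]
        k1 = len(set(l))
        k2 = len(set(r))
        delta = math.log2(3**2 - 2) - (2 * e_all - k1 * el - k2 * er)
        if gain <= (math.log2(n - 1) + delta) / n:
            return
        out.append((v[i - 1] + v[i]) / 2)
        recurse(v[:i], y[:i], out)
        recurse(v[i:], y[i:], out)

    out = []
    recurse(v, y, out)
    return sorted(out)


def _oracle_posterior(leaf: NaiveBayesLeaf, row: dict) -> float:
    """Brute-force log-space Bayes product over the leaf's tables."""
    logp = [math.log(leaf.priors[0]), math.log(leaf.priors[1])]
    for name in leaf.feature_names:
        value = row.get(name)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        if leaf.kinds[name] == "continuous":
            cuts = leaf.cut_points[name]
            b = sum(1 for c in cuts if value > c)
        else:
            if value not in leaf.categories[name]:
                continue
            b = leaf.categories[name].index(value)
        for c in (0, 1):
            logp[c] += math.log(leaf.cond[name][b, c])
    m = max(logp)
    w = [math.exp(x - m) for x in logp]
    return w[1] / (w[0] + w[1])


def _random_frame(rng, n, informative=True):
    y = np.where(rng.random(n) < 0.5, "mr", "benign")
    shift = (y == "mr").astype(float) if informative else 0.0
    df = pd.DataFrame(
        {
            "f1": rng.normal(size=n) + 1.2 * shift,
            "f2": rng.normal(size=n),
            "f3": np.where(rng.random(n) < 0.1, np.nan, rng.normal(size=n) - 0.8 * shift),
            "flag": rng.random(n) < (0.2 + 0.5 * shift),
            "kind": np.where(rng.random(n) < (0.3 + 0.3 * shift), "gain", "loss"),
        }
    )
    return df, y


# ---------------------------------------------------------------------------
# MDL discretization
# ---------------------------------------------------------------------------

class TestMdlCutPoints:
    def test_perfect_separation_single_cut(self):
        cuts = mdl_cut_points([1, 2, 3, 4], ["benign", "benign", "mr", "mr"])
        assert len(cuts) == 1 and 2 < cuts[0] < 3

    def test_pure_labels_no_cut(self):
        assert mdl_cut_points([1, 2, 3, 4], ["mr"] * 4) == []
        assert mdl_cut_points([5, 1, 9, 2], ["benign"] * 4) == []

    def test_constant_values_no_cut(self):
        assert mdl_cut_points([5, 5, 5, 5], ["mr", "benign", "mr", "benign"]) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle_on_gaussian_mixture(self, seed):
        rng = np.random.default_rng(seed)
        y01 = (rng.random(50) < 0.5).astype(int)
        v = rng.normal(loc=2.0 * y01, scale=1.0)
        labels = np.where(y01 == 1, "mr", "benign")
        assert mdl_cut_points(v, labels) == pytest.approx(_oracle_mdl(v, list(y01)))

    def test_nan_values_ignored(self):
        v = [1, 2, np.nan, 3, 4, np.nan]
        lab = ["benign", "benign", "mr", "mr", "mr", "benign"]
        assert mdl_cut_points(v, lab) == mdl_cut_points([1, 2, 3, 4], ["benign", "benign", "mr", "mr"])

    def test_discretization_bins_respect_boundaries(self):
        d = Discretization("x", (1.0, 3.0))
        assert [d.bin(v) for v in (0.5, 1.0, 2.0, 3.0, 3.1)] == [0, 0, 1, 1, 2]
        assert d.bin(float("nan")) == -1
        with pytest.raises(ValueError):
            Discretization("x", (3.0, 1.0))


# ---------------------------------------------------------------------------
# Naive-Bayes leaf
# ---------------------------------------------------------------------------

class TestNaiveBayesLeaf:
    def test_laplace_smoothing_formula(self):
        X = pd.DataFrame({"f": [True] * 4 + [False] * 4})
        y = ["mr"] * 4 + ["benign"] * 4
        leaf = train_nb_leaf(X, y, laplace=1)
        # P(f=True | mr) = (4 + 1) / (4 + 2)
        assert leaf.cond["f"][1, 1] == pytest.approx(5 / 6)
        assert leaf.cond["f"][1, 0] == pytest.approx(1 / 6)

    def test_all_missing_feature_yields_uniform_conditionals(self):
        X = pd.DataFrame({"f": [np.nan] * 6, "g": [1.0, 2, 3, 4, 5, 6]})
        y = ["mr", "benign"] * 3
        leaf = train_nb_leaf(X, y)
        assert np.allclose(leaf.cond["f"], 1.0 / leaf.cond["f"].shape[0])

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            train_nb_leaf(pd.DataFrame({"f": []}), [])

    def test_probability_invariants(self):
        rng = np.random.default_rng(1)
        X, y = _random_frame(rng, 60)
        leaf = train_nb_leaf(X, y)
        assert leaf.priors.sum() == pytest.approx(1.0, abs=1e-12)
        for name, table in leaf.cond.items():
            assert np.all(table > 0)
            assert np.allclose(table.sum(axis=0), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_posterior_matches_bruteforce_product(self, seed):
        rng = np.random.default_rng(100 + seed)
        X, y = _random_frame(rng, 30)
        leaf = train_nb_leaf(X, y)
        for _, row in X.head(10).iterrows():
            expected = _oracle_posterior(leaf, row.to_dict())
            assert nb_posterior(leaf, row.to_dict()) == pytest.approx(expected, abs=1e-10)


class TestNbPosterior:
    def _uniform_leaf(self, ratio=0.5):
        return NaiveBayesLeaf(
            feature_names=["f"],
            kinds={"f": "categorical"},
            cut_points={},
            categories={"f": [False, True]},
            priors=np.array([0.5, 0.5]),
            cond={"f": np.array([[1 - ratio, ratio], [ratio, 1 - ratio]])[::-1]},
            laplace=1.0,
            n_train=10,
            class_counts=np.array([5.0, 5.0]),
        )

    def test_no_evidence_gives_half(self):
        leaf = self._uniform_leaf()
        assert nb_posterior(leaf, {"f": None}) == pytest.approx(0.5)

    def test_nine_to_one_ratio(self):
        leaf = NaiveBayesLeaf(
            feature_names=["f"],
            kinds={"f": "categorical"},
            cut_points={},
            categories={"f": [False, True]},
            priors=np.array([0.5, 0.5]),
            cond={"f": np.array([[0.9, 0.1], [0.1, 0.9]])},  # P(True|mr)=0.9
            laplace=1.0,
            n_train=10,
            class_counts=np.array([5.0, 5.0]),
        )
        assert nb_posterior(leaf, {"f": True}) == pytest.approx(0.9)

    def test_monotone_evidence(self):
        """Strengthening the class-conditional ratio toward mr never
        lowers the posterior."""
        X = pd.DataFrame({"f": [True, True, False, False]})
        base = {"f": True}
        last = -1.0
        for r in (0.5, 0.6, 0.8, 0.95):
            leaf = NaiveBayesLeaf(
                feature_names=["f"],
                kinds={"f": "categorical"},
                cut_points={},
                categories={"f": [False, True]},
                priors=np.array([0.5, 0.5]),
                cond={"f": np.array([[r, 1 - r], [1 - r, r]])},
                laplace=1.0,
                n_train=4,
                class_counts=np.array([2.0, 2.0]),
            )
            p = nb_posterior(leaf, base)
            assert p >= last
            last = p


# ---------------------------------------------------------------------------
# Tree induction
# ---------------------------------------------------------------------------

class TestTrainNbTree:
    def test_depth_zero_equals_plain_naive_bayes(self):
        rng = np.random.default_rng(5)
        X, y = _random_frame(rng, 120)
        model = train_nbtree(X, y, NbTreeParams(max_depth=0, seed=0))
        leaf = train_nb_leaf(X, y)
        tree_post = classify_table(model, X)["mr_distance"].to_numpy()
        leaf_post = leaf.posterior_array(X)
        assert np.allclose(tree_post, leaf_post, atol=1e-10)

    def test_linearly_separable_training_accuracy_is_one(self):
        rng = np.random.default_rng(9)
        n = 200
        y = np.where(np.arange(n) < n // 2, "mr", "benign")
        X = pd.DataFrame(
            {
                "a": np.where(y == "mr", 1, 0) * 10 + rng.normal(scale=0.5, size=n),
                "b": rng.normal(size=n),
            }
        )
        model = train_nbtree(X, y, NbTreeParams(seed=2))
        pred = classify_table(model, X)["predicted"].to_numpy()
        assert (pred == y).all()

    def test_single_class_input_predicts_that_class(self):
        X = pd.DataFrame({"a": np.arange(40.0)})
        model = train_nbtree(X, ["benign"] * 40, NbTreeParams(seed=0))
        res = classify(model, {"a": 5.0})
        assert res.predicted_class == "benign" and res.mr_distance < 0.5

    def test_determinism_and_label_swap_symmetry(self):
        rng = np.random.default_rng(12)
        X, y = _random_frame(rng, 150)
        p = NbTreeParams(seed=33)
        d1 = classify_table(train_nbtree(X, y, p), X)["mr_distance"]
        d2 = classify_table(train_nbtree(X, y, p), X)["mr_distance"]
        assert (d1 == d2).all()
        swapped = np.where(y == "mr", "benign", "mr")
        d3 = classify_table(train_nbtree(X, swapped, p), X)["mr_distance"]
        assert np.allclose(d3, 1.0 - d1, atol=1e-10)

    def test_splits_when_structure_demands_it(self, small_dataset_final):
        X, y = small_dataset_final
        model = train_nbtree(X, y, NbTreeParams(seed=0))
        assert model.n_leaves == model.n_split_nodes + 1  # binary-split tree... per-node arity >= 2
        assert model.depth >= 1


class TestClassify:
    def test_threshold_strictly_above_half(self, trained_model, small_dataset_final):
        model, _, test = trained_model
        X, _ = small_dataset_final
        res = classify_table(model, X.iloc[test])
        assert ((res["mr_distance"] > 0.5) == (res["predicted"] == "mr")).all()

    def test_posteriors_sum_to_one(self, trained_model, small_dataset_final):
        # mr_distance is the normalized posterior: within [0, 1] by
        # construction, and complementing the benign posterior exactly
        model, _, test = trained_model
        X, _ = small_dataset_final
        d = classify_table(model, X.iloc[test])["mr_distance"]
        assert ((d >= 0) & (d <= 1)).all()

    def test_routing_matches_manual_descent(self, trained_model, small_dataset_final):
        from cnvtriage.nbtree import _Leaf

        model, _, test = trained_model
        X, _ = small_dataset_final
        rows = X.iloc[test].head(100)

        def descend(node, row):
            while not isinstance(node, _Leaf):
                v = row[node.feature]
                if node.kind == "continuous":
                    if pd.isna(v):
                        return None
                    node = node.children[0] if v <= node.threshold else node.children[1]
                else:
                    if pd.isna(v) or v not in node.categories:
                        return None
                    node = node.children[node.categories.index(v)]
            return node

        got = classify_table(model, rows)["mr_distance"].to_numpy()
        for i, (_, row) in enumerate(rows.iterrows()):
            leaf = descend(model.root, row)
            if leaf is None:
                continue  # missing split value: fractional path, not hard routing
            expected = leaf.model.posterior_array(rows.iloc[[i]])[0]
            assert got[i] == pytest.approx(expected, abs=1e-12)

    def test_unknown_feature_errors(self, trained_model):
        model, _, _ = trained_model
        with pytest.raises(KeyError):
            classify_table(model, pd.DataFrame({"bogus": [1.0]}))

    def test_depth_zero_classify_equals_leaf_posterior(self):
        rng = np.random.default_rng(2)
        X, y = _random_frame(rng, 80)
        model = train_nbtree(X, y, NbTreeParams(max_depth=0))
        leaf = train_nb_leaf(X, y)
        row = X.iloc[3].to_dict()
        assert classify(model, row).mr_distance == pytest.approx(
            nb_posterior(leaf, row), abs=1e-10
        )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

class TestSerialization:
    def test_roundtrip_identical_classifications(self, trained_model, small_dataset_final, tmp_path):
        model, _, test = trained_model
        X, _ = small_dataset_final
        rows = X.iloc[test].head(50)
        before = classify_table(model, rows)
        p = tmp_path / "model.json"
        save_model(model, p)
        after = classify_table(load_model(p), rows)
        assert (before["mr_distance"] == after["mr_distance"]).all()
        assert (before["predicted"] == after["predicted"]).all()

    def test_corrupt_file_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json!")
        with pytest.raises(ModelFormatError):
            load_model(p)
        p.write_text(json.dumps({"format": "something-else"}))
        with pytest.raises(ModelFormatError):
            load_model(p)

    def test_version_mismatch_raises(self, trained_model, tmp_path):
        model, _, _ = trained_model
        p = tmp_path / "model.json"
        save_model(model, p)
        doc = json.loads(p.read_text())
        doc["version"] = 999
        p.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="version"):
            load_model(p)

    def test_serialized_leaf_count_matches(self, trained_model, tmp_path):
        model, _, _ = trained_model
        p = tmp_path / "model.json"
        save_model(model, p)
        doc = json.loads(p.read_text())

        def count_leaves(node):
            if node["type"] == "leaf":
                return 1
            return sum(count_leaves(c) for c in node["children"])

        assert count_leaves(doc["tree"]) == model.n_leaves
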