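"""Forest engine: parameters, growth, OOB reporting, importances."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from nmrforest.buckets import Bucket, BucketTable
from nmrforest.forest import (
    ForestParams,
    SurrogateForest,
    default_params,
    fit_forest,
    impurity_importance,
    oob_report,
)
from nmrforest.simulate import pure_noise_table


def toy_table(n=40, p=6, seed=0, gap=3.0):
    """Two classes; column 0 separates them by ``gap`` sd, rest is noise."""
    rng = np.random.default_rng(seed)
    X = np.abs(rng.normal(1.0, 0.3, size=(n, p)))
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    X[np.array(labels) == "B", 0] += gap * 0.3
    buckets = [Bucket(1.0 + 0.01 * i, 1.01 + 0.01 * i) for i in range(p - 1, -1, -1)]
    return BucketTable(X, [f"s{i}" for i in range(n)], labels, buckets)


class TestDefaultParams:
    def test_study_scale_arithmetic(self):
        # p = 840: mtry = ceil(840^(3/4)) = 157, s = round(42.0) = 42
        params = default_params(840, {"a": 28, "b": 7, "c": 12, "d": 21, "e": 12})
        assert params.mtry == 157
        assert params.s == 42

    def test_small_p_floors(self):
        # 16^(3/4) = 8 exactly; 0.05*16 = 0.8 rounds to 1 (floor protection)
        params = default_params(16, [10, 10])
        assert params.mtry == 8
        assert params.s == 1

    def test_case_weights_balance_classes(self):
        params = default_params(10, {"A": 30, "B": 10})
        assert params.case_weights["A"] == pytest.approx(1 / (2 * 30))
        assert params.case_weights["B"] == pytest.approx(1 / (2 * 10))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            default_params(0, [5, 5])

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ForestParams(ntree=0)
        with pytest.raises(ValueError):
            ForestParams(s=-1)


class TestForestGrowth:
    def test_single_class_rejected(self):
        t = toy_table()
        with pytest.raises(ValueError, match="2 classes"):
            SurrogateForest(t.intensities, ["A"] * t.n_samples)

    def test_determinism_same_seed(self, tmp_path):
        t = toy_table()
        params = ForestParams(ntree=20, mtry=4, s=2, seed=5)
        a = SurrogateForest.from_bucket_table(t, params).fit()
        b = SurrogateForest.from_bucket_table(t, params).fit()
        pa, pb = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        a.to_jsonl(pa)
        b.to_jsonl(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ(self):
        t = toy_table()
        params = ForestParams(ntree=5, mtry=4, s=2)
        a = SurrogateForest.from_bucket_table(t, params).fit(seed=1)
        b = SurrogateForest.from_bucket_table(t, params).fit(seed=2)
        assert any(
            ta.var.shape != tb.var.shape or (ta.var != tb.var).any()
            or ta.inbag.tolist() != tb.inbag.tolist()
            for ta, tb in zip(a.trees, b.trees)
        )

    def test_structural_invariants_on_every_node(self):
        t = toy_table(n=50, p=8, seed=3, gap=1.0)
        params = ForestParams(ntree=30, mtry=5, s=3, seed=0)
        res = SurrogateForest.from_bucket_table(t, params).fit()
        for tree in res.trees:
            for node in range(tree.n_nodes):
                v = tree.var[node]
                if v < 0:
                    assert tree.left[node] == tree.right[node] == -1
                    continue
                for child in (tree.left[node], tree.right[node]):
                    assert tree.depth[child] == tree.depth[node] + 1
                ss = tree.surrogates[node]
                assert ss is not None
                assert len(ss) <= params.s
                assert np.all(ss.adjusted > 0)
                assert np.all(np.diff(ss.adjusted) <= 0)  # sorted descending
                assert v not in ss.variables
                # adjusted ties resolve towards the smaller variable index
                for i in range(len(ss) - 1):
                    if ss.adjusted[i] == ss.adjusted[i + 1]:
                        assert ss.variables[i] < ss.variables[i + 1]

    def test_s_zero_stores_no_surrogates(self):
        t = toy_table()
        res = SurrogateForest.from_bucket_table(t, ForestParams(ntree=5, mtry=3, s=0)).fit()
        assert all(ss is None for tree in res.trees for ss in tree.surrogates)

    def test_class_weighted_bootstrap_balances_classes(self):
        # imbalanced 30/10 with 1/(K n_c) weights: expected in-bag class
        # shares are equal; check over 1000 bootstraps within 3 sd
        t = toy_table(n=40)
        labels = ["A"] * 30 + ["B"] * 10
        t = BucketTable(t.intensities, t.sample_ids, labels, t.buckets)
        params = default_params(t.n_buckets, t.class_counts())
        model = SurrogateForest.from_bucket_table(t, params)
        w = model._sample_weights()
        rng = np.random.default_rng(0)
        n_b = 1000
        share_b = np.empty(n_b)
        is_b = np.array(labels) == "B"
        for i in range(n_b):
            idx = rng.choice(40, size=40, replace=True, p=w)
            share_b[i] = is_b[idx].mean()
        se = share_b.std(ddof=1) / math.sqrt(n_b)
        assert abs(share_b.mean() - 0.5) < 3 * se + 1e-3


class TestOOBReport:
    def test_separable_data_is_perfectly_classified(self):
        t = toy_table(gap=6.0)
        res = fit_forest(t, default_params(t.n_buckets, t.class_counts(), ntree=100))
        rep = res.oob_report()
        assert rep.accuracy == 1.0
        assert rep.oob_error == 0.0
        assert np.diag(rep.confusion.to_numpy()).tolist() == [20, 20]
        assert (rep.sensitivity == 1.0).all()
        assert (rep.specificity == 1.0).all()

    def test_permuted_labels_give_chance_accuracy(self):
        # with balanced case weights the chance level is 1/K = 0.5
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = toy_table(seed=seed)
            labels = list(rng.permutation(t.class_labels))
            t = BucketTable(t.intensities, t.sample_ids, labels, t.buckets)
            params = default_params(t.n_buckets, t.class_counts(), ntree=60, seed=seed)
            accs.append(fit_forest(t, params).oob_report().accuracy)
        mean = float(np.mean(accs))
        sd = float(np.std(accs, ddof=1))
        assert abs(mean - 0.5) <= 3 * max(sd, 0.03)

    def test_uncovered_samples_warned_and_excluded(self):
        t = toy_table(n=20)
        res = fit_forest(t, ForestParams(ntree=2, mtry=3, seed=0))
        with pytest.warns(UserWarning, match="never out-of-bag"):
            rep = res.oob_report()
        assert rep.confusion.to_numpy().sum() == 20 - rep.n_excluded

    def test_report_summary_mentions_accuracy(self):
        t = toy_table(gap=6.0)
        res = fit_forest(t, default_params(t.n_buckets, t.class_counts(), ntree=50))
        assert "accuracy: 100.0%" in res.oob_report().summary()

    def test_matches_reference_forest_distributionally(self):
        # s = 0, equal weights: OOB accuracy should agree with an
        # established RF implementation within stochastic tolerance
        from sklearn.ensemble import RandomForestClassifier

        t = toy_table(n=60, p=6, seed=2, gap=1.5)  # imperfectly separable
        params = ForestParams(ntree=300, mtry=2, s=0, seed=0)
        ours = fit_forest(t, params).oob_report().accuracy
        ref = RandomForestClassifier(
            n_estimators=300, max_features=2, oob_score=True, random_state=0
        ).fit(t.intensities, t.class_labels)
        assert abs(ours - ref.oob_score_) < 0.15


class TestImportance:
    def test_unused_variable_has_zero_raw_importance(self):
        # column 0 separates perfectly and is always available (mtry=p):
        # after its split every node is pure, so no other variable splits
        t = toy_table(n=30, p=3, gap=8.0)
        res = fit_forest(t, ForestParams(ntree=30, mtry=3, s=0, seed=1))
        imp = res.impurity_importance("raw")
        assert imp.iloc[1:].eq(0).all() or imp.iloc[0] > imp.iloc[1:].max() * 50

    def test_corrected_beats_noise_consistently(self):
        wins = 0
        for seed in range(20):
            t = toy_table(n=40, p=5, seed=seed, gap=2.0)
            res = fit_forest(t, ForestParams(ntree=60, mtry=3, s=0, seed=seed))
            imp = res.impurity_importance("corrected")
            sep_label = t.labels[0]  # column 0 pairs with the first bucket
            wins += imp[sep_label] > imp.drop(index=sep_label).max()
        assert wins >= 19

    def test_corrected_noise_importance_centers_on_zero(self):
        vals = []
        for seed in range(30):
            t = pure_noise_table(n_samples=30, n_buckets=5, n_classes=2, seed=seed)
            res = fit_forest(t, ForestParams(ntree=40, mtry=3, s=0, seed=seed))
            vals.append(res.impurity_importance("corrected").mean())
        mean = float(np.mean(vals))
        se = float(np.std(vals, ddof=1)) / math.sqrt(len(vals))
        assert abs(mean) < 2 * se + 1e-3

    def test_permutation_mode_ranks_separator_first(self):
        t = toy_table(n=40, p=4, gap=4.0)
        res = fit_forest(t, ForestParams(ntree=60, mtry=2, s=0, seed=0))
        imp = res.impurity_importance("permutation")
        assert imp.idxmax() == t.labels[0]

    def test_unknown_mode_rejected(self):
        t = toy_table()
        res = fit_forest(t, ForestParams(ntree=3, mtry=2, seed=0))
        with pytest.raises(ValueError, match="mode"):
            res.impurity_importance("banana")


class TestSerialization:
    def test_jsonl_structure(self, tmp_path):
        t = toy_table()
        params = ForestParams(ntree=4, mtry=3, s=2, seed=0)
        res = SurrogateForest.from_bucket_table(t, params).fit()
        path = res.to_jsonl(tmp_path / "forest.jsonl")
        lines = path.read_text(encoding="utf-8").splitlines()
        header = json.loads(lines[0])["header"]
        assert header["ntree"] == 4 and header["s"] == 2
        assert len(lines) == 1 + 4
        tree = json.loads(lines[1])
        assert len(tree["var"]) == len(tree["depth"]) == len(tree["surrogates"])
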