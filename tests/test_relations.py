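"""Mean adjusted agreement relations, clustering, reduction, disambiguation."""

import numpy as np
import pandas as pd
import pytest

from nmrforest.buckets import Bucket, BucketTable
from nmrforest.forest import ForestParams, SurrogateForest, default_params, fit_forest
from nmrforest.relations import (
    BucketVerdict,
    RelationMatrix,
    adjacency_signal_groups,
    cluster_boxplot_data,
    cluster_relations,
    correlation_matrix,
    disambiguate_bucket,
    mean_adjusted_agreement,
    reduce_same_signal,
)
from nmrforest.simulate import (
    ClassEffect,
    MetaboliteSpec,
    Signal,
    SimulationConfig,
    simulate_dataset,
)


def matrix_from(df_values, labels):
    df = pd.DataFrame(df_values, index=labels, columns=labels, dtype=float)
    sym = (df + df.T) / 2
    np.fill_diagonal(sym.values, 1.0)
    return RelationMatrix(values=sym, directed=df, symmetrized=True)


def separable_table(seed=0, n=40, p=8):
    """Column 0 duplicated into column 1; both separate the classes."""
    rng = np.random.default_rng(seed)
    X = np.abs(rng.normal(1.0, 0.2, size=(n, p)))
    X[n // 2:, 0] += 1.2
    X[:, 1] = X[:, 0] + rng.normal(0, 0.01, size=n)
    y = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    buckets = [Bucket(1.0 + 0.01 * i, 1.01 + 0.01 * i) for i in range(p - 1, -1, -1)]
    return BucketTable(X, [f"s{i}" for i in range(n)], y, buckets)


@pytest.fixture(scope="module")
def fitted():
    t = separable_table()
    params = default_params(t.n_buckets, t.class_counts(), ntree=150, seed=0)
    return t, fit_forest(t, params)


class TestMeanAdjustedAgreement:
    def test_range_symmetry_and_diagonal(self, fitted):
        _, res = fitted
        mat = mean_adjusted_agreement(res)
        v = mat.values.to_numpy()
        assert ((v >= 0) & (v <= 1)).all()
        np.testing.assert_array_equal(v, v.T)
        assert np.diag(v) == pytest.approx(1.0)

    def test_near_duplicate_columns_relate_above_09(self, fitted):
        t, res = fitted
        mat = mean_adjusted_agreement(res)
        assert mat.get(t.labels[0], t.labels[1]) >= 0.9

    def test_noise_vs_informative_relation_is_low(self, fitted):
        # at this tiny p, chance agreement in deep nodes keeps a floor
        # under noise relations; they must still sit far below the
        # near-duplicate pair
        t, res = fitted
        mat = mean_adjusted_agreement(res)
        noise = t.labels[3:]
        vals = [mat.get(a, t.labels[0]) for a in noise]
        dup = mat.get(t.labels[0], t.labels[1])
        assert float(np.mean(vals)) <= 0.25
        assert float(np.mean(vals)) < dup / 3

    def test_variable_subset_restriction(self, fitted):
        t, res = fitted
        keep = t.labels[:3]
        mat = mean_adjusted_agreement(res, variables=keep)
        assert mat.labels == keep
        with pytest.raises(ValueError, match="unknown"):
            mean_adjusted_agreement(res, variables=["9.99-10.00"])

    def test_requires_surrogates(self):
        t = separable_table()
        res = fit_forest(t, ForestParams(ntree=5, mtry=3, s=0, seed=0))
        with pytest.raises(ValueError, match="s >= 1"):
            mean_adjusted_agreement(res)

    def test_directed_and_symmetrized_both_available(self, fitted):
        _, res = fitted
        mat = mean_adjusted_agreement(res, symmetrize=True)
        assert mat.symmetrized
        expected = (mat.directed + mat.directed.T) / 2
        expected_np = expected.to_numpy().copy()
        np.fill_diagonal(expected_np, 1.0)
        np.testing.assert_allclose(mat.values.to_numpy(), expected_np)


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self):
        t = separable_table()
        corr = correlation_matrix(t)
        assert np.diag(corr.to_numpy()) == pytest.approx(1.0)

    def test_anticorrelated_columns(self):
        X = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        t = BucketTable(X, ["a", "b", "c"], ["A", "A", "B"],
                        [Bucket(1.01, 1.02), Bucket(1.00, 1.01)])
        corr = correlation_matrix(t)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_same_signal_buckets_correlate_perfectly_without_noise(self):
        lib = [MetaboliteSpec("m", (Signal(1.105, 2, 3.9, 1.0),))]
        effects = ClassEffect(["A", "B"], {"m": {"A": 1.0, "B": 2.0}}, {"m": 0.3})
        cfg = SimulationConfig(ppm_range=(1.0, 1.2), n_per_class=10, noise_sd=0.0, seed=0)
        table, truth = simulate_dataset(lib, effects, cfg)
        labs = truth.signal_groups()["m:0"]
        corr = correlation_matrix(table, labs)
        assert corr.loc[labs[0], labs[-1]] == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_column_yields_nan(self):
        X = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        t = BucketTable(X, ["a", "b", "c"], ["A", "A", "B"],
                        [Bucket(1.01, 1.02), Bucket(1.00, 1.01)])
        corr = correlation_matrix(t)
        assert np.isnan(corr.iloc[0, 1])

    def test_requires_three_samples(self):
        X = np.ones((2, 2))
        t = BucketTable(X, ["a", "b"], ["A", "B"],
                        [Bucket(1.01, 1.02), Bucket(1.00, 1.01)])
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(t)


class TestClustering:
    def test_block_diagonal_recovers_blocks(self):
        labels = ["1.00-1.01", "1.01-1.02", "2.00-2.01", "2.01-2.02"]
        v = np.array([
            [1.0, 0.9, 0.0, 0.0],
            [0.9, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.9],
            [0.0, 0.0, 0.9, 1.0],
        ])
        cl = cluster_relations(matrix_from(v, labels), k=2)
        groups = {frozenset(m) for m in cl.members.values()}
        assert groups == {frozenset(labels[:2]), frozenset(labels[2:])}

    def test_k_equal_n_gives_singletons(self):
        labels = [f"1.0{i}-1.0{i+1}" for i in range(4)]
        v = np.eye(4)
        cl = cluster_relations(matrix_from(v, labels), k=4)
        assert all(len(m) == 1 for m in cl.members.values())

    def test_k_out_of_range_rejected(self):
        labels = ["1.00-1.01", "1.01-1.02"]
        with pytest.raises(ValueError, match="k must be"):
            cluster_relations(matrix_from(np.eye(2), labels), k=5)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        v = rng.random((6, 6))
        labels = [f"1.0{i}-1.0{i+1}" for i in range(6)]
        cl = cluster_relations(matrix_from((v + v.T) / 2, labels), k=2)
        heights = cl.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_boxplot_data_layout(self):
        t = separable_table(n=6, p=4)
        df = cluster_boxplot_data(t, {1: t.labels[:2], 2: t.labels[2:3]})
        assert list(df.columns) == ["cluster", "bucket", "sample_id", "class", "intensity"]
        assert len(df) == 3 * 6


class TestReduceSameSignal:
    smd = {"a": 1.2, "b": 0.8, "c": 2.0, "d": 0.5}

    def test_lowest_smd_wins(self):
        assert reduce_same_signal(["a", "b", "c"], self.smd, [["a", "b", "c"]]) == ["b"]

    def test_singleton_group_passes_through(self):
        assert reduce_same_signal(["a"], self.smd, [["a"]]) == ["a"]

    def test_ungrouped_labels_pass_through(self):
        got = reduce_same_signal(["a", "b", "d"], self.smd, [["a", "b"]])
        assert got == ["b", "d"]

    def test_tie_breaks_on_label_order(self):
        got = reduce_same_signal(["b", "a"], {"a": 1.0, "b": 1.0}, [["b", "a"]])
        assert got == ["a"]

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError, match="no SMD score"):
            reduce_same_signal(["a", "z"], self.smd, [["a", "z"]])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            reduce_same_signal(["a"], self.smd, [[]])


class TestAdjacencyGroups:
    def test_neighbours_with_high_relation_group(self):
        labels = ["1.02-1.03", "1.01-1.02", "1.00-1.01", "3.00-3.01"]
        v = np.full((4, 4), 0.05)
        np.fill_diagonal(v, 1.0)
        v[0, 1] = v[1, 0] = 0.95
        v[1, 2] = v[2, 1] = 0.85
        groups = adjacency_signal_groups(labels, matrix_from(v, labels))
        assert sorted(map(sorted, groups)) == [
            ["1.00-1.01", "1.01-1.02", "1.02-1.03"], ["3.00-3.01"],
        ]

    def test_distant_buckets_never_group(self):
        labels = ["1.00-1.01", "3.00-3.01"]
        v = np.array([[1.0, 0.99], [0.99, 1.0]])
        groups = adjacency_signal_groups(labels, matrix_from(v, labels))
        assert len(groups) == 2  # related but 2 ppm apart: not one signal


class TestDisambiguation:
    labels = ["3.23-3.24", "4.49-4.50", "3.56-3.57", "1.72-1.73"]

    def matrix(self, strong=0.8, weak=0.02):
        v = np.full((4, 4), 0.0)
        np.fill_diagonal(v, 1.0)
        v[0, 1] = v[1, 0] = strong  # bucket relates to metabolite A's bucket
        v[0, 2] = v[2, 0] = weak    # not to metabolite B's
        v[0, 3] = v[3, 0] = weak
        return matrix_from(v, self.labels)

    def test_supported_vs_unsupported(self):
        verdicts = disambiguate_bucket(
            "3.23-3.24",
            {"cholineOS": ["4.49-4.50"], "GPC": ["3.56-3.57"], "arginine": ["1.72-1.73"]},
            self.matrix(),
        )
        assert verdicts["cholineOS"].status == "supported"
        assert verdicts["GPC"].status == "unsupported"
        assert verdicts["arginine"].status == "unsupported"

    def test_both_supported_when_both_relate(self):
        verdicts = disambiguate_bucket(
            "3.23-3.24",
            {"trehalose": ["4.49-4.50"], "ribonate": ["3.56-3.57"]},
            self.matrix(weak=0.75),
        )
        assert {v.status for v in verdicts.values()} == {"supported"}

    def test_intermediate_relation_is_ambiguous(self):
        verdicts = disambiguate_bucket(
            "3.23-3.24", {"met": ["3.56-3.57"]}, self.matrix(weak=0.2)
        )
        assert verdicts["met"].status == "ambiguous"

    def test_no_candidates_empty_verdict(self):
        assert disambiguate_bucket("3.23-3.24", {}, self.matrix()) == {}

    def test_candidate_without_other_buckets_is_ambiguous(self):
        verdicts = disambiguate_bucket(
            "3.23-3.24", {"met": ["3.23-3.24"]}, self.matrix()
        )
        assert verdicts["met"].status == "ambiguous"
        assert "no other" in verdicts["met"].reason
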