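"""Correlation pruning, mutual information and RFE."""

import numpy as np
import pandas as pd
import pytest

from crispgait import curation as cu
from crispgait.errors import ConfigError


class TestPearsonMatrix:
    def test_copy_and_sign_flip(self, rng):
        x = rng.normal(size=200)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": -x})
        corr = cu.pearson_matrix(X)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_independent_columns_near_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(10000, 2)), columns=["a", "b"])
        assert abs(cu.pearson_matrix(X).loc["a", "b"]) < 0.05

    def test_zero_variance_column_warns(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = cu.pearson_matrix(X)
        assert corr.loc["a", "b"] == 0.0


class TestMutualInformation:
    def test_perfect_dependence_approaches_ln2(self, rng):
        y = rng.integers(0, 2, size=4000)
        mi = cu.mutual_information(y.astype(float), y)
        assert mi == pytest.approx(np.log(2), abs=0.01)

    def test_independent_feature_near_zero(self, rng):
        x = rng.normal(size=10000)
        y = rng.integers(0, 2, size=10000)
        assert cu.mutual_information(x, y) < 0.01
        # permutation null: shuffling labels should not raise MI materially
        perm = rng.permutation(y)
        assert cu.mutual_information(x, perm) < 0.01

    def test_hand_contingency(self):
        # joint counts [[30, 10], [10, 30]] over 2 bins x 2 labels
        x = np.repeat([0.0, 0.0, 1.0, 1.0], [30, 10, 10, 30])
        y = np.array(["a"] * 30 + ["b"] * 10 + ["a"] * 10 + ["b"] * 30)
        p = np.array([[30, 10], [10, 30]]) / 80.0
        expected = sum(
            p[i, j] * np.log(p[i, j] / (p[i, :].sum() * p[:, j].sum()))
            for i in range(2) for j in range(2))
        assert cu.mutual_information(x, y, bins=2) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_and_zero_for_constant(self, rng):
        y = rng.integers(0, 3, size=500)
        assert cu.mutual_information(np.ones(500), y) == 0.0
        for _ in range(5):
            assert cu.mutual_information(rng.normal(size=500), y) >= 0.0

    def test_monotone_invariance(self, rng):
        x = rng.normal(size=2000)
        y = (x + rng.normal(size=2000) > 0).astype(int)
        assert cu.mutual_information(np.exp(x), y) == pytest.approx(
            cu.mutual_information(x, y), abs=1e-12)

    def test_single_class_warns_zero(self, rng):
        with pytest.warns(UserWarning, match="single-class"):
            assert cu.mutual_information(rng.normal(size=50), np.zeros(50)) == 0.0


class TestCorrelationPrune:
    def test_duplicate_dropped_keeps_informative(self, rng):
        n = 1000
        a = rng.normal(size=n)
        y = (a + 0.5 * rng.normal(size=n) > 0).astype(int)
        X = pd.DataFrame({
            "A": a,
            "B": a + 0.5 * rng.normal(size=n),  # noisier sibling, |r| ~ 0.89
            "C": rng.normal(size=n),
        })
        mi = {c: cu.mutual_information(X[c], y) for c in ("A", "B")}
        assert mi["A"] > mi["B"]  # construction sanity: A carries more signal
        result = cu.correlation_prune(X, y)
        assert result.retained == ["A", "C"]
        assert [d[0] for d in result.dropped] == ["B"]
        d = result.dropped[0]
        assert d[3] <= d[4]  # MI of dropped <= MI of partner

    def test_exact_copy_tie_drops_later_name(self, rng):
        a = rng.normal(size=500)
        y = rng.integers(0, 2, size=500)
        X = pd.DataFrame({"A": a, "B": a.copy()})
        result = cu.correlation_prune(X, y)
        assert result.retained == ["A"]

    def test_unreachable_threshold_drops_nothing(self, rng):
        X = pd.DataFrame({"A": rng.normal(size=100), "B": rng.normal(size=100)})
        result = cu.correlation_prune(X, rng.integers(0, 2, 100), r_threshold=1.01)
        assert result.dropped == [] and result.retained == ["A", "B"]

    def test_chain_collapses_to_most_informative(self, rng):
        n = 3000
        a = rng.normal(size=n)
        y = (a + 0.3 * rng.normal(size=n) > 0).astype(int)
        X = pd.DataFrame({
            "A": a,
            "B": a + 0.35 * rng.normal(size=n),
            "C": a + 0.55 * rng.normal(size=n),
        })
        corr = cu.pearson_matrix(X).abs().round(2)
        assert (corr.values >= 0.80).all()  # all pairwise flagged
        mi = {c: cu.mutual_information(X[c], y) for c in X}
        assert mi["A"] > mi["B"] > mi["C"]
        result = cu.correlation_prune(X, y)
        assert result.retained == ["A"]
        assert {d[0] for d in result.dropped} == {"B", "C"}

    def test_postcondition_no_retained_pair_flagged(self, rng):
        n, p = 400, 12
        base = rng.normal(size=(n, p))
        base[:, 5] = base[:, 0] + 0.1 * rng.normal(size=n)
        base[:, 7] = -base[:, 2]
        X = pd.DataFrame(base, columns=[f"f{i}" for i in range(p)])
        y = rng.integers(0, 2, size=n)
        result = cu.correlation_prune(X, y)
        corr = cu.pearson_matrix(X[result.retained]).abs().round(2)
        off_diag = corr.values[~np.eye(len(result.retained), dtype=bool)]
        assert (off_diag < 0.80).all()
        assert sorted(result.retained + [d[0] for d in result.dropped]) == sorted(X.columns)


class TestRfeSelect:
    def test_identity_when_keeping_all(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = rng.integers(0, 2, size=100)
        result = cu.rfe_select(X, y, n_keep=5, n_trees=20)
        assert result.selected == list(X.columns)

    def test_count_invariant_and_determinism(self, rng):
        X = pd.DataFrame(rng.normal(size=(150, 12)),
                         columns=[f"f{i}" for i in range(12)])
        y = (X["f0"] + X["f1"] > 0).astype(int)
        r1 = cu.rfe_select(X, y, n_keep=4, n_trees=30, seed=5)
        r2 = cu.rfe_select(X, y, n_keep=4, n_trees=30, seed=5)
        assert len(r1.selected) == 4
        assert r1.selected == r2.selected and r1.ranking == r2.ranking

    def test_too_few_columns(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        with pytest.raises(ConfigError):
            cu.rfe_select(X, rng.integers(0, 2, 50), n_keep=10)

    def test_signal_columns_survive(self, rng):
        n = 400
        signal = rng.normal(size=(n, 2))
        noise = rng.normal(size=(n, 6))
        y = (signal.sum(axis=1) > 0).astype(int)
        X = pd.DataFrame(np.column_stack([signal, noise]),
                         columns=["s0", "s1"] + [f"n{i}" for i in range(6)])
        result = cu.rfe_select(X, y, n_keep=2, n_trees=50, seed=0)
        assert set(result.selected) == {"s0", "s1"}
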