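"""Fold construction, leakage guard, voting, metrics and paired tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crispgait import classify as cl
from crispgait import evaluate as ev
from crispgait.errors import AuditError, SplitError
from crispgait.features import FeatureMatrix


def _synthetic_matrix(rng, n_subjects=10, cycles=30, n_features=6):
    rows = []
    for s in range(n_subjects):
        label = "PD" if s < n_subjects // 2 else "HC"
        shift = 1.0 if label == "PD" else 0.0
        for c in range(cycles):
            row = {"subject_id": f"S{s:02d}", "walk_id": "01", "foot": "left",
                   "cycle_index": c, "label": label}
            for f in range(n_features):
                row[f"f{f}"] = rng.normal(shift if f < 2 else 0.0, 1.0)
            rows.append(row)
    return FeatureMatrix(df=pd.DataFrame(rows),
                         feature_columns=[f"f{i}" for i in range(n_features)])


class TestMakeFolds:
    def test_subject_grouped_partition(self, rng):
        matrix = _synthetic_matrix(rng)
        folds = ev.make_folds(matrix, ev.FoldPlan(seed=0))
        seen = {}
        for k, (tr, te) in enumerate(folds):
            assert np.intersect1d(tr, te).size == 0
            test_subjects = set(matrix.df.iloc[te]["subject_id"])
            train_subjects = set(matrix.df.iloc[tr]["subject_id"])
            assert not test_subjects & train_subjects
            assert len(test_subjects) == 2  # one per class with 5/5 subjects
            labels = set(matrix.df.iloc[te]["label"])
            assert labels == {"PD", "HC"}
            for sid in test_subjects:
                assert sid not in seen
                seen[sid] = k
        assert len(seen) == 10  # every subject tested exactly once

    def test_too_few_subjects_raises(self, rng):
        matrix = _synthetic_matrix(rng, n_subjects=6)
        with pytest.raises(SplitError):
            ev.make_folds(matrix, ev.FoldPlan(n_folds=5, seed=0))

    def test_cycle_stratified_proportions(self, rng):
        rows = [{"subject_id": f"S{i}", "label": "PD" if i % 5 < 3 else "HC",
                 "walk_id": "01", "foot": "left", "cycle_index": 0, "f0": 0.0}
                for i in range(1000)]
        matrix = FeatureMatrix(df=pd.DataFrame(rows), feature_columns=["f0"])
        folds = ev.make_folds(matrix, ev.FoldPlan(
            split_unit="cycle_stratified", seed=0))
        for _, te in folds:
            frac = (matrix.df.iloc[te]["label"] == "PD").mean()
            assert 0.58 <= frac <= 0.62


class TestLeakageGuard:
    def test_label_access_locked(self, rng):
        matrix = _synthetic_matrix(rng)
        guard = ev.LeakageGuard(matrix.df, matrix.feature_columns, "label")
        assert guard.features().shape[1] == 6
        with pytest.raises(AuditError):
            _ = guard.labels
        with pytest.raises(AuditError):
            _ = guard.meta("label")
        guard.unlock()
        assert len(guard.labels) == len(matrix.df)

    def test_snapshot_isolated_from_mutation(self, rng):
        matrix = _synthetic_matrix(rng)
        guard = ev.LeakageGuard(matrix.df, matrix.feature_columns, "label")
        matrix.df.loc[:, "f0"] = 999.0
        assert guard.features()["f0"].abs().max() < 100


class TestRunPipelineFold:
    def test_crisp_uses_exactly_ten_columns(self, rng):
        # quasi-independent columns: pruning retains >= 10, RFE keeps exactly 10
        matrix = _synthetic_matrix(rng, n_subjects=10, cycles=40, n_features=20)
        folds = ev.make_folds(matrix, ev.FoldPlan(n_folds=3, seed=0))
        tr, te = folds[0]
        result = ev.run_pipeline_fold(matrix, tr, te, "crisp",
                                      cl.ClassifierSpec("RF", seed=0),
                                      fold=0)
        assert result.curation is not None
        assert len(result.curation.selected) == 10
        assert set(result.curation.selected) <= set(result.curation.prune.retained)

    def test_crisp_on_collinear_panel_respects_prune(self, small_matrix):
        # the gait panel is deliberately collinear; RFE keeps at most 10 of
        # whatever pruning leaves
        folds = ev.make_folds(small_matrix, ev.FoldPlan(n_folds=3, seed=0))
        tr, te = folds[0]
        result = ev.run_pipeline_fold(small_matrix, tr, te, "crisp",
                                      cl.ClassifierSpec("RF", seed=0), fold=0)
        cur = result.curation
        assert len(cur.selected) == min(10, len(cur.prune.retained))
        assert result.n_synthetic > 0

    def test_baseline_has_no_curation(self, small_matrix):
        folds = ev.make_folds(small_matrix, ev.FoldPlan(n_folds=3, seed=0))
        tr, te = folds[0]
        result = ev.run_pipeline_fold(small_matrix, tr, te, "baseline",
                                      cl.ClassifierSpec("DT", seed=0))
        assert result.curation is None and result.n_synthetic == 0
        assert len(result.y_pred) == len(te)

    def test_overlapping_folds_rejected(self, small_matrix):
        idx = np.arange(20)
        with pytest.raises(SplitError):
            ev.run_pipeline_fold(small_matrix, idx, idx,
                                 "baseline", cl.ClassifierSpec("DT"))


class TestSubjectVote:
    def _post(self, pd_probs):
        return pd.DataFrame({"PD": pd_probs, "HC": [1 - p for p in pd_probs]})

    def test_strict_majority(self):
        votes = ev.subject_vote(["PD", "PD", "HC"], self._post([0.9, 0.8, 0.4]),
                                ["S1", "S1", "S1"])
        assert votes.loc[0, "decision"] == "PD"
        assert not votes.loc[0, "tie"]

    def test_tie_broken_by_mean_posterior(self):
        votes = ev.subject_vote(["PD", "HC"], self._post([0.9, 0.5]),
                                ["S1", "S1"])
        assert votes.loc[0, "tie"]
        assert votes.loc[0, "decision"] == "PD"  # mean PD posterior 0.70 > 0.30

    def test_one_decision_per_subject(self, rng):
        n = 60
        sids = rng.choice([f"S{i}" for i in range(7)], size=n)
        preds = rng.choice(["PD", "HC"], size=n)
        post = self._post(rng.uniform(size=n))
        votes = ev.subject_vote(preds, post, sids)
        assert sorted(votes["subject_id"]) == sorted(set(sids))


class TestComputeMetrics:
    def test_hand_confusion_matrix(self):
        y_true = [1, 1, 1, 0, 0]
        y_pred = [1, 1, 0, 0, 1]
        m = ev.compute_metrics(y_true, y_pred, positive=1)
        assert m.accuracy == pytest.approx(60.0)
        assert m.precision == pytest.approx(100 * 2 / 3)
        assert m.recall == pytest.approx(100 * 2 / 3)
        assert m.specificity == pytest.approx(50.0)
        assert m.f1 == pytest.approx(100 * 2 / 3)

    def test_perfect_predictions(self):
        y = ["PD", "HC", "PD", "HC"]
        post = pd.DataFrame({"PD": [0.9, 0.1, 0.8, 0.2],
                             "HC": [0.1, 0.9, 0.2, 0.8]})
        m = ev.compute_metrics(y, y, post)
        for name in ("accuracy", "precision", "recall", "specificity", "f1"):
            assert getattr(m, name) == pytest.approx(100.0)
        assert m.roc_auc == pytest.approx(1.0)

    def test_uninformative_posteriors_auc_half(self):
        y_true = ["PD", "PD", "HC", "HC"]
        post = pd.DataFrame({"PD": [0.5] * 4, "HC": [0.5] * 4})
        m = ev.compute_metrics(y_true, ["PD", "PD", "PD", "PD"], post)
        assert m.roc_auc == pytest.approx(0.5)

    def test_macro_multiclass(self):
        y_true = [1, 1, 2, 2, 3, 3]
        y_pred = [1, 2, 2, 2, 3, 1]
        m = ev.compute_metrics(y_true, y_pred)
        assert m.averaging == "macro_ovr"
        assert m.accuracy == pytest.approx(100 * 4 / 6)


class TestPairedCompare:
    def _sets(self, values):
        return [ev.MetricSet(v, v, v, v, v, 0.5, "binary") for v in values]

    def test_hand_computed_t(self):
        base = self._sets([10, 11, 12, 13, 14])
        crisp = self._sets([12, 10, 15, 13, 15])  # diffs (2,-1,3,0,1)
        out = ev.paired_compare(base, crisp)
        row = out[out["metric"] == "accuracy"].iloc[0]
        d = np.array([2, -1, 3, 0, 1], dtype=float)
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        assert row["t"] == pytest.approx(t_expected, abs=1e-9)
        assert row["p"] == pytest.approx(p_expected, abs=1e-9)

    def test_identical_samples_give_p_one(self):
        base = self._sets([90, 91, 92, 93, 94])
        out = ev.paired_compare(base, base)
        assert (out["p"] == 1.0).all()
        assert out["degenerate"].all()

    def test_constant_nonzero_differences_flagged(self):
        base = self._sets([90, 91, 92, 93, 94])
        crisp = self._sets([91, 92, 93, 94, 95])
        out = ev.paired_compare(base, crisp)
        row = out[out["metric"] == "accuracy"].iloc[0]
        assert row["degenerate"] and row["p"] == 0.0

    def test_unequal_fold_counts_rejected(self):
        with pytest.raises(ValueError):
            ev.paired_compare(self._sets([1, 2]), self._sets([1, 2, 3]))


class TestReport:
    def _report(self):
        records = []
        for k, acc in enumerate([90, 92, 94, 91, 93]):
            records.append({"task": "binary", "model": "XGB",
                            "configuration": "crisp", "protocol": "subject_wise",
                            "fold": k, "accuracy": acc, "precision": acc,
                            "recall": acc, "specificity": acc, "f1": acc,
                            "roc_auc": 0.9})
        return ev.EvaluationReport(
            records=pd.DataFrame(records),
            paired=pd.DataFrame(columns=["task", "model", "protocol", "metric",
                                         "t", "p", "mean_diff", "degenerate"]),
            subject_decisions=pd.DataFrame({"subject_id": ["S1"], "decision": ["PD"]}),
            curation_artifacts={})

    def test_hand_mean_sd_aggregation(self):
        agg = self._report().aggregates()
        assert agg.loc[0, "accuracy_mean"] == pytest.approx(92.0)
        assert agg.loc[0, "accuracy_std"] == pytest.approx(1.5811, abs=1e-4)

    def test_json_round_trip_reproduces_table(self, tmp_path):
        report = self._report()
        report.to_json(tmp_path / "r.json")
        back = ev.EvaluationReport.from_json(tmp_path / "r.json")
        assert back.table() == report.table()
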