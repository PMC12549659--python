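"""Cross-validated evaluation of baseline vs. CRISP under two protocols.

The experiment runs 5-fold cross-validation with subject-grouped folds by
default (no subject ever straddles train and test), fits the full CRISP
chain — correlation pruning, RFE, SMOTE, classifier — strictly on training
rows, and scores predictions two ways: the *overall* protocol pools
cycle-level predictions, while the *subject-wise* protocol first collapses
each test subject's cycles into one decision by majority vote (modal class
for the severity task) with average-posterior tie-breaking.  Six metrics are
reported per fold (accuracy, precision, recall, specificity, F1, ROC-AUC)
and CRISP is compared with the baseline by two-sided paired t-tests over
folds.

A :class:`LeakageGuard` wraps every fold's held-out rows: it snapshots them,
hands out feature columns only, and raises :class:`~crispgait.errors.AuditError`
on any label access before predictions exist.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from . import balance, classify, curation
from .errors import AuditError, SplitError
from .features import FeatureMatrix

POSITIVE_CLASS = "PD"
METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1", "roc_auc")


# ---------------------------------------------------------------------------
# fold construction


@dataclass
class FoldPlan:
    n_folds: int = 5
    protocol: str = "subject_wise"          # reporting protocol label
    split_unit: str = "subject_grouped"     # or "cycle_stratified"
    seed: int = 0


def make_folds(matrix: FeatureMatrix, plan: FoldPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition rows into ``n_folds`` disjoint test sets.

    subject_grouped stratifies *subjects* by label and keeps each subject's
    rows together; cycle_stratified stratifies rows directly (provided to
    emulate per-cycle splitting, at the cost of identity leakage).
    """
    y = matrix.y.to_numpy()
    if plan.split_unit == "subject_grouped":
        groups = matrix.subject_ids.to_numpy()
        per_class = pd.DataFrame({"y": y, "g": groups}).groupby("y")["g"].nunique()
        short = per_class[per_class < plan.n_folds]
        if len(short):
            raise SplitError(
                f"classes with fewer subjects than folds: {dict(short)}")
        cv = StratifiedGroupKFold(n_splits=plan.n_folds, shuffle=True,
                                  random_state=plan.seed)
        return [(tr, te) for tr, te in cv.split(np.zeros(len(y)), y, groups)]
    if plan.split_unit == "cycle_stratified":
        cv = StratifiedKFold(n_splits=plan.n_folds, shuffle=True,
                             random_state=plan.seed)
        return [(tr, te) for tr, te in cv.split(np.zeros(len(y)), y)]
    raise SplitError(f"unknown split unit {plan.split_unit!r}")


# ---------------------------------------------------------------------------
# leakage guard


class LeakageGuard:
    """Snapshot of held-out rows that refuses label access while locked.

    The snapshot is taken at construction, so later mutation of the caller's
    frame cannot reach the fold.  ``features()`` is always available;
    ``labels`` raises :class:`AuditError` until :meth:`unlock` is called
    (which the fold runner does only after predictions are in hand).
    """

    def __init__(self, df: pd.DataFrame, feature_columns: list, label_column: str):
        self._df = df.copy(deep=True)
        self._feature_columns = list(feature_columns)
        self._label_column = label_column
        self._locked = True

    def features(self) -> pd.DataFrame:
        return self._df[self._feature_columns].copy()

    def meta(self, column: str) -> pd.Series:
        if column == self._label_column:
            return self.labels  # route through the audit check
        return self._df[column].copy()

    @property
    def labels(self) -> pd.Series:
        if self._locked:
            raise AuditError(
                "held-out labels requested during fitting; unlock the guard "
                "only after predictions are produced")
        return self._df[self._label_column].copy()

    def unlock(self) -> None:
        self._locked = False


# ---------------------------------------------------------------------------
# single fold


@dataclass
class PipelineSettings:
    """Stage parameters of one experiment run (defaults = headline pipeline)."""

    r_threshold: float = curation.DEFAULT_R_THRESHOLD
    n_keep: int = curation.DEFAULT_N_KEEP
    n_trees: int = curation.DEFAULT_N_TREES
    smote_k: int = 5
    tune: bool = False            # grid-search inside the training fold
    inner_folds: int = 5
    # ablation switches (both on = full CRISP)
    use_rfe: bool = True
    use_smote: bool = True


@dataclass
class FoldResult:
    fold: int
    configuration: str
    y_true: np.ndarray
    y_pred: np.ndarray
    posteriors: pd.DataFrame
    subject_ids: np.ndarray
    curation: Optional[curation.CurationResult]
    spec: classify.ClassifierSpec
    n_synthetic: int


def run_pipeline_fold(matrix: FeatureMatrix, train_idx, test_idx,
                      configuration: str, spec: classify.ClassifierSpec,
                      settings: PipelineSettings | None = None,
                      fold: int = 0) -> FoldResult:
    """Fit one configuration on a training fold and predict its test fold.

    CRISP: prune -> RFE -> SMOTE (all on train) -> optional grid search ->
    fit -> predict on the selected columns.  baseline: fit on the full panel,
    no curation or balancing.
    """
    settings = settings or PipelineSettings()
    if np.intersect1d(train_idx, test_idx).size:
        raise SplitError("train and test folds overlap")
    train = matrix.df.iloc[train_idx]
    guard = LeakageGuard(matrix.df.iloc[test_idx], matrix.feature_columns,
                         matrix.label_column)

    X_train = train[matrix.feature_columns].reset_index(drop=True)
    y_train = train[matrix.label_column].to_numpy()

    cur: Optional[curation.CurationResult] = None
    n_synth = 0
    if configuration == "crisp":
        if settings.use_rfe:
            cur = curation.curate(X_train, y_train, r_threshold=settings.r_threshold,
                                  n_keep=settings.n_keep, n_trees=settings.n_trees,
                                  seed=spec.seed)
            selected = cur.selected
        else:
            prune = curation.correlation_prune(X_train, y_train,
                                               r_threshold=settings.r_threshold)
            selected = prune.retained
        X_fit = X_train[selected]
        if settings.use_smote:
            X_fit, y_fit, prov = balance.smote_oversample(
                X_fit, y_train,
                balance.SmoteConfig(k_neighbors=settings.smote_k, seed=spec.seed))
            n_synth = len(prov)
        else:
            y_fit = y_train
    elif configuration == "baseline":
        selected = matrix.feature_columns
        X_fit, y_fit = X_train, y_train
    else:
        raise ValueError(f"configuration must be 'baseline' or 'crisp', got {configuration!r}")

    tuned = spec
    if settings.tune:
        tuned = classify.grid_search(spec, X_fit, y_fit,
                                     inner_folds=settings.inner_folds)
    model = classify.fit(tuned, X_fit, y_fit)

    X_test = guard.features()[selected]
    posteriors = classify.predict_proba(model, X_test)
    y_pred = posteriors.columns.to_numpy()[np.argmax(posteriors.to_numpy(), axis=1)]

    guard.unlock()
    return FoldResult(
        fold=fold, configuration=configuration,
        y_true=guard.labels.to_numpy(), y_pred=y_pred, posteriors=posteriors,
        subject_ids=guard.meta("subject_id").to_numpy(),
        curation=cur, spec=tuned, n_synthetic=n_synth,
    )


# ---------------------------------------------------------------------------
# subject voting


def subject_vote(y_pred, posteriors: pd.DataFrame, subject_ids,
                 y_true=None) -> pd.DataFrame:
    """Collapse cycle predictions into one decision per subject.

    Majority label (modal class for >2 classes); exact ties go to the tied
    class with the highest mean posterior over the subject's cycles.
    """
    y_pred = np.asarray(y_pred)
    subject_ids = np.asarray(subject_ids)
    classes = list(posteriors.columns)
    rows = []
    for sid in pd.unique(subject_ids):
        mask = subject_ids == sid
        if not mask.any():
            warnings.warn(f"subject {sid} has no cycles in the test fold; excluded")
            continue
        votes = pd.Series(y_pred[mask]).value_counts()
        top = votes[votes == votes.max()].index.tolist()
        tie = len(top) > 1
        if tie:
            mean_post = posteriors.loc[mask, top].mean(axis=0)
            decision = mean_post.idxmax()
        else:
            decision = top[0]
        row = {"subject_id": sid, "decision": decision,
               "n_cycles": int(mask.sum()), "tie": tie}
        for c in classes:
            row[f"posterior_{c}"] = float(posteriors.loc[mask, c].mean())
        if y_true is not None:
            truth = np.asarray(y_true)[mask]
            row["truth"] = truth[0]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    roc_auc: float
    averaging: str
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def _binary_metrics(y_true, y_pred, posteriors, positive) -> MetricSet:
    # order: [positive, negatives...]; an absent positive class yields a
    # zero row/column, so the 2x2 formulas still apply
    neg = sorted(c for c in set(y_true) | set(y_pred) if c != positive)
    order = [positive] + neg
    cm = confusion_matrix(y_true, y_pred, labels=order)
    tp, fn = cm[0, 0], cm[0, 1:].sum()
    fp, tn = cm[1:, 0].sum(), cm[1:, 1:].sum()
    flags = []

    def _safe(num, den, name):
        if den == 0:
            flags.append(f"{name}_undefined")
            return 0.0
        return num / den

    precision = _safe(tp, tp + fp, "precision")
    recall = _safe(tp, tp + fn, "recall")
    specificity = _safe(tn, tn + fp, "specificity")
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    accuracy = (tp + tn) / cm.sum()
    auc = np.nan
    if posteriors is not None and positive in posteriors.columns:
        if len(set(y_true)) == 2:
            auc = float(roc_auc_score(np.asarray(y_true) == positive,
                                      posteriors[positive].to_numpy()))
        else:
            flags.append("auc_single_class")
    return MetricSet(100 * accuracy, 100 * precision, 100 * recall,
                     100 * specificity, 100 * f1, auc, "binary", flags)


def _macro_metrics(y_true, y_pred, posteriors) -> MetricSet:
    classes = sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    n = cm.sum()
    precs, recs, specs, f1s = [], [], [], []
    flags: list = []
    for i, _ in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = n - tp - fp - fn
        p = tp / (tp + fp) if (tp + fp) else 0.0
        r = tp / (tp + fn) if (tp + fn) else 0.0
        s = tn / (tn + fp) if (tn + fp) else 0.0
        precs.append(p)
        recs.append(r)
        specs.append(s)
        f1s.append(2 * p * r / (p + r) if (p + r) else 0.0)
    accuracy = np.trace(cm) / n
    auc = np.nan
    if posteriors is not None and set(classes) <= set(posteriors.columns):
        present = sorted(set(y_true))
        if len(present) == len(posteriors.columns) and len(present) > 1:
            auc = float(roc_auc_score(y_true, posteriors.to_numpy(),
                                      multi_class="ovr", average="macro",
                                      labels=list(posteriors.columns)))
        else:
            flags.append("auc_missing_class")
    return MetricSet(100 * accuracy, 100 * float(np.mean(precs)),
                     100 * float(np.mean(recs)), 100 * float(np.mean(specs)),
                     100 * float(np.mean(f1s)), auc, "macro_ovr", flags)


def compute_metrics(y_true, y_pred, posteriors: pd.DataFrame | None = None,
                    positive=POSITIVE_CLASS, averaging: str | None = None
                    ) -> MetricSet:
    """Six metrics in percent (AUC on [0, 1]).

    Binary tasks score against the PD-positive convention; multiclass tasks
    use macro one-vs-rest averaging.  When ``averaging`` is not given it is
    inferred from the class universe — the posterior columns when available,
    otherwise the observed labels.  Undefined ratios (zero denominators)
    report 0 with a flag.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    if posteriors is not None:
        unseen = set(y_pred) - set(posteriors.columns)
        if unseen:
            raise ValueError(f"predicted labels outside the posterior class set: {unseen}")
    if averaging is None:
        universe = (set(posteriors.columns) if posteriors is not None
                    else set(y_true) | set(y_pred))
        averaging = "binary" if len(universe) <= 2 else "macro_ovr"
    if averaging == "binary":
        return _binary_metrics(y_true, y_pred, posteriors, positive)
    if averaging == "macro_ovr":
        return _macro_metrics(y_true, y_pred, posteriors)
    raise ValueError(f"unknown averaging {averaging!r}")


# ---------------------------------------------------------------------------
# paired comparison and aggregation


def paired_compare(baseline: list[MetricSet], crisp: list[MetricSet]) -> pd.DataFrame:
    """Two-sided paired t-test per metric across folds (df = n_folds - 1).

    Zero-variance differences are degenerate: p = 1 when all differences are
    zero, p = 0 otherwise, both flagged.
    """
    if len(baseline) != len(crisp):
        raise ValueError("baseline and CRISP fold counts differ")
    if len(baseline) < 2:
        raise ValueError("need >= 2 folds for a paired test")
    rows = []
    for m in METRIC_NAMES:
        b = np.array([getattr(s, m) for s in baseline], dtype=float)
        c = np.array([getattr(s, m) for s in crisp], dtype=float)
        if np.any(np.isnan(b)) or np.any(np.isnan(c)):
            rows.append({"metric": m, "t": np.nan, "p": np.nan,
                         "mean_diff": np.nan, "degenerate": True})
            continue
        d = c - b
        if np.std(d, ddof=1) == 0:
            p = 1.0 if np.allclose(d, 0) else 0.0
            t = 0.0 if np.allclose(d, 0) else np.inf * np.sign(d.mean())
            rows.append({"metric": m, "t": float(t), "p": p,
                         "mean_diff": float(d.mean()), "degenerate": True})
            continue
        t, p = stats.ttest_rel(c, b)
        rows.append({"metric": m, "t": float(t), "p": float(p),
                     "mean_diff": float(d.mean()), "degenerate": False})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Per-fold metric records plus aggregates and paired-test results."""

    records: pd.DataFrame      # task, model, configuration, protocol, fold, metrics
    paired: pd.DataFrame       # task, model, protocol, metric, t, p
    subject_decisions: pd.DataFrame
    curation_artifacts: dict   # (model, fold) -> CurationResult.to_dict()

    def aggregates(self) -> pd.DataFrame:
        """mean +/- sd per (task, model, configuration, protocol, metric)."""
        keys = ["task", "model", "configuration", "protocol"]
        agg = self.records.groupby(keys)[list(METRIC_NAMES)].agg(["mean", "std"])
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        return agg.reset_index()

    def table(self) -> str:
        agg = self.aggregates()
        lines = []
        for _, row in agg.iterrows():
            cells = [f"{row[f'{m}_mean']:.1f} ± {row[f'{m}_std']:.1f}"
                     for m in METRIC_NAMES[:-1]]
            auc = row["roc_auc_mean"]
            cells.append("-" if np.isnan(auc) else f"{auc:.3f}")
            lines.append("  ".join(
                [f"{row['task']:<8} {row['model']:<4} {row['configuration']:<8} "
                 f"{row['protocol']:<12}"] + cells))
        header = (f"{'task':<8} {'model':<4} {'config':<8} {'protocol':<12}  "
                  + "  ".join(f"{m}" for m in METRIC_NAMES))
        return "\n".join([header] + lines)

    def to_json(self, path) -> None:
        payload = {
            "records": self.records.to_dict(orient="list"),
            "paired": self.paired.to_dict(orient="list"),
            "subject_decisions": self.subject_decisions.to_dict(orient="list"),
            "curation_artifacts": {
                f"{k[0]}|{k[1]}": v for k, v in self.curation_artifacts.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            payload = json.load(fh)
        artifacts = {}
        for key, v in payload["curation_artifacts"].items():
            model, fold = key.split("|")
            artifacts[(model, int(fold))] = v
        return cls(records=pd.DataFrame(payload["records"]),
                   paired=pd.DataFrame(payload["paired"]),
                   subject_decisions=pd.DataFrame(payload["subject_decisions"]),
                   curation_artifacts=artifacts)


def run_experiment(matrix: FeatureMatrix, task: str,
                   models: list[str] = ("XGB",),
                   configurations: tuple[str, ...] = ("baseline", "crisp"),
                   plan: FoldPlan | None = None,
                   settings: PipelineSettings | None = None,
                   seed: int = 0) -> EvaluationReport:
    """Full cross-validated comparison for one task.

    The same folds serve every (model, configuration) pair so paired tests
    are paired by fold; both protocols are scored from the same predictions.
    """
    plan = plan or FoldPlan(seed=seed)
    settings = settings or PipelineSettings()
    folds = make_folds(matrix, plan)

    records, decisions, artifacts = [], [], {}
    fold_metrics: dict[tuple, dict[str, list[MetricSet]]] = {}
    for model_name in models:
        for configuration in configurations:
            for k, (tr, te) in enumerate(folds):
                spec = classify.ClassifierSpec(name=model_name, seed=seed + k)
                result = run_pipeline_fold(matrix, tr, te, configuration, spec,
                                           settings, fold=k)
                if result.curation is not None:
                    artifacts[(model_name, k)] = result.curation.to_dict()

                overall = compute_metrics(result.y_true, result.y_pred,
                                          result.posteriors)
                votes = subject_vote(result.y_pred, result.posteriors,
                                     result.subject_ids, y_true=result.y_true)
                subj_post = pd.DataFrame(
                    {c: votes[f"posterior_{c}"] for c in result.posteriors.columns})
                subject = compute_metrics(votes["truth"].to_numpy(),
                                          votes["decision"].to_numpy(), subj_post)
                votes.insert(0, "fold", k)
                votes.insert(0, "configuration", configuration)
                votes.insert(0, "model", model_name)
                votes.insert(0, "task", task)
                decisions.append(votes)

                for protocol, ms in (("overall", overall), ("subject_wise", subject)):
                    rec = {"task": task, "model": model_name,
                           "configuration": configuration, "protocol": protocol,
                           "fold": k}
                    rec.update(ms.as_dict())
                    records.append(rec)
                    fold_metrics.setdefault((model_name, protocol), {}) \
                        .setdefault(configuration, []).append(ms)

    paired_rows = []
    if set(configurations) >= {"baseline", "crisp"}:
        for (model_name, protocol), cfgs in fold_metrics.items():
            cmp_df = paired_compare(cfgs["baseline"], cfgs["crisp"])
            cmp_df.insert(0, "protocol", protocol)
            cmp_df.insert(0, "model", model_name)
            cmp_df.insert(0, "task", task)
            paired_rows.append(cmp_df)
    paired = (pd.concat(paired_rows, ignore_index=True) if paired_rows
              else pd.DataFrame(columns=["task", "model", "protocol", "metric",
                                         "t", "p", "mean_diff", "degenerate"]))
    return EvaluationReport(
        records=pd.DataFrame(records), paired=paired,
        subject_decisions=pd.concat(decisions, ignore_index=True),
        curation_artifacts=artifacts,
    )
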