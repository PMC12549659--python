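"""Feature curation: correlation pruning with MI tie-breaking, then RFE.

Stage one flags feature pairs whose pairwise Pearson correlation, rounded to
two decimals, reaches |r| >= 0.80, and drops from each flagged pair the
member carrying less mutual information with the diagnostic label.  Stage
two runs recursive feature elimination with a 100-tree random forest down to
ten features.  Both stages must be fitted on training rows only; the
evaluation module enforces that contract.

Mutual information is estimated by quantile-discretizing the feature into
(by default) ten bins and applying the plug-in formula to the bin-by-label
contingency table.  Quantile binning makes the estimate invariant to
strictly monotone transforms of the feature and exactly zero for constant
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE

from .errors import ConfigError

DEFAULT_R_THRESHOLD = 0.80
DEFAULT_MI_BINS = 10
DEFAULT_N_KEEP = 10
DEFAULT_N_TREES = 100


def pearson_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Symmetric unit-diagonal correlation table (full precision).

    Zero-variance columns correlate 0 with everything (warned), keeping the
    table finite.
    """
    if len(X) < 2:
        raise ValueError("need >= 2 rows to correlate")
    corr = X.corr(method="pearson")
    constant = X.columns[X.nunique() <= 1]
    if len(constant):
        warnings.warn(f"zero-variance columns correlate as 0: {list(constant)}")
        corr.loc[constant, :] = 0.0
        corr.loc[:, constant] = 0.0
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def mutual_information(feature, labels, bins: int = DEFAULT_MI_BINS) -> float:
    """Plug-in MI (nats) between a quantile-binned feature and class labels."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        warnings.warn("single-class labels: MI is 0 by convention")
        return 0.0
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    codes = np.digitize(x, edges)
    joint = pd.crosstab(codes, y).to_numpy(dtype=float)
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


@dataclass
class PruneResult:
    retained: list
    dropped: list  # (dropped, partner, rounded |r|, MI_dropped, MI_partner)
    r_threshold: float
    mi: dict

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=[
            "dropped", "partner", "abs_r", "mi_dropped", "mi_partner"])


def correlation_prune(X: pd.DataFrame, y, r_threshold: float = DEFAULT_R_THRESHOLD,
                      bins: int = DEFAULT_MI_BINS) -> PruneResult:
    """Greedy pruning of collinear pairs, keeping the higher-MI member.

    Flagged pairs are visited by descending rounded |r|; a pair is resolved
    only if both members are still retained, so correlated chains collapse
    onto their most label-informative member.  MI ties drop the
    lexicographically later name (determinism).
    """
    corr = pearson_matrix(X)
    rounded = corr.abs().round(2)
    mi = {c: mutual_information(X[c], y, bins=bins) for c in X.columns}

    pairs = []
    cols = list(X.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = float(rounded.loc[a, b])
            if r >= r_threshold:
                pairs.append((r, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    retained = set(cols)
    dropped = []
    for r, a, b in pairs:
        if a not in retained or b not in retained:
            continue
        if mi[a] > mi[b]:
            keep, drop = a, b
        elif mi[b] > mi[a]:
            keep, drop = b, a
        else:
            keep, drop = sorted((a, b))  # tie: drop the later name
        retained.discard(drop)
        dropped.append((drop, keep, r, mi[drop], mi[keep]))
    return PruneResult(retained=[c for c in cols if c in retained],
                       dropped=dropped, r_threshold=r_threshold, mi=mi)


@dataclass
class RfeResult:
    selected: list
    ranking: dict  # feature -> elimination rank (1 = selected)
    importances: dict
    n_trees: int
    seed: int


def rfe_select(X: pd.DataFrame, y, n_keep: int = DEFAULT_N_KEEP,
               n_trees: int = DEFAULT_N_TREES, step: int = 1,
               seed: int = 0) -> RfeResult:
    """Recursive feature elimination with a seeded random forest.

    One feature (``step``) is dropped per iteration, giving a full
    elimination ranking; exactly ``n_keep`` features survive.
    """
    if X.shape[1] < n_keep:
        raise ConfigError(
            f"cannot keep {n_keep} features out of {X.shape[1]} columns")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rfe = RFE(estimator=rf, n_features_to_select=n_keep, step=step)
    rfe.fit(X.to_numpy(), np.asarray(y))
    ranking = dict(zip(X.columns, (int(r) for r in rfe.ranking_)))
    selected = [c for c in X.columns if ranking[c] == 1]
    final = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    final.fit(X[selected].to_numpy(), np.asarray(y))
    importances = dict(zip(selected, (float(v) for v in final.feature_importances_)))
    return RfeResult(selected=selected, ranking=ranking, importances=importances,
                     n_trees=n_trees, seed=seed)


@dataclass
class CurationResult:
    """Per-fold artifact: pruning outcome plus the RFE-selected subset."""

    prune: PruneResult
    rfe: RfeResult

    @property
    def selected(self) -> list:
        return self.rfe.selected

    def to_dict(self) -> dict:
        return {
            "r_threshold": self.prune.r_threshold,
            "retained_after_prune": self.prune.retained,
            "dropped_pairs": [
                {"dropped": d, "partner": p, "abs_r": r,
                 "mi_dropped": md, "mi_partner": mp}
                for d, p, r, md, mp in self.prune.dropped
            ],
            "selected": self.rfe.selected,
            "ranking": self.rfe.ranking,
            "importances": self.rfe.importances,
            "n_trees": self.rfe.n_trees,
            "seed": self.rfe.seed,
        }


def curate(X: pd.DataFrame, y, r_threshold: float = DEFAULT_R_THRESHOLD,
           n_keep: int = DEFAULT_N_KEEP, n_trees: int = DEFAULT_N_TREES,
           seed: int = 0) -> CurationResult:
    """Run both curation stages on training data."""
    prune = correlation_prune(X, y, r_threshold=r_threshold)
    rfe = rfe_select(X[prune.retained], y, n_keep=min(n_keep, len(prune.retained)),
                     n_trees=n_trees, seed=seed)
    return CurationResult(prune=prune, rfe=rfe)
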