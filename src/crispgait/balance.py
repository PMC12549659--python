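"""SMOTE class balancing implemented from the interpolation identity.

Each synthetic minority sample is x_new = x_i + delta * (x_zi - x_i), where
x_i is a minority-class row, x_zi one of its k same-class nearest neighbors
(Euclidean distance after per-fold standardization), and delta ~ Uniform[0,1].
Base rows are visited round-robin (lower coverage variance than uniform
random draws, and seed-reproducible); the neighbor and delta are random.
Every synthetic row records its (base, neighbor, delta) provenance so its
geometry can be re-verified exactly, and originals are emitted unchanged as
a prefix of the output.  Balancing runs only inside training folds — the
evaluation module enforces that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import BalanceError, GeometryError

GEOMETRY_TOL = 1e-9


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    target: str = "equalize_to_majority"  # or explicit {label: count}
    target_counts: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise BalanceError("k_neighbors must be >= 1")


def smote_oversample(X: pd.DataFrame, y, config: SmoteConfig | None = None
                     ) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Equalize class counts by synthetic interpolation.

    Returns (augmented matrix, augmented labels, provenance).  Provenance has
    one row per synthetic sample: output row index, base and neighbor row
    indices (positions within the original block), delta and class.
    """
    config = config or SmoteConfig()
    X = X.reset_index(drop=True)
    y = np.asarray(y)
    rng = np.random.default_rng(config.seed)
    counts = pd.Series(y).value_counts()
    if config.target_counts is not None:
        targets = dict(config.target_counts)
    else:
        targets = {label: int(counts.max()) for label in counts.index}

    # standardize on the (training) input for the neighbor metric only
    mu = X.mean(axis=0).to_numpy()
    sd = X.std(axis=0, ddof=0).to_numpy()
    sd[sd == 0] = 1.0
    Z = (X.to_numpy() - mu) / sd

    values = X.to_numpy()
    new_rows, new_labels, prov = [], [], []
    next_row = len(X)
    for label in counts.index:
        need = targets.get(label, counts[label]) - counts[label]
        if need <= 0:
            continue
        members = np.where(y == label)[0]
        if members.size < 2:
            raise BalanceError(
                f"minority class {label!r} has a single member; cannot interpolate")
        k = config.k_neighbors
        if k > members.size - 1:
            warnings.warn(f"class {label!r}: k truncated from {k} to {members.size - 1}")
            k = members.size - 1
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Z[members])
        _, idx = nn.kneighbors(Z[members])
        neighbors = idx[:, 1:]  # drop self

        for j in range(need):
            b = j % members.size  # round-robin base
            z = int(rng.integers(0, k))
            base = members[b]
            nb = members[neighbors[b, z]]
            delta = float(rng.uniform())
            new_rows.append(values[base] + delta * (values[nb] - values[base]))
            new_labels.append(label)
            prov.append({"row": next_row, "base": int(base), "neighbor": int(nb),
                         "delta": delta, "label": label})
            next_row += 1

    provenance = pd.DataFrame(prov, columns=["row", "base", "neighbor", "delta", "label"])
    if not new_rows:
        return X.copy(), y.copy(), provenance
    X_aug = pd.concat(
        [X, pd.DataFrame(new_rows, columns=X.columns)], ignore_index=True)
    y_aug = np.concatenate([y, np.asarray(new_labels, dtype=y.dtype)])
    return X_aug, y_aug, provenance


def verify_synthetic_geometry(X_aug: pd.DataFrame, y_aug, provenance: pd.DataFrame,
                              tol: float = GEOMETRY_TOL) -> dict:
    """Re-derive every synthetic row from its provenance and check it exactly.

    Raises GeometryError (listing offending rows) if any synthetic row strays
    from its recorded segment by more than ``tol`` per coordinate, or carries
    a class other than its base's.
    """
    values = X_aug.to_numpy()
    y_aug = np.asarray(y_aug)
    bad = []
    max_resid = 0.0
    for rec in provenance.itertuples(index=False):
        expected = values[rec.base] + rec.delta * (values[rec.neighbor] - values[rec.base])
        resid = float(np.max(np.abs(values[rec.row] - expected))) if values.size else 0.0
        max_resid = max(max_resid, resid)
        if resid > tol or y_aug[rec.row] != y_aug[rec.base]:
            bad.append(int(rec.row))
    if bad:
        raise GeometryError(f"synthetic rows off their segments or mislabeled: {bad}")
    return {"n_checked": len(provenance), "max_residual": max_resid, "ok": True}
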