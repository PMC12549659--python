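"""Per-cycle spatiotemporal gait features and per-subject summaries.

Each row of the feature matrix is one valid gait cycle of one foot.  The
default panel (27 named columns) covers the classic timing features (stride,
stance and swing times and percentages, cadence), the stance-to-swing ratio,
distance features derived from a reference walking speed (stride length,
step length, gait speed), trailing-window variability of the timing series,
left/right asymmetry indices, the contralateral foot's timing, and bilateral
means.  Several columns are deliberately collinear by construction (e.g.
swing percentage mirrors stance percentage); the curation stage exists to
prune them.

Stride length cannot be measured from vertical force alone, so it is modeled
as reference_speed x stride_time, with the reference speed taken per subject
from demographics when available (``speed_mps`` column) and from the feature
config otherwise.  This is a modeling choice, not a measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError
from .events import GaitCycle, ValidityConfig, detect_walk_events, segment_cycles
from .io_physionet import SubjectMeta, VgrfRecording
from .preprocess import PreprocessConfig, preprocess_walk

META_COLUMNS = ["subject_id", "walk_id", "foot", "cycle_index"]
LABEL_COLUMN = "label"

BASE_FEATURES = [
    "stride_time", "stance_time", "swing_time", "stance_pct", "swing_pct",
    "cadence", "stance_swing_ratio", "step_time", "speed", "stride_length",
    "step_length",
]
VARIABILITY_FEATURES = ["stride_time_var", "stance_time_var", "swing_time_var",
                        "cadence_var"]
CV_FEATURES = ["stride_time_cv", "stance_time_cv"]
ASYMMETRY_FEATURES = ["stride_time_asym", "stance_time_asym"]
CONTRA_FEATURES = ["contra_stride_time", "contra_stance_time", "contra_swing_time",
                   "contra_stance_pct"]
BILATERAL_FEATURES = ["bilateral_stride_time", "bilateral_stance_time",
                      "bilateral_swing_time"]

DEFAULT_PANEL = (BASE_FEATURES + VARIABILITY_FEATURES + CV_FEATURES
                 + ASYMMETRY_FEATURES + CONTRA_FEATURES + BILATERAL_FEATURES
                 + ["foot_indicator"])


@dataclass
class FeatureConfig:
    variability_window: int = 10
    reference_speed: float = 1.2  # m/s fallback when demographics lack speed
    panel: list = field(default_factory=lambda: list(DEFAULT_PANEL))

    def __post_init__(self) -> None:
        if self.variability_window < 2:
            raise ConfigError("variability_window must be >= 2")


def cycle_features(cycle: GaitCycle, speed: float) -> dict:
    """Timing/distance features of one valid cycle (definitional arithmetic)."""
    if not cycle.valid:
        raise ValueError("cycle_features requires a valid cycle")
    stride = cycle.stride_time
    stance = cycle.stance_time
    swing = cycle.swing_time
    return {
        "stride_time": stride,
        "stance_time": stance,
        "swing_time": swing,
        "stance_pct": 100.0 * stance / stride,
        "swing_pct": 100.0 * swing / stride,
        "cadence": 120.0 / stride,
        "stance_swing_ratio": stance / swing,
        "step_time": stride / 2.0,
        "speed": speed,
        "stride_length": speed * stride,
        "step_length": speed * stride / 2.0,
    }


def rolling_variability(values, window: int = 10) -> np.ndarray:
    """Trailing-window sample standard deviation; NaN for the first window-1."""
    if window < 2:
        raise ConfigError("variability window must be >= 2")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window, min_periods=window).std(ddof=1).to_numpy()


@dataclass
class WalkCycles:
    """Segmented cycles of one walk, per foot, in temporal order."""

    subject_id: str
    walk_id: str
    cycles: dict  # foot -> list[GaitCycle]
    n_skipped: int = 0


def cycles_from_recording(recording: VgrfRecording,
                          preprocess_config: PreprocessConfig | None = None,
                          validity: ValidityConfig | None = None,
                          threshold_frac: float = 0.2) -> WalkCycles:
    """Preprocess one recording, detect its events and segment cycles."""
    rec = preprocess_walk(recording, preprocess_config)
    events = detect_walk_events(rec, threshold_frac=threshold_frac)
    out, skipped = {}, 0
    for foot, ev in events.items():
        cycles, n_skip = segment_cycles(ev, validity)
        out[foot] = cycles
        skipped += n_skip
    return WalkCycles(subject_id=recording.subject_id, walk_id=recording.walk_id,
                      cycles=out, n_skipped=skipped)


def _walk_frame(walk: WalkCycles, speed: float, window: int) -> pd.DataFrame:
    """Per-cycle rows for one walk: base panel + rolling/asymmetry/bilateral."""
    per_foot: dict[str, pd.DataFrame] = {}
    for foot in ("left", "right"):
        cycles = walk.cycles.get(foot, [])
        rows = []
        for idx, cyc in enumerate(cycles):
            base = {
                "subject_id": walk.subject_id, "walk_id": walk.walk_id,
                "foot": foot, "cycle_index": idx, "start_hs": cyc.start_hs,
                "valid": cyc.valid,
                "foot_indicator": 0.0 if foot == "left" else 1.0,
            }
            stride = cyc.stride_time
            stance = cyc.stance_time
            swing = cyc.swing_time
            base.update({
                "stride_time": stride, "stance_time": stance, "swing_time": swing,
                "stance_pct": 100.0 * stance / stride,
                "swing_pct": 100.0 * swing / stride,
                "cadence": 120.0 / stride,
                "stance_swing_ratio": stance / swing if swing > 0 else np.nan,
                "step_time": stride / 2.0,
                "speed": speed,
                "stride_length": speed * stride,
                "step_length": speed * stride / 2.0,
            })
            rows.append(base)
        if not rows:
            per_foot[foot] = pd.DataFrame()
            continue
        df = pd.DataFrame(rows)
        df["stride_time_var"] = rolling_variability(df["stride_time"], window)
        df["stance_time_var"] = rolling_variability(df["stance_time"], window)
        df["swing_time_var"] = rolling_variability(df["swing_time"], window)
        df["cadence_var"] = rolling_variability(df["cadence"], window)
        df["stride_time_cv"] = df["stride_time_var"] / df["stride_time"]
        df["stance_time_cv"] = df["stance_time_var"] / df["stance_time"]
        per_foot[foot] = df

    # pair cycle i with the contralateral cycle at the clamped index
    frames = []
    for foot, other in (("left", "right"), ("right", "left")):
        df = per_foot[foot]
        odf = per_foot[other]
        if df.empty:
            continue
        if odf.empty:
            continue  # single-foot walks cannot support bilateral features
        j = np.minimum(df["cycle_index"].to_numpy(), len(odf) - 1)
        o = odf.iloc[j].reset_index(drop=True)
        df = df.reset_index(drop=True)
        for col, ocol in (("contra_stride_time", "stride_time"),
                          ("contra_stance_time", "stance_time"),
                          ("contra_swing_time", "swing_time"),
                          ("contra_stance_pct", "stance_pct")):
            df[col] = o[ocol].to_numpy()
        for col, src in (("stride_time_asym", "stride_time"),
                         ("stance_time_asym", "stance_time")):
            a = df[src].to_numpy()
            b = o[src].to_numpy()
            df[col] = np.abs(a - b) / ((a + b) / 2.0)
        df["bilateral_stride_time"] = (df["stride_time"] + o["stride_time"].to_numpy()) / 2
        df["bilateral_stance_time"] = (df["stance_time"] + o["stance_time"].to_numpy()) / 2
        df["bilateral_swing_time"] = (df["swing_time"] + o["swing_time"].to_numpy()) / 2
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


@dataclass
class FeatureMatrix:
    """Row-per-cycle design matrix with metadata and task labels."""

    df: pd.DataFrame
    feature_columns: list
    label_column: str = LABEL_COLUMN
    n_dropped_warmup: int = 0
    n_dropped_invalid: int = 0

    @property
    def X(self) -> pd.DataFrame:
        return self.df[self.feature_columns]

    @property
    def y(self) -> pd.Series:
        return self.df[self.label_column]

    @property
    def subject_ids(self) -> pd.Series:
        return self.df["subject_id"]

    def __len__(self) -> int:
        return len(self.df)


def build_feature_matrix(walks: list[WalkCycles],
                         demographics: dict[str, SubjectMeta],
                         task: str = "binary",
                         config: FeatureConfig | None = None) -> FeatureMatrix:
    """Assemble the cohort feature matrix for one prediction task.

    binary: every subject labeled PD or HC.  severity: PD subjects only,
    labeled by Hoehn-Yahr stage (controls and unstaged PD rows excluded).
    Rows from invalid cycles and variability warm-up rows (the first
    window-1 cycles of each foot) are dropped and counted.
    """
    config = config or FeatureConfig()
    missing = sorted({w.subject_id for w in walks} - set(demographics))
    if missing:
        raise IntegrityError(f"subjects missing from demographics: {missing}")
    if task not in ("binary", "severity"):
        raise ConfigError(f"task must be 'binary' or 'severity', got {task!r}")

    frames = []
    for walk in walks:
        meta = demographics[walk.subject_id]
        speed = meta.speed_mps if meta.speed_mps is not None else config.reference_speed
        frame = _walk_frame(walk, speed, config.variability_window)
        if frame.empty:
            continue
        if task == "binary":
            frame[LABEL_COLUMN] = meta.group
        else:
            if meta.group != "PD":
                continue
            if meta.hoehn_yahr is None:
                warnings.warn(f"PD subject {walk.subject_id} lacks a stage; excluded "
                              "from the severity task")
                continue
            frame[LABEL_COLUMN] = meta.hoehn_yahr
        frames.append(frame)
    if not frames:
        raise IntegrityError("no cycles available to build a feature matrix")

    df = pd.concat(frames, ignore_index=True)
    n_invalid = int((~df["valid"]).sum())
    df = df[df["valid"]]
    feature_columns = [c for c in config.panel if c in df.columns]
    n_before = len(df)
    df = df.dropna(subset=feature_columns)
    n_warmup = n_before - len(df)
    df = df.sort_values(["subject_id", "walk_id", "foot", "start_hs"],
                        kind="mergesort").reset_index(drop=True)
    df = df.drop(columns=["valid"])
    return FeatureMatrix(df=df, feature_columns=feature_columns,
                         n_dropped_warmup=n_warmup, n_dropped_invalid=n_invalid)


def cohort_feature_matrix(recordings, demographics, task="binary",
                          preprocess_config=None, feature_config=None,
                          validity=None, threshold_frac=0.2) -> FeatureMatrix:
    """End-to-end: preprocess, detect, segment and assemble for a cohort."""
    walks = [cycles_from_recording(r, preprocess_config, validity, threshold_frac)
             for r in recordings]
    return build_feature_matrix(walks, demographics, task, feature_config)


def subject_summary(matrix: FeatureMatrix) -> pd.DataFrame:
    """Mean and standard deviation of every feature per subject.

    Single-cycle subjects get sd 0 with a warning (a degenerate spread, not
    a missing value).
    """
    if len(matrix) == 0:
        raise ValueError("empty feature matrix")
    g = matrix.df.groupby("subject_id")
    mean = g[matrix.feature_columns].mean()
    sd = g[matrix.feature_columns].std(ddof=1)
    singletons = g.size() == 1
    if singletons.any():
        warnings.warn(f"{int(singletons.sum())} subject(s) have a single cycle; "
                      "sd reported as 0")
        sd.loc[singletons[singletons].index] = 0.0
    mean.columns = [f"{c}_mean" for c in mean.columns]
    sd.columns = [f"{c}_sd" for c in sd.columns]
    out = pd.concat([mean, sd], axis=1)
    out[LABEL_COLUMN] = g[LABEL_COLUMN].first()
    return out.reset_index()
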