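"""Synthetic VGRF cohort generator with exact ground truth.

Each simulated walk is built from analytic per-foot stance templates: a
double-bump vertical force profile (loading-response peak near 25% of
stance, push-off peak near 75%, midstance valley at 0.7 of peak) supported
exactly on [heel-strike, toe-off] and zero during swing.  The template edges
rise steeply (sin^0.4), so the 20%-of-peak threshold used downstream crosses
within a few milliseconds of the true event — the generator's heel-strike
and toe-off times are therefore a usable oracle for the event detector.

Cohorts are hierarchical: per-subject timing parameters are drawn once from
class-level distributions (between-subject variance), then each gait cycle
perturbs them (within-subject variance).  Parkinsonian classes default to
longer stride and swing times, a higher stance percentage, reduced cadence
and reduced walking speed, with an additive per-Hoehn-Yahr-stage gradient;
these directions mirror the bradykinetic gait pattern the pipeline screens
for.  The 16 sensor channels split each foot's total force by fixed
nonnegative weights summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_physionet import (
    N_SENSORS, SubjectMeta, VgrfRecording, write_demographics, write_vgrf_record,
)

#: fixed heel→forefoot weight split of a foot's total force over its 8 sensors
SENSOR_WEIGHTS = np.array([0.18, 0.16, 0.14, 0.12, 0.11, 0.10, 0.10, 0.09])

FEATURE_TRUTH_COLUMNS = [
    "stride_time", "stance_time", "swing_time", "stance_pct", "swing_pct",
    "cadence", "speed", "stride_length", "step_length",
]


def stance_template(s: np.ndarray) -> np.ndarray:
    """Normalized double-bump stance profile on s ∈ [0, 1] (peak ≈ 0.87)."""
    s = np.clip(s, 0.0, 1.0)
    core = np.sin(np.pi * s) ** 0.4
    return core * (1.0 + 0.3 * np.cos(2 * np.pi * s) * np.sin(np.pi * s))


@dataclass
class ClassParams:
    """Timing distribution of one label class (seconds / dimensionless / m/s)."""

    stride_time_mean: float
    stance_fraction_mean: float
    speed_mean: float
    stride_time_sd_between: float = 0.05
    stride_time_sd_within: float = 0.02
    stance_fraction_sd_between: float = 0.015
    stance_fraction_sd_within: float = 0.008
    speed_sd_between: float = 0.08


# Defaults follow the screening literature's directional contrasts: PD walks
# with longer strides in time, higher stance percentage, lower speed, and
# elevated stride-to-stride variability (the within-subject sds), a hallmark
# of parkinsonian gait.  Between-subject overlap is deliberate: some stage-1
# PD subjects look like slow controls, so subject-wise classification is not
# trivially perfect.
DEFAULT_HC = ClassParams(stride_time_mean=1.04, stance_fraction_mean=0.615,
                         speed_mean=1.25)
DEFAULT_PD_STAGE1 = ClassParams(stride_time_mean=1.13, stance_fraction_mean=0.625,
                                speed_mean=1.08, stride_time_sd_within=0.035,
                                stance_fraction_sd_within=0.012)

#: well-separated PD class (~3-4 between-subject sd from controls on each
#: timing axis): a cohort whose Bayes error is negligible, for checks that
#: the pipeline machinery - not class overlap - limits accuracy
HIGH_SEPARATION_PD = ClassParams(stride_time_mean=1.22, stance_fraction_mean=0.66,
                                 speed_mean=0.92, stride_time_sd_within=0.045,
                                 stance_fraction_sd_within=0.014)


def high_separation_config(seed: int, n_per_class: int = 20,
                           **kwargs) -> "GaitSimConfig":
    """Low-noise, strongly separated cohort settings (negligible class overlap)."""
    return GaitSimConfig(n_per_class=n_per_class, seed=seed, noise_sd=5.0,
                         severity_gradient=0.08,
                         pd_stage1=replace(HIGH_SEPARATION_PD), **kwargs)


@dataclass
class GaitSimConfig:
    """Cohort-level simulation settings.

    ``severity_gradient`` shifts the PD stage-1 parameters per stage step:
    stage s adds ``(s - 1) * gradient`` to stride time and stance fraction
    and subtracts it (scaled) from walking speed.
    """

    n_per_class: int = 20
    walks_per_subject: int = 1
    walk_duration: float = 60.0
    sample_rate: float = 100.0
    body_force: float = 700.0
    noise_sd: float = 10.0
    hc: ClassParams = field(default_factory=lambda: replace(DEFAULT_HC))
    pd_stage1: ClassParams = field(default_factory=lambda: replace(DEFAULT_PD_STAGE1))
    stages: tuple[int, ...] = (1, 2, 3)
    stage_weights: Optional[tuple[float, ...]] = None  # severity imbalance knob
    n_hc: Optional[int] = None  # binary imbalance knob (default: n_per_class)
    severity_gradient: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walk_duration < 40.0:
            raise ConfigError("walk_duration must be >= 40 s so trimming leaves >= 10 s")
        for name, cp in (("hc", self.hc), ("pd_stage1", self.pd_stage1)):
            if not 0.0 < cp.stance_fraction_mean < 1.0:
                raise ConfigError(f"{name}: stance_fraction_mean must lie in (0, 1)")
            if cp.stride_time_mean <= 0:
                raise ConfigError(f"{name}: stride_time_mean must be positive")
        if self.stage_weights is not None and len(self.stage_weights) != len(self.stages):
            raise ConfigError("stage_weights must match the configured stage set")

    def params_for(self, group: str, stage: Optional[int]) -> ClassParams:
        if group == "HC":
            return self.hc
        base = self.pd_stage1
        step = 0 if stage is None else stage - self.stages[0]
        g = self.severity_gradient
        return replace(
            base,
            stride_time_mean=base.stride_time_mean + step * g,
            stance_fraction_mean=min(0.88, base.stance_fraction_mean + step * 0.3 * g),
            speed_mean=max(0.4, base.speed_mean - step * 2.0 * g),
            stride_time_sd_within=base.stride_time_sd_within + step * 0.1 * g,
        )


@dataclass
class SubjectParams:
    """Realized per-subject timing parameters (shared across the subject's walks)."""

    subject_id: str
    group: str
    stage: Optional[int]
    stride_time: float
    stance_fraction: float
    speed: float
    stride_time_sd_within: float
    stance_fraction_sd_within: float


@dataclass
class GroundTruth:
    """Exact template events and per-cycle features for one simulated walk."""

    subject_id: str
    walk_id: str
    group: str
    stage: Optional[int]
    heel_strikes: dict  # foot -> array of HS times (s, raw clock)
    toe_offs: dict      # foot -> array of TO times (s, raw clock)
    cycles: pd.DataFrame  # foot, cycle_index, start_hs + FEATURE_TRUTH_COLUMNS


def _draw_subject(config: GaitSimConfig, subject_id: str, group: str,
                  stage: Optional[int], rng: np.random.Generator) -> SubjectParams:
    cp = config.params_for(group, stage)
    stride = max(0.5, rng.normal(cp.stride_time_mean, cp.stride_time_sd_between))
    stance = float(np.clip(rng.normal(cp.stance_fraction_mean, cp.stance_fraction_sd_between),
                           0.45, 0.85))
    speed = max(0.3, rng.normal(cp.speed_mean, cp.speed_sd_between))
    return SubjectParams(
        subject_id=subject_id, group=group, stage=stage,
        stride_time=stride, stance_fraction=stance, speed=speed,
        stride_time_sd_within=cp.stride_time_sd_within,
        stance_fraction_sd_within=cp.stance_fraction_sd_within,
    )


def _foot_events(config: GaitSimConfig, sp: SubjectParams, start: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sequential HS/TO times for one foot until the walk ends."""
    hs, to = [], []
    t = start
    while True:
        stride = max(0.4, rng.normal(sp.stride_time, sp.stride_time_sd_within))
        frac = float(np.clip(rng.normal(sp.stance_fraction, sp.stance_fraction_sd_within),
                             0.42, 0.88))
        if frac >= 1.0:
            raise ConfigError("stance fraction >= 1 implies overlapping stances")
        t_to = t + frac * stride
        t_next = t + stride
        if t_to >= config.walk_duration - 0.05:
            break
        hs.append(t)
        to.append(t_to)
        t = t_next
    return np.asarray(hs), np.asarray(to)


def simulate_walk(config: GaitSimConfig, subject: SubjectParams, walk_id: str,
                  rng: np.random.Generator) -> tuple[VgrfRecording, GroundTruth]:
    """Simulate one walk of a subject, returning the recording and its truth."""
    n = int(round(config.walk_duration * config.sample_rate)) + 1
    time = np.arange(n) / config.sample_rate

    start_left = rng.uniform(0.2, 0.6)
    start_right = start_left + 0.5 * subject.stride_time
    events = {}
    totals = {}
    cycle_rows = []
    for foot, start in (("left", start_left), ("right", start_right)):
        hs, to = _foot_events(config, subject, start, rng)
        events[foot] = (hs, to)
        force = np.zeros(n)
        for h, t_off in zip(hs, to):
            i0 = int(np.ceil(h * config.sample_rate))
            i1 = int(np.floor(t_off * config.sample_rate))
            if i1 < i0:
                continue
            s = (time[i0:i1 + 1] - h) / (t_off - h)
            force[i0:i1 + 1] = config.body_force * stance_template(s)
        if config.noise_sd > 0:
            force = force + rng.normal(0.0, config.noise_sd, size=n)
        totals[foot] = np.clip(force, 0.0, None)

        for idx in range(len(hs) - 1):
            stride = hs[idx + 1] - hs[idx]
            stance = to[idx] - hs[idx]
            swing = stride - stance
            cycle_rows.append({
                "foot": foot, "cycle_index": idx, "start_hs": hs[idx],
                "stride_time": stride, "stance_time": stance, "swing_time": swing,
                "stance_pct": 100.0 * stance / stride,
                "swing_pct": 100.0 * swing / stride,
                "cadence": 120.0 / stride,
                "speed": subject.speed,
                "stride_length": subject.speed * stride,
                "step_length": subject.speed * stride / 2.0,
            })

    sensors = np.empty((n, N_SENSORS))
    sensors[:, :8] = totals["left"][:, None] * SENSOR_WEIGHTS[None, :]
    sensors[:, 8:] = totals["right"][:, None] * SENSOR_WEIGHTS[None, :]
    # totals written as the exact per-row sensor sums for read-back consistency
    total_left = sensors[:, :8].sum(axis=1)
    total_right = sensors[:, 8:].sum(axis=1)

    recording = VgrfRecording(
        subject_id=subject.subject_id, walk_id=walk_id, cohort="SYN",
        sample_rate=config.sample_rate, time=time, sensors=sensors,
        total_left=total_left, total_right=total_right,
    )
    truth = GroundTruth(
        subject_id=subject.subject_id, walk_id=walk_id,
        group=subject.group, stage=subject.stage,
        heel_strikes={f: ev[0] for f, ev in events.items()},
        toe_offs={f: ev[1] for f, ev in events.items()},
        cycles=pd.DataFrame(cycle_rows),
    )
    return recording, truth


#: trim-edge margin (s) inside which template events are not recoverable:
#: the reflect-padded median filter (kernel 9 at 100 Hz) can smear a stance
#: edge across the window boundary, so such stances are dropped as partial.
EDGE_MARGIN_S = 0.06


def recoverable_events(truth: GroundTruth, foot: str, t_start: float, t_end: float,
                       margin: float = EDGE_MARGIN_S) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (HS, TO) pairs whose stance lies fully inside a window."""
    hs = truth.heel_strikes[foot]
    to = truth.toe_offs[foot]
    keep = (hs > t_start + margin) & (to < t_end - margin)
    return hs[keep], to[keep]


@dataclass
class Cohort:
    """A simulated study: recordings, demographics and per-walk ground truth."""

    recordings: list
    demographics: dict
    truths: dict  # (subject_id, walk_id) -> GroundTruth
    config: GaitSimConfig


def _stage_counts(config: GaitSimConfig, n_pd: int) -> dict[int, int]:
    stages = config.stages
    if config.stage_weights is None:
        weights = np.ones(len(stages))
    else:
        weights = np.asarray(config.stage_weights, dtype=float)
    raw = weights / weights.sum() * n_pd
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n_pd - counts.sum()]:
        counts[i] += 1
    return dict(zip(stages, counts))


def simulate_cohort(config: GaitSimConfig, task: str = "binary") -> Cohort:
    """Simulate a labeled cohort for the binary or severity task.

    binary: ``n_per_class`` PD subjects (stages assigned by ``stage_weights``)
    and ``n_per_class`` controls.  severity: PD subjects only, with per-stage
    counts driven by ``stage_weights`` over ``n_per_class * len(stages)``.
    """
    if task not in ("binary", "severity"):
        raise ConfigError(f"task must be 'binary' or 'severity', got {task!r}")
    if config.n_per_class < 2:
        raise ConfigError("n_per_class must be >= 2 for cross-validation use")
    rng = np.random.default_rng(config.seed)

    plan: list[tuple[str, Optional[int]]] = []
    if task == "binary":
        stage_counts = _stage_counts(config, config.n_per_class)
        for stage, cnt in stage_counts.items():
            plan += [("PD", stage)] * cnt
        n_hc = config.n_hc if config.n_hc is not None else config.n_per_class
        plan += [("HC", None)] * n_hc
    else:
        total_pd = config.n_per_class * len(config.stages)
        for stage, cnt in _stage_counts(config, total_pd).items():
            plan += [("PD", stage)] * cnt

    recordings, truths, demographics = [], {}, {}
    counters = {"PD": 0, "HC": 0}
    for group, stage in plan:
        counters[group] += 1
        tag = "Pt" if group == "PD" else "Co"
        sid = f"SYN{tag}{counters[group]:03d}"
        sp = _draw_subject(config, sid, group, stage, rng)
        demographics[sid] = SubjectMeta(
            subject_id=sid, group=group, hoehn_yahr=stage,
            speed_mps=round(sp.speed, 4),
        )
        for w in range(config.walks_per_subject):
            walk_id = f"{w + 1:02d}"
            rec, truth = simulate_walk(config, sp, walk_id, rng)
            recordings.append(rec)
            truths[(sid, walk_id)] = truth
    return Cohort(recordings=recordings, demographics=demographics,
                  truths=truths, config=config)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort to disk: 19-column walk records, demographics CSV and
    a ground-truth sidecar CSV per walk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        write_vgrf_record(rec, out / f"{rec.subject_id}_{rec.walk_id}.txt")
    write_demographics(cohort.demographics, out / "demographics.csv")
    for (sid, wid), truth in cohort.truths.items():
        truth.cycles.to_csv(out / f"{sid}_{wid}_truth.csv", index=False)
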