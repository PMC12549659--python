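"""Heel-strike / toe-off detection and gait-cycle segmentation.

Events are threshold crossings of each foot's total vertical force at 20% of
that channel's peak: heel strike (HS) at the upward crossing, toe off (TO)
at the subsequent downward crossing.  Crossing times are refined by linear
interpolation between the bracketing samples, so event timing is not
quantized to the 100 Hz grid.  A gait cycle spans two successive same-foot
heel strikes; stance is HS→TO and swing is TO→next HS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_physionet import VgrfRecording

DEFAULT_THRESHOLD_FRAC = 0.2
DEFAULT_DEBOUNCE_S = 0.1


@dataclass
class GaitEvents:
    foot: str
    heel_strikes: np.ndarray  # seconds, sorted
    toe_offs: np.ndarray      # seconds, sorted, same length, TO_i > HS_i
    peak_force: float
    threshold: float

    @property
    def n_stances(self) -> int:
        return int(self.heel_strikes.size)


@dataclass
class ValidityConfig:
    """Physiological bounds marking implausible cycles invalid (not dropped)."""

    stride_time_range: tuple[float, float] = (0.4, 2.5)
    stance_fraction_range: tuple[float, float] = (0.40, 0.90)


@dataclass
class GaitCycle:
    foot: str
    start_hs: float
    next_hs: float
    toe_off: float
    valid: bool = True
    reasons: list = field(default_factory=list)

    @property
    def stride_time(self) -> float:
        return self.next_hs - self.start_hs

    @property
    def stance_time(self) -> float:
        return self.toe_off - self.start_hs

    @property
    def swing_time(self) -> float:
        return self.next_hs - self.toe_off


def _interp_crossing(t0, t1, f0, f1, threshold) -> float:
    if f1 == f0:
        return float(t0)
    return float(t0 + (threshold - f0) / (f1 - f0) * (t1 - t0))


def detect_events(force: np.ndarray, sample_rate: float,
                  threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
                  foot: str = "left", time: Optional[np.ndarray] = None,
                  debounce_s: float = DEFAULT_DEBOUNCE_S) -> GaitEvents:
    """Detect HS/TO pairs on one foot's (filtered) total force.

    Stances are maximal runs of samples at or above the threshold; runs
    separated by gaps shorter than ``debounce_s`` are merged and runs shorter
    than ``debounce_s`` discarded (chatter suppression).  A leading run that
    starts at the first sample (partial stance) and a trailing run without a
    downward crossing are discarded.  Constant or all-zero force yields an
    empty result with a warning.
    """
    force = np.asarray(force, dtype=float)
    if time is None:
        time = np.arange(force.size) / sample_rate
    peak = float(np.max(force)) if force.size else 0.0
    threshold = threshold_frac * peak
    empty = GaitEvents(foot=foot, heel_strikes=np.empty(0), toe_offs=np.empty(0),
                       peak_force=peak, threshold=threshold)
    if force.size < 2 or peak <= 0 or np.min(force) == peak:
        warnings.warn(f"{foot}: constant or empty force channel; no events detected")
        return empty

    above = force >= threshold
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)   # first sample at/above
    ends = list(np.where(edges == -1)[0] + 1)    # first sample below
    if above[0]:
        # leading partial stance: drop its end
        if ends:
            ends.pop(0)
        else:
            return empty
    if above[-1] and starts:
        starts.pop()  # trailing HS without a TO

    runs = list(zip(starts, ends))
    if not runs:
        return empty

    # merge runs separated by sub-debounce gaps, then drop sub-debounce runs
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        gap = (time[s] - time[merged[-1][1]])
        if gap < debounce_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = debounce_s
    merged = [(s, e) for s, e in merged if time[e] - time[s] >= min_len]

    hs, to = [], []
    for s, e in merged:
        hs.append(_interp_crossing(time[s - 1], time[s], force[s - 1], force[s], threshold))
        to.append(_interp_crossing(time[e - 1], time[e], force[e - 1], force[e], threshold))
    return GaitEvents(foot=foot, heel_strikes=np.asarray(hs), toe_offs=np.asarray(to),
                      peak_force=peak, threshold=threshold)


def detect_walk_events(recording: VgrfRecording,
                       threshold_frac: float = DEFAULT_THRESHOLD_FRAC
                       ) -> dict[str, GaitEvents]:
    """Run detection independently on each foot's total force."""
    return {
        foot: detect_events(recording.foot_total(foot), recording.sample_rate,
                            threshold_frac=threshold_frac, foot=foot,
                            time=recording.time)
        for foot in ("left", "right")
    }


def segment_cycles(events: GaitEvents, validity: ValidityConfig | None = None
                   ) -> tuple[list[GaitCycle], int]:
    """Build one cycle per consecutive HS pair holding exactly one TO.

    Returns the cycles plus a count of HS pairs skipped for lacking a unique
    TO (missed detections).  Invalid cycles are retained with reason codes,
    never silently dropped.
    """
    validity = validity or ValidityConfig()
    hs = events.heel_strikes
    to = events.toe_offs
    cycles: list[GaitCycle] = []
    skipped = 0
    for i in range(len(hs) - 1):
        in_window = to[(to >= hs[i]) & (to < hs[i + 1])]
        if in_window.size != 1:
            skipped += 1
            continue
        cyc = GaitCycle(foot=events.foot, start_hs=float(hs[i]),
                        next_hs=float(hs[i + 1]), toe_off=float(in_window[0]))
        lo, hi = validity.stride_time_range
        if not lo <= cyc.stride_time <= hi:
            cyc.valid = False
            cyc.reasons.append("stride_out_of_range")
        frac = cyc.stance_time / cyc.stride_time
        flo, fhi = validity.stance_fraction_range
        if not flo <= frac <= fhi:
            cyc.valid = False
            cyc.reasons.append("stance_fraction_out_of_range")
        cycles.append(cyc)
    return cycles, skipped
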