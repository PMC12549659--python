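"""Signal conditioning: min-max normalization, head/tail trimming, median filter.

The stage order is normalize → trim → median-filter.  Because the downstream
heel-strike/toe-off detector thresholds at a fixed fraction of each channel's
peak, min-max normalization does not move event times; it is kept for scale
comparability across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter as _ndi_median

from .errors import ConfigError, TrimError
from .io_physionet import VgrfRecording

MIN_REMAINING_S = 10.0


@dataclass
class PreprocessConfig:
    head_trim: float = 20.0
    tail_trim: float = 10.0
    median_kernel: int = 9
    normalize: bool = True
    #: opt-in for walks shorter than head+tail+10 s: trim 1/3 head, 1/6 tail
    proportional_short_walks: bool = False

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ConfigError(f"median_kernel must be odd and >= 1, got {self.median_kernel}")
        if self.head_trim < 0 or self.tail_trim < 0:
            raise ConfigError("head_trim and tail_trim must be >= 0")


def minmax_normalize(recording: VgrfRecording) -> VgrfRecording:
    """Map every channel to [0, 1] per channel per recording.

    Constant channels (zero range) map to all-zeros with a warning.
    """
    def _scale(x: np.ndarray, name: str) -> np.ndarray:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi == lo:
            warnings.warn(f"channel {name} is constant; normalized to zeros")
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)

    sensors = np.column_stack([
        _scale(recording.sensors[:, j], f"sensor{j + 1}")
        for j in range(recording.sensors.shape[1])
    ])
    return recording.replace(
        sensors=sensors,
        total_left=_scale(recording.total_left, "total_left"),
        total_right=_scale(recording.total_right, "total_right"),
    )


def trim(recording: VgrfRecording, config: PreprocessConfig) -> VgrfRecording:
    """Drop the head/tail seconds of the walk and re-zero the time base."""
    head, tail = config.head_trim, config.tail_trim
    duration = recording.duration
    if duration - head - tail < MIN_REMAINING_S:
        if config.proportional_short_walks:
            head, tail = duration / 3.0, duration / 6.0
        else:
            raise TrimError(
                f"walk of {duration:.1f} s leaves < {MIN_REMAINING_S:.0f} s after "
                f"trimming {head:.0f}+{tail:.0f} s"
            )
    t = recording.time
    keep = (t >= t[0] + head - 1e-9) & (t <= t[-1] - tail + 1e-9)
    idx = np.where(keep)[0]
    new_time = t[idx]
    offset = float(new_time[0])
    return recording.replace(
        time=new_time - offset,
        sensors=recording.sensors[idx],
        total_left=recording.total_left[idx],
        total_right=recording.total_right[idx],
        time_origin=recording.time_origin + offset,
    )


def median_filter(signal: np.ndarray, kernel: int) -> np.ndarray:
    """Sliding-window median with reflect padding; length-preserving."""
    if kernel % 2 == 0 or kernel < 1:
        raise ConfigError(f"median filter kernel must be odd and >= 1, got {kernel}")
    signal = np.asarray(signal, dtype=float)
    if signal.size < kernel:
        raise ConfigError(
            f"signal of length {signal.size} shorter than kernel {kernel}"
        )
    if kernel == 1:
        return signal.copy()
    return _ndi_median(signal, size=kernel, mode="reflect")


def preprocess_walk(recording: VgrfRecording, config: PreprocessConfig | None = None
                    ) -> VgrfRecording:
    """Full conditioning chain: normalize, trim, median-filter every channel."""
    config = config or PreprocessConfig()
    rec = minmax_normalize(recording) if config.normalize else recording
    rec = trim(rec, config)
    k = config.median_kernel
    sensors = np.column_stack([
        median_filter(rec.sensors[:, j], k) for j in range(rec.sensors.shape[1])
    ])
    return rec.replace(
        sensors=sensors,
        total_left=median_filter(rec.total_left, k),
        total_right=median_filter(rec.total_right, k),
    )
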