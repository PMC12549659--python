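"""Reading and writing VGRF walk records in the PhysioNet gait-database dialect.

A walk record is a whitespace-delimited text file sampled at 100 Hz with one
row per 10 ms: time in seconds, sixteen per-sensor vertical forces in Newtons
(eight under the left sole, L1..L8, then eight under the right, R1..R8), and
the summed force under each foot (total left, total right).  A companion
demographics table maps each subject to its diagnostic group (PD or healthy
control) and, for PD, a Hoehn & Yahr severity stage.

Force plates cannot pull, so negative readings are treated as sensor noise:
they are clipped to zero on read and counted on the recording.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, NamingError, ParseError

N_SENSORS = 16
PHYSIONET_COLUMNS = 1 + N_SENSORS + 2  # time + sensors + total L + total R
TIME_STEP_TOL = 1e-6

COHORTS = ("Ga", "Ju", "Si", "SYN")

#: <cohort><Pt|Co><nn>_<ww>.txt — e.g. GaPt03_01.txt, SYNCo007_02.txt
_WALK_RE = re.compile(r"^(Ga|Ju|Si|SYN)(Pt|Co)(\d+)_(\d+)\.txt$")


@dataclass
class VgrfRecording:
    """One walk: time base, 16 sensor channels and per-foot total forces.

    ``time_origin`` carries the offset (in seconds of the original recording)
    of the first retained sample, so trimmed recordings can still be compared
    against event times expressed on the raw clock.
    """

    subject_id: str
    walk_id: str
    cohort: str
    sample_rate: float
    time: np.ndarray
    sensors: np.ndarray  # (n_samples, 16), L1..L8 then R1..R8
    total_left: np.ndarray
    total_right: np.ndarray
    time_origin: float = 0.0
    n_clipped_negative: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.sensors = np.asarray(self.sensors, dtype=float)
        self.total_left = np.asarray(self.total_left, dtype=float)
        self.total_right = np.asarray(self.total_right, dtype=float)
        n = self.time.size
        if n == 0:
            raise FormatError("empty recording")
        if self.sensors.shape != (n, N_SENSORS):
            raise FormatError(
                f"sensor block shape {self.sensors.shape} != ({n}, {N_SENSORS})"
            )
        if self.total_left.size != n or self.total_right.size != n:
            raise FormatError("total-force channels must match the time vector length")
        if n >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise FormatError("time vector is not strictly increasing")
            expected = 1.0 / self.sample_rate
            if np.any(np.abs(steps - expected) > TIME_STEP_TOL):
                raise FormatError(
                    f"time step not constant at 1/{self.sample_rate} s "
                    f"(max deviation {np.max(np.abs(steps - expected)):.2e} s)"
                )
        for name, arr in (("sensors", self.sensors), ("total_left", self.total_left),
                          ("total_right", self.total_right)):
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"non-finite values in {name}")

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        """Walk duration in seconds (last minus first sample time)."""
        return float(self.time[-1] - self.time[0])

    def foot_total(self, foot: str) -> np.ndarray:
        if foot == "left":
            return self.total_left
        if foot == "right":
            return self.total_right
        raise ValueError(f"foot must be 'left' or 'right', got {foot!r}")

    def replace(self, **kwargs) -> "VgrfRecording":
        """Return a copy with some fields replaced (re-validates invariants)."""
        data = {
            "subject_id": self.subject_id, "walk_id": self.walk_id,
            "cohort": self.cohort, "sample_rate": self.sample_rate,
            "time": self.time, "sensors": self.sensors,
            "total_left": self.total_left, "total_right": self.total_right,
            "time_origin": self.time_origin,
            "n_clipped_negative": self.n_clipped_negative,
        }
        data.update(kwargs)
        return VgrfRecording(**data)


@dataclass
class SubjectMeta:
    """Demographics row: diagnostic group plus optional severity and covariates."""

    subject_id: str
    group: str  # "PD" or "HC"
    hoehn_yahr: Optional[int] = None
    age: Optional[float] = None
    sex: Optional[str] = None
    speed_mps: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in ("PD", "HC"):
            raise FormatError(f"group must be PD or HC, got {self.group!r}")
        if self.hoehn_yahr is not None and self.group != "PD":
            raise FormatError(
                f"subject {self.subject_id}: Hoehn-Yahr stage given for a non-PD row"
            )


def parse_walk_filename(name: str) -> tuple[str, str, str]:
    """Decompose ``GaPt03_01.txt``-style names into (cohort, subject_id, walk_id)."""
    m = _WALK_RE.match(Path(name).name)
    if m is None:
        raise NamingError(
            f"unrecognized walk filename {name!r}; accepted patterns: "
            "<Ga|Ju|Si|SYN><Pt|Co><NN>_<WW>.txt (e.g. GaPt03_01.txt, SYNPt007_01.txt)"
        )
    cohort, grp, num, walk = m.groups()
    return cohort, f"{cohort}{grp}{num}", walk


def read_vgrf_record(path, dialect: str = "physionet19") -> VgrfRecording:
    """Read one walk record.

    ``physionet19`` expects 19 whitespace-delimited numeric columns (time,
    16 sensors, total left, total right); ``simple3`` expects time, total
    left, total right (sensor block filled with zeros — fixture use only).
    The sample rate is inferred from the median time step and, for the
    physionet19 dialect, must round to 100 Hz.
    """
    path = Path(path)
    if dialect not in ("physionet19", "simple3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = PHYSIONET_COLUMNS if dialect == "physionet19" else 3

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != ncols:
                raise ParseError(
                    f"{path.name}:{lineno}: expected {ncols} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric value ({exc})")
    if not rows:
        raise FormatError(f"{path.name}: empty record file")

    data = np.asarray(rows, dtype=float)
    time = data[:, 0]
    if time.size >= 2 and np.any(np.diff(time) <= 0):
        raise FormatError(f"{path.name}: non-monotone time column")

    if time.size >= 2:
        sample_rate = 1.0 / float(np.median(np.diff(time)))
    else:
        sample_rate = 100.0
    if dialect == "physionet19" and round(sample_rate) != 100:
        raise FormatError(
            f"{path.name}: inferred sample rate {sample_rate:.3f} Hz does not round to 100"
        )
    sample_rate = float(round(sample_rate))

    if dialect == "physionet19":
        sensors = data[:, 1:17]
        total_left = data[:, 17]
        total_right = data[:, 18]
    else:
        sensors = np.zeros((time.size, N_SENSORS))
        total_left = data[:, 1]
        total_right = data[:, 2]

    n_neg = int(np.sum(sensors < 0) + np.sum(total_left < 0) + np.sum(total_right < 0))
    if n_neg:
        sensors = np.clip(sensors, 0.0, None)
        total_left = np.clip(total_left, 0.0, None)
        total_right = np.clip(total_right, 0.0, None)

    try:
        cohort, subject_id, walk_id = parse_walk_filename(path.name)
    except NamingError:
        cohort, subject_id, walk_id = "SYN", path.stem, "01"

    return VgrfRecording(
        subject_id=subject_id, walk_id=walk_id, cohort=cohort,
        sample_rate=sample_rate, time=time, sensors=sensors,
        total_left=total_left, total_right=total_right,
        n_clipped_negative=n_neg,
    )


def write_vgrf_record(recording: VgrfRecording, path) -> None:
    """Write a recording back out as 19-column whitespace-delimited text."""
    data = np.column_stack([
        recording.time, recording.sensors,
        recording.total_left, recording.total_right,
    ])
    np.savetxt(path, data, fmt="%.6f", delimiter="\t")


_ID_ALIASES = ("subject_id", "id", "subject")
_GROUP_ALIASES = ("group", "diagnosis")
_HY_ALIASES = ("hoehn_yahr", "hoehnyahr", "hy", "severity", "stage")


def _find_column(columns, aliases, what):
    lowered = {c.lower(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    raise FormatError(f"demographics table lacks a {what} column (tried {aliases})")


def read_demographics(path) -> dict[str, SubjectMeta]:
    """Read the subject table (CSV/TSV with header) into SubjectMeta keyed by id."""
    df = pd.read_csv(path, sep=None, engine="python")
    id_col = _find_column(df.columns, _ID_ALIASES, "subject id")
    group_col = _find_column(df.columns, _GROUP_ALIASES, "group")
    hy_col = _find_column(df.columns, _HY_ALIASES, "severity")
    lowered = {c.lower(): c for c in df.columns}

    out: dict[str, SubjectMeta] = {}
    for _, row in df.iterrows():
        sid = str(row[id_col]).strip()
        if sid in out:
            raise IntegrityError(f"duplicate subject_id {sid!r} in demographics")
        group = str(row[group_col]).strip().upper()
        if group in ("CO", "CONTROL", "HEALTHY"):
            group = "HC"
        elif group in ("PT", "PATIENT"):
            group = "PD"
        hy_raw = row[hy_col]
        hy: Optional[int] = None
        if not (pd.isna(hy_raw) or str(hy_raw).strip() in ("", "-", "–", "NA", "None")):
            hy = int(float(hy_raw))
        if group == "PD" and hy is None:
            warnings.warn(f"PD subject {sid} has no Hoehn-Yahr stage; recorded as absent")
        if group == "HC" and hy is not None:
            warnings.warn(f"HC subject {sid} carries a severity stage; ignored")
            hy = None

        def _opt(alias_tuple, cast):
            for a in alias_tuple:
                if a in lowered and not pd.isna(row[lowered[a]]):
                    return cast(row[lowered[a]])
            return None

        out[sid] = SubjectMeta(
            subject_id=sid, group=group, hoehn_yahr=hy,
            age=_opt(("age",), float),
            sex=_opt(("sex", "gender"), str),
            speed_mps=_opt(("speed_mps", "speed"), float),
        )
    return out


def demographics_frame(meta: dict[str, SubjectMeta]) -> pd.DataFrame:
    """Tabular view of a SubjectMeta mapping (one row per subject)."""
    return pd.DataFrame(
        [{
            "subject_id": m.subject_id, "group": m.group,
            "hoehn_yahr": m.hoehn_yahr, "age": m.age, "sex": m.sex,
            "speed_mps": m.speed_mps,
        } for m in meta.values()]
    )


def write_demographics(meta: dict[str, SubjectMeta], path) -> None:
    demographics_frame(meta).to_csv(path, index=False)
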