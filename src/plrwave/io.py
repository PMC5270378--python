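"""Reading, writing, validation and windowing of pupillogram recordings.

A *pupillogram* is the time series of pupil diameter (mm) recorded from one
eye under one chromatic stimulus condition: a light pulse (red 635 nm or
blue 470 nm, at 10 or 100 cd/m^2) followed by a recovery period, sampled at
a fixed rate (30 Hz by default). The four conditions are coded
``r10, r100, b10, b100``.

The canonical on-disk format is a long-format CSV with one sample per row
and columns ``subject,eye,eye_status,condition,time_s,diameter_mm``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

#: Fixed condition order used throughout the package.
CONDITIONS: tuple[str, ...] = ("r10", "r100", "b10", "b100")

EYES: tuple[str, ...] = ("left", "right")

EYE_STATUSES: tuple[str, ...] = (
    "healthy",
    "patient_normal",
    "patient_diseased",
    "unknown",
)

#: Mapping from eye status to the one-letter class label used in
#: classification: H healthy, N patient normal (age-affected), D diseased.
STATUS_TO_LABEL: Mapping[str, str] = {
    "healthy": "H",
    "patient_normal": "N",
    "patient_diseased": "D",
}

# Plausibility bounds for adult pupil diameter; violations after dropout
# repair indicate unit mistakes (e.g. micrometres) and are hard errors.
DIAMETER_BOUNDS_MM = (0.0, 12.0)

REQUIRED_COLUMNS = ("subject", "eye", "condition", "time_s", "diameter_mm")


@dataclass
class Pupillogram:
    """One eye x one condition diameter time series with stimulus timing.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    eye : {"left", "right"}
        Which eye was recorded.
    condition : {"r10", "r100", "b10", "b100"}
        Stimulus condition code (colour and luminance).
    diameters : ndarray of float
        Pupil diameter in millimetres at each sample.
    sampling_rate : float, default 30.0
        Samples per second.
    stimulus_onset_index : int, default 0
        Sample index at which the light pulse starts. Recordings that begin
        at light onset (the default acquisition protocol) use 0.
    stimulus_duration : float, default 10.0
        Length of the light pulse in seconds; also the length of the
        analysis window.
    eye_status : str, default "unknown"
        Clinical status of the eye, one of ``EYE_STATUSES``.
    """

    subject_id: str
    eye: str
    condition: str
    diameters: np.ndarray
    sampling_rate: float = 30.0
    stimulus_onset_index: int = 0
    stimulus_duration: float = 10.0
    eye_status: str = "unknown"

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)

    @property
    def label(self) -> str | None:
        """Class label H/N/D derived from eye status, or None if unknown."""
        return STATUS_TO_LABEL.get(self.eye_status)

    @property
    def window_length(self) -> int:
        """Number of samples in the stimulus analysis window."""
        return int(round(self.stimulus_duration * self.sampling_rate))

    def validate(self) -> None:
        """Check structural invariants; raise :class:`DataError` on failure."""
        if self.condition not in CONDITIONS:
            raise DataError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.eye not in EYES:
            raise DataError(f"unknown eye {self.eye!r}; expected one of {EYES}")
        if self.eye_status not in EYE_STATUSES:
            raise DataError(f"unknown eye_status {self.eye_status!r}")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        lo, hi = DIAMETER_BOUNDS_MM
        d = self.diameters
        if not np.all(np.isfinite(d)):
            raise DataError(
                f"{self._key()}: non-finite diameters present (repair dropouts first)"
            )
        if np.any(d <= lo) or np.any(d >= hi):
            raise DataError(
                f"{self._key()}: diameters outside plausible bounds {DIAMETER_BOUNDS_MM} mm"
            )
        if len(d) < self.stimulus_onset_index + self.window_length:
            raise DataError(
                f"{self._key()}: record too short for a full "
                f"{self.stimulus_duration}-s analysis window"
            )

    def _key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.eye, self.condition)


def analysis_window(pg: Pupillogram) -> np.ndarray:
    """Extract the stimulus-period samples used for feature extraction.

    The first ``stimulus_duration`` seconds after onset (300 samples at the
    30 Hz / 10 s defaults) carry the melanopsin-weighted constriction and
    sustain dynamics that the shape features summarize.

    Returns a copy of exactly ``round(stimulus_duration * sampling_rate)``
    samples starting at ``stimulus_onset_index``.
    """
    n = pg.window_length
    start = pg.stimulus_onset_index
    if start < 0 or start + n > len(pg.diameters):
        raise DataError(
            f"{pg._key()}: analysis window [{start}, {start + n}) exceeds "
            f"record length {len(pg.diameters)}"
        )
    return pg.diameters[start : start + n].copy()


def repair_dropouts(pg: Pupillogram, max_gap: int = 5) -> Pupillogram:
    """Linearly interpolate short dropout runs (blinks, tracking loss).

    A dropout sample is one that is missing (NaN) or non-positive. Runs of
    at most ``max_gap`` consecutive dropouts are replaced by linear
    interpolation between the flanking valid samples; samples outside
    dropout runs are never altered. A longer run, or a run touching the
    record boundary (no flanking value on one side), marks the record
    invalid and raises :class:`DataError`.
    """
    d = pg.diameters
    bad = ~np.isfinite(d) | (d <= 0)
    if not bad.any():
        return pg
    # run-length encode the bad mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], bad, [False])).astype(int)))
    starts, stops = edges[::2], edges[1::2]
    for start, stop in zip(starts, stops):
        if stop - start > max_gap:
            raise DataError(
                f"{pg._key()}: dropout run of {stop - start} samples exceeds "
                f"max_gap={max_gap}; record invalid"
            )
        if start == 0 or stop == len(d):
            raise DataError(
                f"{pg._key()}: dropout at record boundary cannot be interpolated"
            )
    idx = np.arange(len(d))
    repaired = d.copy()
    repaired[bad] = np.interp(idx[bad], idx[~bad], d[~bad])
    return replace(pg, diameters=repaired)


@dataclass
class RecordingSet:
    """A cohort of pupillograms keyed by (subject_id, eye, condition).

    A complete subject carries exactly 8 pupillograms (2 eyes x 4
    conditions). Labels follow eye status: a healthy subject has two H
    eyes; a patient has one age-affected normal (N) and one diseased (D)
    eye.
    """

    records: dict[tuple[str, str, str], Pupillogram] = field(default_factory=dict)

    def add(self, pg: Pupillogram) -> None:
        self.records[pg._key()] = pg

    def get(self, subject_id: str, eye: str, condition: str) -> Pupillogram:
        return self.records[(subject_id, eye, condition)]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Pupillogram]:
        return iter(self.records.values())

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid, _, _ in self.records:
            seen.setdefault(sid)
        return list(seen)

    def eyes_of(self, subject_id: str) -> list[str]:
        seen: dict[str, None] = {}
        for sid, eye, _ in self.records:
            if sid == subject_id:
                seen.setdefault(eye)
        return list(seen)

    def missing(self, subject_id: str) -> list[tuple[str, str]]:
        """(eye, condition) pairs absent for a subject, in canonical order."""
        return [
            (eye, cond)
            for eye in EYES
            for cond in CONDITIONS
            if (subject_id, eye, cond) not in self.records
        ]

    def is_complete(self, subject_id: str) -> bool:
        return not self.missing(subject_id)

    def labels(self) -> dict[tuple[str, str], str]:
        """Map (subject_id, eye) -> H/N/D label where eye status is known."""
        out: dict[tuple[str, str], str] = {}
        for (sid, eye, _), pg in self.records.items():
            if pg.label is not None:
                out[(sid, eye)] = pg.label
        return out

    def validate(self) -> None:
        """Validate every record plus cohort-level label consistency."""
        for pg in self:
            pg.validate()
        for sid in self.subjects:
            statuses = sorted(
                {pg.eye_status for pg in self if pg.subject_id == sid}
            )
            if statuses == ["healthy"] or statuses == ["unknown"]:
                continue
            if statuses == ["patient_diseased", "patient_normal"]:
                continue
            raise DataError(
                f"subject {sid!r}: inconsistent eye statuses {statuses}; expected "
                "two healthy eyes or one patient_normal + one patient_diseased"
            )


def to_frame(rs: RecordingSet) -> pd.DataFrame:
    """Flatten a RecordingSet into the canonical long-format table."""
    parts = []
    for pg in rs:
        n = len(pg.diameters)
        parts.append(
            pd.DataFrame(
                {
                    "subject": pg.subject_id,
                    "eye": pg.eye,
                    "eye_status": pg.eye_status,
                    "condition": pg.condition,
                    "time_s": np.arange(n) / pg.sampling_rate,
                    "diameter_mm": pg.diameters,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_pupillograms(rs: RecordingSet, path: str | Path) -> None:
    """Write a RecordingSet to the canonical long-format CSV.

    Diameters are written with 6 decimal places, so a write/read round trip
    reproduces them to within 1e-6 mm; time is written with 9 decimals so
    the sampling rate re-inferred on read matches to sub-ppm accuracy.
    """
    df = to_frame(rs)
    df["time_s"] = df["time_s"].map(lambda v: f"{v:.9f}")
    df["diameter_mm"] = df["diameter_mm"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def read_pupillograms(
    path: str | Path,
    sampling_rate: float | None = None,
    stimulus_onset_index: int = 0,
    stimulus_duration: float = 10.0,
) -> RecordingSet:
    """Read pupillograms from the canonical long-format CSV.

    Parameters
    ----------
    path : path
        CSV with header ``subject,eye,[eye_status,]condition,time_s,diameter_mm``.
    sampling_rate : float, optional
        Override the rate inferred from the median time step of each group.
    stimulus_onset_index, stimulus_duration :
        Stimulus timing applied to every record (an ``onset_index`` column,
        if present, overrides the former per record).

    Raises
    ------
    FormatError
        Missing required column.
    DataError
        Non-monotone time within a group, or an unknown condition token.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required column(s) {missing_cols}")
    if "eye_status" not in df.columns:
        df["eye_status"] = "unknown"

    rs = RecordingSet()
    for (sid, eye, cond), grp in df.groupby(
        ["subject", "eye", "condition"], sort=False
    ):
        if cond not in CONDITIONS:
            raise DataError(f"unknown condition token {cond!r} for subject {sid!r}")
        t = grp["time_s"].to_numpy(dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise DataError(
                f"non-monotone time within group ({sid!r}, {eye!r}, {cond!r})"
            )
        if sampling_rate is not None:
            rate = sampling_rate
        elif len(t) > 1:
            rate = 1.0 / float(np.median(np.diff(t)))
        else:
            rate = 30.0
        onset = stimulus_onset_index
        if "onset_index" in grp.columns:
            onset = int(grp["onset_index"].iloc[0])
        status = str(grp["eye_status"].iloc[0])
        rs.add(
            Pupillogram(
                subject_id=str(sid),
                eye=str(eye),
                condition=str(cond),
                diameters=grp["diameter_mm"].to_numpy(dtype=float),
                sampling_rate=rate,
                stimulus_onset_index=onset,
                stimulus_duration=stimulus_duration,
                eye_status=status,
            )
        )
    return rs
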