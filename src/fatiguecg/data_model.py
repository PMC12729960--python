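"""Core domain types: ECG records, fatigue classes, segments, study manifests.

A *study* is a collection of 10-minute single-lead ECG sessions recorded
three times daily (morning / noon / evening) over several days per
subject.  Each session carries one Borg RPE 6-20 self-report which is
mapped to an ordinal three-level fatigue class; every fixed-duration
segment cut from a session inherits the session's label.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SESSIONS = ("morning", "noon", "evening")

#: Default Borg 6-20 cutoffs: 6-11 normal, 12-14 slight fatigue, 15-20 fatigued.
#: The boundaries follow the customary RPE verbal anchors ("light" ends near 11,
#: "hard" starts near 15); they are configurable because published protocols vary.
DEFAULT_BORG_CUTOFFS = (11, 14)

BORG_MIN, BORG_MAX = 6, 20


class FatigueClass(enum.IntEnum):
    """Ordinal fatigue level: normal < slight < fatigued."""

    normal = 0
    slight = 1
    fatigued = 2


def map_borg_to_class(score: int, cutoffs: tuple[int, int] = DEFAULT_BORG_CUTOFFS) -> FatigueClass:
    """Map a Borg RPE 6-20 score to a three-level fatigue class.

    ``score <= cutoffs[0]`` is normal, ``cutoffs[0] < score <= cutoffs[1]``
    is slight fatigue, anything above is fatigued.  The mapping is monotone
    non-decreasing in ``score`` for every legal cutoff pair.
    """
    score = int(score)
    if not (BORG_MIN <= score <= BORG_MAX):
        raise ValueError(
            f"Borg score {score} outside the Borg 6-20 scale [{BORG_MIN}, {BORG_MAX}]"
        )
    c1, c2 = cutoffs
    if not (BORG_MIN < c1 <= c2 < BORG_MAX):
        raise ValueError(f"cutoffs must satisfy {BORG_MIN} < c1 <= c2 < {BORG_MAX}, got {cutoffs}")
    if score <= c1:
        return FatigueClass.normal
    if score <= c2:
        return FatigueClass.slight
    return FatigueClass.fatigued


@dataclass
class ECGRecord:
    """One continuous single-lead ECG recording (mV) with session metadata."""

    samples: np.ndarray
    fs: float
    subject_id: str = "s?"
    day: int = 1
    session: str = "morning"
    borg_score: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise ValueError(f"non-finite sample at index {bad[0]}")
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.borg_score is not None and not (BORG_MIN <= self.borg_score <= BORG_MAX):
            raise ValueError(f"Borg score {self.borg_score} outside [{BORG_MIN}, {BORG_MAX}]")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def session_key(self) -> tuple[str, int, str]:
        return (self.subject_id, self.day, self.session)


@dataclass
class Segment:
    """A fixed-duration labelled window cut from one session.

    ``provenance`` is ``(subject_id, day, session, segment_index)``; all
    segments from the same session share one label.
    """

    samples: np.ndarray
    fs: float
    label: FatigueClass
    provenance: tuple[str, int, str, int]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.provenance[3] < 0:
            raise ValueError("segment_index must be >= 0")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def session_key(self) -> tuple[str, int, str]:
        return self.provenance[:3]


@dataclass
class ManifestRow:
    subject_id: str
    day: int
    session: str
    borg: int
    path: str | None = None
    record: ECGRecord | None = None  # in-memory alternative to a file path
    rejected: bool = False
    reject_reason: str | None = None

    @property
    def session_key(self) -> tuple[str, int, str]:
        return (self.subject_id, self.day, self.session)

    @property
    def label(self) -> FatigueClass:
        return map_borg_to_class(self.borg)


@dataclass
class StudyManifest:
    """Index of a study's sessions; (subject_id, day, session) keys are unique."""

    rows: list[ManifestRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for row in self.rows:
            key = row.session_key
            if key in seen:
                raise ValueError(f"duplicate session key {key} in manifest")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def subjects(self) -> list[str]:
        return sorted({r.subject_id for r in self.rows})

    def load_record(self, row: ManifestRow) -> ECGRecord:
        """Return the session recording for ``row``, reading from disk if needed."""
        if row.record is not None:
            return row.record
        if row.path is None:
            raise ValueError(f"manifest row {row.session_key} has neither record nor path")
        rec = read_ecg(row.path)
        rec.subject_id, rec.day, rec.session = row.session_key
        rec.borg_score = row.borg
        return rec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.rows],
                "day": [r.day for r in self.rows],
                "session": [r.session for r in self.rows],
                "borg": [r.borg for r in self.rows],
                "path": [r.path for r in self.rows],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def write_ecg(path: str | Path, record: ECGRecord) -> None:
    """Write a record in the package CSV dialect: ``fs=<Hz>`` header line,
    then one mV sample per line at full repr precision."""
    with open(path, "w") as fh:
        fh.write(f"fs={float(record.fs)!r}\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")


def read_ecg(path: str | Path, format: str = "csv") -> ECGRecord:
    """Read an ECG sample file.

    Only the package CSV dialect is supported (``fs=<Hz>`` header, one
    sample per line); it round-trips bit-exactly with :func:`write_ecg`.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}; only 'csv' is available")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("fs="):
            raise ValueError(f"{path}: missing 'fs=<Hz>' header line")
        try:
            fs = float(header[3:])
        except ValueError as exc:
            raise ValueError(f"{path}: cannot parse sampling rate from {header!r}") from exc
        values = []
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                v = float(line)
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable sample at row {i}") from exc
            if not np.isfinite(v):
                raise ValueError(f"{path}: non-finite sample at row {i}")
            values.append(v)
    return ECGRecord(samples=np.array(values), fs=fs)


REQUIRED_MANIFEST_COLUMNS = ("subject_id", "day", "session", "borg", "path")


def load_manifest(path: str | Path) -> StudyManifest:
    """Load a study manifest CSV with columns subject_id,day,session,borg,path.

    Duplicate (subject, day, session) keys raise; Borg scores are validated
    against the 6-20 scale.  An empty file yields an empty manifest with a
    logged warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("manifest %s is empty", path)
        return StudyManifest([])
    if df.empty:
        logger.warning("manifest %s has no rows", path)
        return StudyManifest([])
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing required columns {missing}")
    rows = []
    for _, r in df.iterrows():
        map_borg_to_class(int(r["borg"]))  # validates the score
        p = r["path"]
        rows.append(
            ManifestRow(
                subject_id=str(r["subject_id"]),
                day=int(r["day"]),
                session=str(r["session"]),
                borg=int(r["borg"]),
                path=None if pd.isna(p) else str(p),
            )
        )
    manifest = StudyManifest(rows)
    base = path.parent
    for row in manifest:
        if row.path is not None:
            resolved = base / row.path if not Path(row.path).is_absolute() else Path(row.path)
            if not resolved.exists():
                raise FileNotFoundError(f"manifest references missing file {row.path}")
            row.path = str(resolved)
    return manifest


def labels_from_segments(segments: Iterable[Segment]) -> np.ndarray:
    return np.array([int(s.label) for s in segments])
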