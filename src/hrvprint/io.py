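"""Beat-annotated RR-interval series and a plain-text exchange format.

An ICD or Holter export reduces, for this analysis, to a list of RR-interval
durations (seconds), each labelled by the type of the beat that *ends* it:
``N`` for a sinus beat, ``V`` for a premature ventricular complex (PVC).
The on-disk dialect is two whitespace-separated columns::

    # recording_id: r001
    # patient_id: p01
    # outcome: pre_event
    0.812345 N
    0.795012 N
    0.501200 V

Header lines start with ``#`` and carry ``key: value`` metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np

VALID_LABELS = frozenset({"N", "V"})
VALID_OUTCOMES = frozenset({"pre_event", "control"})


class RRParseError(ValueError):
    """A malformed line in a two-column RR file (carries the line number)."""


class RRValidationError(ValueError):
    """A structurally parsed series that violates a series invariant."""


@dataclass(frozen=True)
class AnnotatedRRSeries:
    """Ordered RR intervals with N/V beat labels plus recording metadata.

    Parameters
    ----------
    intervals : array of float
        RR-interval durations in seconds, strictly positive and finite.
    labels : array of str
        One of ``"N"`` or ``"V"`` per interval, annotating the beat that
        terminates the interval.
    recording_id, patient_id : str
        Opaque identifiers.
    outcome : str
        ``"pre_event"`` (recording ends just before a VT/VF episode) or
        ``"control"``.
    """

    intervals: np.ndarray
    labels: np.ndarray
    recording_id: str = ""
    patient_id: str = ""
    outcome: str = "control"

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        labels = np.asarray(self.labels, dtype="<U1")
        object.__setattr__(self, "intervals", intervals)
        object.__setattr__(self, "labels", labels)
        if intervals.ndim != 1 or labels.ndim != 1:
            raise RRValidationError("intervals and labels must be 1-D sequences")
        if len(intervals) != len(labels):
            raise RRValidationError(
                f"length mismatch: {len(intervals)} intervals vs {len(labels)} labels"
            )
        if len(intervals) == 0:
            raise RRValidationError("empty series")
        if not np.all(np.isfinite(intervals)) or not np.all(intervals > 0):
            raise RRValidationError("all intervals must be finite and > 0")
        bad = set(labels.tolist()) - VALID_LABELS
        if bad:
            raise RRValidationError(f"invalid beat labels: {sorted(bad)}")
        if self.outcome not in VALID_OUTCOMES:
            raise RRValidationError(
                f"outcome must be one of {sorted(VALID_OUTCOMES)}, got {self.outcome!r}"
            )

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration_s(self) -> float:
        """Total recording duration in seconds (sum of intervals)."""
        return float(self.intervals.sum())

    @property
    def beat_times(self) -> np.ndarray:
        """Time of each interval-terminating beat (cumulative sum, seconds)."""
        return np.cumsum(self.intervals)

    @property
    def n_pvcs(self) -> int:
        return int(np.count_nonzero(self.labels == "V"))

    def equals(self, other: "AnnotatedRRSeries", atol: float = 1e-6) -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(np.abs(self.intervals - other.intervals) <= atol))
            and bool(np.all(self.labels == other.labels))
            and self.recording_id == other.recording_id
            and self.patient_id == other.patient_id
            and self.outcome == other.outcome
        )

    def with_metadata(self, **kwargs) -> "AnnotatedRRSeries":
        return replace(self, **kwargs)


def read_rr_series(path, dialect: str = "two_column") -> AnnotatedRRSeries:
    """Read a beat-annotated RR series from ``path``.

    Only the ``two_column`` text dialect is supported; a reader for raw
    PhysioNet annotation files is not implemented (export such accessions to
    the text dialect first).
    """
    if dialect == "wfdb_annotation":
        raise NotImplementedError(
            "direct PhysioNet annotation input is not implemented; convert the "
            "accession to the two-column text dialect first"
        )
    if dialect != "two_column":
        raise ValueError(f"unknown dialect {dialect!r}")

    path = Path(path)
    meta = {"recording_id": "", "patient_id": "", "outcome": "control"}
    intervals: list[float] = []
    labels: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip()
                    if key in meta:
                        meta[key] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise RRParseError(
                    f"{path}:{lineno}: expected '<interval_seconds> <label>', got {line!r}"
                )
            try:
                value = float(parts[0])
            except ValueError as exc:
                raise RRParseError(
                    f"{path}:{lineno}: interval {parts[0]!r} is not a number"
                ) from exc
            if parts[1] not in VALID_LABELS:
                raise RRParseError(
                    f"{path}:{lineno}: beat label {parts[1]!r} not in {sorted(VALID_LABELS)}"
                )
            intervals.append(value)
            labels.append(parts[1])
    if not intervals:
        raise RRValidationError(f"{path}: no interval data lines")
    return AnnotatedRRSeries(
        intervals=np.array(intervals),
        labels=np.array(labels),
        **meta,
    )


def write_rr_series(series: AnnotatedRRSeries, path) -> None:
    """Write ``series`` in the two-column dialect with a metadata header.

    Intervals are printed with six decimal places (microsecond precision),
    which the round-trip contract requires; repeated writes of the same
    series are byte-identical.
    """
    path = Path(path)
    lines = [
        f"# recording_id: {series.recording_id}",
        f"# patient_id: {series.patient_id}",
        f"# outcome: {series.outcome}",
    ]
    lines.extend(
        f"{iv:.6f} {lab}" for iv, lab in zip(series.intervals, series.labels)
    )
    path.write_text("\n".join(lines) + "\n")


def read_cohort(paths: Iterable) -> list[AnnotatedRRSeries]:
    """Read several two-column recordings, preserving order."""
    return [read_rr_series(p) for p in paths]
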