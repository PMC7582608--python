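"""Recording standardisation and derivation of the sinus-only (NN) series.

Recordings are truncated to their last 1000 beats so that short ICD
pre-event captures and longer control exports are comparable, checked for a
PVC-free tail (PVCs at the very end may already be part of the arrhythmia
onset and would leak outcome information into the features), and converted
to an NN series by replacing PVC-involved intervals with locally
interpolated sinus intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import AnnotatedRRSeries

logger = logging.getLogger(__name__)

DEFAULT_TRUNCATE_N = 1000
DEFAULT_TAIL_BEATS = 10


@dataclass(frozen=True)
class NNSeries:
    """Sinus-only interval series after PVC-interval replacement.

    ``intervals`` are in seconds; ``n_replaced`` counts how many entries of
    the source series were substituted (the V-labelled interval plus the
    immediately following interval, which ends the compensatory pause).
    """

    intervals: np.ndarray
    source_recording_id: str = ""
    n_replaced: int = 0

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        if not np.all(np.isfinite(intervals)) or not np.all(intervals > 0):
            raise ValueError("NN intervals must be finite and > 0")
        if self.n_replaced > len(intervals):
            raise ValueError("n_replaced exceeds series length")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum())

    @property
    def beat_times(self) -> np.ndarray:
        return np.cumsum(self.intervals)


def truncate_last_n(series: AnnotatedRRSeries, n: int = DEFAULT_TRUNCATE_N) -> AnnotatedRRSeries:
    """Keep only the final ``n`` beats of a recording.

    If the recording is already shorter than ``n`` it is returned unchanged
    and a warning is emitted. Metadata is preserved.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if len(series) <= n:
        if len(series) < n:
            warnings.warn(
                f"recording {series.recording_id!r} has {len(series)} beats "
                f"(< {n}); returned unchanged",
                stacklevel=2,
            )
        return series
    return AnnotatedRRSeries(
        intervals=series.intervals[-n:],
        labels=series.labels[-n:],
        recording_id=series.recording_id,
        patient_id=series.patient_id,
        outcome=series.outcome,
    )


def assert_pvc_free_tail(series: AnnotatedRRSeries, tail_beats: int = DEFAULT_TAIL_BEATS) -> bool:
    """True iff none of the final ``tail_beats`` beats is a PVC."""
    if tail_beats < 1:
        raise ValueError(f"tail_beats must be >= 1, got {tail_beats}")
    if tail_beats > len(series):
        raise ValueError(
            f"tail_beats={tail_beats} exceeds series length {len(series)}"
        )
    return not np.any(series.labels[-tail_beats:] == "V")


def estimate_nn_series(series: AnnotatedRRSeries) -> NNSeries:
    """Replace PVC-involved intervals with interpolated sinus estimates.

    Both the V-labelled interval (the coupling interval) and the interval
    immediately following it (ending the compensatory pause) are treated as
    non-sinus and replaced by linear interpolation between the nearest
    unaffected N intervals on either side. The output has the same length as
    the input, so the implicit beat-time axis is preserved for spectral
    analysis.
    """
    labels = series.labels
    n = len(series)
    is_v = labels == "V"
    replace_mask = is_v.copy()
    # successor of a V ends the compensatory pause
    replace_mask[1:] |= is_v[:-1]
    keep = ~replace_mask
    if keep.sum() < 2:
        raise ValueError(
            "need at least 2 unaffected N intervals to interpolate replacements"
        )
    idx = np.arange(n)
    out = series.intervals.astype(float).copy()
    out[replace_mask] = np.interp(
        idx[replace_mask], idx[keep], series.intervals[keep]
    )
    n_replaced = int(replace_mask.sum())
    if n_replaced:
        logger.debug(
            "recording %s: replaced %d of %d intervals",
            series.recording_id, n_replaced, n,
        )
    return NNSeries(
        intervals=out,
        source_recording_id=series.recording_id,
        n_replaced=n_replaced,
    )


def standardize_recording(
    series: AnnotatedRRSeries,
    truncate_n: int = DEFAULT_TRUNCATE_N,
    tail_beats: int = DEFAULT_TAIL_BEATS,
) -> AnnotatedRRSeries | None:
    """Truncate to the last ``truncate_n`` beats and apply the tail check.

    Returns the truncated recording, or ``None`` (with a logged reason) when
    the PVC-free-tail requirement fails — such recordings are excluded from
    the analysis rather than silently kept.
    """
    truncated = truncate_last_n(series, truncate_n)
    if not assert_pvc_free_tail(truncated, min(tail_beats, len(truncated))):
        logger.warning(
            "recording %s excluded: PVC within the final %d beats",
            series.recording_id, tail_beats,
        )
        return None
    return truncated
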