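"""Heartprint indices: PVC density, coupling intervals, and NIB patterns.

The "heartprint" characterises the temporal organisation of premature
ventricular complexes within a recording through three primitives:

* PVC density (PVCs/hour),
* the coupling interval (CI) — the RR interval from the preceding sinus
  beat to a PVC,
* the NIB sequence — the number of intervening sinus beats between each
  pair of consecutive PVCs.

Five summary indices are derived: PVCs/hour, meanCI, SDCI, the modal NIB
value (NIBmax) and the number of NIB entries attaining that mode (sNIB).
With fewer than two PVCs the CI/NIB summaries are undefined and carry NaN,
never a silent zero.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io import AnnotatedRRSeries


@dataclass(frozen=True)
class HeartprintIndices:
    """The 5 heartprint indices; NaN marks an undefined value."""

    pvcs_per_hour: float
    mean_ci: float  # ms
    sd_ci: float  # ms
    nib_mode: float  # most frequent NIB value (beats)
    s_nib: float  # count of NIB entries equal to the mode

    @property
    def defined(self) -> bool:
        """True when the CI/NIB summaries are available (>= 2 PVCs)."""
        return not np.isnan(self.mean_ci)


def coupling_intervals(series: AnnotatedRRSeries) -> np.ndarray:
    """Coupling intervals in ms, one per V interval preceded by an N beat.

    Because labels annotate the beat that terminates each interval, a
    V-labelled interval *is* the span from the previous beat to the PVC.
    V intervals immediately preceded by another V are excluded: their CI is
    not measured against a sinus beat. A V at the very start qualifies.
    """
    labels = series.labels
    is_v = labels == "V"
    qualifies = is_v.copy()
    qualifies[1:] &= labels[:-1] == "N"
    return series.intervals[qualifies] * 1000.0


def nib_sequence(series: AnnotatedRRSeries) -> np.ndarray:
    """Counts of sinus beats strictly between consecutive PVCs.

    Length is (#V − 1); an empty array (with a warning) when the recording
    has fewer than two PVCs.
    """
    v_pos = np.flatnonzero(series.labels == "V")
    if len(v_pos) < 2:
        warnings.warn("fewer than 2 PVCs: empty NIB sequence", stacklevel=2)
        return np.array([], dtype=int)
    return np.diff(v_pos) - 1


def heartprint_summary(series: AnnotatedRRSeries) -> HeartprintIndices:
    """All 5 heartprint indices for one recording.

    Modal ties in the NIB distribution are broken toward the smaller NIB
    value, deterministically.
    """
    duration_h = series.duration_s / 3600.0
    if duration_h <= 0:
        raise ValueError("zero-duration series")
    n_v = series.n_pvcs
    pvcs_per_hour = n_v / duration_h
    if n_v < 2:
        return HeartprintIndices(pvcs_per_hour, np.nan, np.nan, np.nan, np.nan)
    cis = coupling_intervals(series)
    if len(cis) == 0:
        mean_ci = sd_ci = np.nan
    else:
        mean_ci = float(np.mean(cis))
        sd_ci = float(np.std(cis, ddof=1)) if len(cis) > 1 else np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nibs = nib_sequence(series)
    counts = Counter(nibs.tolist())
    max_count = max(counts.values())
    nib_mode = min(v for v, c in counts.items() if c == max_count)
    return HeartprintIndices(
        pvcs_per_hour=float(pvcs_per_hour),
        mean_ci=mean_ci,
        sd_ci=sd_ci,
        nib_mode=float(nib_mode),
        s_nib=float(max_count),
    )
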