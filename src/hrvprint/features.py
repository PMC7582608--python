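"""Feature-table assembly and train-fitted min–max scaling.

Each recording contributes one row of 16 indices (11 HRV + 5 heartprint),
kept in a fixed column order; `recording_id`, `patient_id` and the binary
`outcome` (pre_event=1, control=0) travel as metadata columns. Before
modelling, undefined heartprint entries (recordings with sparse PVCs) are
imputed with training-column medians, and every column is mapped to
(x − min)/(max − min) with the min/max learned on the training rows only —
test values may fall outside [0, 1] and are deliberately not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .heartprint import heartprint_summary
from .hrv import DEFAULT_SPECTRAL, SpectralConfig, hrv_indices
from .io import AnnotatedRRSeries
from .preprocess import estimate_nn_series, truncate_last_n

#: the 16 indices, in their canonical report order
FEATURE_COLUMNS = [
    "meanNN l.m.",
    "SDCI",
    "meanNN",
    "meanCI",
    "LF/HF",
    "SDNN l.m.",
    "LFnu",
    "NIBmax",
    "RMSSD",
    "HFnu",
    "sNIB",
    "SDNN",
    "PVCs/hour",
    "pNN50",
    "LF",
    "HF",
]

HEARTPRINT_COLUMNS = ["SDCI", "meanCI", "NIBmax", "sNIB", "PVCs/hour"]
META_COLUMNS = ["recording_id", "patient_id", "outcome"]

OUTCOME_CODE = {"pre_event": 1, "control": 0}


def extract_features(
    series: AnnotatedRRSeries,
    cfg: SpectralConfig = DEFAULT_SPECTRAL,
    truncate_n: int = 1000,
) -> pd.Series:
    """One feature row (16 indices + metadata) for a recording.

    The recording is truncated to its last ``truncate_n`` beats; HRV indices
    are computed on the PVC-replaced NN series, heartprint indices on the
    annotated series itself. Undefined heartprint indices stay NaN.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trunc = truncate_last_n(series, truncate_n)
    nn = estimate_nn_series(trunc)
    h = hrv_indices(nn, cfg)
    hp = heartprint_summary(trunc)
    values = {
        "meanNN l.m.": h.mean_nn_lm,
        "SDCI": hp.sd_ci,
        "meanNN": h.mean_nn,
        "meanCI": hp.mean_ci,
        "LF/HF": h.lf_hf,
        "SDNN l.m.": h.sdnn_lm,
        "LFnu": h.lf_nu,
        "NIBmax": hp.nib_mode,
        "RMSSD": h.rmssd,
        "HFnu": h.hf_nu,
        "sNIB": hp.s_nib,
        "SDNN": h.sdnn,
        "PVCs/hour": hp.pvcs_per_hour,
        "pNN50": h.pnn50,
        "LF": h.lf,
        "HF": h.hf,
        "recording_id": series.recording_id,
        "patient_id": series.patient_id,
        "outcome": OUTCOME_CODE[series.outcome],
    }
    return pd.Series(values)[FEATURE_COLUMNS + META_COLUMNS]


def build_feature_table(
    recordings,
    cfg: SpectralConfig = DEFAULT_SPECTRAL,
    truncate_n: int = 1000,
) -> pd.DataFrame:
    """Stack `extract_features` rows for a collection of recordings."""
    rows = [extract_features(r, cfg, truncate_n) for r in recordings]
    df = pd.DataFrame(rows).reset_index(drop=True)
    df["outcome"] = df["outcome"].astype(int)
    return df


def fit_imputer(train: pd.DataFrame) -> pd.Series:
    """Training-column medians of the heartprint indices (for NaN imputation)."""
    cols = [c for c in HEARTPRINT_COLUMNS if c in train.columns]
    med = train[cols].median(skipna=True)
    return med.fillna(0.0)


def apply_imputer(medians: pd.Series, table: pd.DataFrame) -> pd.DataFrame:
    """Fill undefined heartprint entries with the training medians."""
    out = table.copy()
    for col in medians.index:
        out[col] = out[col].fillna(medians[col])
    return out


@dataclass(frozen=True)
class MinMaxScaler:
    """Per-column affine map x ↦ (x − min)/(max − min), fitted on training rows.

    A constant training column (max == min) is mapped identically to 0 and
    flagged with a warning at fit time. Test-set values outside the training
    range map outside [0, 1]; no clipping is applied.
    """

    col_min: pd.Series
    col_range: pd.Series

    @property
    def columns(self) -> list[str]:
        return list(self.col_min.index)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks scaler columns: {missing}")
        out = table.copy()
        for col in self.columns:
            rng = self.col_range[col]
            if rng > 0:
                out[col] = (table[col] - self.col_min[col]) / rng
            else:
                out[col] = 0.0
        return out

    def to_text(self, path) -> None:
        lines = ["# column\tmin\trange"]
        for col in self.columns:
            lines.append(f"{col}\t{float(self.col_min[col])!r}\t{float(self.col_range[col])!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path) -> "MinMaxScaler":
        mins, ranges = {}, {}
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            col, lo, rng = line.split("\t")
            mins[col] = float(lo)
            ranges[col] = float(rng)
        return cls(pd.Series(mins), pd.Series(ranges))


def fit_minmax(train: pd.DataFrame, columns=None) -> MinMaxScaler:
    """Learn per-column min and range from the training rows.

    ``columns`` defaults to every feature column present in ``train``.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    if columns is None:
        columns = [c for c in FEATURE_COLUMNS if c in train.columns]
    sub = train[list(columns)].astype(float)
    col_min = sub.min()
    col_range = sub.max() - col_min
    constant = col_range.index[col_range == 0].tolist()
    if constant:
        warnings.warn(
            f"constant training column(s) {constant} mapped to 0", stacklevel=2
        )
    return MinMaxScaler(col_min=col_min, col_range=col_range)


def apply_minmax(scaler: MinMaxScaler, table: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted scaler (see :class:`MinMaxScaler`)."""
    return scaler.transform(table)
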