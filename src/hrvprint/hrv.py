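"""Heart-rate-variability indices from an NN series.

Eleven indices: four time-domain statistics (meanNN, SDNN, RMSSD, pNN50),
five Welch-based frequency-domain quantities (LF, HF, LFnu, HFnu, LF/HF)
averaged over 5-minute segments, and the two "last minute" statistics
(meanNN l.m., SDNN l.m.).

Frequency-domain conventions: the irregular tachogram (NN duration as a
function of beat time) is resampled at 3 Hz by cubic spline, linearly
detrended, and the power spectral density estimated with Welch's method
(Hanning window, 300 samples, 50% overlap). LF covers 0.04–0.15 Hz, HF
0.15–0.4 Hz; normalised units are 100·band/(LF+HF), so LFnu + HFnu = 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .preprocess import NNSeries


@dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the spectral estimation.

    resample_hz : tachogram resampling rate (samples/s).
    window_len : Welch window length in samples.
    overlap_fraction : fractional overlap of Welch windows.
    lf_band, hf_band : (low, high) band edges in Hz.
    segment_seconds : length of the non-overlapping analysis segments.
    last_minute_seconds : window for the "last minute" indices.
    """

    resample_hz: float = 3.0
    window_len: int = 300
    overlap_fraction: float = 0.5
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.4)
    segment_seconds: float = 300.0
    last_minute_seconds: float = 60.0

    def __post_init__(self) -> None:
        lo, mid = self.lf_band
        mid2, hi = self.hf_band
        if not (0 < lo < mid == mid2 < hi < self.resample_hz / 2):
            raise ValueError("bands must satisfy 0 < LF.lo < LF.hi == HF.lo < HF.hi < Nyquist")
        if self.window_len / self.resample_hz > self.segment_seconds:
            raise ValueError("Welch window longer than one analysis segment")


DEFAULT_SPECTRAL = SpectralConfig()


@dataclass(frozen=True)
class HRVIndices:
    """The 11 HRV indices. Durations in ms, powers in ms², pNN50 in percent."""

    mean_nn: float
    sdnn: float
    rmssd: float
    pnn50: float
    lf: float
    hf: float
    lf_nu: float
    hf_nu: float
    lf_hf: float
    mean_nn_lm: float
    sdnn_lm: float


def _to_ms(nn: NNSeries) -> np.ndarray:
    return nn.intervals * 1000.0


def time_domain_indices(nn: NNSeries) -> tuple[float, float, float, float]:
    """(meanNN, SDNN, RMSSD, pNN50) — ms, ms, ms, percent.

    pNN50 counts successive differences strictly greater than 50 ms.
    SDNN uses the sample (n−1) denominator.
    """
    x = _to_ms(nn)
    if len(x) < 2:
        raise ValueError("need at least 2 NN intervals")
    diffs = np.diff(x)
    mean_nn = float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    pnn50 = float(100.0 * np.count_nonzero(np.abs(diffs) > 50.0) / len(diffs))
    return mean_nn, sdnn, rmssd, pnn50


def last_minute_indices(nn: NNSeries, window_s: float = 60.0) -> tuple[float, float]:
    """Mean and sample SD (ms) over the final ``window_s`` seconds.

    The window is the maximal suffix of intervals whose cumulative duration
    does not exceed ``window_s`` (at least two intervals).
    """
    if nn.duration_s < window_s:
        raise ValueError(
            f"recording ({nn.duration_s:.1f}s) shorter than window ({window_s}s)"
        )
    rev_cum = np.cumsum(nn.intervals[::-1])
    k = int(np.searchsorted(rev_cum, window_s, side="right"))
    k = max(k, 2)
    tail = _to_ms(nn)[-k:]
    return float(np.mean(tail)), float(np.std(tail, ddof=1))


def resample_nn(nn: NNSeries, cfg: SpectralConfig = DEFAULT_SPECTRAL) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly resample the tachogram.

    Returns ``(t, x)`` where ``t`` are sample times k/resample_hz within the
    span of the beat times (no extrapolation) and ``x`` the cubic-spline
    interpolated NN durations in ms.
    """
    if len(nn) < 4:
        raise ValueError("need at least 4 beats for cubic interpolation")
    t_beats = nn.beat_times
    values = _to_ms(nn)
    dt = 1.0 / cfg.resample_hz
    k0 = int(np.ceil(t_beats[0] / dt))
    k1 = int(np.floor(t_beats[-1] / dt))
    t = np.arange(k0, k1 + 1) * dt
    spline = CubicSpline(t_beats, values)
    return t, spline(t)


def welch_band_powers(
    x: np.ndarray, cfg: SpectralConfig = DEFAULT_SPECTRAL
) -> tuple[float, float]:
    """(LF, HF) band powers (ms²) of a uniformly sampled tachogram.

    Linear detrend, Hanning window of ``cfg.window_len`` samples with
    ``cfg.overlap_fraction`` overlap, one-sided density normalisation; band
    powers are PSD integrals over the LF and HF bands.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < cfg.window_len:
        raise ValueError(
            f"signal length {len(x)} shorter than one Welch window ({cfg.window_len})"
        )
    freqs, psd = sps.welch(
        x,
        fs=cfg.resample_hz,
        window="hann",
        nperseg=cfg.window_len,
        noverlap=int(round(cfg.window_len * cfg.overlap_fraction)),
        detrend="linear",
        scaling="density",
    )

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[mask], freqs[mask]))

    return band_power(*cfg.lf_band), band_power(*cfg.hf_band)


def spectral_indices(
    nn: NNSeries, cfg: SpectralConfig = DEFAULT_SPECTRAL
) -> tuple[float, float, float, float, float]:
    """Segment-averaged (LF, HF, LFnu, HFnu, LF/HF).

    The recording is cut into consecutive non-overlapping segments of
    ``cfg.segment_seconds`` anchored at the recording end (the most recent
    data are always covered); a leading partial segment is dropped. Indices
    are computed per segment and averaged. Segments with zero HF power are
    excluded from the ratio averages with a warning.
    """
    t, x = resample_nn(nn, cfg)
    seg_len = int(round(cfg.segment_seconds * cfg.resample_hz))
    n_seg = len(x) // seg_len
    if n_seg < 1:
        raise ValueError(
            f"recording ({nn.duration_s:.1f}s) shorter than one "
            f"{cfg.segment_seconds:.0f}s segment"
        )
    rows = []
    raw_powers = []
    for j in range(n_seg):
        hi = len(x) - j * seg_len
        seg = x[hi - seg_len:hi]
        lf, hf = welch_band_powers(seg, cfg)
        raw_powers.append((lf, hf))
        if lf + hf <= 0 or hf <= 0:
            warnings.warn(
                "segment with zero band power excluded from spectral averages",
                stacklevel=2,
            )
            continue
        rows.append((lf, hf, 100.0 * lf / (lf + hf), 100.0 * hf / (lf + hf), lf / hf))
    if not rows:
        # e.g. a strictly constant tachogram: band powers are ~0 and the
        # normalised units / ratio are undefined
        warnings.warn("no segment had positive band power; ratios undefined", stacklevel=2)
        lf, hf = (float(v) for v in np.mean(np.array(raw_powers), axis=0))
        return lf, hf, float("nan"), float("nan"), float("nan")
    return tuple(float(v) for v in np.mean(np.array(rows), axis=0))


def hrv_indices(nn: NNSeries, cfg: SpectralConfig = DEFAULT_SPECTRAL) -> HRVIndices:
    """All 11 HRV indices for one recording."""
    mean_nn, sdnn, rmssd, pnn50 = time_domain_indices(nn)
    lf, hf, lf_nu, hf_nu, lf_hf = spectral_indices(nn, cfg)
    mean_nn_lm, sdnn_lm = last_minute_indices(nn, cfg.last_minute_seconds)
    return HRVIndices(
        mean_nn=mean_nn,
        sdnn=sdnn,
        rmssd=rmssd,
        pnn50=pnn50,
        lf=lf,
        hf=hf,
        lf_nu=lf_nu,
        hf_nu=hf_nu,
        lf_hf=lf_hf,
        mean_nn_lm=mean_nn_lm,
        sdnn_lm=sdnn_lm,
    )
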