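"""Synthetic paired pre-event/control RR recordings.

The generator emulates the structure the pipeline consumes, not cardiac
electrophysiology: the sinus (NN) stream is two sinusoids — 0.10 Hz for the
LF band, 0.30 Hz for the HF band — plus white noise around a mean NN
duration, and PVCs are inserted on top with a controllable hourly rate,
coupling-interval distribution and NIB (intervening-beat) pattern. Each
PVC shortens its interval to a coupling interval drawn from a truncated
normal and is followed by a fully compensatory pause (2·NN − CI), the
textbook timing of a ventricular ectopic. The final 10 beats are always
PVC-free, matching the standardisation step's requirement.

`table2_presets()` provides pre-event/control parameter templates whose
group differences point the way the study populations differ: pre-event
recordings have shorter meanNN, LF-dominant oscillation (larger LF/HF),
more PVCs/hour, and shorter meanCI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .io import AnnotatedRRSeries

TAIL_RESERVE = 10  # last beats kept PVC-free


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic recording.

    Durations in ms, rates in events/hour. ``nib_weights`` maps candidate
    NIB values to sampling weights for the gap between consecutive PVCs.
    """

    n_beats: int = 1000
    mean_nn: float = 750.0  # ms
    sd_noise: float = 20.0  # ms
    lf_amp: float = 25.0  # ms, 0.10 Hz component
    hf_amp: float = 15.0  # ms, 0.30 Hz component
    pvc_rate: float = 100.0  # PVCs/hour
    ci_mean: float = 550.0  # ms
    ci_sd: float = 50.0  # ms
    nib_weights: dict = field(
        default_factory=lambda: {1: 0.25, 2: 0.3, 3: 0.2, 4: 0.15, 9: 0.1}
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mean_nn > self.ci_mean > 0):
            raise ValueError("require meanNN > ci_mean > 0")
        if min(self.sd_noise, self.lf_amp, self.hf_amp, self.ci_sd) < 0:
            raise ValueError("amplitudes and SDs must be >= 0")
        if self.pvc_rate < 0:
            raise ValueError("pvc_rate must be >= 0")
        w = np.array(list(self.nib_weights.values()), dtype=float)
        if len(w) == 0 or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("nib_weights must be non-negative and not all zero")
        if any(int(v) != v or v < 0 for v in self.nib_weights):
            raise ValueError("NIB values must be non-negative integers")


LF_HZ = 0.10
HF_HZ = 0.30


def _pvc_positions(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Choose beat indices that become PVCs.

    The PVC count is fixed from pvc_rate × expected duration; gaps between
    consecutive PVCs are NIB draws from ``nib_weights`` (+1 beat for the
    PVC itself), and whatever beats remain are split at random between a
    PVC-free head and the reserved PVC-free tail.
    """
    expected_hours = params.n_beats * params.mean_nn / 3.6e6
    n_pvc = int(round(params.pvc_rate * expected_hours))
    if n_pvc == 0:
        return np.array([], dtype=int)
    nib_values = np.array(sorted(params.nib_weights), dtype=int)
    probs = np.array([params.nib_weights[v] for v in nib_values], dtype=float)
    probs = probs / probs.sum()
    usable = params.n_beats - TAIL_RESERVE
    while True:
        gaps = rng.choice(nib_values, size=max(n_pvc - 1, 0), p=probs)
        span = 1 + int(np.sum(gaps + 1))
        if span <= usable:
            break
        # recording cannot hold this many PVCs at these gaps: drop one
        n_pvc -= 1
        if n_pvc == 0:
            return np.array([], dtype=int)
    head = int(rng.integers(0, usable - span + 1))
    positions = head + np.concatenate([[0], np.cumsum(gaps + 1)])
    return positions.astype(int)


def generate_recording(params: SynthParams) -> AnnotatedRRSeries:
    """One annotated RR recording from ``params`` (deterministic per seed).

    The NN stream is
    NN(t) = meanNN + lf_amp·sin(2π·0.10·t + φ₁) + hf_amp·sin(2π·0.30·t + φ₂) + ε,
    evaluated at running beat times; at PVC beats the interval becomes the
    coupling interval (truncated normal on (0.2, 0.95)·meanNN) and the next
    sinus interval the compensatory pause 2·NN(t) − CI.
    """
    rng = np.random.default_rng(params.rng_seed)
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    noise = rng.normal(0.0, params.sd_noise, size=params.n_beats) if params.sd_noise > 0 else np.zeros(params.n_beats)
    v_pos = set(_pvc_positions(params, rng).tolist())
    n_pvc = len(v_pos)
    if n_pvc:
        lo = 0.2 * params.mean_nn
        hi = 0.95 * params.mean_nn
        if params.ci_sd > 0:
            a = (lo - params.ci_mean) / params.ci_sd
            b = (hi - params.ci_mean) / params.ci_sd
            ci_draws = stats.truncnorm.rvs(
                a, b, loc=params.ci_mean, scale=params.ci_sd,
                size=params.n_beats, random_state=rng,
            )
        else:
            ci_draws = np.full(params.n_beats, float(np.clip(params.ci_mean, lo, hi)))

    intervals = np.empty(params.n_beats)
    labels = np.full(params.n_beats, "N", dtype="<U1")
    t = 0.0
    prev_ci = None
    for k in range(params.n_beats):
        nn_ms = (
            params.mean_nn
            + params.lf_amp * np.sin(2 * np.pi * LF_HZ * t + phi1)
            + params.hf_amp * np.sin(2 * np.pi * HF_HZ * t + phi2)
            + noise[k]
        )
        nn_ms = max(nn_ms, 0.05 * params.mean_nn)
        if k in v_pos:
            iv_ms = ci_draws[k]
            labels[k] = "V"
            prev_ci = iv_ms
        elif prev_ci is not None:
            iv_ms = max(2.0 * nn_ms - prev_ci, 0.2 * params.mean_nn)
            prev_ci = None
        else:
            iv_ms = nn_ms
        intervals[k] = iv_ms / 1000.0
        t += intervals[k]
    return AnnotatedRRSeries(intervals=intervals, labels=labels)


@dataclass(frozen=True)
class CohortSpec:
    """A paired cohort: per patient, jittered pre-event and control copies."""

    n_patients: int = 20
    recordings_per_patient: tuple[int, int] = (1, 1)  # (pre_event, control)
    pre_event: SynthParams = field(default_factory=lambda: table2_presets()[0])
    control: SynthParams = field(default_factory=lambda: table2_presets()[1])
    jitter_sd: float = 0.05  # multiplicative between-patient jitter
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if min(self.recordings_per_patient) < 0 or max(self.recordings_per_patient) < 1:
            raise ValueError("recordings_per_patient must be non-negative, at least one > 0")


def table2_presets() -> tuple[SynthParams, SynthParams]:
    """Pre-event and control parameter templates.

    Centres follow the training-population group medians: pre-event
    meanNN 676 ms, 159 PVCs/h, meanCI 520 ms, SDCI 63 ms; control
    meanNN 787 ms, 71 PVCs/h, meanCI 575 ms, SDCI 57 ms. The pre-event
    template is LF-dominant (larger LF/HF) and favours short NIB runs.
    """
    pre = SynthParams(
        mean_nn=676.0,
        sd_noise=20.0,
        lf_amp=32.0,
        hf_amp=12.0,
        pvc_rate=159.0,
        ci_mean=520.0,
        ci_sd=63.0,
        nib_weights={1: 0.4, 2: 0.3, 3: 0.2, 5: 0.1},
    )
    control = SynthParams(
        mean_nn=787.0,
        sd_noise=20.0,
        lf_amp=18.0,
        hf_amp=18.0,
        pvc_rate=71.0,
        ci_mean=575.0,
        ci_sd=57.0,
        nib_weights={1: 0.2, 2: 0.4, 3: 0.2, 5: 0.1, 9: 0.1},
    )
    return pre, control


def _jittered(params: SynthParams, factors: dict, seed: int) -> SynthParams:
    return replace(
        params,
        mean_nn=params.mean_nn * factors["nn"],
        ci_mean=min(params.ci_mean * factors["ci"], 0.9 * params.mean_nn * factors["nn"]),
        pvc_rate=params.pvc_rate * factors["rate"],
        lf_amp=params.lf_amp * factors["amp"],
        hf_amp=params.hf_amp * factors["amp"],
        rng_seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> list[AnnotatedRRSeries]:
    """Generate the whole paired cohort, reproducible from one seed.

    Each patient draws one multiplicative jitter factor per parameter
    family (mean NN, coupling interval, PVC rate, oscillation amplitude),
    applied to *both* outcome templates so the within-patient effect
    directions are preserved.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_pre, n_ctrl = spec.recordings_per_patient
    recordings: list[AnnotatedRRSeries] = []
    for p in range(spec.n_patients):
        patient_id = f"p{p:03d}"
        factors = {
            key: float(np.exp(rng.normal(0.0, spec.jitter_sd)))
            for key in ("nn", "ci", "rate", "amp")
        }
        for outcome, template, count in (
            ("pre_event", spec.pre_event, n_pre),
            ("control", spec.control, n_ctrl),
        ):
            for j in range(count):
                seed = int(rng.integers(0, 2**31 - 1))
                series = generate_recording(_jittered(template, factors, seed))
                recordings.append(
                    series.with_metadata(
                        recording_id=f"{patient_id}_{outcome}_{j}",
                        patient_id=patient_id,
                        outcome=outcome,
                    )
                )
    return recordings


def null_cohort_spec(n_patients: int = 20, rng_seed: int = 0) -> CohortSpec:
    """A zero-effect cohort: both outcomes drawn from the control template."""
    _, control = table2_presets()
    return CohortSpec(
        n_patients=n_patients,
        pre_event=control,
        control=control,
        rng_seed=rng_seed,
    )
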