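import numpy as np
import pandas as pd
import pytest

from hrvprint import (
    AnnotatedRRSeries,
    CohortSpec,
    build_feature_table,
    generate_cohort,
)


def make_series(labels, interval=0.8, intervals=None, **meta):
    """Small helper: an annotated series from a label string like 'NNVN'."""
    labels = list(labels)
    if intervals is None:
        intervals = [interval] * len(labels)
    meta.setdefault("recording_id", "r")
    meta.setdefault("patient_id", "p")
    return AnnotatedRRSeries(
        intervals=np.asarray(intervals, dtype=float),
        labels=np.asarray(labels),
        **meta,
    )


@pytest.fixture(scope="session")
def paired_cohort():
    """20 patients, one pre-event + one control recording each."""
    return generate_cohort(CohortSpec(n_patients=20, rng_seed=11))


@pytest.fixture(scope="session")
def paired_table(paired_cohort):
    return build_feature_table(paired_cohort)


def random_annotated_series(rng, n_min=20, n_max=120, p_v=0.25):
    """Random label/interval series for fuzz-style oracle comparisons."""
    n = int(rng.integers(n_min, n_max + 1))
    labels = np.where(rng.random(n) < p_v, "V", "N")
    intervals = rng.uniform(0.3, 1.2, size=n)
    return AnnotatedRRSeries(intervals=intervals, labels=labels)


@pytest.fixture
def separable_table():
    """A paired feature-style table where one column separates the classes."""
    rng = np.random.default_rng(5)
    rows = []
    for p in range(12):
        for outcome in (1, 0):
            rows.append(
                {
                    "recording_id": f"p{p}_{outcome}",
                    "patient_id": f"p{p}",
                    "outcome": outcome,
                    "meanNN": (600 if outcome else 800) + rng.normal(0, 10),
                    "SDNN": rng.normal(50, 10),
                    "RMSSD": rng.normal(20, 5),
                    "pNN50": rng.uniform(0, 5),
                }
            )
    return pd.DataFrame(rows)
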