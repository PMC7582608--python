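"""Patient-paired cross-validation, hyperparameter grids, greedy search.

The model-selection design pairs one pre-event and one control recording
per patient, assigns whole patients to folds (both recordings of a pair
share a fold), and so fixes every fold's class prevalence at exactly 0.5.
Within each CV split the heartprint imputation and min–max scaling are
refit on the nine training folds only, so no test-fold statistic leaks
into training.

The classifier is an RBF-kernel SVM, K(x_i, x_j) = exp(−γ‖x_i − x_j‖²);
hyperparameters are searched on a grid of 20 costs (0.5 to 10, step 0.5)
crossed with 37 kernel widths (2^e for e = −15, −14.5, …, 3). Index
combinations are chosen by greedy forward search: all pairs first, then one
index added at a time, re-optimising (C, γ) at each size. Recordings are
ranked for ROC analysis by the SVM decision margin; accuracy is taken at
the margin-0 threshold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn
from scipy import stats
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC
from statsmodels.stats.proportion import proportion_confint

from .features import FEATURE_COLUMNS, apply_imputer, apply_minmax, fit_imputer, fit_minmax

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hyperparameter grids

@dataclass(frozen=True)
class GridSpec:
    """Arithmetic cost grid and geometric gamma grid."""

    cost_start: float = 0.5
    cost_stop: float = 10.0
    cost_step: float = 0.5
    gamma_exp_start: float = -15.0
    gamma_exp_stop: float = 3.0
    gamma_exp_step: float = 0.5


def hyperparameter_grids(spec: GridSpec = GridSpec()) -> tuple[np.ndarray, np.ndarray]:
    """(cost values, gamma values) per the grid specification.

    Defaults: costs 0.5, 1.0, …, 10.0 (20 values) and gammas 2^e for
    e = −15, −14.5, …, 3 (37 values).
    """
    n_cost = int(round((spec.cost_stop - spec.cost_start) / spec.cost_step)) + 1
    costs = spec.cost_start + spec.cost_step * np.arange(n_cost)
    n_gam = int(round((spec.gamma_exp_stop - spec.gamma_exp_start) / spec.gamma_exp_step)) + 1
    exps = spec.gamma_exp_start + spec.gamma_exp_step * np.arange(n_gam)
    return costs, 2.0**exps


#: reduced grid for quick experiments: 5 costs × 7 gammas
REDUCED_COSTS = np.array([0.5, 2.0, 4.0, 7.0, 10.0])
REDUCED_GAMMAS = 2.0 ** np.array([-7.0, -4.0, -2.0, -0.5, 0.0, 1.0, 3.0])


# ---------------------------------------------------------------------------
# paired folds

@dataclass(frozen=True)
class FoldPlan:
    """Assignment of paired patients to k cross-validation groups."""

    k: int
    assignment: dict  # patient_id -> fold index
    pairs: dict  # patient_id -> (pre_event recording_id, control recording_id)
    rng_seed: int

    def fold_patients(self, fold: int) -> list:
        return [p for p, f in self.assignment.items() if f == fold]

    def fold_recordings(self, fold: int) -> list:
        out = []
        for p in self.fold_patients(fold):
            out.extend(self.pairs[p])
        return out


def build_paired_folds(table: pd.DataFrame, k: int = 10, rng_seed: int = 0) -> FoldPlan:
    """Select one pre-event/control pair per eligible patient and fold them.

    A patient is eligible when it has at least one recording of each
    outcome; one recording per outcome is drawn uniformly at random
    (seeded). Patients are shuffled and dealt round-robin across ``k``
    folds, both recordings of a pair staying together, so every fold has
    equal pre-event and control counts.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(rng_seed)
    pairs: dict = {}
    for patient, grp in table.groupby("patient_id", sort=True):
        pre = grp.loc[grp["outcome"] == 1, "recording_id"].tolist()
        ctrl = grp.loc[grp["outcome"] == 0, "recording_id"].tolist()
        if not pre or not ctrl:
            logger.info("patient %s ineligible (needs both outcomes); excluded", patient)
            continue
        pairs[patient] = (
            pre[rng.integers(len(pre))],
            ctrl[rng.integers(len(ctrl))],
        )
    if len(pairs) < k:
        raise ValueError(
            f"only {len(pairs)} eligible patients for k={k} folds"
        )
    patients = sorted(pairs)
    order = rng.permutation(len(patients))
    assignment = {patients[j]: int(i % k) for i, j in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment, pairs=pairs, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# cross-validated scoring

def prepare_fold_data(table: pd.DataFrame, plan: FoldPlan) -> list[dict]:
    """Per-fold imputed + scaled train/test matrices over all 16 indices.

    Imputation medians and min–max statistics come from the training folds
    of each split only. Column subsets can then be sliced cheaply for every
    candidate index combination without re-scaling (the scaler acts
    column-wise, so a subset of a scaled table equals scaling the subset).
    """
    indexed = table.set_index("recording_id")
    known = [c for c in FEATURE_COLUMNS if c in table.columns]
    extra = [
        c
        for c in table.columns
        if c not in known and c not in ("recording_id", "patient_id", "outcome")
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    cols = known + extra
    folds = []
    for fold in range(plan.k):
        test_ids = plan.fold_recordings(fold)
        train_ids = [
            r for f in range(plan.k) if f != fold for r in plan.fold_recordings(f)
        ]
        train = indexed.loc[train_ids]
        test = indexed.loc[test_ids]
        medians = fit_imputer(train)
        train = apply_imputer(medians, train)
        test = apply_imputer(medians, test)
        scaler = fit_minmax(train, columns=cols)
        train = apply_minmax(scaler, train)
        test = apply_minmax(scaler, test)
        folds.append(
            {
                "X_train": train[cols].to_numpy(float),
                "y_train": train["outcome"].to_numpy(int),
                "X_test": test[cols].to_numpy(float),
                "y_test": test["outcome"].to_numpy(int),
                "columns": {c: i for i, c in enumerate(cols)},
                "scaler": scaler,
            }
        )
    return folds


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC as the Mann–Whitney rank statistic (ties counted 1/2).

    Equivalent to sklearn's ``roc_auc_score`` but cheap enough for the grid
    search's inner loop (tested against brute-force pair counting).
    """
    y_true = np.asarray(y_true)
    n_pos = int((y_true == 1).sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined for a single-class set")
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _fold_scores(folds, indices, C, gamma) -> tuple[np.ndarray, np.ndarray]:
    aucs, accs = [], []
    with sklearn.config_context(assume_finite=True):
        for fd in folds:
            y_test = fd["y_test"]
            if len(np.unique(y_test)) < 2:
                raise ValueError("a fold contains a single class; AUC undefined")
            col = [fd["columns"][c] for c in indices]
            clf = SVC(C=C, gamma=gamma, kernel="rbf")
            clf.fit(fd["X_train"][:, col], fd["y_train"])
            margin = clf.decision_function(fd["X_test"][:, col])
            aucs.append(rank_auc(y_test, margin))
            accs.append(100.0 * np.mean((margin > 0).astype(int) == y_test))
    return np.array(aucs), np.array(accs)


def cross_validated_score(
    table: pd.DataFrame,
    plan: FoldPlan,
    indices,
    C: float,
    gamma: float,
    _folds=None,
) -> tuple[float, float, float, float]:
    """(mean AUC, SD AUC, mean accuracy %, SD accuracy %) across folds.

    Per fold the SVM is trained on the other folds (scaler and imputation
    refit on those training rows) and the held-out recordings are ranked by
    decision margin; AUC is the rank statistic, accuracy the fraction
    correct at margin 0.
    """
    folds = _folds if _folds is not None else prepare_fold_data(table, plan)
    aucs, accs = _fold_scores(folds, indices, C, gamma)
    return (
        float(aucs.mean()),
        float(aucs.std(ddof=1)),
        float(accs.mean()),
        float(accs.std(ddof=1)),
    )


def grid_search_combo(
    folds, indices, cost_values, gamma_values
) -> tuple[float, float, tuple[float, float, float, float]]:
    """Best (C, γ) for one index combination by mean CV AUC.

    Ties are broken toward the smaller C, then the smaller γ (iteration
    order ascending; only strictly better scores replace the incumbent).
    """
    best = None
    for C in np.sort(np.asarray(cost_values, dtype=float)):
        for gamma in np.sort(np.asarray(gamma_values, dtype=float)):
            aucs, accs = _fold_scores(folds, indices, C, gamma)
            score = aucs.mean()
            if best is None or score > best[0] + 1e-12:
                best = (
                    score,
                    float(C),
                    float(gamma),
                    (
                        float(aucs.mean()),
                        float(aucs.std(ddof=1)),
                        float(accs.mean()),
                        float(accs.std(ddof=1)),
                    ),
                )
    return best[1], best[2], best[3]


def greedy_search(
    table: pd.DataFrame,
    plan: FoldPlan,
    cost_values=None,
    gamma_values=None,
    max_size: int | None = None,
    candidate_columns=None,
) -> pd.DataFrame:
    """Greedy forward search over index combinations.

    All pairs of indices are scored first (each at its grid-optimal (C, γ));
    the best pair is fixed and single indices are then added one at a time,
    re-optimising the grid at every size, until ``max_size`` (default: all
    indices). Returns one row per combination size with columns
    ``size, indices, C, gamma, auc_mean, auc_sd, acc_mean, acc_sd``.
    """
    if cost_values is None or gamma_values is None:
        dc, dg = hyperparameter_grids()
        cost_values = dc if cost_values is None else cost_values
        gamma_values = dg if gamma_values is None else gamma_values
    cols = candidate_columns or [c for c in FEATURE_COLUMNS if c in table.columns]
    if len(cols) < 2:
        raise ValueError("need at least 2 candidate indices")
    max_size = len(cols) if max_size is None else min(max_size, len(cols))
    folds = prepare_fold_data(table, plan)

    def best_over(candidates):
        rows = []
        for combo in candidates:
            C, gamma, (am, asd, accm, accsd) = grid_search_combo(
                folds, combo, cost_values, gamma_values
            )
            rows.append((am, combo, C, gamma, asd, accm, accsd))
        # max AUC; ties toward the earlier (lexicographically first) combo
        return max(rows, key=lambda r: r[0])

    results = []
    am, combo, C, gamma, asd, accm, accsd = best_over(
        [list(c) for c in itertools.combinations(cols, 2)]
    )
    selected = list(combo)
    results.append((2, tuple(selected), C, gamma, am, asd, accm, accsd))
    while len(selected) < max_size:
        remaining = [c for c in cols if c not in selected]
        am, combo, C, gamma, asd, accm, accsd = best_over(
            [selected + [c] for c in remaining]
        )
        selected = list(combo)
        results.append((len(selected), tuple(selected), C, gamma, am, asd, accm, accsd))
        logger.info("size %d: AUC %.4f (C=%.1f, gamma=%.4g)", len(selected), am, C, gamma)
    return pd.DataFrame(
        results,
        columns=["size", "indices", "C", "gamma", "auc_mean", "auc_sd", "acc_mean", "acc_sd"],
    )


def select_final(result: pd.DataFrame) -> dict:
    """Combination sizes with the best mean AUC and best mean accuracy.

    Ties are broken toward the smaller size. Returns
    ``{"best_auc_size": s1, "best_accuracy_size": s2}`` (possibly equal).
    """
    if len(result) == 0:
        raise ValueError("empty search result")
    by_size = result.sort_values("size")
    best_auc = int(by_size.loc[by_size["auc_mean"].idxmax(), "size"])
    best_acc = int(by_size.loc[by_size["acc_mean"].idxmax(), "size"])
    return {"best_auc_size": best_auc, "best_accuracy_size": best_acc}


# ---------------------------------------------------------------------------
# evaluation metrics

def auc_hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int, alpha: float = 0.05) -> tuple[float, float]:
    """Hanley–McNeil standard-error based (1−alpha) CI for an AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def evaluate_scores(y_true: np.ndarray, margin: np.ndarray, alpha: float = 0.05) -> dict:
    """ROC AUC (Hanley–McNeil CI) and margin-0 accuracy (Wilson CI).

    Accuracy is reported in percent, matching the summary tables.
    """
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("evaluation requires both classes")
    auc = float(roc_auc_score(y_true, margin))
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    auc_lo, auc_hi = auc_hanley_mcneil_ci(auc, n_pos, n_neg, alpha)
    correct = int(((margin > 0).astype(int) == y_true).sum())
    acc = 100.0 * correct / len(y_true)
    lo, hi = proportion_confint(correct, len(y_true), alpha=alpha, method="wilson")
    return {
        "auc": auc,
        "auc_ci": (auc_lo, auc_hi),
        "accuracy": acc,
        "accuracy_ci": (100.0 * lo, 100.0 * hi),
        "n": len(y_true),
    }
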