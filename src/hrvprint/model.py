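"""Model/Results interface over the paired-CV RBF-SVM pipeline.

`HeartprintSVM` is constructed from a feature table (or directly from
annotated recordings); `fit()` runs the paired 10-fold cross-validation
with the greedy forward index search and returns a `HeartprintSVMResults`
carrying the per-size search table, the chosen combination sizes, and
final SVM models trained on all rows — ready to `evaluate()` on held-out
recordings or to `save()` as a portable JSON bundle.

Typical use::

    model = HeartprintSVM.from_recordings(train_recordings)
    res = model.fit(k=10, seed=7)
    print(res.summary())
    report = res.evaluate(test_table)
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .features import (
    FEATURE_COLUMNS,
    MinMaxScaler,
    apply_imputer,
    apply_minmax,
    build_feature_table,
    fit_imputer,
    fit_minmax,
)
from .hrv import DEFAULT_SPECTRAL, SpectralConfig
from .selection import (
    FoldPlan,
    build_paired_folds,
    evaluate_scores,
    greedy_search,
    hyperparameter_grids,
    select_final,
)


@dataclass(frozen=True)
class FinalSVM:
    """A trained RBF-SVM with its preprocessing, in plain arrays.

    The decision margin is computed directly from the stored support
    vectors: margin(x) = Σ_i α_i · exp(−γ‖s_i − x‖²) + b, so a reloaded
    model reproduces margins exactly.
    """

    indices: tuple[str, ...]
    C: float
    gamma: float
    support_vectors: np.ndarray  # scaled feature space
    dual_coef: np.ndarray
    intercept: float
    scaler: MinMaxScaler
    imputer_medians: pd.Series

    def _prepare(self, table: pd.DataFrame) -> np.ndarray:
        prepared = apply_imputer(self.imputer_medians, table)
        prepared = apply_minmax(self.scaler, prepared)
        return prepared[list(self.indices)].to_numpy(float)

    def decision_margin(self, table: pd.DataFrame) -> np.ndarray:
        """Signed SVM margin for each row of a *raw* feature table."""
        x = self._prepare(table)
        sq = (
            np.sum(self.support_vectors**2, axis=1)[:, None]
            + np.sum(x**2, axis=1)[None, :]
            - 2.0 * self.support_vectors @ x.T
        )
        kernel = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return self.dual_coef @ kernel + self.intercept

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Class prediction (pre_event=1) at the margin-0 threshold."""
        return (self.decision_margin(table) > 0).astype(int)

    def to_dict(self) -> dict:
        return {
            "indices": list(self.indices),
            "C": self.C,
            "gamma": self.gamma,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "scaler_min": {k: float(v) for k, v in self.scaler.col_min.items()},
            "scaler_range": {k: float(v) for k, v in self.scaler.col_range.items()},
            "imputer_medians": {k: float(v) for k, v in self.imputer_medians.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FinalSVM":
        return cls(
            indices=tuple(d["indices"]),
            C=float(d["C"]),
            gamma=float(d["gamma"]),
            support_vectors=np.array(d["support_vectors"], dtype=float),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            scaler=MinMaxScaler(
                col_min=pd.Series(d["scaler_min"]),
                col_range=pd.Series(d["scaler_range"]),
            ),
            imputer_medians=pd.Series(d["imputer_medians"]),
        )


def train_final(table: pd.DataFrame, indices, C: float, gamma: float) -> FinalSVM:
    """Train an RBF-SVM on *all* rows of a raw feature table.

    Imputation medians and the min–max scaler are fitted on the same rows
    and stored with the model so held-out tables are transformed with the
    training factors.
    """
    y = table["outcome"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both outcomes")
    medians = fit_imputer(table)
    prepared = apply_imputer(medians, table)
    scaler = fit_minmax(prepared)
    prepared = apply_minmax(scaler, prepared)
    x = prepared[list(indices)].to_numpy(float)
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(x, y)
    return FinalSVM(
        indices=tuple(indices),
        C=float(C),
        gamma=float(gamma),
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        scaler=scaler,
        imputer_medians=medians,
    )


class HeartprintSVMResults:
    """Fitted results: search table, chosen sizes, final models.

    Attributes
    ----------
    search : DataFrame
        One row per combination size: selected indices, optimal (C, γ),
        mean ± SD AUC and accuracy across the 10 folds.
    selection : dict
        ``best_auc_size`` and ``best_accuracy_size``.
    final_models : dict[int, FinalSVM]
        Final SVMs (trained on all rows) for each chosen size.
    plan : FoldPlan
        The patient-to-fold assignment used.
    """

    def __init__(self, model, search, selection, final_models, plan):
        self.model = model
        self.search = search
        self.selection = selection
        self.final_models = final_models
        self.plan = plan

    def evaluate(self, test_table: pd.DataFrame, size: int | None = None) -> dict:
        """AUC (Hanley–McNeil 95% CI) and accuracy (Wilson 95% CI) on a
        raw held-out feature table, using the final model of ``size``
        (default: the best-AUC size)."""
        size = self.selection["best_auc_size"] if size is None else size
        final = self.final_models[size]
        margin = final.decision_margin(test_table)
        return evaluate_scores(test_table["outcome"].to_numpy(int), margin)

    def summary(self) -> str:
        """Cross-validation search table in report layout."""
        lines = [
            "Paired 10-fold cross-validation, greedy forward index search",
            f"folds: {self.plan.k}   paired patients: {len(self.plan.pairs)}   "
            f"fold seed: {self.plan.rng_seed}",
            "",
            f"{'size':>4}  {'AUC':>17}  {'Accuracy (%)':>17}  {'C':>5}  {'gamma':>8}  indices",
        ]
        for _, row in self.search.iterrows():
            mark = ""
            if row["size"] == self.selection["best_auc_size"]:
                mark += " *"
            if row["size"] == self.selection["best_accuracy_size"]:
                mark += " &"
            lines.append(
                f"{int(row['size']):>4}  "
                f"{row['auc_mean']:.4f} ± {row['auc_sd']:.4f}  "
                f"{row['acc_mean']:>8.2f} ± {row['acc_sd']:.2f}  "
                f"{row['C']:>5.1f}  {row['gamma']:>8.4f}  "
                f"{', '.join(row['indices'])}{mark}"
            )
        lines.append("")
        lines.append("* best AUC; & best accuracy")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Persist the chosen final models (portable JSON bundle)."""
        payload = {
            "selection": self.selection,
            "models": {str(s): m.to_dict() for s, m in self.final_models.items()},
            "search": [
                {**row, "indices": list(row["indices"])}
                for row in self.search.to_dict(orient="records")
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def load_models(path) -> dict[int, FinalSVM]:
        payload = json.loads(Path(path).read_text())
        return {int(s): FinalSVM.from_dict(d) for s, d in payload["models"].items()}


class HeartprintSVM:
    """Imminent-tachyarrhythmia classifier over HRV + heartprint indices.

    Parameters
    ----------
    table : DataFrame
        Raw (unscaled) feature table with the 16 index columns plus
        ``recording_id``, ``patient_id`` and binary ``outcome``
        (pre_event=1, control=0).
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ("recording_id", "patient_id", "outcome") if c not in table.columns]
        if missing:
            raise ValueError(f"feature table lacks metadata columns: {missing}")
        self.table = table.reset_index(drop=True)
        self.feature_columns = [c for c in FEATURE_COLUMNS if c in table.columns]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "HeartprintSVM":
        return cls(df)

    @classmethod
    def from_recordings(
        cls,
        recordings,
        cfg: SpectralConfig = DEFAULT_SPECTRAL,
        truncate_n: int = 1000,
    ) -> "HeartprintSVM":
        """Extract the 16 indices from annotated RR recordings first."""
        return cls(build_feature_table(recordings, cfg, truncate_n))

    def fit(
        self,
        k: int = 10,
        seed: int = 0,
        cost_values=None,
        gamma_values=None,
        max_size: int | None = None,
        plan: FoldPlan | None = None,
    ) -> HeartprintSVMResults:
        """Run fold construction, greedy search and final training.

        ``cost_values``/``gamma_values`` default to the full 20 × 37 grid;
        pass reduced grids for quick runs. ``max_size`` caps the greedy
        chain length.
        """
        if cost_values is None or gamma_values is None:
            dc, dg = hyperparameter_grids()
            cost_values = dc if cost_values is None else cost_values
            gamma_values = dg if gamma_values is None else gamma_values
        if plan is None:
            plan = build_paired_folds(self.table, k=k, rng_seed=seed)
        search = greedy_search(
            self.table, plan, cost_values, gamma_values, max_size=max_size,
            candidate_columns=self.feature_columns,
        )
        selection = select_final(search)
        final_models = {}
        for size in sorted({selection["best_auc_size"], selection["best_accuracy_size"]}):
            row = search.loc[search["size"] == size].iloc[0]
            final_models[size] = train_final(
                self.table, row["indices"], row["C"], row["gamma"]
            )
        return HeartprintSVMResults(self, search, selection, final_models, plan)
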