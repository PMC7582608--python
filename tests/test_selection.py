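import numpy as np
import pandas as pd
import pytest

from hrvprint import (
    build_paired_folds,
    cross_validated_score,
    evaluate_scores,
    greedy_search,
    hyperparameter_grids,
    select_final,
    train_final,
)
from hrvprint.selection import (
    GridSpec,
    auc_hanley_mcneil_ci,
    prepare_fold_data,
    rank_auc,
)
from hrvprint.features import fit_minmax


def brute_force_auc(y, scores):
    """Concordant/discordant pair counting with ties worth 1/2."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def paired_meta_table(n_patients, rng=None, informative=True):
    """Minimal paired table with a controllable informative column."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for p in range(n_patients):
        for outcome in (1, 0):
            effect = -100.0 * outcome if informative else 0.0
            rows.append(
                {
                    "recording_id": f"p{p}_{outcome}",
                    "patient_id": f"p{p}",
                    "outcome": outcome,
                    "meanNN": 750.0 + effect + rng.normal(0, 15),
                    "SDNN": rng.normal(50, 10),
                    "RMSSD": rng.normal(20, 5),
                    "pNN50": rng.uniform(0, 5),
                }
            )
    return pd.DataFrame(rows)


class TestGrids:
    def test_cost_grid_layout(self):
        costs, _ = hyperparameter_grids()
        assert costs[0] == 0.5 and costs[-1] == 10.0 and len(costs) == 20
        np.testing.assert_allclose(np.diff(costs), 0.5)

    def test_gamma_grid_span(self):
        _, gammas = hyperparameter_grids()
        assert len(gammas) == 37
        assert gammas[0] == pytest.approx(2.0**-15)
        assert gammas[-1] == pytest.approx(8.0)

    def test_gamma_at_half_exponent(self):
        _, gammas = hyperparameter_grids()
        value = gammas[np.argmin(np.abs(gammas - 2.0**-0.5))]
        assert round(value, 4) == 0.7071


class TestPairedFolds:
    def test_twenty_patients_ten_folds(self):
        table = paired_meta_table(20)
        plan = build_paired_folds(table, k=10, rng_seed=0)
        outcomes = table.set_index("recording_id")["outcome"]
        for fold in range(10):
            recs = plan.fold_recordings(fold)
            assert len(recs) == 4
            assert outcomes.loc[recs].mean() == 0.5  # prevalence fixed at 0.5
            assert len(plan.fold_patients(fold)) == 2

    def test_pair_shares_fold(self):
        table = paired_meta_table(25)
        plan = build_paired_folds(table, k=10, rng_seed=1)
        for patient, (pre, ctrl) in plan.pairs.items():
            fold = plan.assignment[patient]
            assert pre in plan.fold_recordings(fold)
            assert ctrl in plan.fold_recordings(fold)

    def test_single_outcome_patient_excluded(self):
        table = paired_meta_table(12)
        extra = table.iloc[:1].copy()
        extra["patient_id"] = "lonely"
        extra["recording_id"] = "lonely_0"
        extra["outcome"] = 0
        plan = build_paired_folds(pd.concat([table, extra]), k=10, rng_seed=0)
        assert "lonely" not in plan.pairs

    def test_seed_determinism(self):
        table = paired_meta_table(20)
        a = build_paired_folds(table, k=10, rng_seed=7)
        b = build_paired_folds(table, k=10, rng_seed=7)
        c = build_paired_folds(table, k=10, rng_seed=8)
        assert a.assignment == b.assignment and a.pairs == b.pairs
        assert a.assignment != c.assignment or a.pairs != c.pairs

    def test_too_few_patients(self):
        with pytest.raises(ValueError, match="eligible"):
            build_paired_folds(paired_meta_table(5), k=10)

    def test_k_too_small(self):
        with pytest.raises(ValueError):
            build_paired_folds(paired_meta_table(20), k=1)


class TestRankAUC:
    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            assert rank_auc(y, scores) == pytest.approx(brute_force_auc(y, scores))

    def test_three_of_four_concordant_pairs(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2])
        y = np.array([1, 0, 1, 0])
        assert brute_force_auc(y, scores) == 0.75
        assert rank_auc(y, scores) == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        assert rank_auc(np.array([1, 1, 0, 0]), np.zeros(4)) == pytest.approx(0.5)

    def test_duplicating_every_observation_leaves_auc_unchanged(self):
        rng = np.random.default_rng(3)
        y = np.array([1, 1, 0, 0, 1, 0])
        s = rng.normal(size=6)
        assert rank_auc(np.r_[y, y], np.r_[s, s]) == pytest.approx(rank_auc(y, s))


class TestCrossValidation:
    def test_separable_table_scores_perfectly(self, separable_table):
        plan = build_paired_folds(separable_table, k=4, rng_seed=0)
        auc_m, auc_sd, acc_m, acc_sd = cross_validated_score(
            separable_table, plan, ["meanNN"], C=2.0, gamma=0.5
        )
        assert auc_m == 1.0
        assert acc_m == 100.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(23)
        aucs = []
        for rep in range(20):
            table = paired_meta_table(16, rng=rng, informative=False)
            plan = build_paired_folds(table, k=4, rng_seed=rep)
            auc_m, *_ = cross_validated_score(
                table, plan, ["meanNN", "SDNN"], C=2.0, gamma=0.5
            )
            aucs.append(auc_m)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_scaler_refit_per_split(self, separable_table):
        plan = build_paired_folds(separable_table, k=4, rng_seed=0)
        folds = prepare_fold_data(separable_table, plan)
        full = fit_minmax(separable_table, columns=["meanNN", "SDNN", "RMSSD", "pNN50"])
        diffs = [
            not np.allclose(fd["scaler"].col_min.values, full.col_min.values)
            for fd in folds
        ]
        assert any(diffs)  # at least one split's statistics differ from full-table


class TestGreedySearch:
    def test_planted_pair_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            rows = []
            for p in range(12):
                for outcome in (1, 0):
                    rows.append(
                        {
                            "recording_id": f"p{p}_{outcome}",
                            "patient_id": f"p{p}",
                            "outcome": outcome,
                            "inf1": outcome + rng.normal(0, 0.3),
                            "inf2": outcome + rng.normal(0, 0.3),
                            "noise1": rng.normal(),
                            "noise2": rng.normal(),
                        }
                    )
            table = pd.DataFrame(rows)
            plan = build_paired_folds(table, k=4, rng_seed=seed)
            res = greedy_search(
                table,
                plan,
                cost_values=[2.0],
                gamma_values=[0.5],
                max_size=2,
                candidate_columns=["inf1", "inf2", "noise1", "noise2"],
            )
            if set(res.iloc[0]["indices"]) == {"inf1", "inf2"}:
                hits += 1
        assert hits >= 18  # >= 90% of seeded runs

    def test_greedy_chain_and_row_count(self, separable_table):
        plan = build_paired_folds(separable_table, k=4, rng_seed=0)
        res = greedy_search(
            separable_table, plan, cost_values=[1.0, 2.0], gamma_values=[0.5]
        )
        assert len(res) == 3  # n_features - 1 rows for 4 candidates
        for prev, cur in zip(res["indices"], res["indices"][1:]):
            assert set(prev) < set(cur)


class TestSelectFinal:
    def make_result(self, aucs, accs):
        return pd.DataFrame(
            {
                "size": range(2, 2 + len(aucs)),
                "auc_mean": aucs,
                "acc_mean": accs,
            }
        )

    def test_distinct_optima(self):
        res = self.make_result([0.80, 0.84, 0.86], [84.0, 86.0, 85.0])
        out = select_final(res)
        assert out == {"best_auc_size": 4, "best_accuracy_size": 3}

    def test_monotone_metrics_pick_largest(self):
        res = self.make_result([0.7, 0.8, 0.9], [70.0, 80.0, 90.0])
        out = select_final(res)
        assert out == {"best_auc_size": 4, "best_accuracy_size": 4}

    def test_ties_prefer_smaller_size(self):
        res = self.make_result([0.8, 0.8, 0.8], [80.0, 80.0, 80.0])
        out = select_final(res)
        assert out == {"best_auc_size": 2, "best_accuracy_size": 2}


class TestFinalModel:
    def test_training_set_auc_on_separable_data(self, separable_table):
        final = train_final(separable_table, ["meanNN"], C=2.0, gamma=0.5)
        report = evaluate_scores(
            separable_table["outcome"].to_numpy(),
            final.decision_margin(separable_table),
        )
        assert report["auc"] == 1.0
        assert report["accuracy"] == 100.0

    def test_vanishing_gamma_flattens_margin(self, separable_table):
        final = train_final(separable_table, ["meanNN"], C=2.0, gamma=1e-12)
        margins = final.decision_margin(separable_table)
        assert np.ptp(margins) < 1e-6  # kernel -> all-ones: constant margin

    def test_single_class_rejected(self, separable_table):
        only_pos = separable_table[separable_table["outcome"] == 1]
        with pytest.raises(ValueError):
            train_final(only_pos, ["meanNN"], C=1.0, gamma=0.5)


class TestEvaluateScores:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_scores(np.ones(4, dtype=int), np.arange(4.0))

    def test_hanley_mcneil_interval_shrinks_with_n(self):
        lo1, hi1 = auc_hanley_mcneil_ci(0.8, 10, 10)
        lo2, hi2 = auc_hanley_mcneil_ci(0.8, 100, 100)
        assert (hi2 - lo2) < (hi1 - lo1)
        assert lo1 < 0.8 < hi1

    def test_report_fields(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
        margin = y + rng.normal(0, 0.8, size=40)
        report = evaluate_scores(y, margin)
        assert 0.5 < report["auc"] <= 1.0
        assert report["auc_ci"][0] <= report["auc"] <= report["auc_ci"][1]
        assert report["accuracy_ci"][0] <= report["accuracy"] <= report["accuracy_ci"][1]
        assert report["n"] == 40
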