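"""Splits, baselines, binomial tests and the experiment loop."""

import numpy as np
import pandas as pd
import pytest

from rumblesig.classify import (
    ForestSpec,
    balance_by_subsampling,
    eligible_calls,
    exact_binomial_p,
    fit_population_logistic,
    majority_baseline,
    run_experiment,
    split_holdout_callers,
    split_holdout_core_groups,
    split_holdout_dates,
)

from conftest import make_call_table


class TestBalance:
    def test_study_scale_imbalance_equalized(self):
        calls = pd.DataFrame(
            {
                "call_id": [f"c{i}" for i in range(938 + 414)],
                "population": ["samburu"] * 938 + ["amboseli"] * 414,
            }
        )
        out = balance_by_subsampling(calls, "population", np.random.default_rng(0))
        assert out["population"].value_counts().to_dict() == {
            "samburu": 414,
            "amboseli": 414,
        }

    def test_already_balanced_counts_unchanged(self):
        calls = pd.DataFrame(
            {"call_id": [f"c{i}" for i in range(20)], "y": ["a", "b"] * 10}
        )
        out = balance_by_subsampling(calls, "y", np.random.default_rng(1))
        assert out["y"].value_counts().to_dict() == {"a": 10, "b": 10}

    def test_same_seed_same_subset(self):
        calls = pd.DataFrame(
            {"call_id": [f"c{i}" for i in range(30)], "y": ["a"] * 20 + ["b"] * 10}
        )
        a = balance_by_subsampling(calls, "y", np.random.default_rng(7))
        b = balance_by_subsampling(calls, "y", np.random.default_rng(7))
        assert list(a["call_id"]) == list(b["call_id"])


class TestCallerHoldout:
    def test_twenty_percent_of_ten_is_two(self):
        calls = make_call_table({"p1": 10}, calls_per_caller=6)
        plan = split_holdout_callers(calls, group_by="population", seed=0)
        held = calls.set_index("call_id").loc[plan.test_ids, "caller_id"].nunique()
        assert held == 2

    def test_small_stratum_holds_out_at_least_one(self):
        calls = make_call_table({"p1": 3}, calls_per_caller=6)
        plan = split_holdout_callers(calls, group_by="population", seed=0)
        held = calls.set_index("call_id").loc[plan.test_ids, "caller_id"].nunique()
        assert held == 1

    def test_no_caller_spans_train_and_test(self):
        calls = make_call_table({"p1": 8, "p2": 5}, calls_per_caller=6)
        plan = split_holdout_callers(calls, group_by="population", seed=3)
        idx = calls.set_index("call_id")
        assert not (
            set(idx.loc[plan.train_ids, "caller_id"])
            & set(idx.loc[plan.test_ids, "caller_id"])
        )

    def test_ineligible_callers_stay_in_training(self):
        calls = make_call_table({"p1": 4}, calls_per_caller=6)
        rare = pd.DataFrame(
            [{"call_id": "rare_r0", "caller_id": "rare", "population": "p1",
              "date": "day00", "context": "contact"}]
        )
        calls = pd.concat([calls, rare], ignore_index=True)
        plan = split_holdout_callers(calls, group_by="population", seed=0)
        assert "rare_r0" in plan.train_ids


class TestCoreGroupHoldout:
    def _calls(self, n_bonds=6, cores_per_bond=2):
        frames = []
        for b in range(n_bonds):
            for c in range(cores_per_bond):
                t = make_call_table({f"b{b}c{c}": 2}, calls_per_caller=5)
                t["bond_group"] = f"bond{b}"
                t["core_group"] = f"bond{b}_core{c}"
                frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def test_one_core_held_out_per_bond(self):
        calls = self._calls(n_bonds=6)
        plan = split_holdout_core_groups(calls, seed=1)
        idx = calls.set_index("call_id")
        assert idx.loc[plan.test_ids, "core_group"].nunique() == 6
        assert idx.loc[plan.test_ids, "bond_group"].nunique() == 6

    def test_remaining_core_stays_in_train(self):
        calls = self._calls(n_bonds=1, cores_per_bond=2)
        plan = split_holdout_core_groups(calls, seed=2)
        idx = calls.set_index("call_id")
        assert idx.loc[plan.train_ids, "core_group"].nunique() == 1

    def test_core_ids_disjoint(self):
        calls = self._calls()
        plan = split_holdout_core_groups(calls, seed=5)
        idx = calls.set_index("call_id")
        assert not (
            set(idx.loc[plan.train_ids, "core_group"])
            & set(idx.loc[plan.test_ids, "core_group"])
        )


class TestDateHoldout:
    def _caller(self, caller, dates_counts):
        rows = []
        k = 0
        for d, n in dates_counts.items():
            for _ in range(n):
                rows.append(
                    {"call_id": f"{caller}_r{k}", "caller_id": caller,
                     "population": "p1", "date": d, "context": "contact"}
                )
                k += 1
        return pd.DataFrame(rows)

    def test_whole_date_held_out(self):
        calls = pd.concat(
            [self._caller("A", {"d1": 3, "d2": 4}), self._caller("B", {"d1": 3, "d2": 3})],
            ignore_index=True,
        )
        plan = split_holdout_dates(calls, seed=0)
        idx = calls.set_index("call_id")
        test_a = idx.loc[plan.test_ids].query("caller_id == 'A'")
        assert test_a["date"].nunique() == 1
        assert len(test_a) in (3, 4)

    def test_caller_date_pairs_disjoint(self):
        calls = pd.concat(
            [self._caller("A", {"d1": 3, "d2": 4}), self._caller("B", {"d1": 3, "d2": 3})],
            ignore_index=True,
        )
        plan = split_holdout_dates(calls, seed=4)
        idx = calls.set_index("call_id")
        tr = set(map(tuple, idx.loc[plan.train_ids, ["caller_id", "date"]].values))
        te = set(map(tuple, idx.loc[plan.test_ids, ["caller_id", "date"]].values))
        assert not tr & te
        # every test caller still trains on other dates
        assert {c for c, _ in te} <= {c for c, _ in tr}

    def test_single_date_caller_excluded_by_eligibility(self):
        calls = pd.concat(
            [self._caller("A", {"d1": 3, "d2": 3}), self._caller("C", {"d1": 5})],
            ignore_index=True,
        )
        kept = eligible_calls(calls, "individual")
        assert "C" not in set(kept["caller_id"])


class TestMajorityBaseline:
    def test_worked_example(self):
        train = ["A"] * 6 + ["B"] * 4
        test = ["A"] * 2 + ["B"] * 3
        assert majority_baseline(train, test) == pytest.approx(0.4)

    def test_single_class_training(self):
        assert majority_baseline(["A"] * 5, ["A", "B", "A"]) == pytest.approx(2 / 3)

    def test_baseline_departs_from_half_in_balanced_data(self):
        # balanced classes overall, but the test stratum is skewed
        train = ["A"] * 10 + ["B"] * 8
        test = ["B"] * 7 + ["A"] * 3
        assert majority_baseline(train, test) == pytest.approx(0.3)


class TestExactBinomial:
    def test_closed_form_example(self):
        assert exact_binomial_p(8, 10, 0.5) == pytest.approx(0.0546875, abs=1e-12)

    def test_zero_successes_gives_one(self):
        assert exact_binomial_p(0, 12, 0.3) == 1.0

    def test_all_successes_closed_form(self):
        assert exact_binomial_p(7, 7, 0.3) == pytest.approx(0.3**7, rel=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        ps = [exact_binomial_p(k, 20, 0.4) for k in range(21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_degenerate_null_probabilities(self):
        assert exact_binomial_p(3, 10, 0.0) == 0.0
        assert exact_binomial_p(0, 10, 0.0) == 1.0
        assert exact_binomial_p(10, 10, 1.0) == 1.0


class TestRunExperiment:
    def test_single_iteration_deterministic(self, tiny_features, tiny_annotated_calls):
        spec = ForestSpec(n_trees=30)
        kw = dict(spec=spec, n_iter=1, seed=9)
        a = run_experiment(tiny_features, tiny_annotated_calls, "population", **kw)
        b = run_experiment(tiny_features, tiny_annotated_calls, "population", **kw)
        pd.testing.assert_frame_equal(a.iterations, b.iterations)

    def test_accuracy_and_p_ranges(self, tiny_features, tiny_annotated_calls):
        res = run_experiment(
            tiny_features, tiny_annotated_calls, "individual",
            spec=ForestSpec(n_trees=30), n_iter=3, seed=2,
        )
        it = res.iterations
        assert it["accuracy"].between(0, 1).all()
        assert (it["p_value"] > 0).all() and (it["p_value"] <= 1).all()
        assert (it["accuracy"] == it["n_correct"] / it["n_test"]).all()

    def test_insufficient_classes_error(self, tiny_features, tiny_annotated_calls):
        one_pop = tiny_annotated_calls[
            tiny_annotated_calls["population"] == "pop1"
        ].reset_index(drop=True)
        with pytest.raises(ValueError, match="population"):
            run_experiment(tiny_features, one_pop, "population", n_iter=1)


def simulate_contour_table(delta_f1_mean: float, n_per_pop: int = 100, seed: int = 0):
    """Contour-stat tables for two populations differing only in mean f1."""
    from rumblesig.features import CONTOUR_STAT_NAMES

    rng = np.random.default_rng(seed)
    rows = []
    for pop, shift in (("pop1", 0.0), ("pop2", delta_f1_mean)):
        for _ in range(n_per_pop):
            # populations differ only in the mean; the remaining statistics
            # vary independently so each regressor's contribution is its own
            sd = abs(rng.normal(1.5, 0.4))
            row = {
                "f1_mean": 30.0 + shift + rng.normal(0, 1.5),
                "f1_sd": sd,
                "f1_skew": rng.normal(0, 0.5),
                "f1_kurt": rng.normal(0, 0.5),
                "f1_p10": 30.0 - 1.3 * sd + rng.normal(0, 0.8),
                "f1_p90": 30.0 + 1.3 * sd + rng.normal(0, 0.8),
                "f1_q25": 30.0 + rng.normal(0, 0.8),
                "f1_q50": 30.0 + rng.normal(0, 0.8),
                "f1_q75": 30.0 + rng.normal(0, 0.8),
                "age_days": rng.uniform(10, 60) * 365.25,
                "population": pop,
            }
            rows.append(row)
    df = pd.DataFrame(rows)
    assert list(df.columns[:9]) == list(CONTOUR_STAT_NAMES)
    return df


class TestPopulationLogistic:
    def test_planted_mean_shift_detected(self):
        hits, false_hits = 0, []
        for seed in range(20):
            tbl = simulate_contour_table(3.0, seed=seed)
            res = fit_population_logistic(tbl).set_index("regressor")
            if res.loc["f1_mean", "p_value"] < 0.05:
                hits += 1
            false_hits.append(
                (res.drop(index=["f1_mean", "f1_p10", "f1_p90"])["p_value"] < 0.05).sum()
            )
        assert hits >= 18
        # unrelated regressors significant at roughly the nominal rate
        assert np.mean(false_hits) <= 1.5

    def test_null_p_values_not_inflated(self):
        sig = 0
        n_terms = 0
        for seed in range(20):
            tbl = simulate_contour_table(0.0, seed=100 + seed)
            res = fit_population_logistic(tbl)
            sig += (res["p_value"] < 0.05).sum()
            n_terms += len(res)
        assert sig / n_terms < 0.15

    def test_perfect_separation_flagged(self):
        tbl = simulate_contour_table(0.0, n_per_pop=30, seed=3)
        tbl["f1_mean"] = np.where(tbl["population"] == "pop2", 100.0, 10.0)
        res = fit_population_logistic(tbl)
        assert res["separation"].all()


def test_power_increases_with_planted_population_offset():
    """Median binomial p falls monotonically as the planted between-
    population f1 offset grows over {0, 2, 4} Hz."""
    from rumblesig.features import extract_features_table, mel_feature_names
    from rumblesig.simulate import SimConfig, generate_dataset

    medians = []
    for sig in (0.0, 2.0, 4.0):
        cfg = SimConfig(
            n_populations=2, callers_per_population=(10, 10),
            bond_groups_per_population=1, core_groups_per_bond=2,
            calls_per_caller=8.0, sigma_pop_hz=sig,
            sigma_bond_hz=0.0, sigma_core_hz=0.0, sigma_ind_hz=0.0,
            n_days=10, seed=77,
        )
        ds = generate_dataset(cfg)
        feat = extract_features_table(ds.waveforms)
        calls = ds.calls.merge(
            ds.truth.callers[["caller_id", "bond_group", "core_group"]],
            on="caller_id",
        )
        res = run_experiment(
            feat, calls, "population", n_iter=30, seed=7,
            feature_cols=mel_feature_names(),
        )
        medians.append(res.median_p)
    assert medians[0] > medians[1] > medians[2]
    assert medians[2] < 0.05
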