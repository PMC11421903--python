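"""Proximity scores, pair tables, pair-class GLMMs and contrasts."""

import numpy as np
import pandas as pd
import pytest

from rumblesig.classify import ForestSpec, build_forest
from rumblesig.glmm import simulate_pair_table
from rumblesig.similarity import (
    PAIR_OFFSET,
    build_pair_table,
    fit_pairclass_glmm,
    fit_relatedness_glmm,
    pairwise_contrasts,
    proximity_matrix,
)


class _FakeTree:
    def __init__(self, leaf_assignment):
        self._leaves = np.asarray(leaf_assignment)

    def apply(self, X, check_input=True):
        return self._leaves[: len(X)]


class _FakeForest:
    def __init__(self, trees, samples, n_features):
        self.estimators_ = trees
        self.estimators_samples_ = samples
        self.n_features_in_ = n_features


class TestProximityHandExample:
    def test_two_tree_worked_example(self):
        """Same leaf of training size 4 in tree 1, different leaves in
        tree 2: score = (1/2)(1/4 + 0) = 0.125."""
        n = 6
        # tree 1: observations 0 and 1 share leaf 7; training obs in leaf 7
        # are exactly the four observations 0,1,2,3
        t1 = _FakeTree([7, 7, 7, 7, 8, 8])
        # tree 2: observations 0 and 1 in different leaves
        t2 = _FakeTree([1, 2, 1, 2, 1, 2])
        samples = [np.arange(n), np.arange(n)]
        forest = _FakeForest([t1, t2], samples, n_features=3)
        P = proximity_matrix(forest, np.zeros((n, 3)))
        assert P[0, 1] == pytest.approx(0.125, abs=1e-12)

    def test_identical_observations_hit_row_maximum(self):
        t1 = _FakeTree([1, 1, 2, 2])
        samples = [np.arange(4)]
        forest = _FakeForest([t1], samples, n_features=2)
        P = proximity_matrix(forest, np.zeros((4, 2)))
        assert P[0, 1] == P[0, 0] == pytest.approx(0.5)
        assert np.all(np.diag(P) >= P.max(axis=1) - 1e-12)


def _traverse(tree, x):
    """Independent terminal-node lookup walking the tree arrays directly."""
    t = tree.tree_
    node = 0
    while t.children_left[node] != -1:
        if x[t.feature[node]] <= t.threshold[node]:
            node = t.children_left[node]
        else:
            node = t.children_right[node]
    return node


class TestProximityOracle:
    def test_brute_force_equivalence_small_forest(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((10, 4))
        y = np.array(["a", "b"] * 5)
        forest = build_forest(X, y, ForestSpec(n_trees=5, mtry=2), seed=3)
        P = proximity_matrix(forest, X)
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        expected = np.zeros((10, 10))
        for tree, samples in zip(forest.estimators_, forest.estimators_samples_):
            leaves = [_traverse(tree, X32[i]) for i in range(10)]
            sizes = {}
            for s in samples:
                sizes[leaves[s]] = sizes.get(leaves[s], 0) + 1
            for i in range(10):
                for j in range(10):
                    if leaves[i] == leaves[j]:
                        expected[i, j] += 1.0 / sizes[leaves[i]]
        expected /= 5
        np.testing.assert_array_equal(P, expected)

    def test_feature_mismatch_errors(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 3))
        forest = build_forest(X, np.array(["a", "b"] * 4), ForestSpec(n_trees=2), 0)
        with pytest.raises(ValueError, match="feature mismatch"):
            proximity_matrix(forest, rng.standard_normal((8, 5)))


def _toy_calls(n_callers=4, context="contact"):
    rows = []
    for c in range(n_callers):
        rows.append(
            {
                "call_id": f"c{c}",
                "caller_id": f"f{c}",
                "context": context,
                "population": "pop1",
                "core_group": f"core{c % 2}",
                "bond_group": "bond0",
            }
        )
    return pd.DataFrame(rows)


class TestPairTable:
    def test_four_distinct_callers_give_six_pairs(self):
        calls = _toy_calls(4)
        P = np.full((4, 4), 0.2)
        pairs = build_pair_table(calls, P, scheme="population")
        assert len(pairs) == 6

    def test_same_caller_pair_excluded(self):
        calls = _toy_calls(3)
        calls.loc[2, "caller_id"] = "f0"
        pairs = build_pair_table(calls, np.full((3, 3), 0.1), scheme="population")
        assert len(pairs) == 2  # (c0,c1) and (c1,c2); (c0,c2) share a caller

    def test_cross_context_pair_excluded(self):
        calls = _toy_calls(3)
        calls.loc[2, "context"] = "greeting"
        pairs = build_pair_table(calls, np.full((3, 3), 0.1), scheme="population")
        assert len(pairs) == 1

    def test_offset_keeps_similarity_positive(self):
        calls = _toy_calls(4)
        pairs = build_pair_table(calls, np.zeros((4, 4)), scheme="core3")
        assert (pairs["similarity"] >= PAIR_OFFSET).all()

    def test_uncertain_context_dropped(self):
        calls = _toy_calls(4)
        calls["context_certain"] = [True, True, True, False]
        pairs = build_pair_table(calls, np.full((4, 4), 0.1), scheme="population")
        assert len(pairs) == 3


@pytest.fixture(scope="module")
def three_state_fit():
    df = simulate_pair_table(
        n_dyads=150, pairs_per_dyad=10,
        class_effects={
            "same_core": 0.5, "same_bond_diff_core": 0.1, "diff_bond": 0.0
        },
        sigma_u=0.4, seed=11,
    )
    df["age_scaled"] = 0.0 * df["age_scaled"]  # keep the design minimal
    return fit_pairclass_glmm(df, scheme="core3")


class TestContrasts:
    def test_contrast_linearity_exact(self, three_state_fit):
        tbl = pairwise_contrasts(three_state_fit).set_index("contrast")
        est = tbl["estimate"]
        names = list(tbl.index)
        # A-B + B-C = A-C for the alphabetical triple
        a_b = est["diff_bond - same_bond_diff_core"]
        b_c = est["same_bond_diff_core - same_core"]
        a_c = est["diff_bond - same_core"]
        assert a_b + b_c == pytest.approx(a_c, abs=1e-12)
        assert len(names) == 3

    def test_planted_core_elevation_pattern(self, three_state_fit):
        tbl = pairwise_contrasts(three_state_fit).set_index("contrast")
        assert tbl.loc["diff_bond - same_core", "p_adjusted"] < 0.05
        assert tbl.loc["same_bond_diff_core - same_core", "p_adjusted"] < 0.05

    def test_binary_fit_rejected(self):
        df = simulate_pair_table(n_dyads=60, pairs_per_dyad=6, seed=2)
        fit = fit_pairclass_glmm(df, scheme="population")
        with pytest.raises(ValueError, match="three-state"):
            pairwise_contrasts(fit)


class TestRelatednessModel:
    def test_constant_relatedness_rejected(self):
        df = simulate_pair_table(n_dyads=50, pairs_per_dyad=6, seed=3)
        df["relatedness"] = 0.2
        with pytest.raises(ValueError, match="constant"):
            fit_relatedness_glmm(df)

    def test_collinearity_diagnostic_reported(self):
        df = simulate_pair_table(n_dyads=80, pairs_per_dyad=6, seed=4)
        # relatedness proportional to group co-membership
        df["relatedness"] = 0.25 * (df["pair_class"] == "same") + np.random.default_rng(
            0
        ).normal(0, 1e-3, len(df))
        fit = fit_relatedness_glmm(df)
        assert abs(fit.diagnostics["group_relatedness_corr"]) > 0.99


def test_same_core_contrast_grows_with_planted_core_effect():
    """Raising sigma_core (sigma_bond = 0) raises the same-core GLMM
    coefficient monotonically over three effect levels, end to end from
    waveforms through proximity scores."""
    from rumblesig.classify import eligible_calls
    from rumblesig.features import extract_features_table, mel_feature_names
    from rumblesig.similarity import proximity_forest
    from rumblesig.simulate import SimConfig, generate_dataset

    estimates = []
    for sig in (0.0, 2.0, 5.0):
        cfg = SimConfig(
            n_populations=1, callers_per_population=(16,),
            bond_groups_per_population=2, core_groups_per_bond=2,
            calls_per_caller=8.0, sigma_core_hz=sig,
            sigma_bond_hz=0.0, sigma_ind_hz=1.0, n_days=10, seed=55,
        )
        ds = generate_dataset(cfg)
        feat = extract_features_table(ds.waveforms).set_index("call_id")
        calls = ds.calls.merge(
            ds.truth.callers[["caller_id", "bond_group", "core_group"]],
            on="caller_id",
        )
        calls = eligible_calls(calls, "core")
        X = feat.loc[calls["call_id"], mel_feature_names()].to_numpy()
        forest = proximity_forest(X, calls["core_group"].to_numpy(), seed=3,
                                  n_trees=1000)
        P = proximity_matrix(forest, X)
        ages = dict(zip(ds.truth.callers["caller_id"],
                        ds.truth.callers["age_years"]))
        pairs = build_pair_table(calls, P, scheme="core3", ages=ages)
        fit = fit_pairclass_glmm(pairs, "core3")
        estimates.append(float(fit.coef["pair_class[same_core]"]))
    assert estimates[0] < estimates[1] < estimates[2]
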