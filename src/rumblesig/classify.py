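"""Random-forest vocal-signature experiments with leakage-proof splits.

Five experiment designs probe vocal signatures at nested levels:

* population (mel features, and separately f1-contour features), with the
  larger population subsampled to balance classes each iteration and 20%
  of eligible callers held out per population;
* bond group, holding out one whole core group per bond group;
* core group, holding out 20% of eligible callers per core group;
* individual caller, holding out one recording date per caller.

Each iteration's accuracy is compared with a majority (zero-rate)
classifier via a one-tailed exact binomial test; experiments repeat the
split many times (10 000 in the full protocol) and report medians.
Forest hyperparameters: 500 trees, 6 variables per node, 60% of
observations per tree drawn without replacement, minimum node size 1,
unlimited depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ForestSpec",
    "SplitPlan",
    "IterationResult",
    "ExperimentResult",
    "LEVELS",
    "SubsampleForest",
    "build_forest",
    "balance_by_subsampling",
    "split_holdout_callers",
    "split_holdout_core_groups",
    "split_holdout_dates",
    "majority_baseline",
    "exact_binomial_p",
    "eligible_calls",
    "run_experiment",
    "fit_population_logistic",
]

LEVELS = ("population", "bond", "core", "individual")

_LEVEL_LABEL = {
    "population": "population",
    "bond": "bond_group",
    "core": "core_group",
    "individual": "caller_id",
}


@dataclass(frozen=True)
class ForestSpec:
    """Random-forest hyperparameters (classification experiments default)."""

    n_trees: int = 500
    mtry: int = 6
    sample_frac: float = 0.6
    min_node_size: int = 1
    max_depth: int | None = None


@dataclass
class SplitPlan:
    level: str
    train_ids: list[str]
    test_ids: list[str]
    seed: int


@dataclass
class IterationResult:
    accuracy: float
    baseline_accuracy: float
    n_test: int
    n_correct: int
    p_value: float


@dataclass
class ExperimentResult:
    level: str
    iterations: pd.DataFrame  # accuracy, baseline_accuracy, n_test, n_correct, p_value
    median_accuracy: float
    median_baseline: float
    median_p: float
    test_fraction_mean: float
    test_fraction_sd: float
    n_calls: int = 0
    n_classes: int = 0
    extra: dict = field(default_factory=dict)


class SubsampleForest:
    """Random forest whose trees train on subsamples drawn w/o replacement.

    Each of ``spec.n_trees`` sklearn decision trees (``spec.mtry`` features
    tried per node, fully grown by default) fits on a fresh
    ``spec.sample_frac`` subsample of the observations drawn *without*
    replacement.  Prediction is a hard majority vote across trees, ties
    broken by class order.  ``estimators_`` / ``estimators_samples_``
    expose each tree and its training indices for proximity extraction.
    """

    def __init__(self, spec: ForestSpec, seed: int):
        self.spec = spec
        self.seed = int(seed) % (2**31)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.estimators_samples_: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SubsampleForest":
        X = np.ascontiguousarray(X, dtype=np.float32)
        self.classes_, y_enc = np.unique(np.asarray(y), return_inverse=True)
        y_enc = y_enc.astype(np.float64)
        self.n_features_in_ = X.shape[1]
        n = X.shape[0]
        n_sub = max(1, int(round(self.spec.sample_frac * n)))
        rng = np.random.default_rng(self.seed)
        mtry = min(self.spec.mtry, X.shape[1])
        self.estimators_ = []
        self.estimators_samples_ = []
        for _ in range(self.spec.n_trees):
            idx = rng.choice(n, size=n_sub, replace=False)
            tree = DecisionTreeClassifier(
                max_features=mtry,
                min_samples_leaf=self.spec.min_node_size,
                max_depth=self.spec.max_depth,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[idx], y_enc[idx], check_input=False)
            self.estimators_.append(tree)
            self.estimators_samples_.append(idx)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float32)
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=np.int64)
        rows = np.arange(X.shape[0])
        for tree in self.estimators_:
            pred = tree.predict(X, check_input=False).astype(np.int64)
            votes[rows, pred] += 1
        return self.classes_[np.argmax(votes, axis=1)]

    def apply_all(self, X: np.ndarray) -> np.ndarray:
        """(n_trees, n_obs) terminal-node ids."""
        X = np.ascontiguousarray(X, dtype=np.float32)
        return np.stack([t.apply(X, check_input=False) for t in self.estimators_])


def build_forest(X: np.ndarray, y: np.ndarray, spec: ForestSpec, seed: int):
    """Fit the spec'd forest: trees on 60% subsamples without replacement."""
    return SubsampleForest(spec, seed).fit(X, y)


def balance_by_subsampling(
    calls: pd.DataFrame, class_col: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Subsample every class down to the smallest class count (w/o replacement)."""
    counts = calls[class_col].value_counts()
    if (counts == 0).any() or counts.size < 2:
        raise ValueError("need >= 2 non-empty classes to balance")
    n_min = int(counts.min())
    parts = []
    for cls, grp in calls.groupby(class_col, sort=True):
        take = rng.choice(len(grp), size=n_min, replace=False)
        parts.append(grp.iloc[np.sort(take)])
    return pd.concat(parts, ignore_index=True)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_holdout_callers(
    calls: pd.DataFrame,
    frac: float = 0.2,
    min_calls: int = 5,
    group_by: str = "population",
    seed: int = 0,
) -> SplitPlan:
    """Hold out ``frac`` of eligible callers per stratum; all their calls to test.

    Eligible callers have at least ``min_calls`` calls.  Per stratum the
    number held out is max(1, round(frac * n_eligible)).  Calls of
    ineligible callers stay in the training set.  No caller spans both
    sides.
    """
    rng = np.random.default_rng(seed)
    test_calls: list[str] = []
    caller_counts = calls.groupby("caller_id").size()
    for stratum, grp in calls.groupby(group_by, sort=True):
        eligible = sorted(
            c for c in grp["caller_id"].unique() if caller_counts[c] >= min_calls
        )
        if not eligible:
            raise ValueError(f"no eligible callers in stratum {stratum!r}")
        k = max(1, _round_half_up(frac * len(eligible)))
        held = rng.choice(eligible, size=min(k, len(eligible)), replace=False)
        test_calls.extend(grp.loc[grp["caller_id"].isin(held), "call_id"])
    test = set(test_calls)
    train = [c for c in calls["call_id"] if c not in test]
    return SplitPlan("caller-holdout", train, sorted(test), seed)


def split_holdout_core_groups(calls: pd.DataFrame, seed: int = 0) -> SplitPlan:
    """Hold out one qualifying core group per bond group.

    ``calls`` must already be restricted to eligible bond groups (see
    :func:`eligible_calls`); the held-out core is drawn uniformly among the
    bond's cores holding at least five calls, so the training set keeps at
    least one qualifying core per bond.
    """
    rng = np.random.default_rng(seed)
    test_cores = []
    for bond, grp in calls.groupby("bond_group", sort=True):
        core_counts = grp.groupby("core_group").size()
        qualifying = sorted(core_counts[core_counts >= 5].index)
        if len(qualifying) < 2:
            raise ValueError(
                f"bond group {bond!r} lacks two qualifying core groups"
            )
        test_cores.append(rng.choice(qualifying))
    in_test = calls["core_group"].isin(test_cores)
    return SplitPlan(
        "core-group-holdout",
        list(calls.loc[~in_test, "call_id"]),
        list(calls.loc[in_test, "call_id"]),
        seed,
    )


def split_holdout_dates(
    calls: pd.DataFrame,
    min_calls_per_date: int = 3,
    min_dates: int = 2,
    seed: int = 0,
) -> SplitPlan:
    """Hold out one recording date per caller.

    ``calls`` must already be restricted to eligible callers (at least
    ``min_calls_per_date`` calls on each of at least ``min_dates`` dates);
    the held-out date is drawn uniformly among each caller's qualifying
    dates, so every test caller also appears in training on other dates.
    """
    rng = np.random.default_rng(seed)
    test_calls: list[str] = []
    for caller, grp in calls.groupby("caller_id", sort=True):
        date_counts = grp.groupby("date").size()
        qualifying = sorted(date_counts[date_counts >= min_calls_per_date].index)
        if len(qualifying) < min_dates:
            raise ValueError(f"caller {caller!r} is not eligible")
        held = rng.choice(qualifying)
        test_calls.extend(grp.loc[grp["date"] == held, "call_id"])
    test = set(test_calls)
    train = [c for c in calls["call_id"] if c not in test]
    return SplitPlan("date-holdout", train, sorted(test), seed)


def majority_baseline(
    train_labels: np.ndarray, test_labels: np.ndarray, seed: int = 0
) -> float:
    """Accuracy of always guessing the training set's most common class.

    Ties for the training majority are broken uniformly at random.  Note
    the baseline can exceed or fall below 1/n_classes: the training
    majority need not be the test majority.
    """
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    if train_labels.size == 0 or test_labels.size == 0:
        raise ValueError("empty label set")
    vals, counts = np.unique(train_labels, return_counts=True)
    top = vals[counts == counts.max()]
    majority = top[0] if top.size == 1 else np.random.default_rng(seed).choice(top)
    return float(np.mean(test_labels == majority))


def exact_binomial_p(k_correct: int, n: int, p0: float) -> float:
    """One-tailed exact binomial upper-tail p: P(X >= k), X ~ Bin(n, p0)."""
    if not 0 <= k_correct <= n:
        raise ValueError("need 0 <= k_correct <= n")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    return float(stats.binom.sf(k_correct - 1, n, p0))


def eligible_calls(calls: pd.DataFrame, level: str) -> pd.DataFrame:
    """Apply the level's inclusion rules to the call table.

    population: callers from both populations (no filtering beyond the
    per-iteration balancing).  bond: bond groups with >= 2 core groups
    having >= 5 calls each.  core: core groups with >= 2 callers having
    >= 5 calls each.  individual: callers with >= 3 calls on >= 2 dates.
    """
    if level == "population":
        return calls
    if level == "bond":
        keep_bonds = []
        for bond, grp in calls.groupby("bond_group"):
            core_counts = grp.groupby("core_group").size()
            if (core_counts >= 5).sum() >= 2:
                keep_bonds.append(bond)
        return calls[calls["bond_group"].isin(keep_bonds)].reset_index(drop=True)
    if level == "core":
        keep_cores = []
        for core, grp in calls.groupby("core_group"):
            caller_counts = grp.groupby("caller_id").size()
            if (caller_counts >= 5).sum() >= 2:
                keep_cores.append(core)
        return calls[calls["core_group"].isin(keep_cores)].reset_index(drop=True)
    if level == "individual":
        keep_callers = []
        for caller, grp in calls.groupby("caller_id"):
            date_counts = grp.groupby("date").size()
            if (date_counts >= 3).sum() >= 2:
                keep_callers.append(caller)
        return calls[calls["caller_id"].isin(keep_callers)].reset_index(drop=True)
    raise ValueError(f"unknown level {level!r}")


def _split_for_level(level: str, calls: pd.DataFrame, seed: int) -> SplitPlan:
    if level == "population":
        return split_holdout_callers(calls, group_by="population", seed=seed)
    if level == "bond":
        return split_holdout_core_groups(calls, seed=seed)
    if level == "core":
        return split_holdout_callers(calls, group_by="core_group", seed=seed)
    if level == "individual":
        return split_holdout_dates(calls, seed=seed)
    raise ValueError(f"unknown level {level!r}")


def run_experiment(
    features: pd.DataFrame,
    calls: pd.DataFrame,
    level: str,
    spec: ForestSpec | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    feature_cols: list[str] | None = None,
) -> ExperimentResult:
    """Run one classification experiment at the given level.

    ``features`` holds one row per call_id with the predictor columns;
    ``calls`` holds call metadata including the level's label column
    (bond/core levels need ``bond_group``/``core_group``).  Per iteration:
    (population level only) balance classes by subsampling, draw the
    level's leakage-proof split, train the forest, score the test set and
    compare with the majority baseline by a one-tailed exact binomial
    test.  Medians across iterations summarise the experiment.
    """
    spec = spec or ForestSpec()
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    label_col = _LEVEL_LABEL[level]
    data = eligible_calls(calls, level)
    if data.empty or data[label_col].nunique() < 2:
        raise ValueError(f"insufficient classes for level {level!r} after filtering")
    if feature_cols is None:
        feature_cols = [c for c in features.columns if c != "call_id"]
    feat = features.set_index("call_id")[feature_cols]
    feat = feat.dropna()
    data = data[data["call_id"].isin(feat.index)].reset_index(drop=True)
    if data[label_col].nunique() < 2:
        raise ValueError(f"insufficient classes for level {level!r} after filtering")

    root = np.random.SeedSequence(seed)
    iter_seeds = root.generate_state(n_iter * 2).reshape(n_iter, 2) % (2**31)
    rows = []
    for it in range(n_iter):
        s_split, s_forest = int(iter_seeds[it, 0]), int(iter_seeds[it, 1])
        d = data
        if level == "population":
            d = balance_by_subsampling(
                data, label_col, np.random.default_rng(s_split)
            )
        plan = _split_for_level(level, d, s_split)
        d_idx = d.set_index("call_id")
        y_train = d_idx.loc[plan.train_ids, label_col].to_numpy()
        y_test = d_idx.loc[plan.test_ids, label_col].to_numpy()
        X_train = feat.loc[plan.train_ids].to_numpy()
        X_test = feat.loc[plan.test_ids].to_numpy()
        clf = build_forest(X_train, y_train, spec, s_forest)
        pred = clf.predict(X_test)
        n_test = len(y_test)
        n_correct = int(np.sum(pred == y_test))
        acc = n_correct / n_test
        base = majority_baseline(y_train, y_test, seed=s_split)
        p = exact_binomial_p(n_correct, n_test, base)
        rows.append(
            {
                "accuracy": acc,
                "baseline_accuracy": base,
                "n_test": n_test,
                "n_correct": n_correct,
                "p_value": p,
                "test_fraction": n_test / len(d),
            }
        )
    iters = pd.DataFrame(rows)
    return ExperimentResult(
        level=level,
        iterations=iters,
        median_accuracy=float(iters["accuracy"].median()),
        median_baseline=float(iters["baseline_accuracy"].median()),
        median_p=float(iters["p_value"].median()),
        test_fraction_mean=float(iters["test_fraction"].mean()),
        test_fraction_sd=float(iters["test_fraction"].std()),
        n_calls=len(data),
        n_classes=int(data[label_col].nunique()),
    )


def fit_population_logistic(
    contour_table: pd.DataFrame,
    stat_cols: list[str] | None = None,
    age_col: str = "age_days",
    pop_col: str = "population",
) -> pd.DataFrame:
    """Logistic regression of population on f1-contour stats and caller age.

    One row per call with the nine contour statistics, caller age (days)
    and population.  Returns a table with one row per regressor:
    coefficient, likelihood-ratio chi-square from single-term deletion
    (analysis of deviance) and p-value, plus a ``separation`` flag set
    when the model perfectly separates the populations.
    """
    import statsmodels.api as sm

    from .features import CONTOUR_STAT_NAMES

    stat_cols = list(stat_cols or CONTOUR_STAT_NAMES)
    cols = stat_cols + [age_col]
    df = contour_table.dropna(subset=cols + [pop_col]).reset_index(drop=True)
    pops = sorted(df[pop_col].unique())
    if len(pops) != 2:
        raise ValueError("need exactly 2 populations")
    y = (df[pop_col] == pops[1]).astype(float).to_numpy()
    X = df[cols].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
        raise ValueError("collinear regressor columns")

    def _fit(Xsub):
        Xc = sm.add_constant(Xsub, has_constant="add")
        return sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=200)

    full = _fit(X)
    mu = full.fittedvalues
    separated = bool(np.all(np.abs(mu - y) < 1e-8))
    rows = []
    for j, name in enumerate(cols):
        red = _fit(np.delete(X, j, axis=1))
        chi2 = max(0.0, 2.0 * (full.llf - red.llf))
        rows.append(
            {
                "regressor": name,
                "coefficient": float(full.params[j + 1]),
                "chi2": chi2,
                "p_value": float(stats.chi2.sf(chi2, df=1)),
                "separation": separated,
            }
        )
    return pd.DataFrame(rows)
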