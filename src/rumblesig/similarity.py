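"""Forest-proximity call similarity and its social/genetic regressions.

An 8000-tree forest is trained on *all* observations (no balancing, no
hold-out); the proximity score of a call pair is the proportion of trees
in which both calls land in the same terminal node, each co-occurrence
weighted by the reciprocal of the node's training size, so agreement in a
small, specific leaf counts for more than agreement in a large one.
Pairs of calls (same behavioural context, different callers) then enter
gamma mixed regressions that ask whether similarity tracks social tier
and/or genetic relatedness once caller-dyad identity and age difference
are controlled.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ForestSpec, build_forest
from .glmm import GammaGLMM, GlmmFit

__all__ = [
    "PROXIMITY_FOREST_SPEC",
    "proximity_matrix",
    "proximity_forest",
    "build_pair_table",
    "fit_pairclass_glmm",
    "pairwise_contrasts",
    "fit_relatedness_glmm",
    "PAIR_OFFSET",
]

#: Additive offset keeping zero proximity scores strictly positive.
PAIR_OFFSET = 1e-5

#: Proximity forests reuse the experiment hyperparameters with 8000 trees.
PROXIMITY_FOREST_SPEC = ForestSpec(n_trees=8000)

THREE_STATE = ("same_core", "same_bond_diff_core", "diff_bond")


def proximity_forest(X: np.ndarray, y: np.ndarray, seed: int, n_trees: int = 8000):
    return build_forest(X, y, ForestSpec(n_trees=n_trees), seed)


def proximity_matrix(forest, X: np.ndarray, adjust_node_size: bool = True) -> np.ndarray:
    """Node-size-adjusted random-forest proximity scores.

    ``X`` must be the matrix the forest was trained on (the proximity
    protocol trains on all observations and holds nothing out).
    score(i, j) = (1/T) * sum over trees t of
    ``[leaf_t(i) == leaf_t(j)] / size_t(leaf)``, where ``size_t`` counts
    the tree's *training* observations (its 60% subsample) in that leaf.
    With ``adjust_node_size=False`` the unadjusted proportion of shared
    leaves is returned instead.  Symmetric; the diagonal is each row's
    maximum.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    if X.shape[1] != forest.n_features_in_:
        raise ValueError(
            f"feature mismatch: forest expects {forest.n_features_in_} features, "
            f"got {X.shape[1]}"
        )
    n = X.shape[0]
    P = np.zeros((n, n))
    T = len(forest.estimators_)
    for est, samples in zip(forest.estimators_, forest.estimators_samples_):
        leaves = est.apply(X)
        if adjust_node_size:
            size = np.bincount(leaves[samples], minlength=leaves.max() + 1)
            w = 1.0 / np.maximum(size[leaves], 1)
        else:
            w = np.ones(n)
        P += (leaves[:, None] == leaves[None, :]) * w[None, :]
    return P / T


def _pair_class(scheme: str, meta_i, meta_j) -> str | None:
    if scheme == "population":
        return "same_pop" if meta_i["population"] == meta_j["population"] else "diff_pop"
    same_core = meta_i["core_group"] == meta_j["core_group"]
    same_bond = meta_i["bond_group"] == meta_j["bond_group"]
    if scheme == "core3":
        if same_core:
            return "same_core"
        if same_bond:
            return "same_bond_diff_core"
        return "diff_bond"
    if scheme == "core_binary":
        return "same_core" if same_core else "diff_core"
    if scheme == "bond_binary":
        return "same_bond" if same_bond else "diff_bond"
    raise ValueError(f"unknown pair-class scheme {scheme!r}")


def build_pair_table(
    calls: pd.DataFrame,
    prox: np.ndarray,
    scheme: str = "population",
    ages: dict[str, float] | None = None,
    relatedness: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All retained unordered call pairs with similarity and covariates.

    ``calls`` rows must align with the axes of ``prox`` and carry
    caller_id, context and the scheme's group columns; a boolean
    ``context_certain`` column, if present, drops uncertain calls first.
    Pairs must have the same behavioural context and different callers.
    The proximity score gets a +0.00001 offset; |age difference| is
    z-scored across the emitted table; relatedness (id_a, id_b,
    relatedness) is merged per caller dyad when given.
    """
    calls = calls.reset_index(drop=True)
    if len(calls) != prox.shape[0]:
        raise ValueError("calls and proximity matrix are misaligned")
    if "context_certain" in calls.columns:
        keep = calls["context_certain"].astype(bool).to_numpy()
    else:
        keep = np.ones(len(calls), dtype=bool)

    rel_map = {}
    if relatedness is not None:
        for r in relatedness.itertuples(index=False):
            rel_map[frozenset((r.id_a, r.id_b))] = float(r.relatedness)

    meta = calls.to_dict("records")
    rows = []
    for i, j in itertools.combinations(range(len(calls)), 2):
        if not (keep[i] and keep[j]):
            continue
        mi, mj = meta[i], meta[j]
        if mi["caller_id"] == mj["caller_id"]:
            continue
        if mi["context"] != mj["context"]:
            continue
        dyad = tuple(sorted((mi["caller_id"], mj["caller_id"])))
        row = {
            "call_a": mi["call_id"],
            "call_b": mj["call_id"],
            "dyad": f"{dyad[0]}|{dyad[1]}",
            "pair_class": _pair_class(scheme, mi, mj),
            "context": mi["context"],
            "similarity": float(prox[i, j]) + PAIR_OFFSET,
        }
        if ages is not None:
            row["age_diff"] = abs(ages[mi["caller_id"]] - ages[mj["caller_id"]])
        if rel_map:
            row["relatedness"] = rel_map.get(frozenset(dyad), np.nan)
        rows.append(row)
    if not rows:
        raise ValueError("no pairs survive the filters")
    pairs = pd.DataFrame(rows)
    if "age_diff" in pairs.columns:
        sd = pairs["age_diff"].std()
        pairs["age_scaled"] = (pairs["age_diff"] - pairs["age_diff"].mean()) / (
            sd if sd > 0 else 1.0
        )
    return pairs


def _reference_level(levels: list[str]) -> str:
    # reference = most distant class
    for ref in ("diff_bond", "diff_pop", "diff_core", "different"):
        if ref in levels:
            return ref
    return sorted(levels)[-1]


def _design(pairs: pd.DataFrame, extra_cols: list[str]):
    levels = sorted(pairs["pair_class"].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 pair classes")
    if pairs["dyad"].nunique() < 2:
        raise ValueError("need >= 2 distinct dyads")
    ref = _reference_level(levels)
    dummy_levels = [l for l in levels if l != ref]
    cols = [np.ones(len(pairs))]
    names = ["(intercept)"]
    for l in dummy_levels:
        cols.append((pairs["pair_class"] == l).astype(float).to_numpy())
        names.append(f"pair_class[{l}]")
    terms = {"pair_class": list(range(1, 1 + len(dummy_levels)))}
    for c in extra_cols:
        cols.append(pairs[c].to_numpy(dtype=float))
        names.append(c)
        terms[c] = [len(names) - 1]
    X = np.column_stack(cols)
    return X, names, terms, ref


def fit_pairclass_glmm(pairs: pd.DataFrame, scheme: str = "core3") -> GlmmFit:
    """Gamma GLMM: similarity ~ pair class + scaled age difference + (1|dyad).

    Reference level is the most distant class (different bond groups /
    different populations).  Chi-square rows come from single-term
    deletion.
    """
    extra = ["age_scaled"] if "age_scaled" in pairs.columns else []
    X, names, terms, ref = _design(pairs, extra)
    fit = GammaGLMM(
        X, pairs["similarity"].to_numpy(), pairs["dyad"], names=names, terms=terms
    ).fit()
    fit.diagnostics["reference_level"] = ref
    fit.diagnostics["scheme"] = scheme
    return fit


def pairwise_contrasts(fit: GlmmFit) -> pd.DataFrame:
    """All three pairwise contrasts of the three-state pair class.

    Estimates are on the link (log) scale; p-values carry a Tukey-style
    family adjustment: each contrast's z statistic is referred to the
    distribution of the maximum absolute component of a trivariate normal
    with the contrasts' estimated correlation.
    """
    cls_cols = [c for c in fit.coef.index if c.startswith("pair_class[")]
    if len(cls_cols) != 2:
        raise ValueError("pairwise contrasts need a three-state pair-class fit")
    ref = fit.diagnostics.get("reference_level", "diff_bond")
    lev = [c[len("pair_class["):-1] for c in cls_cols]
    p = len(fit.coef)
    idx = {c: i for i, c in enumerate(fit.coef.index)}
    # effects relative to reference: ref itself is 0
    vec = {ref: np.zeros(p)}
    for c, l in zip(cls_cols, lev):
        v = np.zeros(p)
        v[idx[c]] = 1.0
        vec[l] = v
    levels = lev + [ref]
    contrasts = list(itertools.combinations(sorted(levels), 2))
    C = np.array([vec[a] - vec[b] for a, b in contrasts])
    V = fit.vcov.to_numpy()
    est = C @ fit.coef.to_numpy()
    cov = C @ V @ C.T
    se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    z = est / se
    corr = cov / np.outer(se, se)
    # three contrasts of two free effects are rank-2: clip tiny negative
    # eigenvalues and re-standardise so the mvn quadrature accepts it
    w, V = np.linalg.eigh((corr + corr.T) / 2.0)
    corr = (V * np.clip(w, 1e-6, None)) @ V.T
    d = np.sqrt(np.diag(corr))
    corr = corr / np.outer(d, d)
    corr += 1e-9 * np.eye(len(contrasts))
    p_adj = []
    for zk in z:
        a = abs(zk) * np.ones(len(contrasts))
        inside = stats.multivariate_normal.cdf(
            a, mean=np.zeros(len(contrasts)), cov=corr, lower_limit=-a
        )
        p_adj.append(float(np.clip(1.0 - inside, 0.0, 1.0)))
    return pd.DataFrame(
        {
            "contrast": [f"{a} - {b}" for a, b in contrasts],
            "estimate": est,
            "se": se,
            "z": z,
            "p_adjusted": p_adj,
        }
    )


def fit_relatedness_glmm(pairs: pd.DataFrame, scheme: str = "core_binary") -> GlmmFit:
    """Gamma GLMM: similarity ~ binary pair class + age difference + relatedness.

    Requires relatedness for every dyad in the table.  A collinearity
    diagnostic (correlation between the same-group indicator and
    relatedness, and the design condition number) is reported in
    ``diagnostics``.
    """
    if "relatedness" not in pairs.columns or pairs["relatedness"].isna().any():
        raise ValueError("relatedness must be available for all dyads")
    if pairs["relatedness"].nunique() <= 1:
        raise ValueError("relatedness column is constant")
    extra = ["age_scaled"] if "age_scaled" in pairs.columns else []
    extra = extra + ["relatedness"]
    X, names, terms, ref = _design(pairs, extra)
    fit = GammaGLMM(
        X, pairs["similarity"].to_numpy(), pairs["dyad"], names=names, terms=terms
    ).fit()
    fit.diagnostics["reference_level"] = ref
    fit.diagnostics["scheme"] = scheme
    same = X[:, 1]
    rel = pairs["relatedness"].to_numpy(dtype=float)
    fit.diagnostics["group_relatedness_corr"] = float(np.corrcoef(same, rel)[0, 1])
    fit.diagnostics["design_condition_number"] = float(np.linalg.cond(X))
    return fit
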