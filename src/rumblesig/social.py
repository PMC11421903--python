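"""Social-tier inference from sighting data.

Core groups are inferred by Ward hierarchical clustering of simple-ratio
association indices, with the cut height found automatically at the most
significant knot of the cumulative-bifurcation curve.  Bond groups come
from repeating the procedure on the matriarchs (oldest female per core
group) only; each bond group is the union of its matriarchs' core groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "AssociationMatrix",
    "Dendrogram",
    "SocialPartition",
    "NoKnotError",
    "association_matrix",
    "ward_dendrogram",
    "find_knot",
    "cut_partition",
    "infer_tiers",
]


class NoKnotError(ValueError):
    """Cumulative-bifurcation curve indistinguishable from its chord."""


@dataclass
class AssociationMatrix:
    """Symmetric simple-ratio association indices, diagonal 1 by convention."""

    ids: list[str]
    matrix: np.ndarray
    counts: pd.Series  # sightings per surviving individual


@dataclass
class Dendrogram:
    """Ward merge tree: scipy linkage matrix + leaf ids."""

    linkage: np.ndarray  # (n-1, 4)
    ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class SocialPartition:
    """individual -> core group, core group -> bond group, matriarchs."""

    core_of: dict[str, str]
    bond_of_core: dict[str, str]
    matriarchs: dict[str, str]  # core group -> matriarch id

    def bond_of(self) -> dict[str, str]:
        return {i: self.bond_of_core[c] for i, c in self.core_of.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "individual": i,
                "core_group": c,
                "bond_group": self.bond_of_core[c],
                "is_matriarch": self.matriarchs.get(c) == i,
            }
            for i, c in sorted(self.core_of.items())
        ]
        return pd.DataFrame(rows)


def association_matrix(
    sightings: pd.DataFrame, min_sightings: int = 20
) -> AssociationMatrix:
    """Simple-ratio association indices from a sighting table.

    index(A, B) = x / (x + yA + yB), where x is the number of sighting rows
    containing both A and B and yA/yB the rows containing exactly one.
    Individuals seen fewer than ``min_sightings`` times are dropped before
    the index is computed.
    """
    if sightings.empty:
        raise ValueError("empty sighting table")
    ids = sorted({i for row in sightings["ids"] for i in row})
    idx = {i: k for k, i in enumerate(ids)}
    ind = np.zeros((len(sightings), len(ids)), dtype=bool)
    for r, row in enumerate(sightings["ids"]):
        for i in set(row):
            ind[r, idx[i]] = True
    counts = ind.sum(axis=0)
    keep = counts >= min_sightings
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 individuals with >= {min_sightings} sightings"
        )
    ind = ind[:, keep]
    ids = [i for i, k in zip(ids, keep) if k]
    counts = counts[keep]
    x = (ind.T.astype(np.int64)) @ ind.astype(np.int64)  # joint sightings
    denom = counts[:, None] + counts[None, :] - x  # x + yA + yB
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, x / denom, 0.0)
    np.fill_diagonal(A, 1.0)
    return AssociationMatrix(
        ids=ids, matrix=A, counts=pd.Series(counts, index=ids)
    )


def ward_dendrogram(a: AssociationMatrix) -> Dendrogram:
    """Ward linkage on the dissimilarity d = 1 - association index."""
    if len(a.ids) < 2:
        raise ValueError("need at least 2 individuals")
    D = 1.0 - a.matrix
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    return Dendrogram(linkage=Z, ids=list(a.ids))


def find_knot(d: Dendrogram, tol: float = 1e-9) -> float:
    """Height of the most significant knot of the bifurcation curve.

    The cumulative number of bifurcations is plotted against bifurcation
    distance (merge height); the knot is the point of maximum perpendicular
    distance from the chord joining the curve's endpoints — an automated
    stand-in for identifying the bend by eye.  Raises :class:`NoKnotError`
    when the curve is indistinguishable from its chord.
    """
    h = np.sort(d.heights)
    if h.size < 3:
        raise ValueError("need at least 3 merges to locate a knot")
    count = np.arange(1, h.size + 1, dtype=float)
    # normalise both axes so the chord distance is scale-free
    hs = (h - h[0]) / max(h[-1] - h[0], 1e-300)
    cs = (count - count[0]) / (count[-1] - count[0])
    # perpendicular distance from chord (0,0)-(1,1): |hs - cs| / sqrt(2)
    dist = np.abs(hs - cs) / np.sqrt(2.0)
    if dist.max() < tol:
        raise NoKnotError("no knot: curve indistinguishable from its chord")
    return float(h[int(np.argmax(dist))])


def cut_partition(d: Dendrogram, h: float) -> dict[str, int]:
    """Cluster assignment from cutting the dendrogram at height ``h``.

    Clusters are the connected components of merges at height <= h
    (tolerance 1e-9), so cutting exactly at the knot keeps the merges that
    formed it.
    """
    labels = hierarchy.fcluster(d.linkage, t=h + 1e-9, criterion="distance")
    return dict(zip(d.ids, (int(v) for v in labels)))


def _named_clusters(assign: dict[str, int], prefix: str) -> dict[str, str]:
    """Deterministic cluster names ordered by each cluster's smallest member."""
    groups: dict[int, list[str]] = {}
    for i, lab in assign.items():
        groups.setdefault(lab, []).append(i)
    ordered = sorted(groups.values(), key=lambda members: min(members))
    out = {}
    for k, members in enumerate(ordered):
        for i in members:
            out[i] = f"{prefix}{k + 1}"
    return out


def _cluster_level(
    sightings: pd.DataFrame, min_sightings: int, prefix: str
) -> dict[str, str]:
    a = association_matrix(sightings, min_sightings=min_sightings)
    d = ward_dendrogram(a)
    if d.heights.size >= 3:
        try:
            h = find_knot(d)
            assign = cut_partition(d, h)
        except NoKnotError:
            assign = {i: 1 for i in a.ids}
    else:
        # too few merges for a knot: treat all as one cluster
        assign = {i: 1 for i in a.ids}
    return _named_clusters(assign, prefix)


def infer_tiers(
    sightings: pd.DataFrame,
    ages: dict[str, float],
    min_sightings: int = 20,
) -> SocialPartition:
    """Infer core groups, matriarchs and bond groups from sightings.

    Core groups: Ward + knot cut on the full association matrix (after the
    min-sightings filter).  Matriarch = oldest member of each core group,
    lexicographic id as tie-break.  Bond groups: the same clustering
    procedure on the sighting table restricted to matriarchs (no
    min-sightings filter at this level); each bond group is the union of
    its matriarchs' core groups.  With a single core group, or when no
    knot is detectable among matriarchs, all cores fall into one bond
    group.
    """
    core_of = _cluster_level(sightings, min_sightings, "core")

    cores: dict[str, list[str]] = {}
    for i, c in core_of.items():
        cores.setdefault(c, []).append(i)
    matriarchs = {}
    for c, members in cores.items():
        oldest = max(ages.get(m, -np.inf) for m in members)
        matriarchs[c] = min(m for m in members if ages.get(m, -np.inf) == oldest)

    mat_ids = set(matriarchs.values())
    if len(mat_ids) < 2:
        bond_of_core = {c: "bond1" for c in cores}
        return SocialPartition(core_of, bond_of_core, matriarchs)

    restricted = sightings.copy()
    restricted["ids"] = restricted["ids"].map(
        lambda row: tuple(i for i in row if i in mat_ids)
    )
    restricted = restricted[restricted["ids"].map(len) > 0]
    try:
        mat_bond = _cluster_level(restricted, 0, "bond")
    except ValueError:
        mat_bond = {m: "bond1" for m in mat_ids}
    core_of_mat = {m: c for c, m in matriarchs.items()}
    bond_assign = {core_of_mat[m]: b for m, b in mat_bond.items()}
    # rename bonds deterministically by smallest member core
    bonds: dict[str, list[str]] = {}
    for c, b in bond_assign.items():
        bonds.setdefault(b, []).append(c)
    bond_of_core = {}
    for k, members in enumerate(sorted(bonds.values(), key=min)):
        for c in members:
            bond_of_core[c] = f"bond{k + 1}"
    return SocialPartition(core_of, bond_of_core, matriarchs)
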