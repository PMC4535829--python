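"""Hierarchical clustering of fragments under a dissimilarity pseudometric.

Because the spectral score compares fragments of different lengths with no
alignment, a whole bank can be clustered directly from its pairwise score
matrix: complete-linkage agglomeration, a Davies-Bouldin-guided choice of
the number of flat clusters, a classical (Torgerson) MDS embedding for
plotting, and agreement with a reference labeling under the optimal
cluster-to-reference matching.

The Davies-Bouldin index is adapted to a dissimilarity-only setting by
representing each cluster by its MEDOID (the member minimizing the summed
in-cluster score): scatter is the mean score to the medoid and separation
is the medoid-to-medoid score.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

from .fragment import CAlphaFragment
from .retrieval import _resolve_scorer

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "pairwise_matrix",
    "complete_linkage",
    "davies_bouldin",
    "cut_by_db",
    "cluster_agreement",
    "classical_mds",
    "dendrogram_to_newick",
]


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge tree: scipy linkage matrix plus leaf ids."""

    linkage: np.ndarray  # (n-1, 4) scipy format
    leaf_ids: Tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering: fragment id -> cluster index (0-based), k clusters."""

    labels: Dict[str, int]
    k: int
    db_profile: Optional[Dict[int, float]] = None
    local_minimum: bool = True


def _check_square(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        ids = [str(c) for c in matrix.columns]
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(values.shape[0])]
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"score matrix must be square, got {values.shape}")
    if not np.allclose(values, values.T, atol=1e-8, rtol=0):
        raise ValueError("score matrix must be symmetric")
    return values, ids


def pairwise_matrix(
    bank: Sequence[CAlphaFragment],
    scorer="asd",
    cache: Optional[str] = None,
) -> pd.DataFrame:
    """Symmetric all-against-all score matrix, computed once per pair.

    Returned as a labeled DataFrame; ``cache`` (a TSV path) makes repeated
    runs resume from disk when the ids match.
    """
    ids = [f.id for f in bank]
    if len(set(ids)) != len(ids):
        raise ValueError("fragment ids must be unique for a score matrix")
    if cache is not None:
        try:
            df = pd.read_csv(cache, sep="\t", index_col=0, float_precision="round_trip")
            if list(df.columns) == ids and list(df.index) == ids:
                return df
        except FileNotFoundError:
            pass
    fn = _resolve_scorer(scorer)
    n = len(bank)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = fn(bank[i], bank[j])
            except Exception as exc:
                raise ValueError(
                    f"cannot score pair ({ids[i]}, {ids[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = s
    df = pd.DataFrame(values, index=ids, columns=ids)
    if cache is not None:
        df.to_csv(cache, sep="\t")
    return df


def complete_linkage(matrix: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Agglomerative clustering with max-pairwise inter-cluster distance.

    Merge heights are nondecreasing (complete linkage is monotone).
    """
    values, ids = _check_square(matrix)
    z = linkage(squareform(values, checks=False), method="complete")
    return Dendrogram(linkage=z, leaf_ids=tuple(ids))


def _medoid(values: np.ndarray, members: np.ndarray) -> int:
    sub = values[np.ix_(members, members)]
    return int(members[np.argmin(sub.sum(axis=1))])


def davies_bouldin(matrix: pd.DataFrame | np.ndarray,
                   assignment: ClusterAssignment) -> float:
    """Medoid-based Davies-Bouldin index from a dissimilarity matrix alone.

    ``DB = (1/k) sum_c max_{d != c} (S_c + S_d) / M_{cd}`` with S the mean
    score to the cluster medoid and M the medoid-to-medoid score.  Lower is
    better; zero for well-separated zero-diameter clusters.
    """
    values, ids = _check_square(matrix)
    label_arr = np.array([assignment.labels[i] for i in ids])
    clusters = np.unique(label_arr)
    if clusters.size < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    if all(np.sum(label_arr == c) == 1 for c in clusters):
        warnings.warn("all clusters are singletons; DB index is 0 by convention",
                      stacklevel=2)
    medoids, scatter = [], []
    for c in clusters:
        members = np.nonzero(label_arr == c)[0]
        m = _medoid(values, members)
        medoids.append(m)
        scatter.append(float(values[members, m].mean()))
    db = 0.0
    for a in range(clusters.size):
        ratios = []
        for b in range(clusters.size):
            if a == b:
                continue
            sep = values[medoids[a], medoids[b]]
            if sep == 0.0:
                ratios.append(np.inf if scatter[a] + scatter[b] > 0 else 0.0)
            else:
                ratios.append((scatter[a] + scatter[b]) / sep)
        db += max(ratios)
    return db / clusters.size


def _cut(dendrogram: Dendrogram, k: int) -> ClusterAssignment:
    flat = fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    labels = {fid: int(c - 1) for fid, c in zip(dendrogram.leaf_ids, flat)}
    return ClusterAssignment(labels=labels, k=len(set(flat)))


def cut_by_db(
    dendrogram: Dendrogram,
    matrix: pd.DataFrame | np.ndarray,
    k_range: Sequence[int],
) -> ClusterAssignment:
    """Cut the dendrogram at the first local minimum of the DB-vs-k profile.

    Endpoints of the profile count as local minima when the profile rises
    away from them; with ties everywhere (no strict minimum) the global
    minimum is used, flagged.  The full profile is attached to the result.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = len(dendrogram.leaf_ids)
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    profile: Dict[int, float] = {}
    cuts: Dict[int, ClusterAssignment] = {}
    for k in ks:
        cut = _cut(dendrogram, k)
        cuts[k] = cut
        profile[k] = davies_bouldin(matrix, cut) if cut.k >= 2 else np.inf
    dbs = [profile[k] for k in ks]
    chosen, local = None, True
    for i in range(len(ks)):
        below_prev = i == 0 or dbs[i] < dbs[i - 1]
        below_next = i == len(ks) - 1 or dbs[i] < dbs[i + 1]
        if below_prev and below_next:
            chosen = ks[i]
            break
    if chosen is None:
        chosen = ks[int(np.argmin(dbs))]
        local = False
        warnings.warn("no interior local minimum in the DB profile; "
                      "using the global minimum", stacklevel=2)
    best = cuts[chosen]
    return ClusterAssignment(best.labels, best.k, db_profile=profile,
                             local_minimum=local)


def cluster_agreement(assignment: ClusterAssignment,
                      reference: ClusterAssignment) -> float:
    """Fraction of shared items on which the clusterings agree, after the
    optimal one-to-one cluster-to-reference matching (Hungarian assignment).
    """
    common = sorted(set(assignment.labels) & set(reference.labels))
    if not common:
        raise ValueError("assignments share no fragment ids")
    a = np.array([assignment.labels[i] for i in common])
    b = np.array([reference.labels[i] for i in common])
    ua, ub = np.unique(a), np.unique(b)
    contingency = np.zeros((ua.size, ub.size), dtype=int)
    for x, y in zip(np.searchsorted(ua, a), np.searchsorted(ub, b)):
        contingency[x, y] += 1
    rows, cols = linear_sum_assignment(contingency, maximize=True)
    return float(contingency[rows, cols].sum() / len(common))


def classical_mds(matrix: pd.DataFrame | np.ndarray, dims: int = 2) -> pd.DataFrame:
    """Torgerson double-centering embedding of a dissimilarity matrix.

    Warns when more than half of the eigenvalue mass is negative (strongly
    non-Euclidean input); intended for visualization, not inference.
    """
    values, ids = _check_square(matrix)
    n = values.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (values**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg_mass = float(np.abs(eigval[eigval < 0]).sum())
    total_mass = float(np.abs(eigval).sum())
    if total_mass > 0 and neg_mass / total_mass > 0.5:
        warnings.warn(
            f"negative eigenvalue mass is {neg_mass / total_mass:.0%}; "
            "the dissimilarity is strongly non-Euclidean", stacklevel=2)
    lead = eigval[:dims].copy()
    lead[lead < 1e-12 * max(abs(eigval[0]), 1.0)] = 0.0  # numeric zeros
    coords = eigvec[:, :dims] * np.sqrt(np.clip(lead, 0.0, None))
    return pd.DataFrame(coords, index=ids,
                        columns=[f"mds{d + 1}" for d in range(dims)])


def dendrogram_to_newick(dendrogram: Dendrogram) -> str:
    """Newick serialization with branch lengths = merge-height differences."""
    tree = to_tree(dendrogram.linkage)
    ids = dendrogram.leaf_ids

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return rec(tree, tree.dist) + ";"
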