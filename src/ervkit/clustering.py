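"""Hierarchical clustering of per-cell-type association profiles.

Rows are cell types, columns a shared window grid, values F scores in
[0, 1].  Rows are clustered agglomeratively under Euclidean distance and
the cut at k (default 3) is reported with clusters ordered by descending
mean F ("high", "medium", "low").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from ervkit.association import AssociationProfile

LINKAGE_METHODS = ("average", "complete", "single")


@dataclass
class ProfileMatrix:
    cell_types: List[str]
    windows: np.ndarray
    values: np.ndarray  # shape (n_cell_types, n_windows)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_types), len(self.windows)):
            raise ValueError("profile matrix is not rectangular")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("F scores must lie in [0, 1]")

    @classmethod
    def from_tsv(cls, path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        windows = np.array([int(c) for c in df.columns])
        return cls(list(df.index), windows, df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.cell_types,
                     columns=[str(w) for w in self.windows]).to_csv(path, sep="\t")


@dataclass
class ClusterAssignment:
    labels: Dict[str, int]           # cell type -> cluster id (0 = highest mean F)
    k: int
    mean_f: Dict[int, float]         # cluster id -> mean F over members x windows
    merge_tree: np.ndarray           # scipy linkage matrix

    def members(self, cluster_id: int) -> List[str]:
        return [ct for ct, c in self.labels.items() if c == cluster_id]


def build_profile_matrix(profiles: Sequence[AssociationProfile]) -> ProfileMatrix:
    """Stack profiles sharing one window grid into a matrix (one row each)."""
    if not profiles:
        raise ValueError("no profiles")
    ref = profiles[0].windows
    bad = [p.cell_type for p in profiles
           if len(p.windows) != len(ref) or not np.array_equal(p.windows, ref)]
    if bad:
        raise ValueError(f"profiles on a different window grid: {bad}")
    return ProfileMatrix(
        cell_types=[p.cell_type for p in profiles],
        windows=ref.copy(),
        values=np.vstack([p.f_scores for p in profiles]),
    )


def hierarchical_cluster(matrix: ProfileMatrix,
                         method: str = "average") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage matrix) under Euclidean
    row distance."""
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage {method!r}; choose from {LINKAGE_METHODS}")
    if matrix.values.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    return scipy_linkage(matrix.values, method=method, metric="euclidean")


def cut_clusters(tree: np.ndarray, k: int,
                 matrix: ProfileMatrix) -> ClusterAssignment:
    """Cut the merge tree into k groups; ids are relabelled so cluster 0 has
    the highest mean F."""
    n = matrix.values.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    raw = fcluster(tree, t=k, criterion="maxclust")
    return _assignment_from_raw(raw, matrix, tree)


def cut_clusters_by_height(tree: np.ndarray, height: float,
                           matrix: ProfileMatrix) -> ClusterAssignment:
    raw = fcluster(tree, t=height, criterion="distance")
    return _assignment_from_raw(raw, matrix, tree)


def _assignment_from_raw(raw: np.ndarray, matrix: ProfileMatrix,
                         tree: np.ndarray) -> ClusterAssignment:
    raw_ids = sorted(set(int(c) for c in raw))
    means = {
        rid: float(matrix.values[raw == rid].mean()) for rid in raw_ids
    }
    # descending mean F -> 0, 1, 2, ...
    order = sorted(raw_ids, key=lambda rid: -means[rid])
    remap = {rid: new for new, rid in enumerate(order)}
    labels = {ct: remap[int(c)] for ct, c in zip(matrix.cell_types, raw)}
    mean_f = {remap[rid]: means[rid] for rid in raw_ids}
    return ClusterAssignment(labels=labels, k=len(raw_ids),
                             mean_f=mean_f, merge_tree=tree)


def assignment_to_frame(assignment: ClusterAssignment,
                        names: Optional[Sequence[str]] = None) -> pd.DataFrame:
    rows = [
        {"cell_type": ct, "cluster": cid,
         "cluster_mean_f": assignment.mean_f[cid]}
        for ct, cid in assignment.labels.items()
    ]
    return pd.DataFrame(rows)
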