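"""Cluster structure of the association network.

A hierarchical dendrogram is built on the dissimilarity d = 1 − HWI.  Two
diagnostics decide whether the tree is worth interpreting:

* the cophenetic correlation coefficient (CCC) between dyadic association
  indices and the level at which dyads join in the tree — CCC > 0.8 means
  the dendrogram is a fair representation of the matrix;
* Newman's weighted modularity Q of the best horizontal cut — Q = 0 means
  random structure, Q > 0.3 is taken as meaningful community structure.

Also provided: a two-tailed Mantel test contrasting within- versus
between-cluster association rates, and the minimum-sightings threshold scan
used to decide how many resights an individual needs before it can be placed
reliably in the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .association import association_matrix, AssociationMatrix
from .sightings import SamplingPeriods, build_sampling_periods

__all__ = [
    "ClusterSolution",
    "cluster_hwi",
    "cophenetic_correlation",
    "modularity",
    "best_partition_by_modularity",
    "mean_hwi_cut_partition",
    "mantel_within_between",
    "threshold_scan",
]


@dataclass
class ClusterSolution:
    """Dendrogram plus the modularity-selected flat partition."""

    ids: list[str]
    method: str                    # "average" or "ward"
    linkage: np.ndarray            # scipy linkage matrix, distance scale (1 - HWI)
    hwi: np.ndarray
    partition: np.ndarray | None = None
    q: float | None = None
    ccc: float | None = None

    @property
    def n_clusters(self) -> int | None:
        return None if self.partition is None else int(len(np.unique(self.partition)))

    def merge_heights_association_scale(self) -> np.ndarray:
        """Heights of successive merges reported as association indices."""
        return 1.0 - self.linkage[:, 2]

    def partition_frame(self) -> pd.DataFrame:
        if self.partition is None:
            raise ValueError("no partition selected yet")
        return pd.DataFrame({"individual_id": self.ids, "cluster": self.partition})

    def to_newick(self) -> str:
        """Merge tree as a Newick string; branch lengths on the distance
        scale (1 − HWI), so leaves sit at depth equal to the root height."""
        n = len(self.ids)
        heights = {i: 0.0 for i in range(n)}
        labels = {i: self.ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = f"{labels[a]}:{h - heights[a]:.6g}"
            lb = f"{labels[b]}:{h - heights[b]:.6g}"
            labels[n + k] = f"({la},{lb})"
            heights[n + k] = float(h)
        return labels[2 * n - 2] + ";"


def cluster_hwi(matrix: AssociationMatrix, method: str = "average") -> ClusterSolution:
    """Agglomerative tree on d = 1 − HWI.

    ``method`` is ``"average"`` (UPGMA, the customary choice for association
    matrices) or ``"ward"``.  Heights live on the distance scale internally
    and are mapped back to the association scale for reporting.
    """
    if method not in ("average", "ward"):
        raise ValueError(f"unsupported linkage method {method!r}")
    if matrix.n < 2:
        raise ValueError("clustering requires at least two individuals")
    dist = 1.0 - matrix.hwi
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return ClusterSolution(ids=list(matrix.ids), method=method, linkage=z, hwi=matrix.hwi)


def cophenetic_correlation(solution: ClusterSolution, matrix: AssociationMatrix) -> float:
    """Pearson correlation between dyadic HWI and dendrogram joining levels.

    Computed on the distance scale (1 − HWI versus cophenetic distance),
    which equals the correlation on the association scale.
    """
    if list(solution.ids) != list(matrix.ids):
        raise ValueError("solution and matrix refer to different individuals")
    n = matrix.n
    if n * (n - 1) // 2 < 3:
        raise ValueError("cophenetic correlation needs at least 3 dyads")
    dist = squareform(1.0 - matrix.hwi, checks=False)
    ccc, _ = hierarchy.cophenet(solution.linkage, dist)
    return float(ccc)


def modularity(hwi: np.ndarray, labels: np.ndarray) -> float:
    """Newman's weighted modularity of a partition of the HWI network.

    Q = Σ_c (e_cc − a_c²) where e_cc is the fraction of total edge weight
    inside cluster c and a_c the fraction of weighted degree attached to c.
    A single all-inclusive cluster scores exactly 0; two equal disconnected
    cliques cut apart score 0.5.
    """
    w = np.asarray(hwi, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    total = w.sum()  # = 2m for an undirected network
    if total <= 0:
        return 0.0
    labels = np.asarray(labels)
    q = 0.0
    degrees = w.sum(axis=1)
    for c in np.unique(labels):
        mask = labels == c
        e_cc = w[np.ix_(mask, mask)].sum() / total
        a_c = degrees[mask].sum() / total
        q += e_cc - a_c * a_c
    return float(q)


def _tree_cut_partitions(z: np.ndarray, n: int) -> np.ndarray:
    """All flat partitions obtainable by horizontal cuts (n levels, n labels)."""
    return hierarchy.cut_tree(z)  # (n, n): column k has n - k clusters


def best_partition_by_modularity(
    solution: ClusterSolution,
) -> ClusterSolution:
    """Select, among every horizontal cut of the tree, the partition with
    maximal weighted modularity; ties resolved toward fewer clusters.

    Returns a new ClusterSolution with ``partition`` and ``q`` filled in.
    """
    n = len(solution.ids)
    cuts = _tree_cut_partitions(solution.linkage, n)
    best_q, best_labels, best_k = -np.inf, None, None
    # iterate from coarse (1 cluster) to fine so ties keep the coarser cut
    for col in range(n - 1, -1, -1):
        labels = cuts[:, col]
        k = len(np.unique(labels))
        q = modularity(solution.hwi, labels)
        if q > best_q + 1e-12:
            best_q, best_labels, best_k = q, labels, k
    return ClusterSolution(
        ids=solution.ids,
        method=solution.method,
        linkage=solution.linkage,
        hwi=solution.hwi,
        partition=np.asarray(best_labels),
        q=float(best_q),
        ccc=solution.ccc,
    )


def mean_hwi_cut_partition(solution: ClusterSolution) -> np.ndarray:
    """Flat partition from cutting the dendrogram at the overall mean HWI.

    The cutpoint is the mean dyadic association index mapped onto the
    distance scale (1 − mean HWI); clusters are the subtrees joined more
    tightly than the population average.
    """
    n = len(solution.ids)
    mean_hwi = float(solution.hwi[np.triu_indices(n, k=1)].mean())
    return hierarchy.fcluster(solution.linkage, t=1.0 - mean_hwi, criterion="distance")


def mantel_within_between(
    matrix: AssociationMatrix,
    partition: np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Two-tailed Mantel test: are association rates equal within and
    between clusters?

    The test correlates the HWI matrix with a same-cluster indicator matrix,
    permuting individual labels.  Returns the Mantel correlation ``r``, a
    permutation z-score ``t`` (observed minus null mean, over null SD), the
    two-tailed permutation ``p``, and the within/between means and SDs.
    """
    labels = np.asarray(partition)
    if len(np.unique(labels)) < 2:
        raise ValueError("Mantel test needs at least two clusters")
    n = matrix.n
    if len(labels) != n:
        raise ValueError("partition length does not match matrix")
    iu = np.triu_indices(n, k=1)
    hwi_vals = matrix.hwi[iu]
    rng = np.random.default_rng(seed)

    def stat(lab):
        same = (lab[iu[0]] == lab[iu[1]]).astype(float)
        if same.std() == 0:
            return 0.0
        return float(np.corrcoef(hwi_vals, same)[0, 1])

    r_obs = stat(labels)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = stat(rng.permutation(labels))
    p = (1 + int((np.abs(null) >= abs(r_obs)).sum())) / (n_permutations + 1)
    sd = null.std(ddof=1)
    t = (r_obs - null.mean()) / sd if sd > 0 else np.inf if r_obs > 0 else 0.0
    same_mask = labels[iu[0]] == labels[iu[1]]
    within = hwi_vals[same_mask]
    between = hwi_vals[~same_mask]
    return {
        "r": r_obs,
        "t": float(t),
        "p": float(p),
        "n_permutations": n_permutations,
        "within_mean": float(within.mean()) if within.size else np.nan,
        "within_sd": float(within.std(ddof=1)) if within.size > 1 else 0.0,
        "between_mean": float(between.mean()) if between.size else np.nan,
        "between_sd": float(between.std(ddof=1)) if between.size > 1 else 0.0,
    }


def threshold_scan(
    df: pd.DataFrame,
    k_range,
    method: str = "average",
) -> pd.DataFrame:
    """Sensitivity of the network to the minimum-sightings inclusion rule.

    For each k in ``k_range``: keep individuals identified in ≥ k sampling
    periods, rebuild the HWI matrix, cluster, and report the number of
    individuals, records, modularity-selected cluster count, Q and CCC —
    the machinery behind choosing a resighting threshold (e.g. requiring
    CCC > 0.8 before interpreting clusters).
    """
    rows = []
    all_periods = build_sampling_periods(df)
    counts = dict(zip(all_periods.ids, all_periods.sightings_per_individual()))
    for k in k_range:
        keep = [i for i, c in counts.items() if c >= k]
        n_records = int(df["individual_id"].isin(keep).sum())
        if len(keep) < 2:
            warnings.warn(f"min_sightings={k}: fewer than 2 individuals remain")
            rows.append(
                {"min_sightings": k, "n_individuals": len(keep), "n_records": n_records,
                 "n_clusters": 0, "Q": np.nan, "CCC": np.nan}
            )
            continue
        sub = build_sampling_periods(df[df["individual_id"].isin(keep)])
        matrix = association_matrix(sub)
        tree = cluster_hwi(matrix, method=method)
        best = best_partition_by_modularity(tree)
        try:
            ccc = cophenetic_correlation(tree, matrix)
        except ValueError:
            ccc = np.nan
        rows.append(
            {
                "min_sightings": k,
                "n_individuals": len(keep),
                "n_records": n_records,
                "n_clusters": best.n_clusters,
                "Q": best.q,
                "CCC": ccc,
            }
        )
    return pd.DataFrame(rows)
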