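"""Canberra-based comparison and clustering of approach rank lists.

The Canberra distance between two rankings sums |rank difference| / (rank
sum) over SNPs, so disagreements near the top of the lists weigh more than
disagreements in the noise tail. Its top-k variant truncates both rankings
at a location parameter k+1 before applying the same formula, restricting
the comparison to top-k behavior. Approaches are clustered from these
distances by average-linkage (UPGMA) hierarchical clustering; clusterings
are compared via the cophenetic correlation of their ultrametrics, and a
consensus clustering is built from the average of the input ultrametrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def _as_rank_series(r) -> pd.Series:
    s = pd.Series(r) if not isinstance(r, pd.Series) else r
    n = len(s)
    if sorted(s.to_numpy()) != list(range(1, n + 1)):
        raise ValueError("ranking must be a bijection onto 1..N")
    return s


def _check_universe(sigma: pd.Series, tau: pd.Series) -> None:
    a, b = set(sigma.index), set(tau.index)
    if a != b:
        diff = sorted(a.symmetric_difference(b))
        raise ValueError(f"rankings cover different SNP universes: {diff}")


def canberra(sigma, tau) -> float:
    """Canberra distance between two full rankings of the same SNPs."""
    sigma = _as_rank_series(sigma)
    tau = _as_rank_series(tau)
    _check_universe(sigma, tau)
    t = tau.loc[sigma.index].to_numpy(dtype=float)
    s = sigma.to_numpy(dtype=float)
    return float(np.sum(np.abs(t - s) / (t + s)))


def canberra_topk(sigma, tau, k: int) -> float:
    """Canberra distance with location parameter k+1 (top-k comparison).

    Ranks above k are replaced by k+1 in both rankings before applying the
    Canberra formula; at k = N this reduces to the full Canberra distance.
    """
    sigma = _as_rank_series(sigma)
    tau = _as_rank_series(tau)
    _check_universe(sigma, tau)
    n = len(sigma)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    t = np.minimum(tau.loc[sigma.index].to_numpy(dtype=float), k + 1)
    s = np.minimum(sigma.to_numpy(dtype=float), k + 1)
    return float(np.sum(np.abs(t - s) / (t + s)))


@dataclass
class DistanceMatrix:
    """Symmetric approach-by-approach distance matrix at one location k."""

    matrix: pd.DataFrame
    k: int | str  # the location parameter, or "full"

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy(dtype=float)
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if not np.isfinite(m).all():
            raise ValueError("distance matrix entries must be finite")

    @property
    def names(self) -> list[str]:
        return list(self.matrix.index)

    def write_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="approach")

    @classmethod
    def read_tsv(cls, path: str | Path, k: int | str = "full") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df, k)


def pairwise_distance_matrices(
    rankings: dict[str, pd.Series], k_values: list[int]
) -> dict[int | str, DistanceMatrix]:
    """All pairwise Canberra distances, one matrix per k plus the full Ca.

    k values exceeding the SNP universe size N are clamped to the full
    Canberra distance with a warning (they are equivalent at k >= N).
    """
    names = list(rankings)
    if len(names) < 2:
        raise ValueError("need at least 2 rankings")
    n = len(next(iter(rankings.values())))
    out: dict[int | str, DistanceMatrix] = {}
    ks: list[tuple[int | str, int | None]] = []
    for k in k_values:
        if k >= n:
            warnings.warn(f"k={k} >= N={n}: clamped to the full Canberra distance")
            ks.append((k, None))
        else:
            ks.append((k, k))
    ks.append(("full", None))
    for label, k in ks:
        m = np.zeros((len(names), len(names)))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = rankings[names[i]], rankings[names[j]]
                d = canberra(a, b) if k is None else canberra_topk(a, b, k)
                m[i, j] = m[j, i] = d
        out[label] = DistanceMatrix(pd.DataFrame(m, index=names, columns=names),
                                    label)
    return out


@dataclass
class Dendrogram:
    """Average-linkage hierarchical clustering of approaches.

    Wraps a scipy linkage matrix together with leaf names; the derived
    ultrametric (cophenetic) distance for a leaf pair is the height at
    which the pair is first merged.
    """

    linkage: np.ndarray
    leaves: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def ultrametric(self) -> pd.DataFrame:
        condensed = hierarchy.cophenet(self.linkage)
        m = squareform(condensed)
        return pd.DataFrame(m, index=self.leaves, columns=self.leaves)

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences, so each
        leaf's root distance equals its last merge height."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.leaves[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        inner = rec(tree, tree.dist)
        # root has no branch above it
        return inner.rsplit(":", 1)[0] + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def hclust_average(dist: DistanceMatrix) -> Dendrogram:
    """UPGMA (average-linkage) agglomeration of a distance matrix."""
    m = dist.matrix.to_numpy(dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.isfinite(m).all():
        raise ValueError("distance matrix contains NaN")
    z = hierarchy.linkage(squareform(m, checks=False), method="average")
    return Dendrogram(z, dist.names)


def cophenetic_correlation(dend_a: Dendrogram, dend_b: Dendrogram) -> float:
    """Pearson correlation of two dendrograms' ultrametric distances.

    Computed over all unordered leaf pairs; raises on a constant
    ultrametric (correlation undefined).
    """
    if set(dend_a.leaves) != set(dend_b.leaves):
        raise ValueError("dendrograms have different leaf sets")
    ua = dend_a.ultrametric()
    ub = dend_b.ultrametric().loc[ua.index, ua.columns]
    iu = np.triu_indices(len(ua), k=1)
    va = ua.to_numpy()[iu]
    vb = ub.to_numpy()[iu]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant ultrametric: cophenetic correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def consensus_clustering(dendrograms: list[Dendrogram]) -> Dendrogram:
    """Least-squares consensus of several clusterings of the same leaves.

    The input ultrametric matrices are averaged elementwise (the
    closed-form least-squares aggregate) and the average is re-clustered
    with UPGMA, yielding the consensus ultrametric within the
    UPGMA-reachable family. Averaging makes the result independent of the
    input order.
    """
    if len(dendrograms) < 2:
        raise ValueError("need at least 2 dendrograms")
    leaves = sorted(dendrograms[0].leaves)
    for d in dendrograms[1:]:
        if sorted(d.leaves) != leaves:
            raise ValueError("dendrograms have different leaf sets")
    acc = np.zeros((len(leaves), len(leaves)))
    for d in dendrograms:
        acc += d.ultrametric().loc[leaves, leaves].to_numpy()
    avg = acc / len(dendrograms)
    dm = DistanceMatrix(pd.DataFrame(avg, index=leaves, columns=leaves), "consensus")
    return hclust_average(dm)


def cut_tree(dend: Dendrogram, n_clusters: int) -> pd.Series:
    """Cluster labels from cutting the dendrogram into n_clusters groups.

    Cuts by merge order (undoing the last n_clusters - 1 merges), so tied
    merge heights are broken by merge order and the requested count is
    attained whenever possible; otherwise the nearest attainable count is
    returned with a warning.
    """
    n_leaves = len(dend.leaves)
    if not 1 <= n_clusters <= n_leaves:
        raise ValueError(f"n_clusters must be in 1..{n_leaves}")
    labels = hierarchy.cut_tree(dend.linkage, n_clusters=n_clusters)[:, 0] + 1
    got = len(np.unique(labels))
    if got != n_clusters:
        warnings.warn(
            f"tied merge heights: {got} clusters returned instead of {n_clusters}"
        )
    return pd.Series(labels, index=dend.leaves, name="cluster")


def select_representatives(
    labels: pd.Series,
    dist: DistanceMatrix,
    overrides: dict[int, str] | None = None,
) -> dict[int, str]:
    """One representative approach per cluster: the within-cluster medoid.

    The medoid minimizes the summed distance to the other cluster members
    (ties broken by approach name). ``overrides`` maps cluster label to an
    approach name chosen manually and is respected verbatim.
    """
    missing = set(labels.index) - set(dist.names)
    if missing:
        raise ValueError(f"labels cover approaches absent from matrix: {missing}")
    overrides = overrides or {}
    out: dict[int, str] = {}
    for cluster in sorted(labels.unique()):
        members = sorted(labels.index[labels == cluster])
        if cluster in overrides:
            if overrides[cluster] not in members:
                raise ValueError(
                    f"override {overrides[cluster]!r} not in cluster {cluster}"
                )
            out[cluster] = overrides[cluster]
            continue
        sub = dist.matrix.loc[members, members]
        sums = sub.sum(axis=1)
        out[cluster] = sorted(sums.index[sums == sums.min()])[0]
    return out


def normalize_for_heatmap(dist: DistanceMatrix) -> pd.DataFrame:
    """Divide by the maximum off-diagonal dissimilarity (range becomes [0, 1])."""
    m = dist.matrix.to_numpy(dtype=float).copy()
    off = m[~np.eye(m.shape[0], dtype=bool)]
    mx = off.max() if off.size else 0.0
    if mx <= 0:
        raise ValueError("all-zero distance matrix cannot be normalized")
    return pd.DataFrame(m / mx, index=dist.names, columns=dist.names)
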