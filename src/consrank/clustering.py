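"""Contact-fingerprint clustering of docking models.

Models are clustered on the Hamming distances between their contact maps
(number of differing contacts), with complete linkage: the distance between
two clusters u and v is

    d(u, v) = max over i in u, j in v of dist(u[i], v[j]),

the farthest-point criterion.  Flat clusters are extracted with the
maxclust rule — the smallest dendrogram cut producing at most t clusters —
with t defaulting to one tenth of the ensemble size, so the procedure is
independent of how many models were submitted.  Clusters are then ranked
by population and numbered consecutively from 0; consensus scoring is
re-run inside each of the most populated clusters with the cluster's own
size as the ensemble size, which diversifies the selection when the global
consensus is weak.

The agglomeration is implemented here (Lance-Williams max-update) rather
than delegated, because reproducible cluster sets on integer Hamming
distances require a defined tie rule: equal merge heights are resolved in
favor of the pair whose clusters contain the smallest original indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import squareform

from .contacts import ContactMap
from .scoring import RankEntry, Ranking, conservation_rates, rank_models

__all__ = [
    "DistanceVector",
    "ClusterSet",
    "distance_vector",
    "complete_linkage",
    "flat_clusters_maxclust",
    "default_t",
    "per_cluster_rankings",
]


@dataclass(frozen=True)
class DistanceVector:
    """Condensed pairwise Hamming distances (upper triangle, row-major)."""

    n: int
    d: np.ndarray

    def __post_init__(self) -> None:
        if len(self.d) != self.n * (self.n - 1) // 2:
            raise ValueError("condensed vector length must be n(n-1)/2")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")

    def pair(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        i, j = min(i, j), max(i, j)
        k = i * self.n - i * (i + 1) // 2 + (j - i - 1)
        return float(self.d[k])


@dataclass(frozen=True)
class ClusterSet:
    """Flat clusters, ranked by population and numbered from 0."""

    t: int
    labels: Mapping[str, int]          # model_id -> cluster number
    clusters: tuple[tuple[str, ...], ...]  # cluster number -> member ids

    @property
    def populations(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def to_tsv(self) -> str:
        lines = ["model_id\tcluster\tpopulation"]
        for ci, members in enumerate(self.clusters):
            for mid in members:
                lines.append(f"{mid}\t{ci}\t{len(members)}")
        return "\n".join(lines) + "\n"


def distance_vector(maps: Sequence[ContactMap]) -> DistanceVector:
    """All pairwise Hamming distances in condensed form.

    Computed through the binary contact-incidence matrix:
    d(i, j) = M_i + M_j - 2 |maps_i ∩ maps_j|, evaluated as a Gram matrix
    product.  Equivalent to calling :func:`hamming_distance` on every pair.
    """
    n = len(maps)
    if n < 2:
        raise ValueError("need at least 2 maps")
    universe = {c for m in maps for c in m.contacts}
    index = {c: k for k, c in enumerate(sorted(universe))}
    X = np.zeros((n, len(index)), dtype=np.int64)
    for i, m in enumerate(maps):
        for c in m.contacts:
            X[i, index[c]] = 1
    sizes = X.sum(axis=1)
    inter = X @ X.T
    D = sizes[:, None] + sizes[None, :] - 2 * inter
    np.fill_diagonal(D, 0)
    return DistanceVector(n=n, d=squareform(D, checks=False))


def complete_linkage(dv: DistanceVector) -> np.ndarray:
    """Agglomerative complete-linkage merge tree.

    Returns a linkage matrix in the standard (n-1, 4) format: the two
    cluster ids merged at each step (originals 0..n-1, merged n, n+1, ...),
    the merge height (maximum member-pair distance), and the new cluster
    size.  Equal-height candidate merges are resolved by the smallest
    original member index contained in the two clusters.
    """
    n = dv.n
    D = squareform(dv.d.astype(float), checks=False)
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    cid = np.arange(n)          # current cluster id sitting in each slot
    rep = np.arange(n)          # smallest original member index per slot
    size = np.ones(n, dtype=int)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        sub = D[np.ix_(active, active)]
        h = sub.min()
        slots = np.flatnonzero(active)
        ii, jj = np.where(sub == h)
        keep = ii < jj
        A, B = slots[ii[keep]], slots[jj[keep]]
        # candidate slot pairs at the minimal height; deterministic tie rule
        lo_rep = np.minimum(rep[A], rep[B])
        hi_rep = np.maximum(rep[A], rep[B])
        k = np.lexsort((hi_rep, lo_rep))[0]
        a, b = A[k], B[k]
        i, j = (a, b) if rep[a] <= rep[b] else (b, a)
        lo, hi = sorted((cid[i], cid[j]))
        Z[step] = (lo, hi, h, size[i] + size[j])
        # Lance-Williams update for complete linkage: max of the two rows
        merged = np.maximum(D[i], D[j])
        D[i] = merged
        D[:, i] = merged
        D[i, i] = np.inf
        active[j] = False
        cid[i] = n + step
        rep[i] = min(rep[i], rep[j])
        size[i] += size[j]
    return Z


def default_t(n: int) -> int:
    """Maximum flat-cluster count: one tenth of the ensemble, at least 1."""
    if n < 2:
        raise ValueError("need at least 2 models")
    return max(1, n // 10)


def flat_clusters_maxclust(
    Z: np.ndarray, t: int, model_ids: Sequence[str]
) -> ClusterSet:
    """Cut the merge tree at the smallest height giving at most t clusters.

    The resulting clusters are ranked by population (ties: smallest
    contained model index) and numbered consecutively starting from 0.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    n = len(model_ids)
    if n != Z.shape[0] + 1:
        raise ValueError("model_ids length does not match the merge tree")
    raw = fcluster(Z, t=t, criterion="maxclust")
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(raw):
        groups.setdefault(int(lab), []).append(idx)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    labels: dict[str, int] = {}
    clusters = []
    for ci, members in enumerate(ordered):
        clusters.append(tuple(model_ids[k] for k in members))
        for k in members:
            labels[model_ids[k]] = ci
    return ClusterSet(t=t, labels=labels, clusters=tuple(clusters))


def per_cluster_rankings(
    clusterset: ClusterSet,
    maps: Sequence[ContactMap],
    top_clusters: int = 15,
) -> dict[int, Ranking]:
    """Cluster-local consensus rankings for the most populated clusters.

    Conservation rates are recomputed inside each cluster with the
    cluster's own size as n.  A singleton cluster yields the degenerate
    one-entry ranking with S_norm = 1 (every contact trivially conserved).
    """
    by_id = {m.model_id: m for m in maps}
    out: dict[int, Ranking] = {}
    for ci in range(min(top_clusters, clusterset.n_clusters)):
        members = [by_id[mid] for mid in clusterset.clusters[ci]]
        if len(members) == 1:
            m = members[0]
            entry = RankEntry(model_id=m.model_id, S=float(m.M), M=m.M, S_norm=1.0, rank=1)
            out[ci] = Ranking(entries=(entry,))
        else:
            rates = conservation_rates(members)
            out[ci] = rank_models(members, rates)
    return out
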