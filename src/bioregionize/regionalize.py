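"""Delimit biogeographic regions from a turnover matrix.

The procedure: build Ward dendrograms over many randomized orderings of the
cells, cut each tree at k = 2..K_max, score every partition by explained
dissimilarity and mean silhouette width, pick the cluster count by a
dual-criterion rule (first k whose explained dissimilarity reaches a threshold,
then advance while the silhouette still improves), and condense the replicate
partitions at the chosen k into one consensus region map via co-classification
frequencies.

Why randomized orderings: turnover indices on gridded assemblages produce many
tied and zero dissimilarities, so the agglomeration order — and hence the tree
topology — depends on the input order of the cells.  Replicating the clustering
over random orders and aggregating turns that artifact into a measurable source
of uncertainty instead of a silent one.

The Ward implementation is deliberately hand-rolled: the tie-break (smallest
pair indices in the supplied ordering) is the mechanism the randomization
exploits, and library linkage routines neither expose it nor implement the
raw-dissimilarity ("ward.D") variant used here by default.  The squared-input
variant ("ward.D2", the scipy/Euclidean convention) is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .turnover import TurnoverMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Ward linkage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dendrogram:
    """Merge tree over cells as produced by :func:`ward_linkage`.

    merge_sequence: (n_leaves − 1, 4) array of rows (node_a, node_b, height,
    new_size).  Leaves are numbered 0..n−1 *in the permuted order*; internal
    nodes continue from n.  Heights are recorded exactly as produced by the
    Lance–Williams update — monotonicity is not assumed (raw-dissimilarity
    Ward can invert).
    leaf_order: the permutation used — leaf_order[p] is the original cell
    index sitting at permuted position p.
    """

    merge_sequence: np.ndarray
    leaf_order: np.ndarray
    cell_ids: tuple[str, ...] = field(default=())

    @property
    def n_leaves(self) -> int:
        return self.merge_sequence.shape[0] + 1


def ward_linkage(
    d: TurnoverMatrix | np.ndarray,
    order: np.ndarray | None = None,
    variant: str = "ward.D",
    cell_ids: tuple[str, ...] | None = None,
) -> Dendrogram:
    """Agglomerative Ward clustering with deterministic order-based tie-breaks.

    At each step the minimum-height active pair is merged and the merged
    cluster's dissimilarity to every other cluster w follows the
    Lance–Williams update

        d(uv, w) = ((n_u + n_w) d(u, w) + (n_v + n_w) d(v, w) − n_w d(u, v))
                   / (n_u + n_v + n_w).

    ``variant="ward.D"`` applies the update to the dissimilarities as given;
    ``"ward.D2"`` applies it to squared dissimilarities and reports square-root
    heights (the Euclidean-geometry convention).  Ties are broken toward the
    smallest pair indices in the supplied ``order``: clusters are kept sorted
    by their minimal leaf position under the permutation, and the first
    minimal entry in row-major upper-triangle order wins.  Different orders
    can therefore yield different trees on tied input — exactly the effect the
    randomized-reorder consensus measures.
    """
    if isinstance(d, TurnoverMatrix):
        mat = d.d
        cell_ids = d.cell_ids if cell_ids is None else cell_ids
    else:
        mat = np.asarray(d, dtype=float)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("ward_linkage needs at least 2 cells")
    if order is None:
        order = np.arange(n)
    order = np.asarray(order)
    if sorted(order.tolist()) != list(range(n)):
        raise ValueError("order must be a permutation of all cells")
    if variant not in ("ward.D", "ward.D2"):
        raise ValueError(f"unknown ward variant {variant!r}")

    cur = mat[np.ix_(order, order)].astype(float)
    if variant == "ward.D2":
        cur = cur**2
    ids = list(range(n))          # tree node id of each active cluster
    sizes = np.ones(n)
    merges = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        m = len(ids)
        iu, ju = np.triu_indices(m, k=1)
        flat = np.argmin(cur[iu, ju])  # first minimum in row-major order:
        i, j = int(iu[flat]), int(ju[flat])  # smallest tied pair by position
        h = cur[i, j]
        si, sj = sizes[i], sizes[j]
        height = np.sqrt(h) if variant == "ward.D2" else h
        merges[step] = (ids[i], ids[j], height, si + sj)
        sk = sizes
        new = ((si + sk) * cur[i] + (sj + sk) * cur[j] - sk * h) / (si + sj + sk)
        cur[i, :] = new
        cur[:, i] = new
        cur[i, i] = 0.0
        cur = np.delete(np.delete(cur, j, axis=0), j, axis=1)
        sizes = np.delete(sizes, j)
        sizes[i] = si + sj
        ids[i] = next_id  # position i keeps the smaller representative,
        del ids[j]        # so the active list stays sorted by representative
        next_id += 1
    return Dendrogram(
        merge_sequence=merges,
        leaf_order=order.copy(),
        cell_ids=tuple(cell_ids) if cell_ids else (),
    )


def cut_k(t: Dendrogram, k: int) -> np.ndarray:
    """Labels (aligned with the *original* cell order) after undoing the last
    k − 1 merges; labels are canonicalized by first occurrence."""
    n = t.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # union each of the first n-k merges into its new internal node id
    for step in range(n - k):
        a, b = int(t.merge_sequence[step, 0]), int(t.merge_sequence[step, 1])
        new = n + step
        parent[find(a)] = new
        parent[find(b)] = new

    labels_perm = np.array([find(p) for p in range(n)])
    labels = np.empty(n, dtype=int)
    labels[t.leaf_order] = labels_perm
    # canonicalize by first occurrence in original cell order
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


# ---------------------------------------------------------------------------
# Partition quality
# ---------------------------------------------------------------------------

def mean_silhouette(d: TurnoverMatrix | np.ndarray, labels) -> float:
    """Mean silhouette width of a partition under a precomputed dissimilarity.

    s(i) = (b(i) − a(i)) / max(a(i), b(i)) with a(i) the mean dissimilarity to
    own-cluster co-members and b(i) the smallest mean dissimilarity to another
    cluster; singleton clusters contribute s(i) = 0.  Ranges over [−1, 1];
    negative values flag cells probably assigned to the wrong cluster.
    """
    mat = d.d if isinstance(d, TurnoverMatrix) else np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    n = mat.shape[0]
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("mean_silhouette requires at least 2 clusters")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), inv] = 1.0
    counts = onehot.sum(axis=0)
    sums = mat @ onehot                       # (n, k) summed dissimilarity
    own = counts[inv] - 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(n), inv] / own
    mean_to = sums / counts[None, :]
    mean_to[np.arange(n), inv] = np.inf
    b = mean_to.min(axis=1)
    s = np.zeros(n)
    nonsingleton = own > 0
    denom = np.maximum(a, b)
    good = nonsingleton & (denom > 0)
    s[good] = (b[good] - a[good]) / denom[good]
    return float(s.mean())


def explained_dissimilarity(d: TurnoverMatrix | np.ndarray, labels) -> float:
    """Fraction of total pairwise dissimilarity falling between clusters.

    Sum of d(i, j) over unordered pairs in different clusters, divided by the
    sum over all unordered pairs.  0 for a single cluster, 1 when every pair
    is between-cluster (all singletons).  Maximizing it favors partitions
    whose clusters absorb as much of the landscape's dissimilarity structure
    as possible.
    """
    mat = d.d if isinstance(d, TurnoverMatrix) else np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    total = mat.sum() / 2.0
    if total <= 0:
        raise ValueError("total dissimilarity is 0; degenerate landscape")
    within = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        within += mat[np.ix_(idx, idx)].sum() / 2.0
    return float((total - within) / total)


# ---------------------------------------------------------------------------
# Randomized-order scan, k selection, consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionScan:
    """Quality metrics and replicate partitions for k = 2..K_max.

    summary: DataFrame indexed by k with mean_silhouette and
    explained_dissimilarity averaged over replicates.
    replicate_labels: dict (replicate, k) → label array in original cell
    order.  Reproducible bit-for-bit from (d, k_max, n_reorder, seed).
    """

    summary: pd.DataFrame
    replicate_labels: dict
    n_replicates: int
    k_max: int
    seed: int
    cell_ids: tuple[str, ...] = ()

    def labels_at(self, k: int) -> list[np.ndarray]:
        return [self.replicate_labels[(r, k)] for r in range(self.n_replicates)]


def scan_regions(
    d: TurnoverMatrix,
    k_max: int = 50,
    n_reorder: int = 50,
    seed: int = 0,
    variant: str = "ward.D",
) -> RegionScan:
    """Ward-cluster ``n_reorder`` random orderings and score every cut.

    For each seeded random permutation of the cells a dendrogram is built and
    cut at every k in 2..min(k_max, n−1); mean silhouette width and explained
    dissimilarity are averaged per k across replicates.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n_reorder < 1:
        raise ValueError("n_reorder must be >= 1")
    n = d.n_cells
    ks = list(range(2, min(k_max, n - 1) + 1))
    rng = np.random.default_rng(seed)
    sil = np.zeros((n_reorder, len(ks)))
    exd = np.zeros((n_reorder, len(ks)))
    replicate_labels: dict = {}
    for r in range(n_reorder):
        order = rng.permutation(n)
        tree = ward_linkage(d, order=order, variant=variant)
        for a, k in enumerate(ks):
            labels = cut_k(tree, k)
            replicate_labels[(r, k)] = labels
            sil[r, a] = mean_silhouette(d, labels)
            exd[r, a] = explained_dissimilarity(d, labels)
    summary = pd.DataFrame(
        {
            "mean_silhouette": sil.mean(axis=0),
            "explained_dissimilarity": exd.mean(axis=0),
        },
        index=pd.Index(ks, name="k"),
    )
    return RegionScan(
        summary=summary,
        replicate_labels=replicate_labels,
        n_replicates=n_reorder,
        k_max=k_max,
        seed=seed,
        cell_ids=d.cell_ids,
    )


def select_k(scan: RegionScan | pd.DataFrame, threshold: float = 0.90) -> int:
    """Dual-criterion cluster-count rule.

    Find the smallest k whose mean explained dissimilarity reaches
    ``threshold`` (the 90% convention for a suitable tree cut), then advance
    k → k+1 while the mean silhouette width strictly increases; return the k
    at which the silhouette stops increasing.  If the silhouette still rises
    at the largest scanned k, that k is returned with a warning.
    """
    summary = scan.summary if isinstance(scan, RegionScan) else scan
    ks = summary.index.to_numpy()
    if ks[0] != 2 or (np.diff(ks) != 1).any():
        raise ValueError("scan must cover contiguous k starting at 2")
    exd = summary["explained_dissimilarity"].to_numpy()
    sil = summary["mean_silhouette"].to_numpy()
    reached = np.flatnonzero(exd >= threshold)
    if reached.size == 0:
        raise ValueError(
            "no cluster count reaches the explained-dissimilarity threshold "
            f"{threshold:.2f}; maximum achieved is {exd.max():.4f}"
        )
    i = int(reached[0])
    while i + 1 < len(ks) and sil[i + 1] > sil[i]:
        i += 1
    if i == len(ks) - 1 and len(ks) > 1 and sil[-1] > sil[-2]:
        logger.warning(
            "mean silhouette still increasing at k_max=%d; returning k_max", ks[-1]
        )
    return int(ks[i])


def consensus_partition(
    solutions: list[np.ndarray], d: TurnoverMatrix, variant: str = "ward.D"
) -> np.ndarray:
    """Condense replicate partitions at one k into a single region map.

    Builds the co-classification frequency matrix (fraction of replicates
    placing each cell pair in the same cluster), Ward-clusters its complement
    with the identity ordering, and cuts at the replicates' k.  Invariant
    under relabeling of any replicate's cluster ids; unanimous replicates are
    returned unchanged.
    """
    if not solutions:
        raise ValueError("no replicate solutions given")
    ks = {len(np.unique(s)) for s in solutions}
    if len(ks) != 1:
        raise ValueError(f"replicates disagree on cluster count: {sorted(ks)}")
    k = ks.pop()
    n = len(solutions[0])
    co = np.zeros((n, n))
    for labels in solutions:
        labels = np.asarray(labels)
        co += (labels[:, None] == labels[None, :]).astype(float)
    co /= len(solutions)
    tree = ward_linkage(1.0 - co, order=np.arange(n), cell_ids=d.cell_ids)
    return cut_k(tree, k)
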