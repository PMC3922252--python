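"""Ward hierarchical clustering of predicted genetic-value vectors.

Regions whose kernels capture similar genetic signal produce similar
predicted genetic-value vectors g_hat = K alpha_hat; pairwise Euclidean
norms between those vectors feed an agglomerative clustering under Ward's
minimum-variance criterion, where the distance between two clusters is the
increase in total within-cluster sum of squares caused by merging them.

The agglomeration uses the Lance-Williams recurrence for Ward on squared
Euclidean distances; reported merge heights are on the SSE-increase scale,
directly comparable to a brute-force recomputation of within-cluster sums
of squares from the raw vectors. Ties in the minimum-distance selection are
broken by lexicographic cluster-label order, so dendrograms are
deterministic. Leaf counts here are small (one leaf per region), so the
naive O(L^3) agglomeration is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Dendrogram", "gvalue_distance_matrix", "ward_cluster", "write_newick"]


@dataclass
class Dendrogram:
    """Leaf labels and ordered merges (labels of merged clusters + height)."""

    leaves: list[str]
    merges: list[tuple[str, str, float]]   # (label_a, label_b, SSE-increase height)
    criterion: str = "ward"

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a dendrogram over L leaves has exactly L-1 merges")

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def merge_table(self):
        import pandas as pd

        return pd.DataFrame(self.merges, columns=["cluster_a", "cluster_b", "height"])

    def root_split(self) -> tuple[frozenset, frozenset]:
        """Leaf sets of the two clusters joined by the final merge."""
        members: dict[str, frozenset] = {leaf: frozenset([leaf]) for leaf in self.leaves}
        for a, b, _ in self.merges:
            members[f"({a}+{b})"] = members[a] | members[b]
        a, b, _ = self.merges[-1]
        return members[a], members[b]


def gvalue_distance_matrix(ghat_by_region: dict[str, np.ndarray]):
    """D[r, s] = ||g_hat_r - g_hat_s||_2 over a shared animal ordering."""
    names = list(ghat_by_region)
    vecs = [np.asarray(ghat_by_region[k], dtype=float) for k in names]
    n = {v.shape for v in vecs}
    if len(n) != 1 or vecs[0].ndim != 1:
        raise ValueError("all g_hat vectors must cover the same animals in the same order")
    L = len(names)
    D = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            D[i, j] = D[j, i] = float(np.linalg.norm(vecs[i] - vecs[j]))
    return names, D


def ward_cluster(distance_matrix: np.ndarray, labels=None) -> Dendrogram:
    """Agglomerate by Ward's minimum-variance criterion.

    Input distances are Euclidean; internally the Lance-Williams update runs
    on the SSE-increase scale, initialised for singletons as d^2 / 2 (the
    SSE increase of merging two points at Euclidean distance d).
    """
    D = np.asarray(distance_matrix, dtype=float)
    L = D.shape[0]
    if D.shape != (L, L) or L < 2:
        raise ValueError("need a square distance matrix over >= 2 leaves")
    if not np.allclose(D, D.T) or (D < 0).any() or not np.allclose(np.diag(D), 0):
        raise ValueError("distances must be symmetric, non-negative, zero-diagonal")
    labels = [f"leaf{i}" for i in range(L)] if labels is None else list(labels)

    # active clusters: label -> (size, index into the working cost matrix)
    cost = D.astype(float) ** 2 / 2.0          # SSE increase for singleton pairs
    active = {lab: i for i, lab in enumerate(labels)}
    sizes = {lab: 1 for lab in labels}
    merges: list[tuple[str, str, float]] = []
    work = cost.copy()
    np.fill_diagonal(work, np.inf)

    for _ in range(L - 1):
        # minimum cost pair, ties broken lexicographically on the label pair
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if a >= b:
                    continue
                c = work[active[a], active[b]]
                if best is None or c < best[0] - 1e-12:
                    best = (c, a, b)
        h, a, b = best
        ia, ib = active[a], active[b]
        na, nb = sizes[a], sizes[b]
        new_label = f"({a}+{b})"
        merges.append((a, b, float(h)))
        # Lance-Williams update for Ward on the SSE-increase scale
        for c in active:
            if c in (a, b):
                continue
            ic = active[c]
            nc = sizes[c]
            tot = na + nb + nc
            d_new = ((na + nc) * work[ia, ic] + (nb + nc) * work[ib, ic]
                     - nc * h) / tot
            work[ia, ic] = work[ic, ia] = d_new
        # reuse slot ia for the merged cluster; retire ib
        work[ib, :] = np.inf
        work[:, ib] = np.inf
        del active[a], active[b], sizes[a], sizes[b]
        active[new_label] = ia
        sizes[new_label] = na + nb
    return Dendrogram(labels, merges)


def _node_heights(dendro: Dendrogram) -> dict[str, float]:
    """Ultrametric node heights: leaves at 0, internal nodes at merge height / 2."""
    h = {leaf: 0.0 for leaf in dendro.leaves}
    for a, b, height in dendro.merges:
        h[f"({a}+{b})"] = height / 2.0
    return h


def write_newick(dendro: Dendrogram) -> str:
    """Serialize the merge tree as Newick with ultrametric branch lengths.

    Each internal node sits at half its merge height, so two leaves merged at
    height h are written "(A:h/2,B:h/2);" and the leaf-to-leaf path length
    equals h.
    """
    heights = _node_heights(dendro)
    children: dict[str, tuple[str, str]] = {}
    for a, b, _ in dendro.merges:
        children[f"({a}+{b})"] = (a, b)
    root = f"({dendro.merges[-1][0]}+{dendro.merges[-1][1]})"

    def emit(node: str) -> str:
        if node not in children:
            return node
        a, b = children[node]
        ba = heights[node] - heights[a]
        bb = heights[node] - heights[b]
        return f"({emit(a)}:{ba:.10g},{emit(b)}:{bb:.10g})"

    return emit(root) + ";"


def ward_cluster_bruteforce(vectors: dict[str, np.ndarray]) -> Dendrogram:
    """Reference Ward agglomeration recomputing within-cluster SSE from raw
    vectors at every step; exponential-free but O(L^2) SSE scans.

    Independent of the Lance-Williams path: cluster costs are evaluated as
    SSE(merged) - SSE(a) - SSE(b) with SSE the sum of squared deviations
    from the cluster centroid. Used as the oracle in tests.
    """
    labels = list(vectors)
    members: dict[str, list[np.ndarray]] = {
        lab: [np.asarray(vectors[lab], dtype=float)] for lab in labels}
    merges = []

    def sse(vecs: list[np.ndarray]) -> float:
        arr = np.stack(vecs)
        return float(((arr - arr.mean(axis=0)) ** 2).sum())

    while len(members) > 1:
        best = None
        for a in sorted(members):
            for b in sorted(members):
                if a >= b:
                    continue
                inc = sse(members[a] + members[b]) - sse(members[a]) - sse(members[b])
                if best is None or inc < best[0] - 1e-12:
                    best = (inc, a, b)
        inc, a, b = best
        merges.append((a, b, float(inc)))
        members[f"({a}+{b})"] = members.pop(a) + members.pop(b)
    return Dendrogram(labels, merges)
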