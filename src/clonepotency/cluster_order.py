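"""Hierarchical clustering of clone outputs with optimal leaf ordering.

Clones (rows of the log-scaled yield matrix) are clustered by
complete-linkage agglomeration on Euclidean distances.  For display
orderings, the dendrogram's leaves are permuted — by subtree flips only,
which leave the tree structure unchanged — to maximize the summed
similarity between adjacent leaves (optimal leaf ordering).  A fixed-k
cut (default four clusters) recovers the major potency classes.

The linkage and leaf-ordering computations delegate to
scipy.cluster.hierarchy; this module adds the similarity-maximizing
interface, validation, Newick export and the cluster cut.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError


@dataclasses.dataclass
class Dendrogram:
    """Merge sequence over N leaves (scipy linkage encoding) plus labels."""

    linkage: np.ndarray  # (N-1) x 4
    labels: list

    def __post_init__(self):
        Z = np.asarray(self.linkage, dtype=float)
        if Z.ndim != 2 or Z.shape[1] != 4 or Z.shape[0] != len(self.labels) - 1:
            raise ValidationError("malformed linkage matrix")
        heights = Z[:, 2]
        if (np.diff(heights) < -1e-12).any():
            raise ValidationError("merge heights must be non-decreasing")
        self.linkage = Z

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def hcluster(X: np.ndarray, labels=None) -> Dendrogram:
    """Complete-linkage agglomeration on Euclidean distances between rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need an N x p matrix with N >= 2")
    if not np.isfinite(X).all():
        raise ValidationError("non-finite entries in clustering input")
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    if labels is None:
        labels = list(range(X.shape[0]))
    return Dendrogram(linkage=Z, labels=list(labels))


def similarity_from_points(X: np.ndarray) -> np.ndarray:
    """Default leaf-ordering similarity: negative Euclidean distance."""
    return -squareform(pdist(np.asarray(X, dtype=float)))


def optimal_leaf_order(tree: Dendrogram, S: np.ndarray, chunk: int = 128):
    """Similarity-maximizing leaf permutation via subtree flips.

    Exact dynamic program over subtree endpoint pairs (Bar-Joseph style):
    for every internal node and every admissible (leftmost, rightmost)
    leaf pair, the best achievable cost is a min-plus product of the
    children's tables with the inter-leaf cost matrix.  This maximizes
    the sum of S over adjacent leaf pairs across all 2^(N-1) flip
    combinations while leaving the tree structure unchanged.  Returns
    ``(permutation, objective)``; the mirrored permutation attains the
    same objective and either may be returned.
    """
    S = np.asarray(S, dtype=float)
    n = tree.n_leaves
    if S.shape != (n, n):
        raise ValidationError(f"similarity matrix is {S.shape}, expected {(n, n)}")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValidationError("similarity matrix must be symmetric")
    if n == 1:
        return np.array([0]), 0.0
    # minimize summed adjacent costs D; the affine shift is harmless since
    # every ordering has exactly n-1 adjacencies
    D = S.max() - S
    np.fill_diagonal(D, 0.0)
    Z = tree.linkage.astype(int)

    leaves: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    # M[v][i, j]: best cost of ordering leaves(v) starting at leaves(v)[i]
    # (drawn from one child) and ending at leaves(v)[j] (the other child)
    M: dict[int, np.ndarray] = {i: np.zeros((1, 1)) for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    argm: dict[int, np.ndarray] = {}
    argk: dict[int, np.ndarray] = {}

    for step in range(n - 1):
        v = n + step
        l, r = Z[step, 0], Z[step, 1]
        children[v] = (l, r)
        lL, lR = leaves[l], leaves[r]
        ML, MR = M[l], M[r]
        a, b = len(lL), len(lR)
        Dlr = D[np.ix_(lL, lR)]
        Mv = np.empty((a, b))
        am = np.empty((a, b), dtype=np.intp)
        ak = np.empty((a, b), dtype=np.intp)
        for u0 in range(0, a, chunk):
            u1 = min(u0 + chunk, a)
            # T[u, k] = min_m ML[u, m] + D[m, k]
            cand = ML[u0:u1, :, None] + Dlr[None, :, :]
            t_arg = np.argmin(cand, axis=1)
            T = np.take_along_axis(cand, t_arg[:, None, :], axis=1)[:, 0, :]
            # M[u, w] = min_k T[u, k] + MR[k, w]
            cand2 = T[:, :, None] + MR[None, :, :]
            k_arg = np.argmin(cand2, axis=1)
            Mv[u0:u1] = np.take_along_axis(cand2, k_arg[:, None, :], axis=1)[:, 0, :]
            ak[u0:u1] = k_arg
            am[u0:u1] = np.take_along_axis(t_arg, k_arg, axis=1)
        leaves[v] = np.concatenate([lL, lR])
        # endpoints may come from either child: full table is [[inf, Mv], [Mv.T, inf]]
        full = np.full((a + b, a + b), np.inf)
        full[:a, a:] = Mv
        full[a:, :a] = Mv.T
        M[v] = full
        argm[v], argk[v] = am, ak
        del M[l], M[r]

    root = 2 * n - 2
    flat = int(np.argmin(M[root]))
    ui, wi = divmod(flat, len(leaves[root]))
    objective_cost = M[root][ui, wi]

    def trace(v, ui, wi):
        """Leaf order of node v starting at local index ui, ending at wi."""
        if v < n:
            return [int(leaves[v][0])]
        l, r = children[v]
        a = len(leaves[l])
        if ui < a:  # starts in left child, ends in right child
            m = int(argm[v][ui, wi - a])
            k = int(argk[v][ui, wi - a])
            return trace(l, ui, m) + trace(r, k, wi - a)
        # mirrored: reverse of the (wi, ui) solution
        return trace(v, wi, ui)[::-1]

    perm = np.array(trace(root, ui, wi))
    objective = float(S[perm[:-1], perm[1:]].sum())
    assert abs((S.max() * (n - 1) - objective) - objective_cost) < 1e-6 * max(1, abs(objective_cost))
    return perm, objective


def leaf_order_objective(perm: np.ndarray, S: np.ndarray) -> float:
    perm = np.asarray(perm)
    return float(S[perm[:-1], perm[1:]].sum())


def cut_k(tree: Dendrogram, k: int) -> np.ndarray:
    """Cut the dendrogram into exactly k clusters; labels are 0..k-1."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}]")
    labels = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    return labels - 1


def to_newick(tree: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string with branch lengths."""
    root, _ = hierarchy.to_tree(tree.linkage, rd=True)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{tree.labels[node.id]}:{length:g}"
        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:g}"

    return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"
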