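"""Principal coordinate analysis and neighbour-joining trees.

PCoA is classical metric scaling: Gower-center the squared-distance
matrix, eigendecompose, and keep axes with positive eigenvalues.

Neighbour joining follows Saitou & Nei's agglomeration: repeatedly
join the pair (i, j) minimizing

    Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

with the standard limb-length and distance-update formulas, closing
the unrooted tree with a final three-way join. Negative limb lengths
are clamped to zero with the deficit moved to the sister limb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PcoaResult", "TreeNode", "NJTree", "pcoa", "nj_tree"]


@dataclass
class PcoaResult:
    """Coordinates on positive axes plus eigenvalues and % variance."""

    individual_ids: list[str]
    coordinates: np.ndarray  # (n, n_positive_axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    pct_variance: np.ndarray  # per positive axis, sums to 100

    def frame(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.individual_ids, columns=cols)


def pcoa(dist, eps: float = 1e-9) -> PcoaResult:
    """Classical MDS of a squared-distance matrix (Gower double centering).

    ``dist`` is a :class:`~epimsap.amova.DistanceMatrix` (its ``D2``
    holds squared distances). Axes with eigenvalue <= eps * max(eig)
    are dropped; percentage of variance is over positive eigenvalues.
    Each kept eigenvector's first nonzero loading is made positive so
    coordinates are reproducible across runs and BLAS builds.
    """
    D2 = dist.D2
    n = D2.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 individuals")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    cutoff = eps * max(eigval.max(), 1.0)
    pos = eigval > cutoff
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    pct = 100.0 * eigval[pos] / eigval[pos].sum()
    return PcoaResult(
        individual_ids=list(dist.individual_ids),
        coordinates=coords,
        eigenvalues=eigval,
        pct_variance=pct,
    )


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an unrooted tree; ``children`` pairs (child, branch length)."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def _newick(self) -> str:
        if self.is_leaf:
            return self.name or ""
        parts = [f"{c._newick()}:{l:.10g}" for c, l in self.children]
        return "(" + ",".join(parts) + ")"


@dataclass
class NJTree:
    """Unrooted NJ tree; ``root`` is the trifurcating closing node."""

    root: TreeNode
    leaf_names: list[str]

    def to_newick(self) -> str:
        return self.root._newick() + ";"

    def branch_lengths(self) -> list[float]:
        out: list[float] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child, length in node.children:
                out.append(length)
                stack.append(child)
        return out

    def patristic_distances(self) -> pd.DataFrame:
        """Leaf-to-leaf path-length matrix (oracle for additivity checks)."""
        # path lengths via DFS from each leaf on the undirected tree
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}
        counter = [0]
        index: dict[int, int] = {}

        def visit(node: TreeNode) -> int:
            k = counter[0]
            counter[0] += 1
            index[id(node)] = k
            adj[k] = []
            if node.is_leaf:
                names[k] = node.name or ""
            for child, length in node.children:
                ck = visit(child)
                adj[k].append((ck, length))
                adj[ck].append((k, length))
            return k

        visit(self.root)
        leaves = sorted(names, key=lambda k: self.leaf_names.index(names[k]))
        n = len(leaves)
        D = np.zeros((n, n))
        for a, start in enumerate(leaves):
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for b, stop in enumerate(leaves):
                D[a, b] = dist[stop]
        labels = [names[k] for k in leaves]
        return pd.DataFrame(D, index=labels, columns=labels)


def nj_tree(D, leaf_names: list[str] | None = None) -> NJTree:
    """Saitou–Nei neighbour joining on a plain (non-squared) distance matrix.

    ``D`` may be a :class:`~epimsap.amova.DistanceMatrix` (its square
    roots are used) or a symmetric nonnegative array with
    ``leaf_names``. Q-matrix ties break on the lowest (row, column)
    pair, so output is deterministic.
    """
    from .amova import DistanceMatrix

    if isinstance(D, DistanceMatrix):
        leaf_names = list(D.individual_ids)
        mat = D.distances()
    else:
        mat = np.asarray(D, dtype=float)
        if leaf_names is None:
            raise ValueError("leaf_names required for a plain array input")
    n = mat.shape[0]
    if mat.shape != (n, n) or len(leaf_names) != n:
        raise ValueError("distance matrix / label size mismatch")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("NJ needs at least 3 leaves")

    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in leaf_names]
    d = mat.astype(float).copy()
    active = list(range(n))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        # negative limb: clamp at 0, move deficit to sister limb
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)  # lowest (row, col) on ties via C-order argmin
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (rowsum[ai] - rowsum[aj]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining active nodes
        newdist = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            newdist[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : newdist.size - 1] = newdist[:-1]
        d[: newdist.size - 1, -1] = newdist[:-1]
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # closing three-way join
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )
    return NJTree(root=root, leaf_names=list(leaf_names))
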