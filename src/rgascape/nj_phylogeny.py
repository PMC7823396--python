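"""Distance-based neighbour-joining phylogeny over family members.

Distances derive from best-hit percent identity (d = 1 - identity/100,
symmetrised by the minimum); the joining loop is the classic rate-corrected
agglomeration with a deterministic lexicographic tie-break and negative
branch lengths clamped to zero (deficit moved to the sibling branch).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .io_formats import SimilarityHit

_CLAMP_TOL = 1e-9


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over ordered labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.d < 0):
            raise ValueError("distance matrix has negative entries")


def distances_from_hits(
    all_vs_all_hits: Iterable[SimilarityHit], labels: Sequence[str]
) -> DistanceMatrix:
    """Identity-based distances: d = 1 - best identity / 100.

    Missing pairs default to 1.0; asymmetric hits are symmetrised by the
    minimum distance (i.e. the higher identity governs).
    """
    labels = list(labels)
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    for h in all_vs_all_hits:
        i = index.get(h.query_id)
        j = index.get(h.subject_id)
        if i is None or j is None or i == j:
            continue
        dist = 1.0 - h.pct_identity / 100.0
        if dist < d[i, j]:
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=labels, d=d)


def _join_lengths(dij: float, ri: float, rj: float, n: int) -> tuple[float, float]:
    li = 0.5 * dij + (ri - rj) / (2.0 * (n - 2))
    lj = dij - li
    # clamp negative branches, moving the deficit to the sibling
    if li < -_CLAMP_TOL or lj < -_CLAMP_TOL:
        if li < lj:
            li, lj = 0.0, dij
        else:
            li, lj = dij, 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbour joining; returns an unrooted tree (trifurcating
    root) with 2n-3 edges for n leaves.

    Ties on the Q criterion resolve to the smallest (i, j) index pair in the
    current matrix ordering, making the output bitwise deterministic.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError(f"neighbour joining requires n >= 3 leaves, got {n}")

    d = matrix.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in matrix.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> lexicographically first (i, j), row-major scan
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li, lj = _join_lengths(d[i, j], r[i], r[j], m)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new_node = TreeNode(children=[child_i, child_j])

        dk_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.empty((m - 1, m - 1))
        d_next[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        d_next[m - 2, : m - 2] = dk_new[keep]
        d_next[: m - 2, m - 2] = dk_new[keep]
        d_next[m - 2, m - 2] = 0.0
        nodes = [nodes[k] for k in keep] + [new_node]
        d = d_next

    # final three-way join around a central node
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    root = TreeNode(children=[a, b, c])
    root.length = None
    return root


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def group_cut(tree: TreeNode, k: int) -> list[set[str]]:
    """Partition leaves into k groups by cutting the longest edges.

    Edges are considered longest-first (internal edges before leaf edges on
    ties, then by smallest subtree leaf name, so the cut is deterministic);
    an edge is cut only when it actually splits a current group, and cutting
    proceeds until k groups exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    all_leaves = frozenset(t.name for t in tree.tips())
    if k > len(all_leaves):
        raise ValueError(f"k={k} exceeds leaf count {len(all_leaves)}")

    edges = []  # (length, is_leaf_edge, tie_name, leafset under edge)
    for node in tree.traverse(include_self=False):
        leafset = frozenset(
            t.name for t in (node.tips() if node.children else [node])
        )
        edges.append(
            (
                -(node.length or 0.0),
                0 if node.children else 1,
                min(leafset),
                leafset,
            )
        )
    edges.sort(key=lambda e: e[:3])

    groups: list[set[str]] = [set(all_leaves)]
    for _, _, _, leafset in edges:
        if len(groups) >= k:
            break
        # the nested-split structure guarantees leafset sits inside one group
        for g in groups:
            if leafset <= g:
                if leafset < g:
                    g.difference_update(leafset)
                    groups.append(set(leafset))
                break
    if len(groups) != k:
        raise ValueError(f"could not partition tree into {k} groups")
    return sorted(groups, key=lambda s: sorted(s)[0])
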