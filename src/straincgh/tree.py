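"""Shared agglomerative-clustering machinery.

Both the karyotype branch (UPGMA on 1 - Jaccard) and the array-CGH branch
(complete linkage on Euclidean distances) produce the same kind of object: a
rooted binary merge tree with heights over a fixed set of leaf labels.  This
module holds that type plus the generic agglomeration loop, Newick export,
deterministic leaf ordering and tree cutting.

Determinism contract: when several cluster pairs are at the minimal distance,
the pair whose (smallest leaf label, smallest leaf label) tuple sorts first
lexicographically is merged, and within a merge the cluster holding the
smaller leaf label becomes the left child.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Dendrogram", "agglomerate"]

_SYM_TOL = 1e-12


@dataclass(frozen=True)
class Dendrogram:
    """Rooted binary merge tree.

    ``labels`` are the leaf labels in their input order; node ids 0..n-1 are
    the leaves and node ``n + i`` is the cluster created by ``merges[i]``.
    Each merge is ``(left_id, right_id, height)`` with non-negative heights.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError(
                f"binary tree over {n} leaves needs {n - 1} merges, "
                f"got {len(self.merges)}"
            )
        for left, right, height in self.merges:
            if height < 0:
                raise ValueError("merge heights must be non-negative")
            if left == right:
                raise ValueError("degenerate merge of a cluster with itself")

    def node_height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return self.merges[node - self.n_leaves][2]

    def _children(self, node: int) -> tuple[int, int]:
        left, right, _ = self.merges[node - self.n_leaves]
        return left, right

    def leaves_of(self, node: int) -> tuple[int, ...]:
        """Leaf ids under ``node`` in deterministic traversal order."""
        if node < self.n_leaves:
            return (node,)
        left, right = self._children(node)
        return self.leaves_of(left) + self.leaves_of(right)

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def leaf_order(self) -> list[str]:
        """Leaf labels by recursive left-first traversal from the root."""
        if self.n_leaves == 1:
            return [self.labels[0]]
        return [self.labels[i] for i in self.leaves_of(self.root)]

    def newick(self) -> str:
        """Serialize with branch lengths = parent height - child height."""

        def fmt(x: float) -> str:
            return format(x, ".12g")

        def render(node: int, parent_height: float) -> str:
            length = max(parent_height - self.node_height(node), 0.0)
            if node < self.n_leaves:
                return f"{self.labels[node]}:{fmt(length)}"
            left, right = self._children(node)
            h = self.node_height(node)
            inner = f"({render(left, h)},{render(right, h)})"
            return f"{inner}:{fmt(length)}"

        if self.n_leaves == 1:
            return f"{self.labels[0]};"
        root = self.root
        h = self.node_height(root)
        left, right = self._children(root)
        return f"({render(left, h)},{render(right, h)});"

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into ``k`` clusters by undoing the last
        ``k - 1`` merges.  Cluster indices are assigned by the smallest leaf
        label in each cluster, so the mapping is deterministic."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}], got {k}")
        roots = set(range(n))
        for i, (left, right, _) in enumerate(self.merges[: n - k]):
            roots.discard(left)
            roots.discard(right)
            roots.add(n + i)
        clusters = []
        for r in roots:
            members = sorted(self.labels[i] for i in self.leaves_of(r))
            clusters.append(members)
        clusters.sort(key=lambda m: m[0])
        assignment: dict[str, int] = {}
        for idx, members in enumerate(clusters):
            for label in members:
                assignment[label] = idx
        return assignment


def _validate_distance_matrix(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if np.abs(d - d.T).max() > _SYM_TOL:
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(d)).max() > _SYM_TOL:
        raise ValueError("distance matrix must have a zero diagonal")


def agglomerate(
    distances: np.ndarray, labels: list[str] | tuple[str, ...], method: str
) -> Dendrogram:
    """Agglomerative clustering with deterministic tie handling.

    method="average" is UPGMA: the distance from a merged cluster to any
    other is the size-weighted mean of the members' distances (equivalently
    the arithmetic mean over all cross leaf pairs) and the merge height is
    half the merge distance.  method="complete" uses the maximum cross-pair
    distance and the merge height equals the merge distance.
    """
    d = np.asarray(distances, dtype=float)
    _validate_distance_matrix(d)
    labels = tuple(str(x) for x in labels)
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")
    if method not in ("average", "complete"):
        raise ValueError(f"unknown linkage method {method!r}")

    # active cluster state, keyed by node id
    size = {i: 1 for i in range(n)}
    min_label = {i: labels[i] for i in range(n)}
    dist: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = d[i, j]
    active = set(range(n))

    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        best_pair: tuple[int, int] | None = None
        best_key: tuple[float, tuple[str, str]] | None = None
        for pair, dd in dist.items():
            a, b = sorted(pair)
            key = (dd, tuple(sorted((min_label[a], min_label[b]))))
            if best_key is None or key < best_key:
                best_key = key
                best_pair = (a, b)
        assert best_pair is not None and best_key is not None
        a, b = best_pair
        dd = best_key[0]
        if min_label[b] < min_label[a]:
            a, b = b, a
        new = n + step
        height = dd / 2.0 if method == "average" else dd
        merges.append((a, b, height))

        active.discard(a)
        active.discard(b)
        for c in active:
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            if method == "average":
                upd = (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
            else:
                upd = max(dac, dbc)
            dist[frozenset((new, c))] = upd
        dist.pop(frozenset((a, b)))
        size[new] = size[a] + size[b]
        min_label[new] = min(min_label[a], min_label[b])
        active.add(new)

    return Dendrogram(labels=labels, merges=tuple(merges))
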