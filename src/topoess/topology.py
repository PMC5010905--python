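"""Unrooted tree topologies and ordered posterior samples of them.

A :class:`Topology` is a branching pattern over a fixed set of leaf labels
with branch lengths discarded: the object of interest when asking how well a
Bayesian MCMC has sampled tree space. Two topologies are equal exactly when
their non-trivial unrooted splits (bipartitions) coincide.

A :class:`TreeSample` is the ordered sequence of topologies recorded from one
chain. It caches the per-tree encodings the distance metrics need — split
sets for Robinson–Foulds, leaf-pair path-length vectors for the path
difference — so that the O(N·lags) distance computations downstream stay
cheap.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import ContentError, UsageError

__all__ = ["Topology", "TreeSample"]


def _quote_label(label: str) -> str:
    if any(c in label for c in "();:, \t'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


class Topology:
    """An unrooted tree topology on a fixed, uniquely-labelled leaf set.

    Internally leaves are numbered ``0..n-1`` in lexicographic label order
    (so matrices and vectors derived from different trees on the same leaf
    set are directly comparable) and internal nodes follow. Rooted inputs
    are silently unrooted: nodes of degree two are suppressed on
    construction.
    """

    __slots__ = ("_labels", "_adj", "_splits", "_path_vec", "_hash")

    def __init__(self, adj: Sequence[Sequence[int]], labels: Sequence[str]):
        # internal constructor: adj already canonical (leaves first, no
        # degree-2 nodes); use from_edges() to build from arbitrary input
        self._labels: tuple[str, ...] = tuple(labels)
        self._adj: tuple[tuple[int, ...], ...] = tuple(tuple(a) for a in adj)
        self._splits: frozenset[int] | None = None
        self._path_vec: np.ndarray | None = None
        self._hash: int | None = None

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Hashable, Hashable]],
        leaf_labels: Mapping[Hashable, str],
    ) -> "Topology":
        """Build a topology from an edge list and a leaf-key → label map.

        Degree-two nodes (e.g. the artificial root of a rooted newick) are
        suppressed; leaves must have degree one and unique labels; at least
        four leaves are required.
        """
        adj: dict[Hashable, list[Hashable]] = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        leaves = [k for k in adj if k in leaf_labels]
        labels = [leaf_labels[k] for k in leaves]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ContentError(f"duplicate leaf labels: {dupes}")
        if len(leaves) < 4:
            raise UsageError(
                f"a topology needs at least 4 leaves, got {len(leaves)}"
            )
        for k in leaves:
            if len(adj[k]) != 1:
                raise ContentError(
                    f"leaf {leaf_labels[k]!r} has degree {len(adj[k])}, expected 1"
                )
        n_nodes = len(adj)
        n_edges = sum(len(v) for v in adj.values()) // 2
        if n_edges != n_nodes - 1:
            raise ContentError("edge list does not describe a tree")
        # suppress degree-2 internal nodes (unroot rooted inputs)
        leafset = set(leaves)
        changed = True
        while changed:
            changed = False
            for node in list(adj):
                if node not in leafset and len(adj[node]) == 2:
                    a, b = adj.pop(node)
                    adj[a] = [b if x == node else x for x in adj[a]]
                    adj[b] = [a if x == node else x for x in adj[b]]
                    changed = True
        # renumber: leaves 0..n-1 by sorted label, internals after
        order = sorted(range(len(leaves)), key=lambda i: labels[i])
        index = {leaves[i]: rank for rank, i in enumerate(order)}
        nxt = len(leaves)
        for node in adj:
            if node not in index:
                index[node] = nxt
                nxt += 1
        canon: list[list[int]] = [[] for _ in range(nxt)]
        for node, nbrs in adj.items():
            canon[index[node]] = [index[x] for x in nbrs]
        topo = cls(canon, sorted(labels))
        # connectivity check: splits computation walks the whole tree
        if len(topo._compute_parents()) != nxt:
            raise ContentError("edge list does not describe a connected tree")
        return topo

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    @property
    def leaf_labels(self) -> tuple[str, ...]:
        """Leaf labels in lexicographic order."""
        return self._labels

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    def edges(self) -> list[tuple[int, int]]:
        """Edges as (u, v) pairs with u < v, over internal node ids."""
        return [
            (u, v) for u, nbrs in enumerate(self._adj) for v in nbrs if u < v
        ]

    def neighbors(self, node: int) -> tuple[int, ...]:
        return self._adj[node]

    @property
    def is_binary(self) -> bool:
        n = self.n_leaves
        return all(len(a) == 3 for a in self._adj[n:])

    def _compute_parents(self) -> dict[int, int]:
        """Parent map of a DFS rooted at leaf 0 (also proves connectivity)."""
        parents = {0: -1}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in self._adj[u]:
                if v not in parents:
                    parents[v] = u
                    stack.append(v)
        return parents

    # ------------------------------------------------------------------
    # derived encodings
    # ------------------------------------------------------------------
    def splits(self) -> frozenset[int]:
        """Non-trivial unrooted splits as leaf bitmasks.

        Each split is encoded by the bitmask of the side that does not
        contain leaf 0; only splits with 2..n-2 leaves on that side are kept
        (trivial single-leaf splits carry no topological information).
        """
        if self._splits is None:
            n = self.n_leaves
            parents = self._compute_parents()
            # post-order accumulation of subtree leaf masks below each node
            order = list(parents)  # DFS discovery order; reverse ≈ post-order
            mask = {u: (1 << u) if u < n else 0 for u in range(self.n_nodes)}
            for u in reversed(order):
                p = parents[u]
                if p >= 0:
                    mask[p] |= mask[u]
            full_pop = n
            out = []
            for u in order:
                if parents[u] >= 0:
                    m = mask[u]
                    pop = int(m).bit_count()
                    if 2 <= pop <= full_pop - 2:
                        out.append(m)
            self._splits = frozenset(out)
        return self._splits

    def leaf_path_vector(self) -> np.ndarray:
        """Condensed vector of leaf-pair path lengths in edges.

        Entries follow ``scipy.spatial.distance.squareform`` ordering over
        leaf pairs (i, j), i < j, with leaves in lexicographic label order.
        """
        if self._path_vec is None:
            n = self.n_leaves
            m = self.n_nodes
            rows, cols = [], []
            for u, nbrs in enumerate(self._adj):
                for v in nbrs:
                    rows.append(u)
                    cols.append(v)
            g = csr_matrix(
                (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(m, m)
            )
            d = shortest_path(g, method="D", unweighted=True, indices=range(n))
            iu, ju = np.triu_indices(n, k=1)
            self._path_vec = d[iu, ju].astype(np.float64)
        return self._path_vec

    # ------------------------------------------------------------------
    # serialisation
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        """One-line newick string (no branch lengths), ';'-terminated."""
        root = self._adj[0][0]  # internal neighbour of leaf 0

        def subtree(u: int, parent: int) -> str:
            if u < self.n_leaves:
                return _quote_label(self._labels[u])
            parts = [subtree(v, u) for v in self._adj[u] if v != parent]
            return "(" + ",".join(parts) + ")"

        parts = [subtree(v, root) for v in self._adj[root]]
        return "(" + ",".join(parts) + ");"

    # ------------------------------------------------------------------
    # identity
    # ------------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self._labels == other._labels and self.splits() == other.splits()

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self._labels, self.splits()))
        return self._hash

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Topology n_leaves={self.n_leaves} splits={len(self.splits())}>"


class TreeSample:
    """An ordered sequence of topologies sampled from one chain."""

    def __init__(self, topologies: Sequence[Topology], source: str = ""):
        topologies = list(topologies)
        if not topologies:
            raise ContentError("empty tree sample")
        ref = topologies[0].leaf_labels
        for i, t in enumerate(topologies):
            if t.leaf_labels != ref:
                offending = sorted(
                    set(t.leaf_labels).symmetric_difference(ref)
                )
                raise ContentError(
                    f"tree {i} has a different leaf set; offending labels: "
                    f"{offending}"
                )
        self.topologies: list[Topology] = topologies
        self.source = source
        self._path_matrix: np.ndarray | None = None
        self._split_sets: list[frozenset[int]] | None = None

    @property
    def N(self) -> int:
        return len(self.topologies)

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return self.topologies[0].leaf_labels

    def __len__(self) -> int:
        return len(self.topologies)

    def __getitem__(self, i: int) -> Topology:
        return self.topologies[i]

    def __iter__(self) -> Iterator[Topology]:
        return iter(self.topologies)

    # cached per-tree encodings -----------------------------------------
    def split_sets(self) -> list[frozenset[int]]:
        if self._split_sets is None:
            self._split_sets = [t.splits() for t in self.topologies]
        return self._split_sets

    def path_vectors(self) -> np.ndarray:
        """(N, n·(n−1)/2) array of leaf-pair path lengths, one row per tree.

        Identical topologies (common in chains that revisit trees) share one
        computation: rows are deduplicated through the split-set hash.
        """
        if self._path_matrix is None:
            cache: dict[frozenset[int], np.ndarray] = {}
            rows = []
            for t in self.topologies:
                key = t.splits()
                vec = cache.get(key)
                if vec is None:
                    vec = t.leaf_path_vector()
                    cache[key] = vec
                rows.append(vec)
            self._path_matrix = np.vstack(rows)
        return self._path_matrix

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<TreeSample N={self.N} n_leaves={len(self.leaf_labels)} "
            f"source={self.source!r}>"
        )
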