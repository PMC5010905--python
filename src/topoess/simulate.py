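"""Synthetic posterior samples of trees with controllable mixing.

There is no known way to simulate a phylogenetic MCMC with a known
topological ESS, so validation relies on chains whose mixing varies
predictably:

* **Unimodal SPR walks** — start from a random binary topology and apply a
  fixed number of random subtree-prune-and-regraft (SPR) moves between
  successive samples. More moves per step means less autocorrelation; this
  is a phylogenetic MCMC stripped of any sequence data.
* **Bimodal switching chains** — build two distantly related sets of trees
  (their seed trees many SPR moves apart, each padded with close satellite
  trees) and sample by switching between sets with a fixed probability at
  each step. Switch probability 0.5 gives i.i.d.-like mixing between the
  modes; probability 0 confines the chain to one mode, which is
  indistinguishable from perfect mixing of a unimodal posterior.

All randomness flows from a single seed; identical specs reproduce
byte-identical newick output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TopoessError, UsageError
from .topology import Topology, TreeSample

__all__ = [
    "UnimodalSpec",
    "BimodalSpec",
    "random_topology",
    "random_spr",
    "simulate_unimodal",
    "simulate_bimodal",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class UnimodalSpec:
    """A single-mode SPR-walk chain.

    Defaults mirror the validation design the estimators were built
    against: 50 taxa and 1,000 samples per chain.
    """

    n_taxa: int = 50
    n_samples: int = 1000
    sprs_per_step: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise UsageError(f"n_taxa must be >= 4, got {self.n_taxa}")
        if self.n_samples < 20:
            raise UsageError(f"n_samples must be >= 20, got {self.n_samples}")
        if self.sprs_per_step < 1:
            raise UsageError(
                f"sprs_per_step must be >= 1, got {self.sprs_per_step}"
            )


@dataclass(frozen=True)
class BimodalSpec:
    """A two-mode switching chain.

    ``switch_prob`` is the probability of jumping to the other set of trees
    at each step (0 = never leave the starting mode; 0.5 = a fair coin, the
    best mixing this design can express). The two set seeds are separated
    by ``seed_separation_moves`` SPR moves; each set holds ``set_size``
    trees, the satellites ``within_set_moves`` SPR moves from their seed.
    """

    n_taxa: int = 50
    n_samples: int = 1000
    switch_prob: float = 0.1
    set_size: int = 10
    seed_separation_moves: int = 50
    within_set_moves: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise UsageError(f"n_taxa must be >= 4, got {self.n_taxa}")
        if self.n_samples < 20:
            raise UsageError(f"n_samples must be >= 20, got {self.n_samples}")
        if not 0.0 <= self.switch_prob <= 0.5:
            raise UsageError(
                f"switch_prob must lie in [0, 0.5], got {self.switch_prob}"
            )
        if self.set_size < 1:
            raise UsageError(f"set_size must be >= 1, got {self.set_size}")
        if self.seed_separation_moves < 1 or self.within_set_moves < 0:
            raise UsageError("move counts must be positive")


# ---------------------------------------------------------------------------
# mutable working representation (adjacency dict) for the random walks
# ---------------------------------------------------------------------------
def _adj_from_topology(t: Topology) -> dict[int, list[int]]:
    return {u: list(t.neighbors(u)) for u in range(t.n_nodes)}


def _topology_from_adj(
    adj: dict[int, list[int]], labels: tuple[str, ...]
) -> Topology:
    edges = [(u, v) for u, nbrs in adj.items() for v in nbrs if u < v]
    return Topology.from_edges(
        edges, {i: labels[i] for i in range(len(labels))}
    )


def _path(adj: dict[int, list[int]], src: int, dst: int) -> list[int]:
    """The unique path from ``src`` to ``dst`` as a node list."""
    parent = {src: -1}
    stack = [src]
    while stack:
        u = stack.pop()
        if u == dst:
            break
        for w in adj[u]:
            if w not in parent:
                parent[w] = u
                stack.append(w)
    path = [dst]
    while path[-1] != src:
        path.append(parent[path[-1]])
    path.reverse()
    return path


def _nni_in_place(adj: dict[int, list[int]], rng: np.random.Generator) -> None:
    """One uniform NNI: swap a subtree across a random internal edge."""
    internal_edges = [
        (u, v)
        for u, nbrs in adj.items()
        for v in nbrs
        if u < v and len(adj[u]) == 3 and len(adj[v]) == 3
    ]
    u, v = internal_edges[rng.integers(len(internal_edges))]
    x = next(w for w in adj[u] if w != v)
    others = [w for w in adj[v] if w != u]
    y = others[rng.integers(2)]
    adj[u] = [y if w == x else w for w in adj[u]]
    adj[v] = [x if w == y else w for w in adj[v]]
    adj[x] = [v if w == u else w for w in adj[x]]
    adj[y] = [u if w == v else w for w in adj[y]]


def _spr_in_place(adj: dict[int, list[int]], rng: np.random.Generator) -> None:
    """One random SPR rearrangement, mutating ``adj``.

    A move is indexed by an unordered pair of internal nodes: adjacent
    pairs carry the 2 NNI rearrangements of their shared edge, pairs at
    larger distance carry 8 subtree-transfer rearrangements (2 roles × 2
    prunable subtrees at one node × 2 regraft edges at the other). The pair
    is drawn with weight 2 if adjacent else 8 and the rearrangement
    uniformly within the pair, i.e. uniformly over the move classes of the
    standard random-SPR kernel used in phylogenetic tree-rearrangement
    libraries. The move never returns the identical topology.
    """
    internal = [u for u, nbrs in adj.items() if len(nbrs) == 3]
    n_int = len(internal)
    n_pairs = n_int * (n_int - 1) // 2
    n_adjacent = n_int - 1  # internal edges of the induced internal subtree
    w_nni = 2.0 * n_adjacent
    w_spr = 8.0 * (n_pairs - n_adjacent)
    if w_spr == 0 or rng.random() < w_nni / (w_nni + w_spr):
        _nni_in_place(adj, rng)
        return
    for _ in range(1000):
        i, j = (internal[t] for t in rng.choice(n_int, size=2, replace=False))
        if j not in adj[i]:  # need a non-adjacent pair
            break
    else:  # pragma: no cover - unreachable when w_spr > 0
        raise TopoessError("no non-adjacent internal node pair found")
    path = _path(adj, i, j)
    p_i, p_j = path[1], path[-2]
    off_i = [w for w in adj[i] if w != p_i]
    v = off_i[rng.integers(2)]  # root of the transferred subtree
    off_j = [w for w in adj[j] if w != p_j]
    c = off_j[rng.integers(2)]  # regraft onto edge (j, c)
    # detach (i, v); i keeps v and moves with it, so suppress i by merging
    # its two other neighbours, then subdivide (j, c) with i
    a, b = (w for w in adj[i] if w != v)
    adj[a] = [b if w == i else w for w in adj[a]]
    adj[b] = [a if w == i else w for w in adj[b]]
    adj[j] = [i if w == c else w for w in adj[j]]
    adj[c] = [i if w == j else w for w in adj[c]]
    adj[i] = [j, c, v]


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------
def random_topology(n_taxa: int, seed: int | np.random.Generator = 0) -> Topology:
    """A random binary unrooted topology by sequential leaf attachment.

    Leaves are labelled t1..tn. Each new leaf is attached to a uniformly
    chosen edge of the growing tree, which samples topologies
    near-uniformly and is deterministic per seed.
    """
    if n_taxa < 4:
        raise UsageError(f"n_taxa must be >= 4, got {n_taxa}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # leaves keyed 0..n-1 (labels assigned afterwards), internals from n
    adj: dict[int, list[int]] = {0: [n_taxa], 1: [n_taxa], 2: [n_taxa]}
    adj[n_taxa] = [0, 1, 2]
    next_internal = n_taxa + 1
    for leaf in range(3, n_taxa):
        edges = [(u, v) for u, nbrs in adj.items() for v in nbrs if u < v]
        x, y = edges[rng.integers(len(edges))]
        w = next_internal
        next_internal += 1
        adj[x] = [w if t == y else t for t in adj[x]]
        adj[y] = [w if t == x else t for t in adj[y]]
        adj[w] = [x, y, leaf]
        adj[leaf] = [w]
    # leaf key i gets label t(i+1); Topology reorders lexicographically
    return Topology.from_edges(
        [(u, v) for u, nbrs in adj.items() for v in nbrs if u < v],
        {i: f"t{i + 1}" for i in range(n_taxa)},
    )


def random_spr(t: Topology, seed: int | np.random.Generator = 0) -> Topology:
    """One random SPR move on a binary unrooted topology (>= 5 leaves).

    The result is always a different topology on the same leaf set (the
    regraft edge that would restore the original attachment is excluded).
    """
    if not t.is_binary:
        raise UsageError("random_spr requires a binary topology")
    if t.n_leaves < 5:
        raise UsageError("random_spr requires at least 5 leaves")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    adj = _adj_from_topology(t)
    _spr_in_place(adj, rng)
    return _topology_from_adj(adj, t.leaf_labels)


def simulate_unimodal(spec: UnimodalSpec) -> TreeSample:
    """An SPR-walk chain: each sample is the previous one after
    ``sprs_per_step`` random SPR moves."""
    rng = np.random.default_rng(spec.seed)
    start = random_topology(spec.n_taxa, rng)
    labels = start.leaf_labels
    adj = _adj_from_topology(start)
    samples = [start]
    for _ in range(spec.n_samples - 1):
        for _ in range(spec.sprs_per_step):
            _spr_in_place(adj, rng)
        samples.append(_topology_from_adj(adj, labels))
    return TreeSample(
        samples,
        source=(
            f"simulate_unimodal(n_taxa={spec.n_taxa}, "
            f"n_samples={spec.n_samples}, sprs_per_step={spec.sprs_per_step}, "
            f"seed={spec.seed})"
        ),
    )


def _satellite(
    seed_tree: Topology, moves: int, rng: np.random.Generator
) -> Topology:
    if moves == 0:
        return seed_tree
    adj = _adj_from_topology(seed_tree)
    for _ in range(moves):
        _spr_in_place(adj, rng)
    return _topology_from_adj(adj, seed_tree.leaf_labels)


def simulate_bimodal(spec: BimodalSpec) -> TreeSample:
    """A two-mode switching chain over two distantly related tree sets.

    Set 1 is a random seed tree plus ``set_size − 1`` satellites each
    ``within_set_moves`` SPR moves from the seed; set 2 is built the same
    way around a seed ``seed_separation_moves`` moves from set 1's seed.
    The chain starts in set 1; at each step it switches sets with
    probability ``switch_prob`` and then draws a tree uniformly (with
    replacement) from the current set.
    """
    rng = np.random.default_rng(spec.seed)
    seed1 = random_topology(spec.n_taxa, rng)
    seed2 = _satellite(seed1, spec.seed_separation_moves, rng)
    set1 = [seed1] + [
        _satellite(seed1, spec.within_set_moves, rng)
        for _ in range(spec.set_size - 1)
    ]
    set2 = [seed2] + [
        _satellite(seed2, spec.within_set_moves, rng)
        for _ in range(spec.set_size - 1)
    ]
    sets = (set1, set2)
    current = 0
    samples = [set1[rng.integers(spec.set_size)]]
    for _ in range(spec.n_samples - 1):
        if rng.random() < spec.switch_prob:
            current = 1 - current
        samples.append(sets[current][rng.integers(spec.set_size)])
    return TreeSample(
        samples,
        source=(
            f"simulate_bimodal(n_taxa={spec.n_taxa}, "
            f"n_samples={spec.n_samples}, switch_prob={spec.switch_prob}, "
            f"set_size={spec.set_size}, "
            f"seed_separation_moves={spec.seed_separation_moves}, "
            f"within_set_moves={spec.within_set_moves}, seed={spec.seed})"
        ),
    )
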