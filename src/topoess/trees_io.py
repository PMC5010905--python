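"""Reading and writing posterior samples of trees.

Supports the two formats Bayesian phylogenetics software emits: plain newick
(one ';'-terminated tree per line) and NEXUS trees blocks with an optional
translate table. Parsing is delegated to dendropy; branch lengths and
support values are parsed but discarded, and rooted inputs are unrooted,
because every downstream computation is topology-only.
"""

from __future__ import annotations

import math
import os
from typing import Iterable

import dendropy

from .errors import ContentError, TreeParseError, UsageError
from .topology import Topology, TreeSample

__all__ = [
    "read_tree_sample",
    "write_tree_sample",
    "topology_from_newick",
]

_FORMATS = ("newick", "nexus")


def _topology_from_dendropy(tree: dendropy.Tree, index: int) -> Topology:
    edges = []
    labels = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            edges.append((id(node.parent_node), id(node)))
        if node.is_leaf():
            taxon = node.taxon
            label = taxon.label if taxon is not None else node.label
            if label is None:
                raise ContentError(f"tree {index}: unlabelled leaf")
            labels[id(node)] = str(label)
    return Topology.from_edges(edges, labels)


def topology_from_newick(newick: str) -> Topology:
    """Parse a single newick string into a :class:`Topology`."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise TreeParseError(f"could not parse newick string: {exc}") from exc
    return _topology_from_dendropy(tree, 0)


def _read_newick_trees(path: str) -> list[Topology]:
    out = []
    with open(path) as fh:
        index = 0
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                tree = dendropy.Tree.get(data=line, schema="newick")
                out.append(_topology_from_dendropy(tree, index))
            except (TreeParseError, ContentError, UsageError):
                raise
            except Exception as exc:
                raise TreeParseError(
                    f"tree {index}: malformed newick ({exc})"
                ) from exc
            index += 1
    return out


def _read_nexus_trees(path: str) -> list[Topology]:
    try:
        trees = dendropy.TreeList.get(path=path, schema="nexus")
    except Exception as exc:
        raise TreeParseError(f"could not parse NEXUS file: {exc}") from exc
    return [_topology_from_dendropy(t, i) for i, t in enumerate(trees)]


def read_tree_sample(
    path: str | os.PathLike,
    format: str = "newick",
    burnin_fraction: float = 0.0,
) -> TreeSample:
    """Read an ordered posterior sample of topologies from a file.

    Parameters
    ----------
    path
        Tree file. Newick files hold one ';'-terminated tree per line;
        NEXUS files hold a trees block whose translate table (if present)
        is resolved to leaf labels.
    format
        ``"newick"`` or ``"nexus"``.
    burnin_fraction
        Fraction in [0, 1) of the chain to discard from the front;
        ``floor(burnin_fraction * total)`` trees are dropped. The default 0
        assumes the file is already post-burn-in, as deposited posterior
        samples usually are.
    """
    if format not in _FORMATS:
        raise UsageError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not 0.0 <= burnin_fraction < 1.0:
        raise UsageError("burnin_fraction must lie in [0, 1)")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise TreeParseError(f"no such file: {path}")
    topologies = (
        _read_newick_trees(path) if format == "newick" else _read_nexus_trees(path)
    )
    if not topologies:
        raise ContentError(f"no trees found in {path}")
    drop = math.floor(burnin_fraction * len(topologies))
    kept = topologies[drop:]
    if not kept:
        raise ContentError(
            f"burn-in of {drop} trees leaves an empty sample ({path})"
        )
    return TreeSample(kept, source=f"{path} (burnin_fraction={burnin_fraction})")


def _newick_lines(sample: TreeSample) -> Iterable[str]:
    for t in sample:
        yield t.to_newick()


def write_tree_sample(
    sample: TreeSample, path: str | os.PathLike, format: str = "newick"
) -> None:
    """Write a sample to disk; ``read(write(s))`` reproduces the topologies.

    Newick output is one tree per line without branch lengths. NEXUS output
    carries a taxa block and a translate table and marks trees unrooted.
    """
    if format not in _FORMATS:
        raise UsageError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = os.fspath(path)
    if format == "newick":
        with open(path, "w") as fh:
            for line in _newick_lines(sample):
                fh.write(line + "\n")
        return
    # NEXUS: round-trip through dendropy so the translate table, taxa block
    # and [&U] rooting comments follow the conventions other tools expect.
    data = "\n".join(_newick_lines(sample))
    trees = dendropy.TreeList.get(data=data, schema="newick")
    for t in trees:
        t.is_rooted = False
    trees.write(
        path=path,
        schema="nexus",
        translate_tree_taxa=True,
        suppress_edge_lengths=True,
    )
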