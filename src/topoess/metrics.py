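"""Topology-only distances between pairs of trees.

Two metrics are supported, both ignoring branch lengths:

* **Robinson–Foulds**: the size of the symmetric difference of the two
  trees' non-trivial split (bipartition) sets. Fast, but coarse — it takes
  few distinct values and saturates quickly between dissimilar trees.
* **Path difference**: the Euclidean norm of the difference between the two
  trees' leaf-pair path-length matrices, with path length counted in edges.
  Slower but far more discriminating, which makes it the preferred metric
  for autocorrelation and ESS work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform

from .errors import ContentError, UsageError
from .topology import Topology

__all__ = [
    "DistanceMetric",
    "PATH_DIFFERENCE",
    "ROBINSON_FOULDS",
    "robinson_foulds",
    "path_difference",
    "leaf_path_matrix",
    "pairwise_distance",
]

_METRIC_NAMES = ("path_difference", "robinson_foulds")
_ALIASES = {"pd": "path_difference", "rf": "robinson_foulds"}


@dataclass(frozen=True)
class DistanceMetric:
    """A named metric plus whether consumers want squared values."""

    name: str = "path_difference"
    squared: bool = False

    def __post_init__(self) -> None:
        name = _ALIASES.get(self.name, self.name)
        if name not in _METRIC_NAMES:
            raise UsageError(
                f"unknown metric {self.name!r}; expected one of "
                f"{_METRIC_NAMES} (or aliases {tuple(_ALIASES)})"
            )
        object.__setattr__(self, "name", name)


PATH_DIFFERENCE = DistanceMetric("path_difference")
ROBINSON_FOULDS = DistanceMetric("robinson_foulds")


def _check_pair(t1: Topology, t2: Topology) -> None:
    if t1.leaf_labels != t2.leaf_labels:
        offending = sorted(
            set(t1.leaf_labels).symmetric_difference(t2.leaf_labels)
        )
        raise ContentError(
            f"trees have different leaf sets; offending labels: {offending}"
        )


def robinson_foulds(t1: Topology, t2: Topology) -> int:
    """Robinson–Foulds distance: splits present in exactly one tree.

    Zero iff the two topologies are identical; at most 2(n−3) for binary
    trees on n leaves.
    """
    _check_pair(t1, t2)
    return len(t1.splits() ^ t2.splits())


def path_difference(t1: Topology, t2: Topology) -> float:
    """Path difference: Euclidean distance between leaf-pair path vectors.

    Path lengths are edge counts, so the value reflects topology only. Zero
    iff the two trees induce identical leaf-pair path-length matrices.
    """
    _check_pair(t1, t2)
    diff = t1.leaf_path_vector() - t2.leaf_path_vector()
    return float(np.sqrt(np.dot(diff, diff)))


def leaf_path_matrix(t: Topology) -> np.ndarray:
    """Symmetric matrix of leaf-to-leaf path lengths (edge counts).

    Rows and columns are ordered by sorted leaf label, so matrices from
    trees on the same leaf set subtract elementwise.
    """
    return squareform(t.leaf_path_vector()).astype(int)


def pairwise_distance(
    t1: Topology, t2: Topology, metric: DistanceMetric = PATH_DIFFERENCE
) -> float:
    """Distance under ``metric``, squared when ``metric.squared`` is set."""
    if metric.name == "robinson_foulds":
        d = float(robinson_foulds(t1, t2))
    else:
        d = path_difference(t1, t2)
    return d * d if metric.squared else d
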