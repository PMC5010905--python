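"""Visual and model-based diagnostics of topology autocorrelation.

Two complementary views of a chain's behaviour in tree space:

* **Topology trace** — the distance of every sampled tree from one focal
  topology, against sample index. The tree-space analogue of a parameter
  trace: slow drifts and long flat stretches reveal poor mixing.
* **Jump distance profile** — the mean (and mean squared) distance between
  pairs of trees as a function of the sampling interval separating them.
  Uncorrelated samples give a flat profile; autocorrelated samples give a
  rising profile that may saturate at an asymptote. The interval at which
  the asymptote is reached estimates the topology autocorrelation time.

The saturating shape is modelled with an exponential semivariogram
``f(k) = D·(1 − exp(−k/a))``, fitted by least squares to the mean squared
distances; the fitted curve is used only to locate ``m``, the smallest
interval at which samples are treated as independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ContentError, UsageError
from .metrics import PATH_DIFFERENCE, DistanceMetric
from .topology import Topology, TreeSample

__all__ = [
    "DistanceTrace",
    "JumpProfile",
    "SemivariogramFit",
    "sampling_intervals",
    "pairs_at_lag",
    "topology_trace",
    "jump_profile",
    "distances_at_lag",
    "fit_semivariogram",
    "trace_plot_data",
    "jump_plot_data",
]

MAX_INTERVALS = 100


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class DistanceTrace:
    """Per-sample distance to a focal topology."""

    values: np.ndarray
    metric: DistanceMetric
    focal_index: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": np.arange(len(self.values)), "distance": self.values}
        )


@dataclass
class JumpProfile:
    """Mean and mean squared pairwise distance at each sampling interval."""

    intervals: np.ndarray
    mean_distance: np.ndarray
    mean_squared_distance: np.ndarray
    n_pairs: np.ndarray
    metric: DistanceMetric
    N: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": self.intervals,
                "n_pairs": self.n_pairs,
                "mean_distance": self.mean_distance,
                "mean_squared_distance": self.mean_squared_distance,
            }
        )


@dataclass
class SemivariogramFit:
    """Result of fitting f(k) = D·(1 − exp(−k/a)) to a jump profile.

    ``m`` is the smallest integer interval at which the fitted curve exceeds
    ``threshold·D`` — the interval from which samples are treated as
    independent. ``asymptote_reached`` is False when ``m`` lies beyond the
    largest profiled interval, in which case downstream consumers fall back
    to an upper-bound rule. ``status`` is ``"ok"``, ``"flat_zero"`` (all
    squared distances zero — no parameters to report) or ``"fit_failed"``.
    """

    D: float | None
    a: float | None
    m: int
    asymptote_reached: bool
    residual_norm: float
    status: str = "ok"
    threshold: float = 0.95


# ---------------------------------------------------------------------------
# interval and pair bookkeeping
# ---------------------------------------------------------------------------
def sampling_intervals(N: int) -> np.ndarray:
    """Sampling intervals 1..floor(N/10), capped at 100 distinct values.

    When floor(N/10) exceeds 100 the grid is thinned to exactly 100
    approximately evenly spaced integers that always include 1 and
    floor(N/10); the thinning is deterministic (rounded linspace).
    """
    if N < 20:
        raise UsageError(
            f"need at least 20 samples for a jump profile, got {N}"
        )
    kmax = N // 10
    if kmax <= MAX_INTERVALS:
        return np.arange(1, kmax + 1)
    grid = np.unique(np.round(np.linspace(1, kmax, MAX_INTERVALS)).astype(int))
    grid[0], grid[-1] = 1, kmax
    return grid


def pairs_at_lag(N: int, k: int) -> list[tuple[int, int]]:
    """All overlapping index pairs (i, i+k), 1-based, for i = 1..N−k."""
    if not 1 <= k < N:
        raise UsageError(f"lag k must satisfy 1 <= k < N, got k={k}, N={N}")
    return [(i, i + k) for i in range(1, N - k + 1)]


# ---------------------------------------------------------------------------
# distances along the chain
# ---------------------------------------------------------------------------
def _raw_distances_at_lag(
    sample: TreeSample, metric: DistanceMetric, k: int
) -> np.ndarray:
    if metric.name == "path_difference":
        v = sample.path_vectors()
        diff = v[k:] - v[:-k]
        return np.sqrt(np.einsum("ij,ij->i", diff, diff))
    splits = sample.split_sets()
    return np.array(
        [len(splits[i] ^ splits[i + k]) for i in range(len(splits) - k)],
        dtype=float,
    )


def distances_at_lag(
    sample: TreeSample, metric: DistanceMetric, k: int
) -> np.ndarray:
    """Distances over all overlapping pairs at sampling interval ``k``.

    Values are squared when ``metric.squared`` is set.
    """
    if not 1 <= k < sample.N:
        raise UsageError(f"lag k must satisfy 1 <= k < N, got k={k}, N={sample.N}")
    d = _raw_distances_at_lag(sample, metric, k)
    return d * d if metric.squared else d


def topology_trace(
    sample: TreeSample,
    focal: int | Topology,
    metric: DistanceMetric = PATH_DIFFERENCE,
) -> DistanceTrace:
    """Distance of every sampled tree from a focal topology.

    ``focal`` is either an index into the sample or an external topology on
    the same leaf set (an external focal tree avoids the start-tree artefact
    that makes traces anchored at the first sample look like burn-in).
    """
    focal_index: int | None
    if isinstance(focal, (int, np.integer)):
        if not 0 <= focal < sample.N:
            raise UsageError(f"focal index {focal} out of range for N={sample.N}")
        focal_index = int(focal)
        focal_topology = sample[focal_index]
    else:
        focal_index = None
        focal_topology = focal
        if focal_topology.leaf_labels != sample.leaf_labels:
            raise ContentError("focal tree leaf set differs from the sample's")
    if metric.name == "path_difference":
        v = sample.path_vectors()
        diff = v - focal_topology.leaf_path_vector()
        values = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    else:
        fs = focal_topology.splits()
        values = np.array([len(s ^ fs) for s in sample.split_sets()], dtype=float)
    if metric.squared:
        values = values**2
    return DistanceTrace(values=values, metric=metric, focal_index=focal_index)


def jump_profile(
    sample: TreeSample,
    metric: DistanceMetric = PATH_DIFFERENCE,
    intervals: Sequence[int] | None = None,
) -> JumpProfile:
    """Mean and mean squared pairwise distance at each sampling interval.

    Every overlapping pair (i, i+k) contributes at lag k; nothing is
    subsampled except the interval grid itself. Deterministic for a fixed
    sample.
    """
    N = sample.N
    if intervals is None:
        ks = sampling_intervals(N)
    else:
        ks = np.asarray(sorted(set(int(k) for k in intervals)), dtype=int)
        if ks.size == 0 or ks[0] < 1 or ks[-1] >= N:
            raise UsageError("intervals must be distinct integers in 1..N-1")
    mean_d = np.empty(ks.size)
    mean_sq = np.empty(ks.size)
    n_pairs = np.empty(ks.size, dtype=int)
    for j, k in enumerate(ks):
        d = _raw_distances_at_lag(sample, metric, int(k))
        mean_d[j] = d.mean()
        mean_sq[j] = np.mean(d * d)
        n_pairs[j] = d.size
    return JumpProfile(
        intervals=ks,
        mean_distance=mean_d,
        mean_squared_distance=mean_sq,
        n_pairs=n_pairs,
        metric=metric,
        N=N,
    )


# ---------------------------------------------------------------------------
# semivariogram fit
# ---------------------------------------------------------------------------
def _derive_m(a: float, threshold: float) -> int:
    # smallest integer k with 1 - exp(-k/a) >= threshold
    return max(1, math.ceil(-a * math.log1p(-threshold)))


def fit_semivariogram(
    profile: JumpProfile, asymptote_threshold: float = 0.95
) -> SemivariogramFit:
    """Least-squares fit of D·(1 − exp(−k/a)) to the mean squared distances.

    Initialisation is deterministic and scale-aware: D starts at the largest
    observed mean squared distance and a at the smallest interval whose
    value exceeds (1 − 1/e) of it. ``m`` follows from the fitted range:
    the smallest integer k whose fitted value reaches
    ``asymptote_threshold·D`` (0.95 by default, i.e. m = ceil(a·ln 20)).
    """
    if not 0 < asymptote_threshold < 1:
        raise UsageError("asymptote_threshold must lie strictly in (0, 1)")
    k = np.asarray(profile.intervals, dtype=float)
    y = np.asarray(profile.mean_squared_distance, dtype=float)
    if k.size < 2:
        raise UsageError("need at least 2 profiled intervals to fit")
    kmax = int(profile.intervals.max())
    if np.all(y == 0):
        return SemivariogramFit(
            D=None,
            a=None,
            m=1,
            asymptote_reached=True,
            residual_norm=0.0,
            status="flat_zero",
            threshold=asymptote_threshold,
        )
    d0 = float(y.max())
    over = k[y >= (1.0 - math.exp(-1.0)) * d0]
    a0 = float(over.min()) if over.size else 1.0

    def resid(theta: np.ndarray) -> np.ndarray:
        D, a = theta
        return D * (1.0 - np.exp(-k / a)) - y

    try:
        res = least_squares(
            resid,
            x0=np.array([d0, a0]),
            bounds=(np.array([1e-12, 1e-12]), np.array([np.inf, np.inf])),
            ftol=1e-8,
            xtol=1e-12,
            gtol=1e-12,
        )
        ok = res.success and np.all(np.isfinite(res.x))
    except Exception:
        ok = False
    if not ok:
        return SemivariogramFit(
            D=None,
            a=None,
            m=kmax + 1,
            asymptote_reached=False,
            residual_norm=float("nan"),
            status="fit_failed",
            threshold=asymptote_threshold,
        )
    D_hat, a_hat = (float(x) for x in res.x)
    m = _derive_m(a_hat, asymptote_threshold)
    return SemivariogramFit(
        D=D_hat,
        a=a_hat,
        m=m,
        asymptote_reached=m <= kmax,
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        status="ok",
        threshold=asymptote_threshold,
    )


# ---------------------------------------------------------------------------
# plot-ready tables
# ---------------------------------------------------------------------------
def trace_plot_data(
    trace: DistanceTrace | Mapping[str, DistanceTrace],
) -> pd.DataFrame:
    """Long-format table for a topology trace plot.

    A single trace gives columns (generation, distance); a mapping of
    chain-name → trace (traces sharing one focal tree) gives the overlay
    table (chain, generation, distance) used for convergence assessment.
    """
    if isinstance(trace, DistanceTrace):
        return trace.to_frame()
    frames = []
    for chain, tr in trace.items():
        df = tr.to_frame()
        df.insert(0, "chain", chain)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def jump_plot_data(profile: JumpProfile) -> pd.DataFrame:
    """Table of (interval, mean_distance) for a jump distance plot."""
    return pd.DataFrame(
        {"interval": profile.intervals, "mean_distance": profile.mean_distance}
    )
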