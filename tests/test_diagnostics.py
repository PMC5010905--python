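"""Topology traces, jump profiles, and the semivariogram fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import topoess as tp
from topoess.diagnostics import JumpProfile

PD = tp.PATH_DIFFERENCE
RF = tp.ROBINSON_FOULDS


# ---------------------------------------------------------------------------
# sampling intervals and lag pairs
# ---------------------------------------------------------------------------
def test_intervals_small_n():
    assert list(tp.sampling_intervals(50)) == [1, 2, 3, 4, 5]
    assert list(tp.sampling_intervals(20)) == [1, 2]


def test_intervals_exactly_100_for_n_1000():
    ks = tp.sampling_intervals(1000)
    assert len(ks) == 100
    assert ks[0] == 1 and ks[-1] == 100


def test_intervals_subsampled_above_100():
    ks = tp.sampling_intervals(5000)
    assert len(ks) == 100
    assert ks[0] == 1 and ks[-1] == 500
    assert np.all(np.diff(ks) > 0)


def test_intervals_reject_tiny_samples():
    with pytest.raises(tp.UsageError):
        tp.sampling_intervals(19)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(min_value=20, max_value=50000))
def test_interval_grid_properties(n):
    ks = tp.sampling_intervals(n)
    assert ks[0] == 1
    assert ks[-1] == n // 10
    assert len(ks) == min(100, n // 10)
    assert np.all(np.diff(ks) > 0)


def test_pairs_at_lag_worked_example():
    assert tp.pairs_at_lag(5, 2) == [(1, 3), (2, 4), (3, 5)]
    assert tp.pairs_at_lag(5, 4) == [(1, 5)]
    assert len(tp.pairs_at_lag(1000, 1)) == 999


def test_pairs_at_lag_rejects_bad_lags():
    with pytest.raises(tp.UsageError):
        tp.pairs_at_lag(5, 5)
    with pytest.raises(tp.UsageError):
        tp.pairs_at_lag(5, 0)


# ---------------------------------------------------------------------------
# topology traces
# ---------------------------------------------------------------------------
def test_trace_toy_values(quartets):
    t_ab, t_ac, _ = quartets
    sample = tp.TreeSample([t_ab, t_ab, t_ac])
    trace = tp.topology_trace(sample, 0, RF)
    assert list(trace.values) == [0.0, 0.0, 2.0]
    assert trace.focal_index == 0


def test_trace_zero_at_focal_and_flat_for_identical(identical_sample):
    trace = tp.topology_trace(identical_sample, 7, PD)
    assert np.all(trace.values == 0)
    trace2 = tp.topology_trace(identical_sample, 0, RF)
    assert trace2.values[0] == 0


def test_trace_external_focal(quartets):
    t_ab, t_ac, _ = quartets
    sample = tp.TreeSample([t_ab, t_ab])
    trace = tp.topology_trace(sample, t_ac, RF)
    assert list(trace.values) == [2.0, 2.0]
    assert trace.focal_index is None


def test_trace_focal_leaf_set_mismatch(quartets):
    t_ab, _, _ = quartets
    other = tp.topology_from_newick("((A,B),(C,X));")
    with pytest.raises(tp.ContentError):
        tp.topology_trace(tp.TreeSample([t_ab]), other, RF)


def test_trace_squared_metric(quartets):
    t_ab, t_ac, _ = quartets
    sample = tp.TreeSample([t_ab, t_ac])
    sq = tp.DistanceMetric("rf", squared=True)
    assert list(tp.topology_trace(sample, 0, sq).values) == [0.0, 4.0]


# ---------------------------------------------------------------------------
# jump profiles
# ---------------------------------------------------------------------------
def test_jump_profile_identical_trees(identical_sample):
    prof = tp.jump_profile(identical_sample, PD)
    assert np.all(prof.mean_distance == 0)
    assert np.all(prof.mean_squared_distance == 0)


def test_jump_profile_pair_counts(sticky_sample):
    prof = tp.jump_profile(sticky_sample, PD)
    assert np.array_equal(prof.n_pairs, sticky_sample.N - prof.intervals)


def test_jump_profile_reversal_invariance(sticky_sample):
    prof = tp.jump_profile(sticky_sample, RF)
    rev = tp.TreeSample(list(sticky_sample)[::-1])
    prof_rev = tp.jump_profile(rev, RF)
    assert np.allclose(prof.mean_distance, prof_rev.mean_distance)
    assert np.allclose(
        prof.mean_squared_distance, prof_rev.mean_squared_distance
    )


def test_jump_profile_jensen_inequality(sticky_sample):
    prof = tp.jump_profile(sticky_sample, PD)
    assert np.all(prof.mean_squared_distance >= prof.mean_distance**2 - 1e-9)


def test_autocorrelated_chain_profile_rises(sticky_sample):
    prof = tp.jump_profile(sticky_sample, PD)
    assert prof.mean_distance[0] < prof.mean_distance[9]
    slope = np.polyfit(prof.intervals, prof.mean_distance, 1)[0]
    assert slope > 0


def test_iid_chain_profile_is_flat():
    # relative drift of the fitted line across the profile stays tiny
    drifts = []
    for seed in range(5):
        s = tp.simulate_bimodal(
            tp.BimodalSpec(n_taxa=20, n_samples=400, switch_prob=0.5, seed=seed)
        )
        prof = tp.jump_profile(s, PD)
        slope = np.polyfit(prof.intervals, prof.mean_distance, 1)[0]
        drifts.append(slope * prof.intervals.max() / prof.mean_distance.mean())
    assert abs(np.median(drifts)) < 0.05


# ---------------------------------------------------------------------------
# semivariogram fit
# ---------------------------------------------------------------------------
def _synthetic_profile(D, a, kmax=100):
    k = np.arange(1, kmax + 1)
    y = D * (1 - np.exp(-k / a))
    return JumpProfile(
        intervals=k,
        mean_distance=np.sqrt(y),
        mean_squared_distance=y,
        n_pairs=np.full(k.size, 1000) - k,
        metric=PD,
        N=1000,
    )


@pytest.mark.parametrize(
    "D,a", [(100.0, 5.0), (10.0, 0.5), (1e4, 50.0), (500.0, 12.0)]
)
def test_semivariogram_recovers_noiseless_parameters(D, a):
    fit = tp.fit_semivariogram(_synthetic_profile(D, a))
    assert fit.status == "ok"
    assert fit.D == pytest.approx(D, rel=0.01)
    assert fit.a == pytest.approx(a, rel=0.01)
    assert fit.m == max(1, math.ceil(a * math.log(20)))


def test_semivariogram_flat_profile_gives_m_1(iid_sample):
    prof = tp.jump_profile(iid_sample, PD)
    fit = tp.fit_semivariogram(prof)
    assert fit.status == "ok"
    assert fit.m == 1
    assert fit.asymptote_reached


def test_semivariogram_unsaturated_profile_flags_no_asymptote():
    fit = tp.fit_semivariogram(_synthetic_profile(1000.0, 300.0))
    assert fit.status == "ok"
    assert not fit.asymptote_reached
    assert fit.m > 100


def test_semivariogram_all_zero_profile_is_distinguished(identical_sample):
    prof = tp.jump_profile(identical_sample, PD)
    fit = tp.fit_semivariogram(prof)
    assert fit.status == "flat_zero"
    assert fit.D is None and fit.a is None
    assert fit.m == 1


def test_semivariogram_threshold_validated(sticky_sample):
    prof = tp.jump_profile(sticky_sample, PD)
    with pytest.raises(tp.UsageError):
        tp.fit_semivariogram(prof, asymptote_threshold=1.0)


# ---------------------------------------------------------------------------
# plot tables
# ---------------------------------------------------------------------------
def test_trace_plot_table_shapes(sticky_sample):
    trace = tp.topology_trace(sticky_sample, 0, PD)
    df = tp.trace_plot_data(trace)
    assert len(df) == sticky_sample.N
    assert list(df.columns) == ["generation", "distance"]


def test_trace_overlay_table_has_chain_column(sticky_sample, iid_sample):
    focal = sticky_sample[0]
    traces = {
        "a": tp.topology_trace(sticky_sample, 0, PD),
        "b": tp.topology_trace(sticky_sample, 1, PD),
    }
    df = tp.trace_plot_data(traces)
    assert list(df.columns) == ["chain", "generation", "distance"]
    assert set(df["chain"]) == {"a", "b"}
    assert len(df) == 2 * sticky_sample.N


def test_jump_plot_table_rows(sticky_sample):
    prof = tp.jump_profile(sticky_sample, PD)
    df = tp.jump_plot_data(prof)
    assert len(df) == len(prof.intervals)
    assert list(df.columns) == ["interval", "mean_distance"]
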