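# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `topoess`.

## The object being estimated

A Bayesian phylogenetic MCMC yields an ordered sample x₁ … x_N of tree
topologies. Sequential samples are autocorrelated, so the sample carries
the information of fewer than N independent draws; that number is the
effective sample size (ESS). Topologies are not continuous parameters, so
the spectral ESS used for continuous traces cannot be applied directly.
Both estimators here reduce the problem to topological distances, with
branch lengths discarded (they are continuous and can be assessed with
conventional tools).

### Distance metrics

* **Robinson–Foulds (RF)**: the number of non-trivial splits
  (bipartitions induced by internal edges) present in exactly one of the
  two trees. Integer-valued, bounded by 2(n−3) on binary n-taxon trees.
* **Path difference (PD)**: each tree is encoded as the vector of
  leaf-pair path lengths counted in edges; PD is the Euclidean distance
  between the two vectors. Zero iff the path-length matrices coincide.

PD is the default metric. RF takes few distinct values and saturates at
its maximum between even moderately dissimilar trees; whenever distinct
tree pairs collapse onto one distance value, autocorrelation is
overestimated and the ESS underestimated. PD discriminates far more pairs
and is therefore preferred for ESS work; RF remains available because it
is cheaper and ubiquitous.

Internally a `TreeSample` caches one split set (bitmask set) and one
path-length vector per tree, deduplicated across topologically identical
trees, so all lag and trace computations are vectorised array operations.

## Diagnostics

**Topology trace.** The distance of every sampled tree from one focal
topology against sample index. The focal tree is by default a uniformly
drawn member of the sample (seeded). Anchoring the trace at the *first*
tree makes the initial segment rise from zero even in a perfectly
stationary chain — an artefact of the focal choice, not burn-in; an
external focal topology (e.g. an independently estimated tree) avoids
this. A trace can be flat yet hide structure if two sampled modes happen
to be equidistant from the focal tree; plotting several traces with
different focal trees guards against this false negative.

**Jump distance profile.** For sampling intervals k the mean (and mean
squared) distance over all N−k overlapping pairs (xᵢ, xᵢ₊ₖ). Intervals
run 1 … ⌊N/10⌋; if that exceeds 100 the grid is thinned deterministically
(rounded linspace, endpoints forced) to exactly 100 distinct integers. No
pair subsampling is done — every overlapping pair at a profiled lag
contributes. For an uncorrelated chain the profile is flat; under
autocorrelation it rises and, if the chain is long enough relative to its
autocorrelation time, saturates at an asymptote.

**Semivariogram fit.** The mean squared distances are fitted with the
range form of the exponential semivariogram

    f(k) = D · (1 − exp(−k/a)),   D > 0, a > 0,

by bounded least squares (`scipy.optimize.least_squares`, ftol 1e−8).
The range form is used so that a is expressed in units of sampling
intervals (the rate form e^(−k·a) is the same family under a ↦ 1/a).
Initialisation is deterministic and scale-aware: D₀ is the largest
observed mean squared distance, a₀ the smallest interval whose value
exceeds (1−1/e)·D₀ (1 if none). From the fit, the independence lag is

    m = max(1, ceil(−a · ln(1 − θ))),   θ = 0.95 by default,

the smallest integer lag at which the fitted curve reaches θ·D. The
threshold θ is an operational choice — "asymptote reached" has no unique
definition for an exponential — and is exposed as a parameter
(`asymptote_threshold`). With θ = 0.95, m = ⌈a·ln 20⌉. A profile that is
identically zero (all sampled trees identical) is reported as a
distinguished `flat_zero` status rather than a degenerate fit, and a fit
whose m exceeds the largest profiled interval sets
`asymptote_reached = False`.

## Pseudo-ESS

Convert the topologies to a continuous trace (distance to a focal tree)
and apply the standard univariate estimator: ESS = N·Var(x)/S(0), with
S(0) the spectral density at frequency zero from an autoregressive fit.
The AR machinery is a Levinson–Durbin recursion over Yule–Walker
solutions (biased autocovariances, FFT), order chosen by AIC over
0 … min(N−1, ⌊10·log₁₀N⌋) — the estimator family standard in MCMC
diagnostics. A constant trace returns N with a `FlatTraceWarning`: flat
traces are uninformative, not evidence of independence.

Because the focal tree is arbitrary — and replicate estimates can differ
by an order of magnitude on badly mixed chains — the calculation is
repeated for `n_replicates = 100` focal trees drawn *without replacement*
(duplicated focal trees would waste replicates; requesting more
replicates than trees is an error). The reported value is the replicate
median with the 2.5%/97.5% percentiles as a 95% interval; focal indices
are recorded for reproducibility. Pseudo-ESS values are not clamped to N
(sampling noise can push the AR estimate above N); values above N are
annotated with an `exceeds_n` flag.

## Approximate-ESS

For M independent draws from the posterior, the M(M−1)/2 unordered pairs
each have expected squared distance D, giving a normalised expected
squared distance of M(M−1)D/(4M²) = (M−1)D/(4M). Equating this with the
same quantity computed from the autocorrelated chain of N samples gives

    (M−1)/(4M) = r,
    r = [ Σᵢ₌₁^{N−1} Σₖ₌₁^{min(m−1, N−i)} f(k) + (N−m+1)(N−m)/2 · D ]
        / (2N²D),

and M = 1/(1 − 4r). Each of the N−k pairs at lag k < m contributes the
empirical f(k) (the mean squared distance over all pairs at that lag,
computed on demand for lags the thinned profile skipped); each of the
(N−m+1)(N−m)/2 pairs at lag ≥ m contributes D, estimated as the
pair-count-weighted mean of the profiled mean squared distances at lags
≥ m. The fitted semivariogram is used *only* to locate m; f(k) and D are
empirical. To leading order in 1/N,

    M ≈ N / (1 + 2·Σₖ₌₁^{m−1} (1 − f(k)/D)),

i.e. the classical N over the integrated autocorrelation time with
ρₖ = 1 − f(k)/D playing the role of the lag-k autocorrelation. One
derivation detail is deliberate: the double sum runs to min(m−1, N−i),
so that pairs at lag exactly m are counted once (in the D term). Running
it to min(m, N−i) double-counts the N−m lag-m pairs and flips the
denominator to 2Σρ − 1, an estimator that diverges (and must be clamped
to N) whenever Σρ < ½ — inconsistent with the estimator's own
independent-sample limit. With the single count, m = 1 yields
r = (N−1)/(4N) and M = N *exactly*: a chain whose samples are already
independent at lag 1 reports the full sample size.

Numerical guards: M is clamped to [1, N] (r ≥ ¼ is the
independent/over-dispersed regime and maps to N; r ≤ 0 maps to 1). If the
profile never saturates (m beyond the largest profiled lag, or the fit
fails), D is replaced by the largest observed mean squared distance, m is
capped at the largest profiled interval, and the result carries
`is_upper_bound = True`: underestimating D inflates M, so the true ESS
lies below the reported value. An all-identical sample reports N with a
`flat_sample` flag, mirroring the flat-trace convention.

Because m is an integer, the approximate-ESS moves in discrete jumps as
mixing degrades continuously (between jumps the value is constant in m);
this granularity matters only near ESS ≈ N, far above any decision
threshold in practice.

## Chain simulators

There is no way to simulate a phylogenetic MCMC with a *known* topology
ESS, so validation uses chains whose mixing varies predictably. Defaults
are the validation design: 50 taxa, N = 1000 samples.

**Random topologies** are grown by sequential random leaf attachment
(uniform edge choice per leaf), labelled t1 … tn — near-uniform over
binary unrooted topologies and fully seeded.

**SPR moves.** A rearrangement is indexed by an unordered pair of
internal nodes: adjacent pairs carry the two NNI rearrangements of their
shared edge; pairs at distance ≥ 2 carry eight subtree-transfer
rearrangements (2 role orientations × 2 prunable subtrees at one node ×
2 regraft edges at the other). A move draws the pair with weight 2 if
adjacent else 8, then a uniform rearrangement within the pair — the
weighting of the standard random-SPR kernel in phylogenetic
tree-rearrangement libraries, which favours long-range transfers and is
what gives small tree spaces their fast per-move mixing. The move never
returns the identical topology.

**Unimodal chains** apply a fixed number of SPR moves between successive
samples; more moves per step means less autocorrelation ("an MCMC without
sequence data").

**Bimodal chains** build two sets of `set_size = 10` trees: set 1 from a
random seed tree plus satellites one SPR move away, set 2 identically
around a seed 50 SPR moves from set 1's seed. The chain starts in set 1
and at each step switches sets with probability `switch_prob` (then draws
uniformly, with replacement, from the current set). `switch_prob` is the
probability of *switching*: at 0 the chain never leaves set 1 — sampling
i.i.d. from one mode, indistinguishable from perfect unimodal mixing —
and at 0.5 set membership is a fair coin. Within-set draws are uniform
with replacement; nothing excludes immediate repeats.

What the simulators do *not* emulate: likelihood-driven acceptance (no
sequence data), branch lengths, heated chains, or the long-tailed
proposal mixtures of real samplers. Passing tests on these chains shows
the estimators respond correctly to autocorrelation injected through the
sampling process; it does not certify behaviour on posteriors with
structure the simulators cannot express (e.g. many overlapping modes).

## Validation conditions and problem sizes

The test suite exercises, among others: exact hand-derived quartet
distances (RF 2, PD 2.0); equivalence of both metrics with brute-force
graph oracles on trees of ≤ 7 leaves; semivariogram parameter recovery
within 1% on noiseless profiles; equality of the collapsed r computation
with a literal double loop over chain indices (≤ 1e−9) on 200-sample
chains; monotone non-decreasing median ESS (5 seeds per point, N = 1000,
50 taxa, path differences) across both the SPR sweep {1, 2, 5, 10, 20,
50} and the switch-probability sweep {0.01, 0.1, 0.2, 0.3, 0.4, 0.5};
agreement of the approximate-ESS with the pseudo-ESS 95% interval in most
of those regimes; and the two saturation designs (bimodal switch 0 and
unimodal 5-taxon) returning the full sample size. Chain lengths in the
heavier sweeps are the full N = 1000 of the validation design; smaller
fixtures (N = 120–400, 10–20 taxa) are used where the property under
test does not depend on chain length.

## Known limitations

* The pseudo-ESS is only as small as the most discriminating focal tree
  it happens to draw; it is an upper-bound-ish heuristic, and large
  values deserve caution.
* Both estimators presuppose a *mixed* chain: the approximate-ESS reads
  autocorrelation off the jump profile, which a chain stuck in one mode
  renders flat. Inspect the topology trace first; an unvisited mode is
  invisible to every within-chain diagnostic.
* The asymptote threshold θ = 0.95 is a convention; m (and hence the
  approximate-ESS) is piecewise constant in it.
* RF-based estimates are systematically smaller than PD-based ones; the
  metric, not the chain, is usually the cause.
* Multi-chain pooling (combining replicate analyses before estimating a
  joint ESS) is out of scope; run the estimators per chain and compare
  traces with a shared focal tree instead.
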