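# Methods

## Observation model and objective

A measurement `y ∈ R^N` is modelled as `K` shifted copies of a known
template `x ∈ R^L` plus i.i.d. Gaussian noise of variance σ². Occurrence
locations are 0-based **left edges**; an occurrence at `m` occupies the
half-open window `[m, m+L)`, so valid edges lie in `[0, N−L]`. Two
separation regimes are modelled: *arbitrary* spacing (pairwise gaps ≥ L —
windows merely do not overlap) and *well separated* (gaps ≥ 2L).

With the template, noise level and count known, maximum-likelihood
estimation of the locations reduces to least squares and hence to maximizing
the sum of matched-filter scores `c[m] = ⟨y[m:m+L], x⟩` over K separated
left edges. We index correlations by left edge rather than window center:
a center convention with half-width `⌊L/2⌋` gives windows of `2⌊L/2⌋+1`
samples, which is wrong by one for even L, whereas the left-edge window has
exactly L samples for all L and matches the generative model directly.

## The dynamic program

Let `g[n, j]` be the best objective over `j` windows fully contained in the
prefix `y[0:n]`. A window ending at prefix position `n` has left edge
`n − L`, and the remaining `j−1` windows must fit in `y[0:n−L]`, giving

    g[n, j] = max( g[n−1, j],  g[n−L, j−1] + c[n−L] ),

with `g[·, 0] = 0` and `g[n, j] = −∞` for `n < jL`. The step back of a full
L in the count-decremented term is what enforces the non-overlap constraint
exactly; stepping back only half a window would admit overlapping
placements, and the implementation is adjudicated against a brute-force
enumeration of the constrained objective rather than against any particular
recursion notation. Boundary handling is implicit in the valid edge range
`[0, N−L]`; states with `n < jL` are infeasible (−∞), which also reproduces
the "no signal near the ends" rule.

Each column of the table is a running maximum over "place a window ending
here" candidates, so filling it is K vectorized passes of length N —
`O(NK)` after the `O(N log N)` FFT correlation, i.e. `O(N·max(K, log N))`
overall. Backtracking prefers the "do not place" branch on exact ties,
yielding the left-most optimal configuration deterministically.

Semantics are **exactly K**: the program places K windows even when marginal
scores are negative, faithful to the constrained likelihood. An opt-in
`at_most=True` flag instead returns the argmax over the objective curve
`g(N, j)`, j = 0..K.

Floating-point: the FFT correlation is required to agree with direct
summation to 1e−9 relative (tested); given the correlation vector the DP is
exact, and the DP-vs-enumeration tests assert *bitwise equal* objectives
because both consume the same correlation vector and add scores in the same
(ascending-location) order.

## Baselines

**Greedy** (non-maximum suppression): repeatedly take the largest feasible
correlation score, suppressing all edges within L; ties break toward the
smaller index. In dense regimes greedy can exhaust feasible candidates
before placing K; it then returns the partial set flagged `complete=False`,
which benchmarks score as missed detections — mirroring how practical
pickers behave rather than raising.

**Random placement** uses the simulator's rejection procedure and serves as
the F1 floor.

**Convex ℓ1 deconvolution**: the clean measurement is `Gᵀs` with `G` the
circulant matrix whose row i is the template shifted by i, and `s ∈ {0,1}^N`
an indicator of left edges. Relaxing to the box `[0,1]` gives

    min ‖s‖₁  s.t.  ‖y − Gs‖₂² ≤ δ = 1.2·N·σ²,  0 ≤ s ≤ 1.

We solve it with a homotopy solver written for this package: on the box the
ℓ1 term is linear, so for each penalty weight μ the problem
`min ½‖y−Gs‖² + μ·Σs` over the box is solved by FISTA with a clip prox, and
the KKT conditions of the constrained program coincide with the penalized
one at `μ = 1/(2λ)`. Since the residual is nondecreasing in μ, bisection on
μ (60 steps, warm-started) lands on the constraint boundary. Feasibility is
accepted at 1e−6 slack; recovery assertions in tests use 1e−4. Note that
with δ = 1.2Nσ² the program is *genuinely infeasible* on a noticeable
fraction of draws (the noise energy ~ σ²·χ²_N exceeds δ with probability
≈ 11% at N = 75): the solver raises an explicit error and the benchmark
scores the trial as zero detections for this method, reporting the failure
count. Peak-picking on the denoised `s` uses its raw values (it is already
the location indicator) restricted to non-wrapping edges `[0, N−L]`, with
the same greedy suppression at separation L.

## Gap-statistic model order selection

`g(N, K)` is nondecreasing in K and its growth flattens beyond the true
count. The null reference is obtained by uniformly permuting `y` (the value
multiset is kept, embedded signals are destroyed) P times and averaging the
per-K objective; the estimator selects the first maximizer of
`gap(K) = g(N,K) − mean_i g_i(N,K)`. The sign is chosen so the gap is
nonnegative in expectation and peaks near the true K — the geometry of the
"maximal gap between the two curves". Defaults: P = 50 permutations;
`Kmax = ⌊N/L⌋` (the largest feasible count, presuming nothing about the
truth); per-permutation RNG streams are spawned from one master seed so the
result is independent of evaluation order. The greedy analogue substitutes
the cumulative greedy score (one run at Kmax suffices, since greedy's picks
are nested; if it runs out of feasible picks the curve stays flat).

## Simulator

Placement is rejection sampling exactly as the study protocol describes:
the first left edge is uniform on `[0, N−L]`; each subsequent uniform
proposal is accepted iff it is ≥ L (arbitrary) or ≥ 2L (well separated) from
every accepted edge. Caps of 1,000 proposals per placement and 100 restarts
prevent non-termination near maximal packing. The default template is the
rectangular pulse of L ones. Noise is i.i.d. `N(0, σ²)` from numpy's PCG64,
reproducible across platforms for a fixed seed.

What the simulator does *not* emulate about real micrograph stripes:
occurrence-to-occurrence shape variability, colored noise (handled
separately by the whitening step, and generated only in whitening tests as
an AR(1) fixture), and contrast effects. Passing synthetic benchmarks
therefore demonstrates correctness of the estimator under its stated model,
not end-to-end performance on real 2D data.

## Evaluation

A detection matches a truth when `|n̂ − n| < L/2`, strict (for odd L on
integers this is `≤ ⌊L/2⌋`). Matching is one-to-one and maximum-cardinality
so duplicates cannot inflate precision: candidate pairs are seeded greedily
by increasing |difference| (deterministic tie-breaks) and completed with
augmenting paths. When both lists are L-separated every node has degree ≤ 1
and the seed is already maximal; augmentation matters for misspecified
detectors whose detections are more closely spaced. Precision is defined 0
when nothing is detected; F1 is 0 when precision + recall = 0. In the
unknown-template-length experiments the matching tolerance uses the *true*
L (evaluation should not depend on the detector's misspecification); a flag
exposes the alternative. Count error is `|K̂/K − 1|`.

## Whitening

The noise PSD is estimated from a manually identified signal-free region
with Welch's method (half-overlapping segments of length min(256, region
length), converted to the two-sided density so white noise of variance v
has PSD ≈ v), interpolated onto the measurement's rFFT grid, floored at
1e−6 of its maximum (floored bins logged), and the measurement's spectrum
divided by its **square root**, so output noise is approximately white with
unit variance — which is what the downstream Gaussian-likelihood detector
assumes. The literal division by the power spectrum itself is available as
`power=True`/`--whiten-power`. MRC micrograph reading is behind an optional
import; stripe extraction operates on any 2D array.

## Benchmark scale and numerical choices

Default benchmark scale is 300 trials per grid point for the known-K and
misspecified-L sweeps (noise grid σ² ∈ {0.5, 1, 2}), 100 trials for the
gap-statistic, scaling and convex studies — chosen as the package's
desk-scale default giving mean-F1 standard errors well under 0.01; a flag
raises it. The scaling study fixes occupancy `K·L/N = 0.6` with L = 20 and
σ² = 0.5, a mid-range noise level from the sweeps above, and estimates K per
trial with `Kmax = ⌊N/L⌋`. The runtime check fixes K = 6, L = 30 and varies
N over 10³–10⁵, the regime where the `O(N·max(K, log N))` bound predicts
near-linear growth.

Known limitations: 1D only (no 2D picking), single known template per
measurement (no shape heterogeneity), integer-grid shifts only, and the
exactly-K program requires a feasible K (`K·L ≤ N`).
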