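# sigdp

Exact detection of non-overlapping signal occurrences in noisy 1D
measurements, by dynamic programming.

## The problem

A measurement `y ∈ R^N` contains `K` shifted copies of a known template
`x ∈ R^L` plus white Gaussian noise:

```
y[n] = Σ_{k=1..K} x[n − n_k] + ε[n],    ε[n] ~ N(0, σ²) i.i.d.
```

The unknown left-edge locations `n_k` satisfy a separation condition: the
occurrences do not overlap (`|n_i − n_j| ≥ L`), or in the easier regime are
well separated (`≥ 2L`). This is the 1D analogue of particle picking in
cryo-electron microscopy, where densely packed, low-SNR particle projections
must be located in a micrograph before 3D reconstruction.

Maximizing the Gaussian likelihood under the separation constraint is
equivalent to

```
max_{n̂_1..n̂_K}  Σ_k ⟨ y[n̂_k : n̂_k+L] , x ⟩    s.t.  |n̂_i − n̂_j| ≥ L,
```

i.e. choosing K matched-filter (cross-correlation) scores whose windows do
not overlap. The classical greedy picker — take the largest correlation
peak, suppress everything within L, repeat — is optimal when occurrences are
far apart but fails in dense regimes. `sigdp` solves the constrained program
*exactly* with a dynamic program over prefixes:

```
g[n, j] = max( g[n−1, j],  g[n−L, j−1] + c[n−L] ),
```

where `c[m]` is the correlation score at left edge `m` and `g[n, j]` is the
best objective for `j` windows inside the first `n` samples. The table costs
`O(NK)` after one `O(N log N)` FFT correlation, and backtracking recovers the
optimal locations.

The package also provides:

- a **gap-statistic** estimator of the unknown occurrence count `K`: the
  objective curve `g(N, K)` is compared against its average over `P`
  random permutations of `y` (a signal-free null with the same value
  multiset); the selected `K̂` maximizes `g(N,K) − mean_i g_i(N,K)`;
- **baselines**: the greedy picker, uniform random placement, and an ℓ1
  sparse-deconvolution program `min ‖s‖₁ s.t. ‖y − Gs‖² ≤ 1.2Nσ²,
  0 ≤ s ≤ 1` over the circulant shift matrix `G`;
- a **simulator** reproducing the observation model in both separation
  regimes, an **evaluation** module (one-to-one matching within `L/2`,
  precision/recall/F1, count error `|K̂/K − 1|`), **noise whitening** from a
  signal-free region, and a reproducible **benchmark runner**.

## Worked example

```python
import numpy as np
from sigdp import (SimulationConfig, synthesize, rectangular_template,
                   dp_detect, greedy_detect, estimate_k, score)

cfg = SimulationConfig(n=300, l=30, k=6, sigma2=1.0, mode="arbitrary", seed=42)
y = synthesize(cfg)                      # measurement with ground truth attached
x = rectangular_template(30)             # square pulse of 30 ones

dp = dp_detect(y, x, 6)
print(list(y.truth))                     # [24, 54, 118, 177, 209, 264]
print(list(dp.locations))                # [24, 55, 115, 177, 209, 265]
print(round(dp.objective, 1))            # 176.1
print(score(y.truth, dp.locations, 30).f1)   # 1.0  (all within the L/2 tolerance)

gc = estimate_k(y, x, k_max=10, p=50, seed=0)    # K unknown
print(gc.k_hat)                          # 6
```

Every detection is within the `|n̂ − n| < L/2` matching tolerance, so the F1
score is 1.0 even though individual edges are off by a few samples at σ²=1.
The gap curve rises until `K = 6` and falls after, so the permutation-null
estimator recovers the true count.

Where the exact program earns its keep is dense conflicts. On the toy
measurement `y = [5, 9, 5, 0]` with template `[1, 0]` and `K = 2`, greedy
grabs the single biggest peak (score 9) and then has nowhere feasible left,
while the dynamic program pairs the two flanking peaks:

```python
det, trace = greedy_detect([5, 9, 5, 0], [1, 0], 2)
print(list(det.locations), det.objective, det.complete)   # [1] 9.0 False
dp = dp_detect([5, 9, 5, 0], [1, 0], 2)
print(list(dp.locations), dp.objective)                    # [0, 2] 10.0
```

The same is available from a shell:

```
sigdp simulate --n 300 --l 30 --k 6 --sigma2 1 --seed 42 --out y.csv --truth-out truth.json
sigdp detect --measurement y.csv --rect-l 30 --method dp --k 6 --out det.json
sigdp evaluate --truth truth.json --pred det.json
sigdp benchmark --experiment dense-known-k --trials 300 --seed 0 --out results.csv
```

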