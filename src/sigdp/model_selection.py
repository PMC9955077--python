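"""Estimating the number of signal occurrences via the gap statistic.

The constrained-likelihood objective g(N, K) is monotonically nondecreasing
in K; its growth flattens once K exceeds the true occurrence count, because
further placements only collect noise correlations. The gap statistic makes
that knee detectable by standardizing the curve against a null reference:
permute the samples of y (which destroys any embedded signals while keeping
the value multiset) P times, compute the objective curve on each permuted
copy, and compare

    gap(K) = g(N, K) - mean_i g_i(N, K).

On real data the objective outruns the null up to the true K and then grows
at the null's rate, so the gap is maximized near the true count. K-hat is
the first K attaining the maximal gap.

The same construction applies to the greedy detector with its cumulative
peak score in place of the exact objective.
"""

from __future__ import annotations

import numpy as np

from .baselines import greedy_objective_curve
from .detect import dp_objective_curve
from .types import GapCurve, InfeasibleInputError, Measurement, as_measurement, as_template

__all__ = ["permute_measurement", "estimate_k"]


def permute_measurement(y, rng: np.random.Generator) -> Measurement:
    """Uniformly permute the samples of y; the value multiset is preserved
    exactly, and any embedded signal structure is destroyed."""
    y = as_measurement(y)
    return Measurement(samples=rng.permutation(y.samples))


_CURVES = {
    "dp": dp_objective_curve,
    "greedy": greedy_objective_curve,
}


def estimate_k(
    y,
    x,
    k_max: int,
    p: int = 50,
    seed: int | np.random.SeedSequence | None = None,
    detector: str = "dp",
) -> GapCurve:
    """Gap-statistic estimate of the number of occurrences.

    Parameters
    ----------
    y, x
        Measurement and template.
    k_max
        Largest candidate count; must satisfy ``k_max * L <= N``.
    p
        Number of permutation-null replicates (default 50).
    seed
        Master seed; per-permutation streams are spawned from it, so the
        result does not depend on evaluation order.
    detector
        'dp' for the exact objective curve, 'greedy' for the cumulative
        greedy score.

    Returns
    -------
    GapCurve
        Real and null curves, their gap, and the selected k_hat (first
        maximizer on ties).
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if detector not in _CURVES:
        raise ValueError(f"unknown detector {detector!r}")
    y = as_measurement(y)
    x = as_template(x)
    if k_max * x.length > y.length:
        raise InfeasibleInputError(
            f"k_max={k_max} windows of length {x.length} do not fit in {y.length} samples"
        )
    curve_fn = _CURVES[detector]
    real = np.asarray(curve_fn(y, x, k_max), dtype=float)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(p)
    nulls = np.empty((p, k_max))
    for i, child in enumerate(streams):
        y_perm = permute_measurement(y, np.random.default_rng(child))
        nulls[i] = curve_fn(y_perm, x, k_max)

    null_mean = nulls.mean(axis=0)
    gap = real - null_mean
    k_hat = int(np.argmax(gap)) + 1  # first maximizer; k is 1-based
    return GapCurve(
        k_values=np.arange(1, k_max + 1),
        objective_real=real,
        null_objectives=nulls,
        null_mean=null_mean,
        gap=gap,
        k_hat=k_hat,
        p=p,
        seed=seed if isinstance(seed, (int, type(None))) else None,
    )
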