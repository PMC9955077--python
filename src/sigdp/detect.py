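"""Exact maximum-likelihood detection of non-overlapping signal occurrences.

The observation model is ``y[n] = sum_k x[n - n_k] + eps[n]`` with i.i.d.
Gaussian noise and the separation condition ``|n_i - n_j| >= L``: the K
windows of length L do not overlap. Under this model, maximizing the
likelihood over the locations is equivalent to maximizing the sum of
matched-filter (cross-correlation) scores at the chosen left edges, subject
to the separation constraint.

The dynamic program here solves that combinatorial problem exactly. Let
``c[m]`` be the correlation score at left edge ``m`` and define

    g[n, j] = best objective over j windows fully contained in y[0:n].

A window ending at prefix position ``n`` has left edge ``n - L``, and the
remaining ``j - 1`` windows must fit inside ``y[0 : n - L]``, so

    g[n, j] = max( g[n - 1, j],  g[n - L, j - 1] + c[n - L] )

with ``g[n, 0] = 0`` and ``g[n, j] = -inf`` when ``n < j*L`` (j windows
cannot fit). ``g[N, K]`` is the constrained maximum-likelihood objective and
the locations are recovered by backtracking. The table costs O(N*K) after an
O(N log N) FFT correlation.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import (
    CorrelationProfile,
    Detection,
    InfeasibleInputError,
    Measurement,
    Template,
    as_measurement,
    as_template,
)

__all__ = [
    "cross_correlate",
    "dp_detect",
    "dp_objective_curve",
    "brute_force_detect",
    "count_separated_subsets",
]


def cross_correlate(y, x) -> CorrelationProfile:
    """Matched-filter scores of template ``x`` at every left edge of ``y``.

    Returns ``scores`` of length ``N - L + 1`` with
    ``scores[m] = sum_i y[m + i] * x[i]``, computed with an FFT-based
    correlation.

    Raises
    ------
    InfeasibleInputError
        If the measurement is shorter than the template.
    """
    y = as_measurement(y)
    x = as_template(x)
    n, l = y.length, x.length
    if n < l:
        raise InfeasibleInputError(f"measurement length {n} < template length {l}")
    scores = signal.correlate(y.samples, x.values, mode="valid", method="fft")
    return CorrelationProfile(scores=scores, template_length=l)


def _dp_table(c: np.ndarray, n: int, l: int, k: int) -> np.ndarray:
    """Fill the (N+1) x (k+1) prefix table g described in the module docstring.

    ``c`` has length ``n - l + 1``. Column j is a running maximum over the
    "place a window ending at this prefix position" candidates, which makes
    each column a single vectorized pass.
    """
    g = np.full((n + 1, k + 1), -np.inf)
    g[:, 0] = 0.0
    for j in range(1, k + 1):
        cand = np.full(n + 1, -np.inf)
        ends = np.arange(j * l, n + 1)  # prefix positions where a j-th window can end
        if ends.size:
            cand[ends] = g[ends - l, j - 1] + c[ends - l]
        g[:, j] = np.maximum.accumulate(cand)
    return g


def _backtrack(g: np.ndarray, c: np.ndarray, l: int, k: int) -> list[int]:
    """Recover locations from the table; on ties prefer 'do not place', which
    yields the left-most optimal configuration."""
    locs: list[int] = []
    n, j = g.shape[0] - 1, k
    while j > 0:
        if g[n, j] == g[n - 1, j]:
            n -= 1
        else:
            locs.append(n - l)
            n -= l
            j -= 1
    locs.reverse()
    return locs


def dp_detect(y, x, k: int, *, at_most: bool = False) -> Detection:
    """Maximum-likelihood placement of exactly ``k`` non-overlapping windows.

    Parameters
    ----------
    y, x
        Measurement and template (arrays or domain objects).
    k
        Number of occurrences to place. Must satisfy ``k * L <= N``.
    at_most
        If True, return the best placement over 0..k occurrences (the argmax
        of the objective curve) instead of exactly k. Off by default: the
        constrained likelihood places exactly k even when some marginal
        correlations are negative.

    Returns
    -------
    Detection
        Sorted left edges (pairwise >= L apart), the attained objective, and
        the per-count objective curve ``g(N, j)`` for j = 1..k.
    """
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    y = as_measurement(y)
    x = as_template(x)
    n, l = y.length, x.length
    if k * l > n:
        raise InfeasibleInputError(
            f"cannot place {k} non-overlapping windows of length {l} in {n} samples"
        )
    if k == 0:
        return Detection(locations=(), objective=0.0, k=0, objective_curve=np.empty(0))

    c = cross_correlate(y, x).scores
    g = _dp_table(c, n, l, k)
    curve = g[n, 1:].copy()

    k_used = k
    if at_most:
        # best over 0..k; empty placement has objective 0
        best_j = int(np.argmax(np.concatenate(([0.0], curve))))
        if best_j == 0:
            return Detection(locations=(), objective=0.0, k=0, objective_curve=curve)
        k_used = best_j

    locs = _backtrack(g, c, l, k_used)
    return Detection(
        locations=tuple(locs),
        objective=float(g[n, k_used]),
        k=k_used,
        objective_curve=curve,
    )


def dp_objective_curve(y, x, k_max: int) -> np.ndarray:
    """Optimal objective ``g(N, j)`` for j = 1..k_max, from a single table.

    Entry ``j-1`` equals ``dp_detect(y, x, j).objective``; the dynamic program
    computes the whole curve in one pass, so no re-runs are needed.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    y = as_measurement(y)
    x = as_template(x)
    n, l = y.length, x.length
    if k_max * l > n:
        raise InfeasibleInputError(
            f"cannot place {k_max} non-overlapping windows of length {l} in {n} samples"
        )
    c = cross_correlate(y, x).scores
    g = _dp_table(c, n, l, k_max)
    return g[n, 1:].copy()


def count_separated_subsets(n: int, l: int, k: int) -> int:
    """Number of k-subsets of left edges in [0, n-l] with pairwise separation
    >= l. Closed form C(n - k*l + k, k) by the usual gap substitution."""
    from math import comb

    if k == 0:
        return 1
    if k * l > n:
        return 0
    return comb(n - k * l + k, k)


def _iter_separated(m_max: int, l: int, k: int, start: int = 0):
    """Yield all sorted k-tuples of left edges in [start, m_max] with
    consecutive gaps >= l."""
    if k == 0:
        yield ()
        return
    # last window needs room: left edge <= m_max - (k-1)*l
    for m in range(start, m_max - (k - 1) * l + 1):
        for rest in _iter_separated(m_max, l, k - 1, m + l):
            yield (m,) + rest


def brute_force_detect(y, x, k: int, *, max_configs: int = 10_000_000) -> Detection:
    """Exhaustive-enumeration oracle for the constrained objective.

    Enumerates every feasible set of ``k`` separated left edges and returns
    the maximizer. Intended only to verify the dynamic program on small
    instances; refuses when the configuration count exceeds ``max_configs``.
    """
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    y = as_measurement(y)
    x = as_template(x)
    n, l = y.length, x.length
    if k * l > n:
        raise InfeasibleInputError(
            f"cannot place {k} non-overlapping windows of length {l} in {n} samples"
        )
    n_cfg = count_separated_subsets(n, l, k)
    if n_cfg > max_configs:
        raise InfeasibleInputError(
            f"{n_cfg} configurations exceed the oracle cap {max_configs}"
        )
    if k == 0:
        return Detection(locations=(), objective=0.0, k=0)

    c = cross_correlate(y, x).scores
    best_obj = -np.inf
    best_locs: tuple[int, ...] = ()
    for locs in _iter_separated(n - l, l, k):
        obj = float(sum(c[m] for m in locs))
        if obj > best_obj:
            best_obj = obj
            best_locs = locs
    return Detection(locations=best_locs, objective=best_obj, k=k)
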