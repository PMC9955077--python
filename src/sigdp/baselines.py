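"""Baseline detectors: greedy correlation-peak picking, random placement,
and l1 sparse deconvolution with a box constraint.

The greedy detector picks the highest matched-filter peak, suppresses every
left edge within L of it, and repeats — the standard non-maximum-suppression
picker. It is optimal when occurrences are well separated but can paint
itself into a corner in dense regimes, which is exactly the gap the exact
dynamic program closes.

The convex baseline models the clean measurement as ``G s`` where ``G`` is
the circulant matrix whose i-th row is the template shifted by i, and ``s``
is a 0/1 indicator of left edges. It relaxes the binary constraint to the
box [0, 1] and solves

    min ||s||_1   s.t.   ||y - G s||_2^2 <= delta,   0 <= s <= 1

with ``delta = 1.2 * N * sigma^2``, then peak-picks the denoised ``s``.
"""

from __future__ import annotations

import numpy as np

from .detect import cross_correlate
from .types import (
    ConvexSolution,
    Detection,
    GreedyTrace,
    InfeasibleInputError,
    as_measurement,
    as_template,
)

__all__ = [
    "greedy_detect",
    "random_detect",
    "build_shift_matrix",
    "convex_denoise",
    "convex_detect",
]


def _greedy_pick(scores: np.ndarray, l: int, k: int) -> tuple[list[int], list[float]]:
    """Pick up to k peaks of ``scores`` subject to pairwise separation >= l.

    Ties break toward the smaller index (np.argmax convention). Returns the
    picked left edges in pick order and their scores; may return fewer than k
    when no feasible candidate remains.
    """
    m = scores.size
    feasible = np.ones(m, dtype=bool)
    locs: list[int] = []
    vals: list[float] = []
    for _ in range(k):
        if not feasible.any():
            break
        masked = np.where(feasible, scores, -np.inf)
        idx = int(np.argmax(masked))
        locs.append(idx)
        vals.append(float(scores[idx]))
        lo = max(0, idx - l + 1)
        feasible[lo : idx + l] = False
    return locs, vals


def greedy_detect(y, x, k: int) -> tuple[Detection, GreedyTrace]:
    """Greedy correlation-peak detector with L-separation suppression.

    Iteratively selects the highest-scoring feasible left edge (at least L
    from every previous pick). If fewer than ``k`` feasible choices remain
    the partial placement is returned with ``Detection.complete = False`` so
    benchmarks can count the shortfall as missed detections.

    Returns the Detection plus a GreedyTrace with per-step scores and their
    cumulative sum (the greedy objective gamma_K).
    """
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    y = as_measurement(y)
    x = as_template(x)
    if k == 0:
        return (
            Detection(locations=(), objective=0.0, k=0),
            GreedyTrace(locations=(), step_scores=np.empty(0), cumulative=0.0),
        )
    scores = cross_correlate(y, x).scores
    locs, vals = _greedy_pick(scores, x.length, k)
    trace = GreedyTrace(
        locations=tuple(locs), step_scores=np.array(vals), cumulative=float(sum(vals))
    )
    det = Detection(
        locations=tuple(sorted(locs)),
        objective=float(sum(vals)),
        k=len(locs),
        complete=(len(locs) == k),
    )
    return det, trace


def greedy_objective_curve(y, x, k_max: int) -> np.ndarray:
    """Cumulative greedy objective gamma_K for K = 1..k_max from one run.

    Greedy picks are nested (the first j picks do not depend on k), so the
    curve is the cumulative sum of per-step scores. If greedy runs out of
    feasible picks before k_max, the curve stays flat from there on.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    y = as_measurement(y)
    x = as_template(x)
    scores = cross_correlate(y, x).scores
    _, vals = _greedy_pick(scores, x.length, k_max)
    curve = np.cumsum(np.asarray(vals, dtype=float))
    if curve.size < k_max:  # ran out of feasible picks: objective stops growing
        pad = np.full(k_max - curve.size, curve[-1] if curve.size else 0.0)
        curve = np.concatenate([curve, pad])
    return curve


def random_detect(n: int, l: int, k: int, rng, *, scores: np.ndarray | None = None) -> Detection:
    """Uniform-random placement satisfying the L-separation condition.

    Uses the same rejection-placement procedure as the simulator: propose
    uniform left edges in [0, n-l] and keep those at least L from every
    accepted edge. The objective is the sum of ``scores`` at the drawn
    locations when a correlation profile is supplied, else 0.
    """
    from .simulate import place_locations  # local import to avoid a cycle

    rng = np.random.default_rng(rng)
    locs = place_locations(n=n, l=l, k=k, min_gap=l, rng=rng)
    obj = float(sum(scores[m] for m in locs)) if scores is not None else 0.0
    return Detection(locations=tuple(locs), objective=obj, k=k)


def build_shift_matrix(x, n: int) -> np.ndarray:
    """Circulant N x N matrix whose i-th row is the template at offset i.

    Row i holds ``x`` left-edge-aligned at column i with wraparound, so
    ``s @ G`` (equivalently ``G.T @ s``) synthesizes the clean measurement
    from a left-edge indicator ``s`` for interior (non-wrapping) locations.
    """
    x = as_template(x)
    if x.length > n:
        raise InfeasibleInputError(f"template length {x.length} > n={n}")
    row = np.zeros(n)
    row[: x.length] = x.values
    g = np.empty((n, n))
    for i in range(n):
        g[i] = np.roll(row, i)
    return g


def _box_lasso_fista(
    gram: np.ndarray,
    gty: np.ndarray,
    mu: float,
    s0: np.ndarray,
    lipschitz: float,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Minimize 0.5*||y - G s||^2 + mu * sum(s) over the box [0,1]^N by FISTA.

    Since s >= 0 on the box, the l1 term is linear and the prox step is a
    clip. ``gram = G^T G`` and ``gty = G^T y`` are precomputed.
    """
    s = s0.copy()
    z = s.copy()
    t = 1.0
    step = 1.0 / lipschitz
    for _ in range(max_iter):
        grad = gram @ z - gty
        s_new = np.clip(z - step * (grad + mu), 0.0, 1.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = s_new + ((t - 1.0) / t_new) * (s_new - s)
        if np.max(np.abs(s_new - s)) < tol:
            s = s_new
            break
        s, t = s_new, t_new
    return s


class ConvexSolverError(RuntimeError):
    """Raised when the l1 denoising program is infeasible or fails to
    converge to the required tolerance."""


def convex_denoise(y, x, sigma2: float, *, feas_tol: float = 1e-6) -> ConvexSolution:
    """Solve min ||s||_1 s.t. ||y - G s||^2 <= delta, 0 <= s <= 1.

    ``delta = 1.2 * N * sigma2``. Solved by homotopy: the KKT conditions of
    the constrained program coincide with those of the box-constrained lasso
    ``min 0.5||y - Gs||^2 + mu*sum(s)`` at ``mu = 1/(2*lambda)``, and the
    residual of the lasso path is nondecreasing in ``mu``, so we bisect on
    ``mu`` until the residual meets the constraint boundary. Each inner
    problem is solved by FISTA with a clip prox (warm-started).

    Raises
    ------
    ConvexSolverError
        If no s in the box can satisfy the residual ball (infeasible), or
        the solver cannot reach feasibility within tolerance.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    y = as_measurement(y)
    x = as_template(x)
    n = y.length
    delta = 1.2 * n * sigma2

    g = build_shift_matrix(x, n)
    gt = g.T  # columns of gt are shifted templates; model is y = G^T s = s @ G
    gram = gt.T @ gt  # = G G^T, symmetric PSD
    gty = gt.T @ y.samples
    lipschitz = float(np.linalg.eigvalsh(gram)[-1])
    if lipschitz <= 0:
        raise ConvexSolverError("degenerate shift matrix")

    def resid_sq(s: np.ndarray) -> float:
        r = y.samples - gt @ s
        return float(r @ r)

    # trivial solution check: s = 0
    if resid_sq(np.zeros(n)) <= delta:
        s0 = np.zeros(n)
        return ConvexSolution(s_hat=s0, residual_norm_sq=resid_sq(s0), delta=delta, l1_norm=0.0)

    # mu = 0: best achievable residual over the box
    s_lo = _box_lasso_fista(gram, gty, 0.0, np.clip(gty / max(lipschitz, 1e-12), 0, 1), lipschitz)
    r_lo = resid_sq(s_lo)
    slack = max(feas_tol, feas_tol * max(delta, 1.0))
    if r_lo > delta + slack:
        raise ConvexSolverError(
            f"infeasible: minimal box residual {r_lo:.6g} exceeds delta={delta:.6g}"
        )
    if delta == 0.0 or r_lo >= delta:
        s = s_lo
        return ConvexSolution(
            s_hat=s, residual_norm_sq=resid_sq(s), delta=delta, l1_norm=float(np.abs(s).sum())
        )

    # bracket mu: residual increases with mu
    mu_hi = float(np.max(np.abs(gty))) + 1.0  # at this mu the lasso solution is ~0
    mu_lo = 0.0
    s = s_lo
    for _ in range(60):
        mu = 0.5 * (mu_lo + mu_hi)
        s = _box_lasso_fista(gram, gty, mu, s, lipschitz)
        r = resid_sq(s)
        if r > delta:
            mu_hi = mu
        else:
            mu_lo = mu
        if mu_hi - mu_lo < 1e-12 * (1.0 + mu_hi):
            break
    # return the feasible side
    s = _box_lasso_fista(gram, gty, mu_lo, s, lipschitz, max_iter=4000)
    r = resid_sq(s)
    if r > delta + slack:
        raise ConvexSolverError(f"solver did not reach feasibility: residual {r:.6g} > {delta:.6g}")
    return ConvexSolution(
        s_hat=s, residual_norm_sq=r, delta=delta, l1_norm=float(np.abs(s).sum())
    )


def convex_detect(y, x, sigma2: float, k: int) -> Detection:
    """Denoise with the l1 program, then greedily peak-pick the k largest
    entries of s_hat with L-separation; wrapped (circulant) placements are
    excluded by restricting left edges to [0, N - L]."""
    if k < 0:
        raise ValueError(f"k must be nonnegative, got {k}")
    y = as_measurement(y)
    x = as_template(x)
    if k == 0:
        return Detection(locations=(), objective=0.0, k=0)
    sol = convex_denoise(y, x, sigma2)
    valid = sol.s_hat[: y.length - x.length + 1]
    locs, vals = _greedy_pick(valid, x.length, k)
    return Detection(
        locations=tuple(sorted(locs)),
        objective=float(sum(vals)),
        k=len(locs),
        complete=(len(locs) == k),
    )
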