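"""Scoring detections against ground truth.

A detection at ``m_hat`` counts as a true positive for a truth location ``m``
when ``|m_hat - m| < L/2`` (strict; for odd L on integers this is
``|diff| <= floor(L/2)``). Matching is one-to-one and maximum-cardinality so
duplicate detections of the same occurrence cannot inflate precision:
candidate pairs are seeded greedily in order of increasing |difference| (a
deterministic preference for tight matches) and then completed to a true
maximum matching with augmenting paths. When both lists are L-separated each
node has degree at most one and the greedy seed is already maximal; the
augmentation matters when a misspecified detector emits more closely spaced
detections.

From the matching: precision = TP / detections (0 when nothing was
detected), TPR (recall) = TP / truths, and F1 is their harmonic mean. The
model-order error for an estimated count is |k_hat / k - 1|.
"""

from __future__ import annotations

import numpy as np

from .types import EvalReport

__all__ = ["match_detections", "score", "k_error"]


def match_detections(truth, detected, l: int) -> list[tuple[int, int]]:
    """Maximum one-to-one matching of detections to truths within L/2.

    Pairs (truth, detection) with ``|detection - truth| < l/2`` are admitted
    greedily in order of increasing absolute difference (ties break on
    truth index, then detection index), then completed to maximum cardinality
    with augmenting paths. Deterministic and independent of input ordering.
    """
    truth = sorted(int(v) for v in truth)
    detected = sorted(int(v) for v in detected)
    half = l / 2.0
    adj: list[list[int]] = [[] for _ in truth]
    candidates = []
    for i, t in enumerate(truth):
        for j, d in enumerate(detected):
            diff = abs(d - t)
            if diff < half:
                adj[i].append(j)
                candidates.append((diff, i, j))
    candidates.sort()

    match_t = [-1] * len(truth)  # truth index -> detection index
    match_d = [-1] * len(detected)
    for _, i, j in candidates:
        if match_t[i] == -1 and match_d[j] == -1:
            match_t[i] = j
            match_d[j] = i

    def try_augment(i: int, seen: list[bool]) -> bool:
        for j in adj[i]:
            if seen[j]:
                continue
            seen[j] = True
            if match_d[j] == -1 or try_augment(match_d[j], seen):
                match_d[j] = i
                match_t[i] = j
                return True
        return False

    for i in range(len(truth)):
        if match_t[i] == -1:
            try_augment(i, [False] * len(detected))

    matches = [(truth[i], detected[j]) for i, j in enumerate(match_t) if j != -1]
    matches.sort()
    return matches


def score(truth, detected, l: int, k_hat: int | None = None, k: int | None = None) -> EvalReport:
    """Precision, TPR (recall) and F1 from the one-to-one matching.

    ``f1 = 2 * precision * tpr / (precision + tpr)``, defined as 0 when both
    are 0. When ``k_hat`` and ``k`` are given, the report also carries the
    count-estimation error ``|k_hat/k - 1|``.
    """
    truth = list(truth)
    detected = list(detected)
    matches = match_detections(truth, detected, l)
    tp = len(matches)
    n_true = len(truth)
    n_det = len(detected)
    precision = tp / n_det if n_det > 0 else 0.0
    tpr = tp / n_true if n_true > 0 else 0.0
    f1 = 0.0 if precision + tpr == 0 else 2 * precision * tpr / (precision + tpr)
    ke = k_error(k_hat, k) if (k_hat is not None and k is not None) else None
    return EvalReport(
        n_true=n_true,
        n_detected=n_det,
        true_positives=tp,
        precision=precision,
        tpr=tpr,
        f1=f1,
        matches=tuple(matches),
        k_error=ke,
    )


def k_error(k_hat: int, k: int) -> float:
    """Relative error of an estimated occurrence count: |k_hat/k - 1|."""
    if k < 1:
        raise ValueError("true count k must be >= 1")
    return abs(k_hat / k - 1.0)


def max_matching_oracle(truth, detected, l: int) -> int:
    """Maximum-cardinality matching size by exhaustive enumeration (test
    oracle; exponential, small instances only).

    Recursively tries, for each truth in turn, leaving it unmatched or
    pairing it with each still-free detection within the |diff| < l/2
    tolerance, and returns the best cardinality found.
    """
    truth = list(truth)
    detected = list(detected)
    half = l / 2.0
    adj = [
        [j for j, d in enumerate(detected) if abs(d - t) < half]
        for t in truth
    ]

    def best(i: int, used: frozenset[int]) -> int:
        if i == len(truth):
            return 0
        out = best(i + 1, used)  # leave truth i unmatched
        for j in adj[i]:
            if j not in used:
                out = max(out, 1 + best(i + 1, used | {j}))
        return out

    return best(0, frozenset())
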