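"""Core domain containers shared across the detection pipeline.

All locations are 0-based left edges: a signal occurrence at location ``m``
occupies the half-open window ``[m, m + L)`` of the measurement. Valid left
edges therefore lie in ``[0, N - L]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InfeasibleInputError(ValueError):
    """Raised when an input violates a structural precondition (e.g. N < L,
    or more signal windows requested than fit in the measurement)."""


@dataclass(frozen=True)
class Template:
    """A known 1D signal shape of length L.

    Parameters
    ----------
    values
        Real vector of length ``L`` (arbitrary intensity units). Must be
        finite with a strictly positive squared norm.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise InfeasibleInputError("template must be a 1D vector of length >= 1")
        if not np.all(np.isfinite(v)):
            raise InfeasibleInputError("template values must be finite")
        if not np.dot(v, v) > 0:
            raise InfeasibleInputError("template must have positive squared norm")
        object.__setattr__(self, "values", v)

    @property
    def length(self) -> int:
        return int(self.values.size)

    @property
    def energy(self) -> float:
        """Squared Euclidean norm of the template."""
        return float(np.dot(self.values, self.values))


@dataclass(frozen=True)
class Measurement:
    """An observed 1D vector, optionally with ground truth attached.

    Parameters
    ----------
    samples
        Real vector of length ``N``.
    noise_variance
        Variance of the additive white Gaussian noise, if known.
    truth
        Sorted 0-based left-edge locations of the embedded signal
        occurrences, if known (synthetic data).
    """

    samples: np.ndarray
    noise_variance: float | None = None
    truth: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1:
            raise InfeasibleInputError("measurement must be a 1D vector")
        object.__setattr__(self, "samples", s)
        if self.noise_variance is not None and self.noise_variance < 0:
            raise InfeasibleInputError("noise variance must be nonnegative")
        if self.truth is not None:
            t = tuple(int(v) for v in self.truth)
            if list(t) != sorted(t):
                raise InfeasibleInputError("truth locations must be sorted")
            object.__setattr__(self, "truth", t)

    @property
    def length(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class CorrelationProfile:
    """Matched-filter scores at every candidate left edge.

    ``scores[m]`` is the inner product of ``y[m:m+L]`` with the template,
    for ``m`` in ``[0, N - L]``; the vector has length ``N - L + 1``.
    """

    scores: np.ndarray
    template_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))


@dataclass(frozen=True)
class Detection:
    """A set of estimated left edges with the attained objective value.

    ``objective`` is the sum of the correlation-profile scores at the
    returned locations; ``objective_curve`` (when present) holds the optimal
    objective for 1..k placements, and ``complete`` is False when a detector
    could not place all requested signals (greedy in dense regimes).
    """

    locations: tuple[int, ...]
    objective: float
    k: int
    objective_curve: np.ndarray | None = None
    complete: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "locations", tuple(int(v) for v in self.locations))

    def to_dict(self) -> dict:
        d = {
            "locations": list(self.locations),
            "objective": self.objective,
            "k": self.k,
            "coordinate_convention": "0-based left edge",
        }
        if self.objective_curve is not None:
            d["objective_curve"] = [float(v) for v in self.objective_curve]
        if not self.complete:
            d["complete"] = False
        return d


@dataclass(frozen=True)
class GreedyTrace:
    """Per-step record of the greedy detector: chosen left edges and the
    per-step correlation scores, plus their cumulative sum."""

    locations: tuple[int, ...]
    step_scores: np.ndarray
    cumulative: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "step_scores", np.asarray(self.step_scores, dtype=float))


@dataclass(frozen=True)
class ConvexSolution:
    """Solution of the box-constrained l1 denoising program.

    ``s_hat`` lies in [0, 1]^N and satisfies ``||y - G s_hat||^2 <= delta``
    up to solver tolerance.
    """

    s_hat: np.ndarray
    residual_norm_sq: float
    delta: float
    l1_norm: float = field(default=0.0)

    def to_dict(self) -> dict:
        return {
            "s_hat": [float(v) for v in self.s_hat],
            "residual_norm_sq": self.residual_norm_sq,
            "delta": self.delta,
            "l1_norm": self.l1_norm,
        }


@dataclass(frozen=True)
class GapCurve:
    """Gap-statistic diagnostics for model-order selection.

    ``gap[k-1] = objective_real[k-1] - null_mean[k-1]`` for k = 1..Kmax;
    ``k_hat`` is the first k attaining the maximal gap.
    """

    k_values: np.ndarray
    objective_real: np.ndarray
    null_objectives: np.ndarray  # shape (P, Kmax)
    null_mean: np.ndarray
    gap: np.ndarray
    k_hat: int
    p: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "k_values": [int(v) for v in self.k_values],
            "objective_real": [float(v) for v in self.objective_real],
            "null_mean": [float(v) for v in self.null_mean],
            "gap": [float(v) for v in self.gap],
            "k_hat": int(self.k_hat),
            "permutations": int(self.p),
            "seed": self.seed,
        }


@dataclass(frozen=True)
class EvalReport:
    """Detection scores after one-to-one matching within the L/2 tolerance."""

    n_true: int
    n_detected: int
    true_positives: int
    precision: float
    tpr: float
    f1: float
    matches: tuple[tuple[int, int], ...]
    k_error: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_true": self.n_true,
            "n_detected": self.n_detected,
            "true_positives": self.true_positives,
            "precision": self.precision,
            "tpr": self.tpr,
            "f1": self.f1,
            "matches": [list(m) for m in self.matches],
            "k_error": self.k_error,
        }


def as_measurement(y) -> Measurement:
    """Coerce an array-like or Measurement into a Measurement."""
    if isinstance(y, Measurement):
        return y
    return Measurement(np.asarray(y, dtype=float))


def as_template(x) -> Template:
    """Coerce an array-like or Template into a Template."""
    if isinstance(x, Template):
        return x
    return Template(np.asarray(x, dtype=float))
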