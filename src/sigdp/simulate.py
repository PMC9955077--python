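"""Synthetic 1D measurements: shifted template copies plus white Gaussian noise.

The generator reproduces the statistical structure of the observation model:
K copies of a known template placed at left edges satisfying a separation
condition — at least L apart ("arbitrary" spacing: windows merely do not
overlap) or at least 2L apart ("well separated") — plus i.i.d. zero-mean
Gaussian noise of variance sigma^2.

Placement follows rejection sampling: the first left edge is uniform over
[0, n-l]; each subsequent proposal is kept only if it is at least the
required gap from every accepted edge, and re-drawn otherwise. Near maximal
packing density this can stall, so proposals are capped and the whole
placement restarts from scratch a bounded number of times.

Randomness uses numpy's default_rng (PCG64), which is reproducible across
platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import InfeasibleInputError, Measurement, Template, as_template

__all__ = [
    "SimulationConfig",
    "rectangular_template",
    "place_locations",
    "synthesize",
]

MAX_ATTEMPTS_DEFAULT = 1000
MAX_RESTARTS_DEFAULT = 100


def rectangular_template(l: int) -> Template:
    """Rectangular (square-pulse) template of length l: a vector of ones."""
    if l < 1:
        raise InfeasibleInputError("template length must be >= 1")
    return Template(np.ones(l))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic measurement.

    Parameters
    ----------
    n : measurement length N.
    l : template length L.
    k : number of occurrences.
    sigma2 : variance of the additive white Gaussian noise.
    mode : 'arbitrary' (gaps >= L) or 'well_separated' (gaps >= 2L).
    template : custom template; defaults to the rectangular pulse of ones.
    seed : RNG seed (or a numpy Generator/SeedSequence).
    max_attempts, max_restarts : rejection-sampling caps.
    """

    n: int
    l: int
    k: int
    sigma2: float = 0.0
    mode: str = "arbitrary"
    template: Template | None = None
    seed: int | None = None
    max_attempts: int = MAX_ATTEMPTS_DEFAULT
    max_restarts: int = MAX_RESTARTS_DEFAULT

    def __post_init__(self) -> None:
        if self.mode not in ("arbitrary", "well_separated"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sigma2 < 0:
            raise InfeasibleInputError("sigma2 must be nonnegative")
        if self.l < 1 or self.n < self.l or self.k < 0:
            raise InfeasibleInputError("need l >= 1, n >= l, k >= 0")
        gap = self.min_gap
        if self.k > 0 and (self.k - 1) * gap + self.l > self.n:
            raise InfeasibleInputError(
                f"{self.k} windows of length {self.l} with gaps >= {gap} "
                f"do not fit in {self.n} samples"
            )
        if self.template is not None and self.template.length != self.l:
            raise InfeasibleInputError("template length must equal l")

    @property
    def min_gap(self) -> int:
        return self.l if self.mode == "arbitrary" else 2 * self.l

    def resolved_template(self) -> Template:
        return self.template if self.template is not None else rectangular_template(self.l)


def place_locations(
    n: int,
    l: int,
    k: int,
    min_gap: int,
    rng: np.random.Generator,
    max_attempts: int = MAX_ATTEMPTS_DEFAULT,
    max_restarts: int = MAX_RESTARTS_DEFAULT,
) -> list[int]:
    """Draw k left edges in [0, n-l], pairwise >= min_gap apart, by rejection.

    Proposals are uniform over [0, n-l]; a proposal is eligible when its
    left edge is at least ``min_gap`` from every accepted left edge. After
    ``max_attempts`` consecutive rejections the placement restarts from
    scratch, up to ``max_restarts`` times.
    """
    if k == 0:
        return []
    if (k - 1) * min_gap + l > n:
        raise InfeasibleInputError(
            f"{k} windows of length {l} with gaps >= {min_gap} do not fit in {n} samples"
        )
    hi = n - l  # inclusive upper bound for a left edge
    for _ in range(max_restarts):
        placed: list[int] = [int(rng.integers(0, hi + 1))]
        attempts = 0
        while len(placed) < k and attempts < max_attempts:
            cand = int(rng.integers(0, hi + 1))
            attempts += 1
            if all(abs(cand - p) >= min_gap for p in placed):
                placed.append(cand)
        if len(placed) == k:
            return sorted(placed)
    raise InfeasibleInputError(
        f"rejection sampling failed after {max_restarts} restarts "
        f"(n={n}, l={l}, k={k}, min_gap={min_gap})"
    )


def synthesize(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> Measurement:
    """Generate one measurement: sum of shifted template copies plus noise.

    The ground-truth left edges and the noise variance are attached to the
    returned Measurement. Deterministic given ``cfg.seed`` (or the supplied
    generator).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    x = cfg.resolved_template()
    locs = place_locations(
        cfg.n, cfg.l, cfg.k, cfg.min_gap, rng, cfg.max_attempts, cfg.max_restarts
    )
    samples = np.zeros(cfg.n)
    for m in locs:
        samples[m : m + cfg.l] += x.values
    if cfg.sigma2 > 0:
        samples += rng.normal(0.0, np.sqrt(cfg.sigma2), size=cfg.n)
    return Measurement(samples=samples, noise_variance=cfg.sigma2, truth=tuple(locs))
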