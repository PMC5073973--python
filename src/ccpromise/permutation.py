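"""Adaptive permutation p-values with a shared, reproducible permutation stream.

Significance of a projection statistic is assessed by permuting the
assignment of endpoint rows to molecular rows and recomputing the statistic.
The adaptive scheme stops a statistic's permutation loop as soon as B0
permuted statistics have matched or exceeded the observed magnitude — at
that point the p-value is already known to be unremarkable to sufficient
precision — and otherwise runs the full B1 permutations, reporting

    p = (number of |t_b| >= |t_0|) / (permutations performed).

All statistics evaluated on one dataset consume the *same* permutation
sequence, whatever their individual stopping points, so that competing
analyses receive identical protection against type I error and their
p-values are directly comparable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

# Exceedance comparisons use |t_b| >= |t_0| - TIE_TOL: the tiny absolute
# guard keeps a permutation that reproduces t_0 exactly (e.g. the identity)
# counted as an exceedance despite floating-point noise in recomputation.
TIE_TOL = 1e-12

_BLOCK = 256  # permutations generated per cached block


@dataclass(frozen=True)
class PermutationConfig:
    """Adaptive permutation parameters.

    B0: exceedances at which the loop may stop early (default 100).
    B1: maximum number of permutations (default 10,000).
    """

    B0: int = 100
    B1: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.B0 <= self.B1):
            raise ValueError("require 0 < B0 <= B1")


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of one adaptive permutation test."""

    p: float
    exceed_count: int
    performed: int
    stopped_early: bool


@dataclass
class PermutationStream:
    """Deterministic, shared sequence of permutations of n sample labels.

    Permutation b is a fixed function of (seed, b): permutations are drawn in
    blocks, block j from ``Generator(Philox(SeedSequence((seed, j))))``, and
    cached, so every statistic evaluated on the dataset sees the identical
    sequence regardless of where its adaptive loop stops.
    """

    seed: int
    n: int
    B1: int
    _blocks: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 to permute")

    def _block(self, j: int) -> np.ndarray:
        blk = self._blocks.get(j)
        if blk is None:
            size = min(_BLOCK, self.B1 - j * _BLOCK)
            rng = np.random.Generator(np.random.Philox(np.random.SeedSequence((self.seed, j))))
            blk = rng.permuted(
                np.broadcast_to(np.arange(self.n), (size, self.n)).copy(), axis=1
            )
            self._blocks[j] = blk
        return blk

    def get(self, b: int) -> np.ndarray:
        """The b-th permutation (0-based), shape (n,)."""
        if not 0 <= b < self.B1:
            raise IndexError(f"permutation index {b} outside [0, {self.B1})")
        return self._block(b // _BLOCK)[b % _BLOCK]

    def get_block(self, b0: int, b1: int) -> np.ndarray:
        """Permutations b0..b1-1 stacked into a (b1 - b0, n) matrix."""
        rows = []
        j0, j1 = b0 // _BLOCK, (b1 - 1) // _BLOCK
        for j in range(j0, j1 + 1):
            blk = self._block(j)
            lo = max(b0 - j * _BLOCK, 0)
            hi = min(b1 - j * _BLOCK, blk.shape[0])
            rows.append(blk[lo:hi])
        return np.vstack(rows)


def permutation_stream(seed: int, n: int, B1: int) -> PermutationStream:
    """Construct the reproducible permutation sequence for one dataset."""
    return PermutationStream(seed=seed, n=n, B1=B1)


def _finalize(count: int, performed: int, B1: int, stopped_early: bool) -> PermutationResult:
    p = count / performed if count > 0 else 1.0 / B1
    return PermutationResult(
        p=p, exceed_count=count, performed=performed, stopped_early=stopped_early
    )


def adaptive_pvalue(
    t0: float,
    stat_under_perm: Callable[[np.ndarray], float],
    cfg: PermutationConfig,
    stream: PermutationStream | None = None,
) -> PermutationResult:
    """Adaptive permutation p-value for one statistic.

    Iterates the stream, counting permutations with |t_b| >= |t_0|; stops
    when the count reaches B0 or after B1 permutations. With B0 = 100, a
    statistic reaching 100 exceedances at permutation 200 reports
    p = 100/200 = 0.50 without spending the remaining budget.
    """
    if not math.isfinite(t0):
        raise ValueError("observed statistic must be finite")
    if stream is None:
        stream = permutation_stream(cfg.seed, _infer_n(stat_under_perm), cfg.B1)
    threshold = abs(t0) - TIE_TOL
    count = 0
    for b in range(cfg.B1):
        if abs(stat_under_perm(stream.get(b))) >= threshold:
            count += 1
            if count >= cfg.B0:
                return _finalize(count, b + 1, cfg.B1, stopped_early=(b + 1 < cfg.B1))
    return _finalize(count, cfg.B1, cfg.B1, stopped_early=False)


def _infer_n(stat_under_perm: Callable) -> int:  # pragma: no cover - convenience only
    raise ValueError("pass an explicit PermutationStream so n is known")


def adaptive_pvalues_shared(
    t0s: np.ndarray,
    block_stats: Callable[[np.ndarray], np.ndarray],
    cfg: PermutationConfig,
    stream: PermutationStream,
) -> list[PermutationResult]:
    """Adaptive p-values for S statistics sharing one permutation stream.

    ``block_stats`` maps a (b, n) matrix of permutations to a (b, S) matrix
    of permuted statistics. Blocks are evaluated until every statistic has
    stopped (reached B0 exceedances) or B1 permutations are exhausted; each
    statistic's p-value uses exactly the permutations its own adaptive loop
    would have consumed, so results are identical to running
    :func:`adaptive_pvalue` per statistic — only faster.
    """
    t0s = np.asarray(t0s, dtype=float)
    if not np.isfinite(t0s).all():
        raise ValueError("observed statistics must be finite")
    S = t0s.size
    thresholds = np.abs(t0s) - TIE_TOL
    counts = np.zeros(S, dtype=int)
    results: list[PermutationResult | None] = [None] * S
    active = np.ones(S, dtype=bool)
    b = 0
    while b < cfg.B1 and active.any():
        b_next = min(b + _BLOCK, cfg.B1)
        T = np.abs(np.asarray(block_stats(stream.get_block(b, b_next))))
        exceed = T >= thresholds[None, :]
        for s in np.flatnonzero(active):
            cum = counts[s] + np.cumsum(exceed[:, s])
            hit = np.flatnonzero(cum >= cfg.B0)
            if hit.size:
                performed = b + int(hit[0]) + 1
                results[s] = _finalize(cfg.B0, performed, cfg.B1, performed < cfg.B1)
                active[s] = False
            else:
                counts[s] = int(cum[-1]) if cum.size else counts[s]
        b = b_next
    for s in np.flatnonzero(active):
        results[s] = _finalize(int(counts[s]), cfg.B1, cfg.B1, stopped_early=False)
    return results  # type: ignore[return-value]


def exact_reference_pvalue(
    t0: float, stat_under_perm: Callable[[np.ndarray], float], n: int
) -> float:
    """Exact permutation p-value by full enumeration (test oracle; n <= 8).

    Applies the same >=-magnitude proportion definition over all n!
    permutations.
    """
    if n > 8:
        raise ValueError("full enumeration refused for n > 8")
    threshold = abs(t0) - TIE_TOL
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(stat_under_perm(np.array(perm))) >= threshold:
            count += 1
    return count / total
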