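"""Projection of endpoint-association statistics onto the most interesting
statistical evidence.

With K endpoints, a feature's associations form a vector a = (a_1, ..., a_K)
on the correlation-like scale. Prior biological knowledge singles out one
direction lambda in {-1, +1}^K (first entry +1 by symmetry) as the most
interesting joint pattern — e.g. "greater expression associates with
sensitisation on every endpoint". The projection statistic

    t = sum_k lambda_k a_k

measures how far the observed associations deviate from the global null
along that direction. Expression and methylation projections are combined
additively, the methylation term entering with the sign of the
methylation-expression correlation so that only concordant evidence
accumulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_data import EndpointSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidenceDirection:
    """The most-interesting-evidence direction lambda.

    Entries are +/-1, optionally scaled by 1/K (``normalized``) so that the
    projection statistic stays on a correlation-like scale. The first entry
    is constrained to be positive before scaling.
    """

    lambdas: np.ndarray
    normalized: bool = True

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "lambdas", lam)
        if lam.ndim != 1 or lam.size < 1:
            raise ValueError("lambda must be a non-empty 1-D vector")
        mags = np.abs(lam)
        if not np.allclose(mags, mags[0]):
            raise ValueError("lambda entries must all have equal magnitude")
        if lam[0] <= 0:
            raise ValueError("first lambda entry must be positive (+1 convention)")

    @property
    def K(self) -> int:
        return int(self.lambdas.size)


@dataclass(frozen=True)
class PromiseStat:
    """A projection statistic with the components that produced it."""

    t: float
    kind: str  # expression | methylation | combined
    components: tuple = ()
    direction: "EvidenceDirection | None" = None


def build_evidence_vector(
    endpoints: list[EndpointSpec], normalized: bool = True
) -> EvidenceDirection:
    """Construct lambda from the per-endpoint interesting-direction signs.

    lambda_k = direction_sign_k / direction_sign_1, forcing the first entry
    to +1; with ``normalized`` each entry is divided by K. The projection's
    permutation p-value is invariant to the 1/K scaling.
    """
    if not endpoints:
        raise ValueError("need at least one endpoint")
    signs = np.array([e.direction_sign for e in endpoints], dtype=float)
    lam = signs / signs[0]
    if normalized:
        lam = lam / lam.size
    return EvidenceDirection(lambdas=lam, normalized=normalized)


def promise_stat(a: np.ndarray, direction: EvidenceDirection, kind: str = "expression") -> PromiseStat:
    """t = sum_k lambda_k a_k; missing entries (NaN) contribute zero evidence."""
    a = np.asarray(a, dtype=float)
    if a.shape != direction.lambdas.shape:
        raise ValueError(
            f"association vector length {a.size} != lambda length {direction.K}"
        )
    missing = np.isnan(a)
    if missing.any():
        logger.warning("%d missing association value(s) contribute zero evidence", missing.sum())
        a = np.where(missing, 0.0, a)
    t = float(direction.lambdas @ a)
    return PromiseStat(t=t, kind=kind, components=(tuple(a),), direction=direction)


def combined_stat(t_expr: PromiseStat, t_meth: PromiseStat, r: float) -> PromiseStat:
    """t* = t_expr + sign(r) * t_meth, with sign(0) = 0.

    ``r`` is the methylation-expression correlation for the pair (at gene
    level, the post-orientation score correlation, hence sign +1). Both
    inputs must have been computed against the same lambda.
    """
    if t_expr.kind == t_meth.kind:
        raise ValueError("combined statistic needs one expression and one methylation input")
    if (
        t_expr.direction is not None
        and t_meth.direction is not None
        and not np.array_equal(t_expr.direction.lambdas, t_meth.direction.lambdas)
    ):
        raise ValueError("expression and methylation statistics use different lambda vectors")
    s = float(np.sign(r))
    return PromiseStat(
        t=t_expr.t + s * t_meth.t,
        kind="combined",
        components=(t_expr.t, t_meth.t, s),
        direction=t_expr.direction,
    )
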