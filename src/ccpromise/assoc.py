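"""Pairwise association statistics on a common correlation-like scale.

Every endpoint-feature statistic returned here lies in [-1, +1] with 0
meaning no association, so that statistics for endpoints of different types
(quantitative, binary, censored time-to-event) can be combined in a single
projection statistic. Rank-based forms are used throughout for robustness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import EndpointSpec, EndpointTable

logger = logging.getLogger(__name__)


class UndefinedStatisticError(ValueError):
    """The requested statistic is not defined for the given input."""


class InsufficientDataError(ValueError):
    """Fewer usable observations than the statistic requires."""


@dataclass(frozen=True)
class AssociationStat:
    """An endpoint-feature association on the correlation-like scale."""

    value: float
    n_used: int
    endpoint_name: str = ""


@dataclass(frozen=True)
class PairCorrelation:
    """Pearson correlation of one expression feature with one methylation marker."""

    r: float
    p: float
    n_used: int


def _pairwise_complete(*vectors: np.ndarray) -> tuple[np.ndarray, ...]:
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    mask = np.ones(arrs[0].shape[0], dtype=bool)
    for a in arrs:
        mask &= ~np.isnan(a)
    return tuple(a[mask] for a in arrs)


def rank_standardize(v: np.ndarray) -> np.ndarray:
    """Average ranks, centered and scaled to unit Euclidean norm.

    The dot product of two such vectors is the Spearman correlation of the
    originals. Raises :class:`UndefinedStatisticError` on constant input.
    """
    r = stats.rankdata(np.asarray(v, dtype=float))
    r = r - r.mean()
    nrm = np.linalg.norm(r)
    if nrm < 1e-12:
        raise UndefinedStatisticError("constant vector: rank correlation undefined")
    return r / nrm


def spearman_assoc(x: np.ndarray, y: np.ndarray, name: str = "") -> AssociationStat:
    """Spearman rank correlation (average ranks for ties), pairwise-complete."""
    x, y = _pairwise_complete(x, y)
    n = x.shape[0]
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 non-missing pairs, got {n}")
    value = float(rank_standardize(x) @ rank_standardize(y))
    return AssociationStat(value=value, n_used=n, endpoint_name=name)


def binary_assoc(x: np.ndarray, group: np.ndarray, name: str = "") -> AssociationStat:
    """Association of a feature with a binary endpoint.

    Realised as the Spearman correlation of the feature with the 0/1 group
    indicator, a rank-biserial form bounded in [-1, 1].
    """
    x, g = _pairwise_complete(x, group)
    if x.shape[0] < 3:
        raise InsufficientDataError(f"need n >= 3 non-missing pairs, got {x.shape[0]}")
    levels = np.unique(g)
    if levels.size != 2:
        raise UndefinedStatisticError(
            f"binary endpoint must have exactly two observed levels, got {levels.size}"
        )
    return spearman_assoc(x, g, name=name)


def nelson_aalen_cumhaz(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at each subject's own time.

    H(t) = sum over distinct event times t_j <= t of d_j / n_j, with d_j the
    number of events at t_j and n_j the number at risk (time >= t_j).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    t_events = np.unique(time[event == 1])
    H_at = np.zeros_like(time)
    H = 0.0
    increments = []
    for tj in t_events:
        d = float(np.sum((time == tj) & (event == 1)))
        n_risk = float(np.sum(time >= tj))
        H += d / n_risk
        increments.append((tj, H))
    for i, t in enumerate(time):
        h = 0.0
        for tj, Hj in increments:
            if tj <= t:
                h = Hj
            else:
                break
        H_at[i] = h
    return H_at


def martingale_residuals(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Null-model martingale residuals: event indicator minus Nelson-Aalen H(t)."""
    return np.asarray(event, dtype=float) - nelson_aalen_cumhaz(time, event)


def survival_assoc(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, name: str = ""
) -> AssociationStat:
    """Association of a feature with a censored time-to-event endpoint.

    Spearman correlation of the feature with the null-model martingale
    residuals, negated so that positive values mean higher feature values
    associate with longer survival. Bounded in [-1, 1].
    """
    x, t, e = _pairwise_complete(x, time, event)
    n = x.shape[0]
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 non-missing triples, got {n}")
    if np.sum(e) == 0:
        logger.warning(
            "survival endpoint %s: zero events, no association information", name or "<unnamed>"
        )
        return AssociationStat(value=0.0, n_used=n, endpoint_name=name)
    resid = martingale_residuals(t, e)
    try:
        z_resid = rank_standardize(resid)
    except UndefinedStatisticError:
        # e.g. a single event at the latest time: residuals identically zero
        logger.warning(
            "survival endpoint %s: constant martingale residuals, no information",
            name or "<unnamed>",
        )
        return AssociationStat(value=0.0, n_used=n, endpoint_name=name)
    value = -float(rank_standardize(x) @ z_resid)
    return AssociationStat(value=value, n_used=n, endpoint_name=name)


def pair_correlation(x: np.ndarray, m: np.ndarray) -> PairCorrelation:
    """Pearson correlation of an expression feature with a methylation marker.

    Two-sided p-value from the t distribution with n - 2 degrees of freedom.
    """
    x, m = _pairwise_complete(x, m)
    n = x.shape[0]
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 non-missing pairs, got {n}")
    if np.std(x) < 1e-12 or np.std(m) < 1e-12:
        raise UndefinedStatisticError("constant vector: Pearson correlation undefined")
    res = stats.pearsonr(x, m)
    return PairCorrelation(r=float(res.statistic), p=float(res.pvalue), n_used=n)


def endpoint_surrogate(endpoints: EndpointTable, spec: EndpointSpec) -> np.ndarray:
    """Per-sample vector whose Spearman correlation with a feature equals the
    endpoint's association statistic (before the direction sign).

    Quantitative and ordinal endpoints map to their own values, binary
    endpoints to the 0/1 indicator, and survival endpoints to the negated
    null-model martingale residuals (computed on complete cases; samples with
    a missing time or event stay missing). This reduction is what allows the
    permutation engine to evaluate all endpoint types with one rank inner
    product.
    """
    if spec.kind in ("quantitative", "ordinal", "binary"):
        return endpoints.values[spec.name].copy()
    time = endpoints.values[spec.name]
    event = endpoints.values[spec.name + "_event"]
    out = np.full(time.shape, np.nan)
    mask = ~np.isnan(time) & ~np.isnan(event)
    if np.sum(event[mask] == 1) == 0:
        out[mask] = 0.0
        return out
    out[mask] = -martingale_residuals(time[mask], event[mask])
    return out


def endpoint_assoc_vector(
    feature: np.ndarray, endpoints: EndpointTable
) -> list[AssociationStat | None]:
    """Association of one feature with every endpoint, direction-signed.

    Dispatches by endpoint kind; each statistic is multiplied by the
    endpoint's ``direction_sign`` so that "interesting" associations are
    positive. Per-endpoint failures become ``None`` entries with a warning.
    """
    out: list[AssociationStat | None] = []
    for spec in endpoints.endpoints:
        try:
            if spec.kind in ("quantitative", "ordinal"):
                stat = spearman_assoc(feature, endpoints.values[spec.name], name=spec.name)
            elif spec.kind == "binary":
                stat = binary_assoc(feature, endpoints.values[spec.name], name=spec.name)
            elif spec.kind == "survival":
                stat = survival_assoc(
                    feature,
                    endpoints.values[spec.name],
                    endpoints.values[spec.name + "_event"],
                    name=spec.name,
                )
            else:  # pragma: no cover - kinds validated upstream
                raise UndefinedStatisticError(f"unsupported endpoint kind {spec.kind!r}")
            out.append(
                AssociationStat(
                    value=spec.direction_sign * stat.value,
                    n_used=stat.n_used,
                    endpoint_name=spec.name,
                )
            )
        except (UndefinedStatisticError, InsufficientDataError) as exc:
            logger.warning("endpoint %s: statistic undefined (%s)", spec.name, exc)
            out.append(None)
    return out
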