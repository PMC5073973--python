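"""Per-gene orchestration of the integrated analyses.

For each gene this module runs:

* the complete score-based analysis (CCPR): canonical correlation scores for
  expression and methylation substituted into the projection statistic, and
  the combined statistic with the post-orientation sign;
* feature-level projection analyses for expression (XPR) and methylation
  (MPR), summarised per gene as the minimum p (UXPR/UMPR) or minimum
  Bonferroni-adjusted p (AXPR/AMPR);
* the overlap rules UOV = max(UMPR, UXPR) and AOV = max(AMPR, AXPR).

Every p-value for a dataset is drawn from one shared permutation stream, so
the competing analyses are compared on identical permutations.

Under permutation only the assignment of endpoint rows moves; canonical
weights and scores are functions of the molecular data alone and are
therefore permutation-invariant — they are computed once from the observed
data and held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import (
    InsufficientDataError,
    UndefinedStatisticError,
    endpoint_surrogate,
    rank_standardize,
)
from .cca import CCAResult, DegenerateGeneError, fit_cca, orient_scores
from .core_data import AlignedDataset, EndpointTable, GeneFeatureMap
from .permutation import (
    PermutationConfig,
    PermutationResult,
    PermutationStream,
    adaptive_pvalues_shared,
)
from .promise import EvidenceDirection, PromiseStat, combined_stat, promise_stat

logger = logging.getLogger(__name__)


@dataclass
class GeneResult:
    """All statistics and gene-level summaries for one gene."""

    gene_id: str
    r_cc: float
    p_cc: float
    t_expr: float
    p_expr: float
    t_meth: float
    p_meth: float
    t_combined: float
    p_combined: float
    xpr: pd.DataFrame = field(repr=False, default=None)  # per expression feature t, p
    mpr: pd.DataFrame = field(repr=False, default=None)  # per methylation marker t, p
    uxpr: float = np.nan
    axpr: float = np.nan
    umpr: float = np.nan
    ampr: float = np.nan
    uov: float = np.nan
    aov: float = np.nan
    skipped: bool = False
    skip_reason: str = ""


def summarize_unadjusted(p_values: np.ndarray) -> float:
    """Gene summary of feature-level p-values: their minimum (no adjustment)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to summarize")
    return float(np.min(p))


def summarize_bonferroni(p_values: np.ndarray) -> float:
    """Minimum Bonferroni-adjusted feature-level p-value: min_j min(1, J p_j)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to summarize")
    return float(np.min(np.minimum(1.0, p.size * p)))


def overlap_p(p_a: float, p_b: float) -> float:
    """List-overlap rule: significant only if both analyses are, so max(p_a, p_b)."""
    return float(max(p_a, p_b))


class _EndpointDesign:
    """Endpoint surrogates prepared for permutation testing.

    Reduces every endpoint (quantitative, binary, survival) to a per-sample
    surrogate vector whose Spearman correlation with a feature is the
    endpoint's association statistic; the direction sign is folded into the
    rank-standardized column. When all surrogates are complete, permuted
    statistics for every feature reduce to one matrix product per block.
    """

    def __init__(self, endpoints: EndpointTable, direction: EvidenceDirection):
        if direction.K != endpoints.K:
            raise ValueError("lambda length does not match number of endpoints")
        self.direction = direction
        self.surrogates = np.column_stack(
            [endpoint_surrogate(endpoints, spec) for spec in endpoints.endpoints]
        )
        self.signs = np.array([spec.direction_sign for spec in endpoints.endpoints], dtype=float)
        self.complete = not np.isnan(self.surrogates).any()
        if self.complete:
            cols = []
            for k in range(endpoints.K):
                try:
                    z = rank_standardize(self.surrogates[:, k])
                except UndefinedStatisticError:
                    z = np.zeros(self.surrogates.shape[0])
                    logger.warning(
                        "endpoint %s is constant; it contributes zero evidence",
                        endpoints.endpoints[k].name,
                    )
                cols.append(self.signs[k] * z)
            self.Zy = np.column_stack(cols)
            # the direction signs are already folded into the columns, so signed
            # statistics are projected with the lambda magnitudes — identical to
            # projecting raw statistics onto the signed lambda (up to the
            # first-entry-positive sign convention). Correlating a feature with
            # this single vector gives its projection statistic.
            self.w = self.Zy @ np.abs(direction.lambdas)

    def signed_assoc_vector(self, feature: np.ndarray, perm: np.ndarray) -> np.ndarray:
        """Direction-signed association vector under an endpoint permutation.

        Pairwise-complete: each endpoint uses the samples at which both the
        feature and the *permuted* surrogate are observed. Undefined entries
        are NaN (zero evidence downstream).
        """
        out = np.empty(self.surrogates.shape[1])
        for k in range(self.surrogates.shape[1]):
            s = self.surrogates[perm, k]
            mask = ~np.isnan(s) & ~np.isnan(feature)
            if mask.sum() < 3:
                out[k] = np.nan
                continue
            try:
                out[k] = self.signs[k] * float(
                    rank_standardize(feature[mask]) @ rank_standardize(s[mask])
                )
            except UndefinedStatisticError:
                out[k] = np.nan
        return out


def _shared_projection_pvalues(
    design: _EndpointDesign,
    feature_columns: np.ndarray,
    combine: list[tuple[int, int, float]],
    cfg: PermutationConfig,
    stream: PermutationStream,
) -> tuple[np.ndarray, list[PermutationResult]]:
    """Observed projection statistics and adaptive p-values for a set of
    feature columns, plus combined statistics t_i + sign * t_j.

    ``combine`` lists (i, j, sign) triples appended after the per-column
    statistics. All statistics share ``stream``.
    """
    n, S = feature_columns.shape
    lam_mag = np.abs(design.direction.lambdas)  # applied to direction-signed stats
    col_complete = not np.isnan(feature_columns).any()

    if design.complete and col_complete:
        Z = np.column_stack([rank_standardize(feature_columns[:, s]) for s in range(S)])
        t_cols = Z.T @ design.w

        def block_stats(perms: np.ndarray) -> np.ndarray:
            T = design.w[perms] @ Z  # (b, S)
            if combine:
                extra = [T[:, i] + sign * T[:, j] for i, j, sign in combine]
                T = np.column_stack([T] + extra)
            return T

    else:

        def _stats_for_perm(perm: np.ndarray) -> np.ndarray:
            a = np.vstack(
                [design.signed_assoc_vector(feature_columns[:, s], perm) for s in range(S)]
            )
            return np.where(np.isnan(a), 0.0, a) @ lam_mag

        t_cols = _stats_for_perm(np.arange(n))

        def block_stats(perms: np.ndarray) -> np.ndarray:
            T = np.vstack([_stats_for_perm(p) for p in perms])
            if combine:
                extra = [T[:, i] + sign * T[:, j] for i, j, sign in combine]
                T = np.column_stack([T] + extra)
            return T

    t0s = np.concatenate(
        [t_cols, [t_cols[i] + sign * t_cols[j] for i, j, sign in combine]]
    )
    results = adaptive_pvalues_shared(t0s, block_stats, cfg, stream)
    return t0s, results


def feature_promise(
    features_matrix: np.ndarray,
    endpoints: EndpointTable,
    direction: EvidenceDirection,
    cfg: PermutationConfig,
    stream: PermutationStream | None = None,
    feature_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Feature-level projection analysis: one (t, p) row per feature column.

    ``features_matrix`` is n x J (samples by features). All features share
    the permutation stream, so identical features get identical p-values.
    """
    F = np.atleast_2d(np.asarray(features_matrix, dtype=float))
    if F.shape[0] != endpoints.n_samples:
        raise ValueError("features matrix must have one row per sample")
    if stream is None:
        stream = PermutationStream(cfg.seed, F.shape[0], cfg.B1)
    design = _EndpointDesign(endpoints, direction)
    t0s, res = _shared_projection_pvalues(design, F, [], cfg, stream)
    ids = feature_ids if feature_ids is not None else [f"f{j}" for j in range(F.shape[1])]
    return pd.DataFrame(
        {"feature_id": ids, "t": t0s, "p": [r.p for r in res]}
    ).set_index("feature_id")


def ccpr_gene(
    X_g: np.ndarray,
    M_g: np.ndarray,
    endpoints: EndpointTable,
    direction: EvidenceDirection,
    cfg: PermutationConfig,
    stream: PermutationStream | None = None,
) -> tuple[PromiseStat, float, PromiseStat, float, PromiseStat, float, CCAResult]:
    """Score-based analysis of one gene.

    Fits and orients the canonical correlation, computes the projection
    statistic of each score and the combined statistic (post-orientation
    sign +1), and assigns the three adaptive permutation p-values from the
    shared stream. Returns (t_expr, p_expr, t_meth, p_meth, t_comb, p_comb,
    cca).
    """
    X_g = np.atleast_2d(np.asarray(X_g, dtype=float))
    M_g = np.atleast_2d(np.asarray(M_g, dtype=float))
    if X_g.shape[0] != endpoints.n_samples:
        raise ValueError("molecular matrices must have one row per sample")
    if stream is None:
        stream = PermutationStream(cfg.seed, X_g.shape[0], cfg.B1)
    cca = orient_scores(fit_cca(X_g, M_g), X_g)
    design = _EndpointDesign(endpoints, direction)
    scores = np.column_stack([cca.expr_scores, cca.meth_scores])
    t0s, res = _shared_projection_pvalues(design, scores, [(0, 1, 1.0)], cfg, stream)
    a_x = design.signed_assoc_vector(cca.expr_scores, np.arange(endpoints.n_samples))
    a_m = design.signed_assoc_vector(cca.meth_scores, np.arange(endpoints.n_samples))
    # the association vectors are direction-signed, so the projection uses the
    # lambda magnitudes (equivalent to the signed lambda on raw statistics)
    mag_direction = EvidenceDirection(np.abs(direction.lambdas), direction.normalized)
    t_expr = promise_stat(a_x, mag_direction, kind="expression")
    t_meth = promise_stat(a_m, mag_direction, kind="methylation")
    t_comb = combined_stat(t_expr, t_meth, r=1.0)  # post-orientation sign is +1
    return t_expr, res[0].p, t_meth, res[1].p, t_comb, res[2].p, cca


def run_study(
    dataset: AlignedDataset,
    gene_maps: list[GeneFeatureMap],
    direction: EvidenceDirection,
    cfg: PermutationConfig,
) -> tuple[pd.DataFrame, list[GeneResult]]:
    """Run all analyses for every gene; returns (summary table, full results).

    One permutation stream serves the whole dataset: the score-based,
    expression feature-level and methylation marker-level analyses of every
    gene see the same permutations. Genes whose canonical correlation is
    degenerate (all columns constant) are reported as skipped, not fatal.
    """
    n = dataset.n_samples
    stream = PermutationStream(cfg.seed, n, cfg.B1)
    design = _EndpointDesign(dataset.endpoints, direction)
    results: list[GeneResult] = []
    for g_idx, gm in enumerate(gene_maps):
        res = _run_gene(dataset, gm, design, direction, cfg, stream)
        results.append(res)
        if (g_idx + 1) % 1000 == 0:
            logger.info("processed %d genes", g_idx + 1)
        else:
            logger.debug("gene %s done (skipped=%s)", gm.gene_id, res.skipped)
    n_skipped = sum(r.skipped for r in results)
    if n_skipped:
        logger.info("%d of %d genes skipped", n_skipped, len(results))
    return _results_table(results), results


def _run_gene(
    dataset: AlignedDataset,
    gm: GeneFeatureMap,
    design: _EndpointDesign,
    direction: EvidenceDirection,
    cfg: PermutationConfig,
    stream: PermutationStream,
) -> GeneResult:
    def _skip(reason: str) -> GeneResult:
        return GeneResult(
            gene_id=gm.gene_id,
            r_cc=np.nan,
            p_cc=np.nan,
            t_expr=np.nan,
            p_expr=np.nan,
            t_meth=np.nan,
            p_meth=np.nan,
            t_combined=np.nan,
            p_combined=np.nan,
            skipped=True,
            skip_reason=reason,
        )

    if not gm.expr_feature_ids or not gm.meth_feature_ids:
        return _skip("no usable features on one side")
    X = dataset.expr.subset_features(gm.expr_feature_ids).values.T  # n x F
    M = dataset.meth.subset_features(gm.meth_feature_ids).values.T  # n x L

    # complete-case per gene for the canonical fit: features (columns) with
    # any missing value are excluded from the score computation
    X_cc = X[:, ~np.isnan(X).any(axis=0)]
    M_cc = M[:, ~np.isnan(M).any(axis=0)]
    if X_cc.shape[1] == 0 or M_cc.shape[1] == 0:
        return _skip("no complete features for the canonical fit")
    try:
        cca = orient_scores(fit_cca(X_cc, M_cc), X_cc)
    except (DegenerateGeneError, ValueError) as exc:
        return _skip(f"degenerate canonical fit: {exc}")

    F, L = X.shape[1], M.shape[1]
    cols = np.column_stack([X, M, cca.expr_scores, cca.meth_scores])
    try:
        t0s, res = _shared_projection_pvalues(
            design, cols, [(F + L, F + L + 1, 1.0)], cfg, stream
        )
    except (UndefinedStatisticError, InsufficientDataError) as exc:
        return _skip(f"association statistics undefined: {exc}")

    p = np.array([r.p for r in res])
    xpr = pd.DataFrame(
        {"feature_id": gm.expr_feature_ids, "t": t0s[:F], "p": p[:F]}
    ).set_index("feature_id")
    mpr = pd.DataFrame(
        {"feature_id": gm.meth_feature_ids, "t": t0s[F : F + L], "p": p[F : F + L]}
    ).set_index("feature_id")
    uxpr = summarize_unadjusted(xpr["p"].to_numpy())
    axpr = summarize_bonferroni(xpr["p"].to_numpy())
    umpr = summarize_unadjusted(mpr["p"].to_numpy())
    ampr = summarize_bonferroni(mpr["p"].to_numpy())
    return GeneResult(
        gene_id=gm.gene_id,
        r_cc=cca.r_cc,
        p_cc=cca.p_cc,
        t_expr=float(t0s[F + L]),
        p_expr=float(p[F + L]),
        t_meth=float(t0s[F + L + 1]),
        p_meth=float(p[F + L + 1]),
        t_combined=float(t0s[F + L + 2]),
        p_combined=float(p[F + L + 2]),
        xpr=xpr,
        mpr=mpr,
        uxpr=uxpr,
        axpr=axpr,
        umpr=umpr,
        ampr=ampr,
        uov=overlap_p(umpr, uxpr),
        aov=overlap_p(ampr, axpr),
    )


_TABLE_COLUMNS = [
    "gene_id",
    "skipped",
    "skip_reason",
    "r_cc",
    "p_cc",
    "t_expr",
    "p_expr",
    "t_meth",
    "p_meth",
    "t_combined",
    "p_combined",
    "uxpr",
    "axpr",
    "umpr",
    "ampr",
    "uov",
    "aov",
]


def _results_table(results: list[GeneResult]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in _TABLE_COLUMNS} for r in results]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
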