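"""Shared data model for two-omics / multi-endpoint datasets.

An analysis dataset consists of two molecular matrices (features x samples),
an endpoint table (samples x endpoints, with per-endpoint type and
"interesting direction" declarations), and a gene-to-feature map that groups
molecular features into genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENDPOINT_KINDS = ("quantitative", "ordinal", "binary", "survival")


class DataError(ValueError):
    """Raised for structurally invalid or inconsistent input data."""


@dataclass
class OmicsMatrix:
    """One molecular data type: a features x samples numeric matrix.

    Values may be methylation beta-values, expression intensities, or any
    quantitative molecular measurement; missing values are NaN.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DataError("duplicate feature ids in omics matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids in omics matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_index(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)

    def subset_features(self, feature_ids: list[str]) -> "OmicsMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return OmicsMatrix(list(feature_ids), list(self.sample_ids), self.values[idx])

    def reorder_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return OmicsMatrix(list(self.feature_ids), list(sample_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class EndpointSpec:
    """Declaration of one endpoint: its type and interesting direction.

    ``direction_sign`` is the sign that makes a biologically "interesting"
    association positive on the correlation-like scale, e.g. -1 for a drug
    resistance measure when the interesting pattern is sensitisation.
    """

    name: str
    kind: str
    direction_sign: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ENDPOINT_KINDS:
            raise DataError(
                f"endpoint {self.name!r}: kind {self.kind!r} not one of {ENDPOINT_KINDS}"
            )
        if self.direction_sign not in (-1, 1):
            raise DataError(f"endpoint {self.name!r}: direction_sign must be -1 or +1")


@dataclass
class EndpointTable:
    """Per-sample endpoint values with declared types.

    ``values[name]`` is a float vector over samples. Survival endpoints hold
    the observed time under ``name`` and the 0/1 event indicator under
    ``name + "_event"``; times must be non-negative.
    """

    sample_ids: list[str]
    endpoints: list[EndpointSpec]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.endpoints) < 1:
            raise DataError("endpoint table must declare at least one endpoint (K >= 1)")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample ids in endpoint table")
        n = len(self.sample_ids)
        for spec in self.endpoints:
            cols = [spec.name] + ([spec.name + "_event"] if spec.kind == "survival" else [])
            for c in cols:
                if c not in self.values:
                    raise DataError(f"endpoint column {c!r} missing from values")
                v = np.asarray(self.values[c], dtype=float)
                if v.shape != (n,):
                    raise DataError(f"endpoint column {c!r} has wrong length")
                self.values[c] = v
            if spec.kind == "survival":
                t = self.values[spec.name]
                e = self.values[spec.name + "_event"]
                ok = np.isnan(t) | (t >= 0)
                if not ok.all():
                    raise DataError(f"survival endpoint {spec.name!r} has negative times")
                ok = np.isnan(e) | np.isin(e, (0.0, 1.0))
                if not ok.all():
                    raise DataError(
                        f"survival endpoint {spec.name!r} has event values outside {{0, 1}}"
                    )

    @property
    def K(self) -> int:
        return len(self.endpoints)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def reorder_samples(self, sample_ids: list[str]) -> "EndpointTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        vals = {c: v[idx] for c, v in self.values.items()}
        return EndpointTable(list(sample_ids), list(self.endpoints), vals)


@dataclass
class GeneFeatureMap:
    """Links one gene to its methylation markers and expression features."""

    gene_id: str
    meth_feature_ids: list[str]
    expr_feature_ids: list[str]

    def __post_init__(self) -> None:
        for name, ids in (("meth", self.meth_feature_ids), ("expr", self.expr_feature_ids)):
            if len(set(ids)) != len(ids):
                raise DataError(f"gene {self.gene_id!r}: duplicate {name} feature ids")


@dataclass
class AlignedDataset:
    """The three inputs restricted to a common, identically ordered sample set."""

    meth: OmicsMatrix
    expr: OmicsMatrix
    endpoints: EndpointTable
    n_dropped: dict[str, int] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.endpoints.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def align_dataset(
    meth: OmicsMatrix, expr: OmicsMatrix, endpoints: EndpointTable
) -> AlignedDataset:
    """Restrict all three inputs to their common samples, in a common order.

    Alignment is by sample-id string match. The common order is the order of
    appearance in the methylation matrix. Raises :class:`DataError` if the
    intersection is empty, naming the first unmatched ids.
    """
    sets = {
        "meth": set(meth.sample_ids),
        "expr": set(expr.sample_ids),
        "endpoints": set(endpoints.sample_ids),
    }
    common = sets["meth"] & sets["expr"] & sets["endpoints"]
    if not common:
        examples = {k: sorted(v)[:3] for k, v in sets.items()}
        raise DataError(
            "no samples are shared by the methylation, expression and endpoint "
            f"inputs; leading ids per input: {examples}"
        )
    order = [s for s in meth.sample_ids if s in common]
    dropped = {k: len(v) - len(common) for k, v in sets.items()}
    for k, d in dropped.items():
        if d:
            logger.info("alignment dropped %d sample(s) from %s", d, k)
    return AlignedDataset(
        meth=meth.reorder_samples(order),
        expr=expr.reorder_samples(order),
        endpoints=endpoints.reorder_samples(order),
        n_dropped=dropped,
    )


def validate_gene_map(
    gene_map: GeneFeatureMap, meth: OmicsMatrix, expr: OmicsMatrix
) -> tuple[GeneFeatureMap, bool]:
    """Drop feature ids absent from the matrices; flag unusable genes.

    Returns ``(validated_map, skipped)`` where ``skipped`` is True when the
    gene is left without any methylation marker or any expression feature.
    Missing ids are reported, never invented.
    """
    meth_ids = [f for f in gene_map.meth_feature_ids if f in set(meth.feature_ids)]
    expr_ids = [f for f in gene_map.expr_feature_ids if f in set(expr.feature_ids)]
    n_lost = (len(gene_map.meth_feature_ids) - len(meth_ids)) + (
        len(gene_map.expr_feature_ids) - len(expr_ids)
    )
    if n_lost:
        logger.warning(
            "gene %s: %d mapped feature id(s) absent from the matrices",
            gene_map.gene_id,
            n_lost,
        )
    validated = replace(gene_map, meth_feature_ids=meth_ids, expr_feature_ids=expr_ids)
    skipped = not meth_ids or not expr_ids
    if skipped:
        logger.warning("gene %s skipped: no usable features on one side", gene_map.gene_id)
    return validated, skipped
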