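"""Delimited-text readers/writers and run bookkeeping.

Canonical formats (tab-separated; comma accepted via ``sep``):

* omics matrix: first column the feature id, header row of sample ids;
* endpoint table: first column the sample id, one column per endpoint,
  survival endpoints as a ``<name>_time`` / ``<name>_event`` column pair;
* gene map: columns ``gene_id``, ``data_type`` in {meth, expr}, ``feature_id``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    DataError,
    EndpointSpec,
    EndpointTable,
    GeneFeatureMap,
    OmicsMatrix,
)

logger = logging.getLogger(__name__)


def read_omics_tsv(path: str | Path, sep: str = "\t") -> OmicsMatrix:
    """Read a features x samples matrix; non-numeric cells become missing."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"{path}: duplicate feature id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise DataError(f"{path}: duplicate sample id {dup!r}")
    def _parse(v):
        # python float() round-trips shortest-repr decimals exactly, unlike
        # pandas' fast to_numeric path
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    values = df.map(_parse).to_numpy(dtype=float)
    n_coerced = int(np.isnan(values).sum() - df.isna().to_numpy().sum())
    if n_coerced:
        logger.warning("%s: %d non-numeric cell(s) treated as missing", path, n_coerced)
    return OmicsMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=values,
    )


def read_endpoints_tsv(
    path: str | Path, specs: list[EndpointSpec], sep: str = "\t"
) -> EndpointTable:
    """Read the sample x endpoint table against the declared endpoint specs."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        raise DataError(f"{path}: duplicate sample id")
    values: dict[str, np.ndarray] = {}
    for spec in specs:
        cols = (
            [spec.name + "_time", spec.name + "_event"]
            if spec.kind == "survival"
            else [spec.name]
        )
        for c in cols:
            if c not in df.columns:
                raise DataError(f"{path}: declared endpoint column {c!r} not found")
        if spec.kind == "survival":
            values[spec.name] = pd.to_numeric(df[spec.name + "_time"], errors="coerce").to_numpy()
            ev = pd.to_numeric(df[spec.name + "_event"], errors="coerce").to_numpy()
            bad = ~np.isnan(ev) & ~np.isin(ev, (0.0, 1.0))
            if bad.any():
                raise DataError(
                    f"{path}: endpoint {spec.name!r} has event values outside {{0, 1}}"
                )
            values[spec.name + "_event"] = ev
        else:
            values[spec.name] = pd.to_numeric(df[spec.name], errors="coerce").to_numpy()
    return EndpointTable(
        sample_ids=[str(i) for i in df.index], endpoints=list(specs), values=values
    )


def read_gene_map_tsv(path: str | Path, sep: str = "\t") -> list[GeneFeatureMap]:
    """Read the long-format gene map into one :class:`GeneFeatureMap` per gene."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"gene_id", "data_type", "feature_id"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: gene map needs columns {sorted(required)}")
    bad = set(df["data_type"]) - {"meth", "expr"}
    if bad:
        raise DataError(f"{path}: unknown data_type value(s) {sorted(bad)}")
    maps = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        maps.append(
            GeneFeatureMap(
                gene_id=str(gene_id),
                meth_feature_ids=list(dict.fromkeys(grp.loc[grp.data_type == "meth", "feature_id"])),
                expr_feature_ids=list(dict.fromkeys(grp.loc[grp.data_type == "expr", "feature_id"])),
            )
        )
    return maps


def write_omics_tsv(matrix: OmicsMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="feature_id", float_format="%.17g")


def write_results(
    results: pd.DataFrame,
    path: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write the per-gene results table plus a JSON sidecar.

    The sidecar records the configuration, seed, package version and skip
    counts — enough to reproduce the run bit-exactly.
    """
    from . import __version__

    path = Path(path)
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "version": __version__,
        "seed": seed,
        "config": config or {},
        "n_genes": int(results.shape[0]),
        "n_skipped": int(results["skipped"].sum()) if "skipped" in results else 0,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def expected_false_discoveries(threshold: float, n_genes: int) -> float:
    """Expected count of false discoveries: threshold x number of genes tested.

    E.g. a p-value threshold of 0.001 over 11,620 genes is expected to yield
    0.001 x 11620 = 11.6 false discoveries under the global null.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    return threshold * n_genes
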