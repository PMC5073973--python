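"""Simulation machinery: single-gene data generator and operating-characteristic
estimation for the competing analysis strategies.

Each simulated dataset holds one gene with M = 10 methylation markers,
F = 2 expression features and K = 2 quantitative endpoints for n subjects.
Per subject: the first marker is standard normal, subsequent markers follow
the autoregression m_l = beta_m * m_{l-1} + e; the two expression features
follow x_j = beta_x * m_j + e (j = 1, 2); the two endpoints follow
y_j = beta_y * x_j + e; every e is an independent standard normal. Thus
beta_x links methylation to expression and beta_y links the molecular data
to the endpoints — settings with beta_y = 0 are null settings in which any
declared significance is a type I error, and settings with beta_y != 0
measure power. Note the marker chain is not variance-stationary: the
variances propagate as var(m_1) = 1, var(m_l) = 1 + beta_m^2 var(m_{l-1}).

The default evaluation grid crosses beta_m, beta_x, beta_y over
{-0.5, -0.3, 0, 0.3, 0.5} with n in {30, 50, 100, 500} (500 settings, 100
of them null), with 1000 replicates per setting and a significance
threshold of 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import run_study
from .core_data import (
    AlignedDataset,
    EndpointSpec,
    EndpointTable,
    GeneFeatureMap,
    OmicsMatrix,
)
from .permutation import PermutationConfig
from .promise import build_evidence_vector

logger = logging.getLogger(__name__)

BETA_GRID = (-0.5, -0.3, 0.0, 0.3, 0.5)
N_GRID = (30, 50, 100, 500)

METHODS = ("CCPR", "UXPR", "AXPR", "UMPR", "AMPR", "UOV", "AOV")

_METHOD_COLUMN = {
    "CCPR": "p_combined",
    "UXPR": "uxpr",
    "AXPR": "axpr",
    "UMPR": "umpr",
    "AMPR": "ampr",
    "UOV": "uov",
    "AOV": "aov",
}


@dataclass(frozen=True)
class SimulationSetting:
    """One point of the simulation grid."""

    beta_m: float
    beta_x: float
    beta_y: float
    n: int
    n_markers: int = 10
    n_expr: int = 2
    K: int = 2

    def key(self) -> tuple[int, int, int, int]:
        """Non-negative integer encoding used to derive per-replicate seeds."""
        return (
            int(round(self.beta_m * 10)) + 100,
            int(round(self.beta_x * 10)) + 100,
            int(round(self.beta_y * 10)) + 100,
            self.n,
        )

    @property
    def is_null(self) -> bool:
        return self.beta_y == 0.0


@dataclass
class SettingResult:
    """Rejection proportions for each method at one setting."""

    setting: SimulationSetting
    reps: int
    alpha: float
    rejection_rate: dict[str, float] = field(default_factory=dict)
    mcse: dict[str, float] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        s = self.setting
        return [
            {
                "beta_m": s.beta_m,
                "beta_x": s.beta_x,
                "beta_y": s.beta_y,
                "n": s.n,
                "reps": self.reps,
                "alpha": self.alpha,
                "method": m,
                "rejection_rate": self.rejection_rate[m],
                "mcse": self.mcse[m],
            }
            for m in self.rejection_rate
        ]


def generate_dataset(setting: SimulationSetting, seed) -> AlignedDataset:
    """Generate one single-gene two-omics dataset with two endpoints.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``. Endpoints are
    quantitative with interesting direction +1.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.Philox(ss))
    n, M = setting.n, setting.n_markers
    meth = np.empty((M, n))
    meth[0] = rng.standard_normal(n)
    for l in range(1, M):
        meth[l] = setting.beta_m * meth[l - 1] + rng.standard_normal(n)
    expr = np.empty((setting.n_expr, n))
    for j in range(setting.n_expr):
        expr[j] = setting.beta_x * meth[j] + rng.standard_normal(n)
    y = np.empty((setting.K, n))
    for j in range(setting.K):
        y[j] = setting.beta_y * expr[j] + rng.standard_normal(n)

    samples = [f"s{i}" for i in range(n)]
    meth_m = OmicsMatrix([f"m{l + 1}" for l in range(M)], samples, meth)
    expr_m = OmicsMatrix([f"x{j + 1}" for j in range(setting.n_expr)], samples, expr)
    specs = [EndpointSpec(f"y{k + 1}", "quantitative", 1) for k in range(setting.K)]
    endpoints = EndpointTable(samples, specs, {f"y{k + 1}": y[k] for k in range(setting.K)})
    return AlignedDataset(meth=meth_m, expr=expr_m, endpoints=endpoints)


def simulated_gene_map(setting: SimulationSetting) -> GeneFeatureMap:
    return GeneFeatureMap(
        gene_id="G1",
        meth_feature_ids=[f"m{l + 1}" for l in range(setting.n_markers)],
        expr_feature_ids=[f"x{j + 1}" for j in range(setting.n_expr)],
    )


def replicate_pvalues(
    setting: SimulationSetting,
    rep: int,
    perm_cfg: PermutationConfig,
    seed: int,
    methods=METHODS,
) -> dict[str, float]:
    """Run every requested analysis on one simulated replicate.

    The replicate's data seed and permutation seed are both derived from
    (base seed, setting, replicate index), so any single replicate is
    reproducible in isolation.
    """
    ss = np.random.SeedSequence((seed, *setting.key(), rep))
    data_ss, perm_ss = ss.spawn(2)
    dataset = generate_dataset(setting, data_ss)
    perm_seed = int(perm_ss.generate_state(1)[0])
    cfg = replace(perm_cfg, seed=perm_seed)
    direction = build_evidence_vector(dataset.endpoints.endpoints, normalized=True)
    table, _ = run_study(dataset, [simulated_gene_map(setting)], direction, cfg)
    row = table.iloc[0]
    return {m: float(row[_METHOD_COLUMN[m]]) for m in methods}


def run_setting(
    setting: SimulationSetting,
    reps: int = 1000,
    alpha: float = 0.01,
    methods=METHODS,
    perm_cfg: PermutationConfig | None = None,
    seed: int = 0,
) -> SettingResult:
    """Estimate each method's rejection proportion at one setting.

    A method rejects a replicate when its gene summary p-value is <= alpha.
    The Monte Carlo standard error is sqrt(p_hat (1 - p_hat) / reps).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if perm_cfg is None:
        perm_cfg = PermutationConfig()
    rejections = {m: 0 for m in methods}
    for rep in range(reps):
        pvals = replicate_pvalues(setting, rep, perm_cfg, seed, methods=methods)
        for m in methods:
            if pvals[m] <= alpha:
                rejections[m] += 1
    result = SettingResult(setting=setting, reps=reps, alpha=alpha)
    for m in methods:
        phat = rejections[m] / reps
        result.rejection_rate[m] = phat
        result.mcse[m] = float(np.sqrt(phat * (1.0 - phat) / reps))
    return result


def default_grid(
    beta_m=BETA_GRID, beta_x=BETA_GRID, beta_y=BETA_GRID, n=N_GRID
) -> list[SimulationSetting]:
    """The evaluation grid; pass subsets of each axis to restrict it."""
    return [
        SimulationSetting(bm, bx, by, nn)
        for bm in beta_m
        for bx in beta_x
        for by in beta_y
        for nn in n
    ]


def run_grid(
    settings: list[SimulationSetting],
    reps: int = 1000,
    alpha: float = 0.01,
    out_path: str | Path | None = None,
    perm_cfg: PermutationConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run a list of settings, checkpointing per setting.

    Returns one row per (setting, method). With ``out_path`` set, results
    are appended after each setting and settings already present in the file
    are skipped, making long grids resumable.
    """
    out_path = Path(out_path) if out_path is not None else None
    done: set[tuple] = set()
    frames: list[pd.DataFrame] = []
    if out_path is not None and out_path.exists():
        prev = pd.read_csv(out_path, sep="\t")
        frames.append(prev)
        done = {
            (round(r.beta_m, 6), round(r.beta_x, 6), round(r.beta_y, 6), int(r.n))
            for r in prev.itertuples()
        }
    for i, setting in enumerate(settings):
        skey = (
            round(setting.beta_m, 6),
            round(setting.beta_x, 6),
            round(setting.beta_y, 6),
            setting.n,
        )
        if skey in done:
            logger.info("setting %s already computed, skipping", skey)
            continue
        res = run_setting(setting, reps=reps, alpha=alpha, perm_cfg=perm_cfg, seed=seed)
        frames.append(pd.DataFrame(res.to_rows()))
        if out_path is not None:
            pd.concat(frames, ignore_index=True).to_csv(out_path, sep="\t", index=False)
        logger.info("setting %d/%d done: %s", i + 1, len(settings), skey)
    if not frames:
        return pd.DataFrame(
            columns=[
                "beta_m",
                "beta_x",
                "beta_y",
                "n",
                "reps",
                "alpha",
                "method",
                "rejection_rate",
                "mcse",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def null_and_power_summaries(grid_results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split grid results into the null subset (beta_y = 0) and the rest."""
    is_null = grid_results["beta_y"] == 0.0
    return grid_results[is_null].copy(), grid_results[~is_null].copy()
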