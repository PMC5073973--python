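import itertools

import numpy as np
import pytest
from scipy import stats

from ccpromise.analysis import (
    ccpr_gene,
    feature_promise,
    overlap_p,
    run_study,
    summarize_bonferroni,
    summarize_unadjusted,
)
from ccpromise.cca import fit_cca, orient_scores
from ccpromise.core_data import (
    AlignedDataset,
    EndpointSpec,
    EndpointTable,
    GeneFeatureMap,
    OmicsMatrix,
)
from ccpromise.permutation import PermutationConfig
from ccpromise.promise import EvidenceDirection, build_evidence_vector
from ccpromise.simulation import (
    SimulationSetting,
    generate_dataset,
    replicate_pvalues,
    simulated_gene_map,
)
from tests.test_permutation import EnumeratingStream


def _quant_table(values: dict, signs=None):
    n = len(next(iter(values.values())))
    samples = [f"s{i}" for i in range(n)]
    signs = signs or [1] * len(values)
    specs = [EndpointSpec(k, "quantitative", s) for k, s in zip(values, signs)]
    return EndpointTable(samples, specs, {k: np.asarray(v, float) for k, v in values.items()})


class TestGeneSummaries:
    @pytest.mark.parametrize(
        "ps, expected", [((0.004, 0.2), 0.004), ((0.03,), 0.03), ((1.0, 1.0), 1.0)]
    )
    def test_unadjusted_is_the_minimum(self, ps, expected):
        assert summarize_unadjusted(np.array(ps)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ps, expected", [((0.004, 0.2), 0.008), ((0.6, 0.7), 1.0), ((0.03,), 0.03)]
    )
    def test_bonferroni_scales_and_caps(self, ps, expected):
        assert summarize_bonferroni(np.array(ps)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pa, pb, expected", [((0.008), 0.03, 0.03), (0.5, 0.5, 0.5), (1e-4, 1.0, 1.0)]
    )
    def test_overlap_takes_the_maximum(self, pa, pb, expected):
        assert overlap_p(pa, pb) == pytest.approx(expected)


class TestCcprGene:
    def _gene(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 2))
        M = rng.standard_normal((n, 4)) + 0.5 * X[:, :1]
        return X, M

    def test_endpoints_equal_to_expression_score_give_unit_statistic(self):
        X, M = self._gene()
        score = orient_scores(fit_cca(X, M), X).expr_scores
        table = _quant_table({"y1": score, "y2": score})
        d = build_evidence_vector(table.endpoints, normalized=True)
        tx, px, tm, pm, tc, pc, _ = ccpr_gene(
            X, M, table, d, PermutationConfig(B0=100, B1=10_000, seed=4)
        )
        assert tx.t == pytest.approx(1.0)
        assert px <= 0.01

    def test_duplicated_endpoint_doubles_the_unnormalized_statistic(self):
        X, M = self._gene(seed=1)
        rng = np.random.default_rng(2)
        y1 = rng.standard_normal(30)
        table = _quant_table({"y1": y1, "y2": y1})
        d = build_evidence_vector(table.endpoints, normalized=False)
        tx, *_ = ccpr_gene(X, M, table, d, PermutationConfig(B0=50, B1=500, seed=9))
        score = orient_scores(fit_cca(X, M), X).expr_scores
        single = stats.spearmanr(score, y1).statistic
        assert tx.t == pytest.approx(2 * single, abs=1e-10)

    def test_combined_uses_post_orientation_positive_sign(self):
        X, M = self._gene(seed=3)
        rng = np.random.default_rng(5)
        table = _quant_table({"y1": rng.standard_normal(30), "y2": rng.standard_normal(30)})
        d = build_evidence_vector(table.endpoints)
        tx, _, tm, _, tc, _, cca = ccpr_gene(X, M, table, d, PermutationConfig(B0=20, B1=200, seed=2))
        assert tc.t == pytest.approx(tx.t + tm.t, abs=1e-12)
        assert np.corrcoef(cca.expr_scores, cca.meth_scores)[0, 1] >= 0

    def test_null_combined_pvalues_approximately_uniform(self):
        """Permutation p of the combined score statistic calibrates under a
        null in which endpoints are independent of the molecular data."""
        cfg = PermutationConfig(B0=300, B1=300, seed=0)
        setting = SimulationSetting(0.3, 0.3, 0.0, 30)
        ps = np.array(
            [replicate_pvalues(setting, rep, cfg, seed=77)["CCPR"] for rep in range(300)]
        )
        counts, _ = np.histogram(ps, bins=np.linspace(0, 1, 11))
        assert stats.chisquare(counts).pvalue > 0.001


class TestFeaturePromise:
    def test_single_feature_equal_to_single_endpoint_gives_lambda(self):
        y = np.arange(10.0)
        table = _quant_table({"y1": y})
        d = EvidenceDirection(np.array([1.0]), normalized=False)
        out = feature_promise(y[:, None], table, d, PermutationConfig(B0=20, B1=100, seed=0))
        assert out["t"].iloc[0] == pytest.approx(1.0)

    def test_mixed_direction_signs_accumulate_interesting_evidence(self):
        """A feature matching the interesting pattern of every endpoint
        (positively for sign +1, negatively for sign -1) attains t = +1
        under the normalized direction — the signs are applied exactly once."""
        f = np.arange(12.0)
        table = _quant_table({"y1": f, "y2": -f}, signs=[1, -1])
        d = build_evidence_vector(table.endpoints, normalized=True)
        out = feature_promise(f[:, None], table, d, PermutationConfig(B0=10, B1=60, seed=2))
        assert out["t"].iloc[0] == pytest.approx(1.0)

    def test_identical_features_share_statistic_and_pvalue(self):
        rng = np.random.default_rng(21)
        f = rng.standard_normal(20)
        F = np.column_stack([f, f])
        table = _quant_table({"y1": rng.standard_normal(20), "y2": rng.standard_normal(20)})
        d = build_evidence_vector(table.endpoints)
        out = feature_promise(F, table, d, PermutationConfig(B0=50, B1=1000, seed=5))
        assert out["t"].iloc[0] == out["t"].iloc[1]
        assert out["p"].iloc[0] == out["p"].iloc[1]

    def test_adaptive_pvalue_matches_exact_enumeration_on_tiny_n(self):
        from ccpromise.assoc import rank_standardize
        from ccpromise.permutation import exact_reference_pvalue

        n = 6
        rng = np.random.default_rng(31)
        f = rng.standard_normal(n)
        y1, y2 = rng.standard_normal(n), rng.standard_normal(n)
        table = _quant_table({"y1": y1, "y2": y2})
        d = build_evidence_vector(table.endpoints)
        stream = EnumeratingStream(n)
        cfg = PermutationConfig(B0=stream.B1, B1=stream.B1, seed=0)
        out = feature_promise(f[:, None], table, d, cfg, stream=stream)

        zf = rank_standardize(f)
        zys = np.column_stack([rank_standardize(y1), rank_standardize(y2)])

        def stat(perm):
            return float(zf @ (zys[perm] @ d.lambdas))

        expected = exact_reference_pvalue(stat(np.arange(n)), stat, n)
        assert out["p"].iloc[0] == pytest.approx(expected)


class TestRunStudy:
    def _dataset(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(n)]
        meth_ids = [f"cg{i}" for i in range(6)]
        expr_ids = [f"ps{i}" for i in range(4)]
        meth_vals = rng.standard_normal((6, n))
        meth_vals[4:] = 1.0  # two constant markers -> gene g3 degenerate
        meth = OmicsMatrix(meth_ids, samples, meth_vals)
        expr = OmicsMatrix(expr_ids, samples, rng.standard_normal((4, n)))
        table = _quant_table({"y1": rng.standard_normal(n), "y2": rng.standard_normal(n)})
        maps = [
            GeneFeatureMap("g1", ["cg0", "cg1"], ["ps0", "ps1"]),
            GeneFeatureMap("g2", ["cg2", "cg3"], ["ps2"]),
            GeneFeatureMap("g3", ["cg4", "cg5"], ["ps3"]),
        ]
        return AlignedDataset(meth=meth, expr=expr, endpoints=table), maps

    def test_degenerate_gene_is_skipped_not_fatal(self):
        ds, maps = self._dataset()
        d = build_evidence_vector(ds.endpoints.endpoints)
        table, results = run_study(ds, maps, d, PermutationConfig(B0=20, B1=200, seed=1))
        assert table.shape[0] == 3
        assert table["skipped"].sum() == 1
        assert table.loc[table.gene_id == "g3", "skipped"].item()

    def test_rerun_with_same_seed_is_bit_identical(self):
        ds, maps = self._dataset(seed=2)
        d = build_evidence_vector(ds.endpoints.endpoints)
        cfg = PermutationConfig(B0=20, B1=500, seed=11)
        t1, _ = run_study(ds, maps, d, cfg)
        t2, _ = run_study(ds, maps, d, cfg)
        import pandas as pd

        pd.testing.assert_frame_equal(t1, t2)

    def test_simulated_gene_populates_all_seven_summaries(self):
        setting = SimulationSetting(0.3, 0.5, 0.5, 40)
        ds = generate_dataset(setting, 3)
        d = build_evidence_vector(ds.endpoints.endpoints)
        table, results = run_study(
            ds, [simulated_gene_map(setting)], d, PermutationConfig(B0=50, B1=1000, seed=3)
        )
        row = table.iloc[0]
        for col in ("p_combined", "uxpr", "axpr", "umpr", "ampr", "uov", "aov"):
            assert 0 < row[col] <= 1.0
        assert row["uxpr"] <= row["axpr"]
        assert row["umpr"] <= row["ampr"]
        assert row["uov"] == max(row["umpr"], row["uxpr"])
        assert row["aov"] == max(row["ampr"], row["axpr"])

    def test_missing_endpoint_values_fall_back_to_pairwise_path(self):
        ds, maps = self._dataset(seed=4)
        y1 = ds.endpoints.values["y1"].copy()
        y1[:3] = np.nan
        ds.endpoints.values["y1"] = y1
        d = build_evidence_vector(ds.endpoints.endpoints)
        table, _ = run_study(ds, maps[:1], d, PermutationConfig(B0=10, B1=60, seed=5))
        assert not table.iloc[0]["skipped"]
        assert 0 < table.iloc[0]["p_combined"] <= 1

    def test_score_analysis_set_contains_at_least_the_overlap_set(self):
        """On matched simulations with shared permutations, the gene set
        declared significant by the score-based combined analysis is at
        least as large as the overlap-rule set (the rejection-region
        containment tendency, asserted as a set-size inequality)."""
        setting = SimulationSetting(0.5, 0.5, 0.5, 50)
        cfg = PermutationConfig(B0=100, B1=10_000)
        alpha = 0.001
        n_ccpr = n_uov = 0
        for rep in range(120):
            pv = replicate_pvalues(setting, rep, cfg, seed=13, methods=("CCPR", "UOV"))
            n_ccpr += pv["CCPR"] <= alpha
            n_uov += pv["UOV"] <= alpha
        assert n_ccpr >= n_uov
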