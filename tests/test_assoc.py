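import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ccpromise.assoc import (
    InsufficientDataError,
    UndefinedStatisticError,
    binary_assoc,
    endpoint_assoc_vector,
    martingale_residuals,
    nelson_aalen_cumhaz,
    pair_correlation,
    spearman_assoc,
    survival_assoc,
)
from ccpromise.core_data import EndpointSpec, EndpointTable

finite_floats = st.floats(-1e6, 1e6, allow_nan=False)


class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (10, 20, 30), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3), (3, 1, 2), -0.5),  # rank-covariance on the 3-point ranks
        ],
    )
    def test_known_values(self, x, y, expected):
        assert spearman_assoc(np.array(x), np.array(y)).value == pytest.approx(expected)

    def test_pairwise_missing_removal(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, np.nan])
        res = spearman_assoc(x, y)
        assert res.n_used == 3
        assert res.value == pytest.approx(1.0)

    def test_too_few_points_raise(self):
        with pytest.raises(InsufficientDataError):
            spearman_assoc(np.array([1.0, 2.0]), np.array([3.0, 4.0]))

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_assoc(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=30, unique=True).flatmap(
        lambda x: st.tuples(st.just(x), st.permutations(x))
    ))
    def test_invariant_under_strictly_monotone_transforms(self, xy):
        x, y = np.array(xy[0], float), np.array(xy[1], float)
        base = spearman_assoc(x, y).value
        # arctan and affine maps are strictly increasing
        assert spearman_assoc(np.arctan(x), y).value == pytest.approx(base, abs=1e-12)
        assert spearman_assoc(x, 2.0 * y + 1).value == pytest.approx(base, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.integers(4, 25),
    )
    def test_all_statistics_bounded_by_one(self, seed, n):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        assert abs(spearman_assoc(x, y).value) <= 1 + 1e-12
        g = (rng.random(n) < 0.5).astype(float)
        if 0 < g.sum() < n:
            assert abs(binary_assoc(x, g).value) <= 1 + 1e-12
        t = rng.exponential(1.0, n)
        e = (rng.random(n) < 0.7).astype(float)
        if e.sum() > 0:
            assert abs(survival_assoc(x, t, e).value) <= 1 + 1e-12


class TestBinary:
    def test_two_group_rank_biserial_value(self):
        # Spearman of ranks (1,2,3,4) with the 0/1 indicator: 4 / (2*sqrt(5))
        res = binary_assoc(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 1, 1]))
        assert res.value == pytest.approx(2 / np.sqrt(5), abs=1e-10)

    def test_single_group_raises(self):
        with pytest.raises(UndefinedStatisticError):
            binary_assoc(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))

    def test_constant_feature_raises(self):
        with pytest.raises(UndefinedStatisticError):
            binary_assoc(np.array([2.0, 2.0, 2.0, 2.0]), np.array([0, 0, 1, 1]))


class TestSurvival:
    def test_all_event_anti_concordant_matches_hand_oracle(self):
        """Nelson-Aalen table for time 1..5, all events, n at risk 5..1:
        H = (0.2, 0.45, 0.7833.., 1.2833.., 2.2833..), residuals 1 - H are
        strictly decreasing, so x = (5,4,3,2,1) is perfectly concordant with
        the residuals and the negated statistic is exactly -1."""
        time = np.arange(1.0, 6.0)
        event = np.ones(5)
        H_oracle = np.array([1 / 5, 1 / 5 + 1 / 4, 1 / 5 + 1 / 4 + 1 / 3,
                             1 / 5 + 1 / 4 + 1 / 3 + 1 / 2,
                             1 / 5 + 1 / 4 + 1 / 3 + 1 / 2 + 1 / 1])
        np.testing.assert_allclose(nelson_aalen_cumhaz(time, event), H_oracle, atol=1e-12)
        resid_oracle = event - H_oracle
        x = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        expected = -stats.spearmanr(x, resid_oracle).statistic
        res = survival_assoc(x, time, event)
        assert res.value == pytest.approx(expected, abs=1e-12)
        assert res.value == pytest.approx(-1.0)

    def test_sign_convention_higher_x_longer_survival_is_positive(self):
        time = np.arange(1.0, 9.0)
        x = time.copy()  # larger x, later event
        assert survival_assoc(x, time, np.ones(8)).value > 0

    def test_zero_events_return_zero_information(self):
        res = survival_assoc(np.array([1.0, 2.0, 3.0]), np.array([5.0, 6.0, 7.0]), np.zeros(3))
        assert res.value == 0.0

    def test_cumulative_hazard_matches_lifelines(self):
        from lifelines import NelsonAalenFitter

        rng = np.random.default_rng(7)
        time = rng.exponential(2.0, 40).round(2) + 0.01
        event = (rng.random(40) < 0.6).astype(float)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(time, event_observed=event)
        ours = nelson_aalen_cumhaz(time, event)
        theirs = naf.cumulative_hazard_at_times(time).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_residuals_sum_to_zero_with_no_censoring(self):
        rng = np.random.default_rng(3)
        time = rng.exponential(1.0, 30)
        resid = martingale_residuals(time, np.ones(30))
        assert resid.sum() == pytest.approx(0.0, abs=1e-9)


class TestPairCorrelation:
    @pytest.mark.parametrize(
        "x, m, expected",
        [
            ((0, 1, 2), (1, 3, 5), 1.0),
            ((1, 2, 3), (1, 3, 2), 0.5),  # direct Pearson on centered vectors
            ((1, 2, 3), (3, 2, 1), -1.0),
        ],
    )
    def test_known_values(self, x, m, expected):
        assert pair_correlation(np.array(x, float), np.array(m, float)).r == pytest.approx(
            expected
        )

    def test_constant_input_raises(self):
        with pytest.raises(UndefinedStatisticError):
            pair_correlation(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_pvalues_uniform_under_independence(self):
        """Two-sided t-based p-values are uniform for independent normals."""
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(2000):
            x, m = rng.standard_normal(15), rng.standard_normal(15)
            ps.append(pair_correlation(x, m).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestEndpointAssocVector:
    def _table(self, values, signs=(1, 1)):
        n = len(next(iter(values.values())))
        samples = [f"s{i}" for i in range(n)]
        specs = [
            EndpointSpec(name, "quantitative", sign)
            for name, sign in zip(values, signs)
        ]
        return EndpointTable(samples, specs, {k: np.asarray(v, float) for k, v in values.items()})

    def test_perfectly_associated_endpoints_give_plus_one(self):
        f = np.arange(8.0)
        table = self._table({"a": f, "b": f})
        vals = [s.value for s in endpoint_assoc_vector(f, table)]
        assert vals == pytest.approx([1.0, 1.0])

    def test_direction_sign_makes_interesting_association_positive(self):
        f = np.arange(8.0)
        table = self._table({"a": f, "b": f}, signs=(1, -1))
        vals = [s.value for s in endpoint_assoc_vector(f, table)]
        assert vals == pytest.approx([1.0, -1.0])

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(5)
        n = 4000
        f = rng.standard_normal(n)
        table = self._table({"a": rng.standard_normal(n)}, signs=(1,))
        (stat,) = endpoint_assoc_vector(f, table)
        assert abs(stat.value) < 3 / np.sqrt(n)

    def test_failed_endpoint_becomes_none_not_fatal(self):
        f = np.arange(6.0)
        table = self._table({"a": f, "b": np.ones(6)})
        out = endpoint_assoc_vector(f, table)
        assert out[0].value == pytest.approx(1.0)
        assert out[1] is None
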