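"""Exact Galton-Watson analytics: PGF, extinction probability, CDF, E[T]."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitolineage import (
    classify_criticality,
    dual_subcritical,
    extinction_cdf,
    extinction_probability,
    extinction_quantile,
    make_empirical_pmf,
    mean_extinction_time,
    parametric_pmf,
    pgf_eval,
)
from mitolineage.errors import ParameterError, QuantileUnreachableError

from conftest import pmf_strategy


class TestPgf:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(dist=pmf_strategy())
    def test_boundary_values(self, dist):
        assert pgf_eval(dist, 1.0) == pytest.approx(1.0, abs=1e-12)
        assert pgf_eval(dist, 0.0) == pytest.approx(
            dist.pmf_dict().get(0, 0.0), abs=1e-15
        )

    def test_poisson_against_series_oracle(self, poisson_095):
        # f(s) = e^{m(s-1)} for Poisson; at s = 0.5 this is e^{-0.475}.
        sup, prob = poisson_095.as_arrays()
        series = float(np.sum(prob * 0.5**sup))
        assert pgf_eval(poisson_095, 0.5) == pytest.approx(series, abs=1e-15)
        assert pgf_eval(poisson_095, 0.5) == pytest.approx(
            math.exp(-0.475), abs=1e-9
        )

    def test_domain_error(self, poisson_095):
        with pytest.raises(ParameterError):
            pgf_eval(poisson_095, 1.5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(dist=pmf_strategy(), s=st.floats(0, 1), t=st.floats(0, 1))
    def test_monotone_in_s(self, dist, s, t):
        lo, hi = sorted((s, t))
        assert pgf_eval(dist, lo) <= pgf_eval(dist, hi) + 1e-12


class TestCriticality:
    def test_classification(
        self, census_standin, unit_law, binary_fission, critical_geometric, zero_law
    ):
        assert classify_criticality(census_standin) == "subcritical"
        assert classify_criticality(zero_law) == "subcritical"
        assert classify_criticality(unit_law) == "degenerate_unit"
        assert classify_criticality(binary_fission) == "supercritical"
        assert classify_criticality(critical_geometric) == "critical"


class TestExtinctionProbability:
    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(dist=pmf_strategy())
    def test_certain_extinction_iff_mean_at_most_one(self, dist):
        cls = classify_criticality(dist)
        q = extinction_probability(dist)
        if cls in ("subcritical", "critical"):
            assert q == 1.0
        elif cls == "degenerate_unit":
            assert q == 0.0
        else:
            assert q < 1.0
            # smallest fixed point: f(q) = q
            assert pgf_eval(dist, q) == pytest.approx(q, abs=1e-10)

    def test_binary_fission_quadratic_root(self, binary_fission):
        # 0.8 q^2 - q + 0.2 = 0 has smallest root exactly 1/4.
        assert extinction_probability(binary_fission) == pytest.approx(
            0.25, abs=1e-10
        )

    def test_unit_law_never_dies(self, unit_law):
        assert extinction_probability(unit_law) == 0.0


class TestExtinctionCdf:
    def test_critical_geometric_closed_form(self, critical_geometric):
        curve = extinction_cdf(critical_geometric, horizon=120)
        n = np.arange(101)
        np.testing.assert_allclose(curve.q[:101], n / (n + 1), atol=1e-12)

    def test_zero_law_extinct_after_founder(self, zero_law):
        curve = extinction_cdf(zero_law, horizon=5)
        assert curve.q[1] == 1.0

    def test_poisson_two_step_hand_iteration(self, poisson_095):
        curve = extinction_cdf(poisson_095, horizon=10)
        q1 = math.exp(-0.95)
        q2 = math.exp(0.95 * (q1 - 1))
        assert curve.q[1] == pytest.approx(q1, abs=1e-9)
        assert curve.q[2] == pytest.approx(q2, abs=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(dist=pmf_strategy())
    def test_monotone_and_bounded_by_q_star(self, dist):
        curve = extinction_cdf(dist, horizon=300)
        q = np.asarray(curve.q)
        assert q[0] == 0.0
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all(q <= curve.q_star + 1e-12)
        # fixed-point consistency of the limit
        assert pgf_eval(dist, curve.q_star) == pytest.approx(
            curve.q_star, abs=1e-11
        )

    def test_near_critical_reports_nonconvergence(self):
        near = parametric_pmf("geometric", 0.999999)
        curve = extinction_cdf(near, horizon=10)
        assert not curve.converged
        assert curve.q_star == 1.0

    def test_dual_process_curve_is_rescaled_original(self, binary_fission):
        q_star = extinction_probability(binary_fission)
        orig = extinction_cdf(binary_fission, horizon=60)
        dual = extinction_cdf(dual_subcritical(binary_fission), horizon=60)
        np.testing.assert_allclose(
            dual.q, np.asarray(orig.q) / q_star, atol=1e-9
        )


class TestMeanExtinctionTime:
    def test_zero_law_forced_convention(self, zero_law):
        assert mean_extinction_time(zero_law) == 1.0

    def test_poisson_half_against_long_summation(self, poisson_half):
        # independent oracle: plain summation of survival probabilities
        q, total = 0.0, 0.0
        for _ in range(10_000):
            total += 1.0 - q
            q = pgf_eval(poisson_half, q)
        assert total == pytest.approx(1.7405360939, abs=1e-8)
        assert mean_extinction_time(poisson_half) == pytest.approx(total, abs=1e-6)

    @pytest.mark.parametrize("mean", [0.3, 0.6, 0.9])
    def test_subcritical_matches_brute_force(self, mean):
        dist = parametric_pmf("geometric", mean)
        q, total = 0.0, 0.0
        for _ in range(100_000):
            total += 1.0 - q
            q = pgf_eval(dist, q)
        assert mean_extinction_time(dist) == pytest.approx(total, abs=1e-6)

    def test_critical_and_degenerate_diverge(self, critical_geometric, unit_law):
        assert math.isinf(mean_extinction_time(critical_geometric))
        assert math.isinf(mean_extinction_time(unit_law))

    def test_supercritical_conditioned_on_extinction(self, binary_fission):
        # dual of binary fission swaps the weights: {0: 0.8, 2: 0.2}
        expected = mean_extinction_time(make_empirical_pmf([0, 2], [4, 1]))
        assert mean_extinction_time(binary_fission) == pytest.approx(
            expected, abs=1e-8
        )


class TestQuantiles:
    def test_critical_geometric_closed_form(self, critical_geometric):
        curve = extinction_cdf(critical_geometric, horizon=200)
        # q_n = n/(n+1) first reaches 0.8 at n = 4
        assert extinction_quantile(curve, 0.8) == 4
        assert extinction_quantile(curve, 0.5) == 1

    def test_zero_law(self, zero_law):
        curve = extinction_cdf(zero_law, horizon=3)
        assert extinction_quantile(curve, 0.5) == 1

    def test_unreachable_quantile_names_attained_maximum(self, binary_fission):
        curve = extinction_cdf(binary_fission, horizon=50)
        with pytest.raises(QuantileUnreachableError, match="0.25"):
            extinction_quantile(curve, 0.9)
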