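"""Closed-form translation of (d, ir, rr) into tables, phi and chi-squared."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epiphi import (
    ContingencyTable,
    Scenario,
    at_risk_incidence,
    chi2_from_measures,
    chi2_from_table,
    expected_table,
    overall_incidence,
    phi_from_measures,
    phi_from_table,
    rr_upper_limit,
    stratum,
)
from epiphi.measures import LESS_THAN_1, REACHING_1

# probabilities kept away from the degenerate edges so every margin is positive
probs = st.floats(0.01, 0.99)
ratios = st.floats(0.05, 30.0)


class TestAtRiskIncidence:
    @pytest.mark.parametrize(
        "ir, rr, expected",
        [(0.1, 2, 0.2), (0.8, 25, 1.0), (0.3, 1, 0.3), (0.05, 10, 0.5)],
    )
    def test_product_capped_at_one(self, ir, rr, expected):
        assert at_risk_incidence(ir, rr) == pytest.approx(expected)

    @pytest.mark.parametrize("ir, rr", [(0.0, 2), (-0.1, 2), (0.1, 0), (0.1, -1), (1.5, 1)])
    def test_domain_errors(self, ir, rr):
        with pytest.raises(ValueError):
            at_risk_incidence(ir, rr)


class TestStratum:
    @pytest.mark.parametrize(
        "ir, rr, expected",
        [
            (0.1, 10, REACHING_1),  # product exactly 1 counts as reaching
            (0.2, 5, REACHING_1),
            (0.05, 10, LESS_THAN_1),
            (0.8, 2, REACHING_1),
            (0.4, 2, LESS_THAN_1),
        ],
    )
    def test_boundary_classification(self, ir, rr, expected):
        assert stratum(ir, rr) == expected

    def test_grid_has_13_of_30_reaching_cells(self):
        cells = [(ir, rr) for ir in (0.05, 0.1, 0.2, 0.4, 0.8)
                 for rr in (0.5, 1, 2, 5, 10, 25)]
        reaching = [c for c in cells if stratum(*c) == REACHING_1]
        assert len(reaching) == 13


class TestRRUpperLimit:
    @pytest.mark.parametrize(
        "ir, limit", [(0.05, 20), (0.1, 10), (0.2, 5), (0.4, 2.5), (0.8, 1.25), (1.0, 1.0)]
    )
    def test_inverse_of_baseline_incidence(self, ir, limit):
        assert rr_upper_limit(ir) == pytest.approx(limit)

    def test_rejects_zero_incidence(self):
        with pytest.raises(ValueError):
            rr_upper_limit(0.0)


class TestOverallIncidence:
    def test_prevalence_weighted_mixture(self):
        assert overall_incidence(0.2, 0.1, 2) == pytest.approx(0.12)
        assert overall_incidence(0.8, 0.8, 25) == pytest.approx(0.96)  # capped q = 1

    @given(d=probs, ir=probs)
    def test_null_risk_ratio_leaves_incidence_unchanged(self, d, ir):
        assert overall_incidence(d, ir, 1.0) == pytest.approx(ir)

    @given(d=probs, ir=probs, rr=ratios)
    def test_bounded_by_baseline_and_at_risk_incidence(self, d, ir, rr):
        p = overall_incidence(d, ir, rr)
        q = at_risk_incidence(ir, rr)
        assert min(ir, q) - 1e-12 <= p <= max(ir, q) + 1e-12


class TestExpectedTable:
    def test_cell_products(self):
        t = expected_table(Scenario(rho=0, d=0.2, ir=0.1, rr=2, n=10_000))
        assert (t.a, t.b, t.c, t.dd) == (400, 800, 1600, 7200)

    def test_capped_scenario_has_no_asymptomatic_diseased(self):
        t = expected_table(Scenario(rho=0, d=0.1, ir=0.1, rr=10, n=1_000))
        assert t.c == pytest.approx(0.0)

    @given(d=probs, ir=probs, rr=ratios)
    @settings(max_examples=200)
    def test_cells_sum_to_n_and_independence_at_rr_1(self, d, ir, rr):
        t = expected_table(Scenario(rho=0, d=d, ir=ir, rr=rr, n=10_000))
        assert t.n == pytest.approx(10_000)
        t1 = expected_table(Scenario(rho=0, d=d, ir=ir, rr=1.0, n=10_000))
        assert t1.a / (t1.a + t1.c) == pytest.approx(t1.b / (t1.b + t1.dd))


class TestPhi:
    def test_perfect_association_and_independence(self):
        assert phi_from_table(ContingencyTable(50, 0, 0, 50)) == pytest.approx(1.0)
        assert phi_from_table(ContingencyTable(25, 25, 25, 25)) == pytest.approx(0.0)

    def test_zero_margin_flagged_nan(self):
        assert math.isnan(phi_from_table(ContingencyTable(0, 0, 10, 90)))

    def test_matches_pearson_correlation_of_expanded_indicators(self):
        # brute-force oracle: expand the table into 0/1 vectors and correlate
        t = expected_table(Scenario(rho=0, d=0.2, ir=0.1, rr=2, n=10_000))
        a, b, c, dd = (int(x) for x in (t.a, t.b, t.c, t.dd))
        disease = np.repeat([1, 0, 1, 0], [a, b, c, dd])
        symptom = np.repeat([1, 1, 0, 0], [a, b, c, dd])
        r = np.corrcoef(disease, symptom)[0, 1]
        assert phi_from_table(t) == pytest.approx(r, abs=1e-12)
        assert phi_from_table(t) == pytest.approx(0.1231, abs=5e-5)

    @pytest.mark.parametrize(
        "d, ir, rr, expected",
        [(0.2, 0.1, 2, 0.12309149097933274), (0.4, 0.2, 0.5, -0.1336306209562122)],
    )
    def test_closed_form_equals_expected_table_phi(self, d, ir, rr, expected):
        # frozen values come from phi_from_table on the expected table
        assert phi_from_measures(d, ir, rr) == pytest.approx(expected, rel=1e-9)

    @given(d=probs, ir=probs, rr=ratios)
    @settings(max_examples=300)
    def test_oracle_equivalence_on_random_measures(self, d, ir, rr):
        t = expected_table(Scenario(rho=0, d=d, ir=ir, rr=rr, n=10_000))
        assert phi_from_measures(d, ir, rr) == pytest.approx(
            phi_from_table(t), abs=1e-12
        )

    @given(d=probs, ir=probs)
    def test_zero_iff_null_risk_ratio(self, d, ir):
        assert phi_from_measures(d, ir, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_sign_follows_risk_ratio_direction(self):
        assert phi_from_measures(0.2, 0.1, 2) > 0
        assert phi_from_measures(0.2, 0.1, 0.5) < 0

    @given(d=probs, ir=st.floats(0.01, 0.5))
    @settings(max_examples=200)
    def test_strictly_increasing_in_rr_below_cap(self, d, ir):
        rrs = np.linspace(0.2, 1.0 / ir, 8)
        phis = [phi_from_measures(d, ir, rr) for rr in rrs]
        assert all(p1 < p2 for p1, p2 in zip(phis, phis[1:]))

    @given(d=probs, ir=probs, rr=ratios)
    @settings(max_examples=300)
    def test_bounded_in_unit_interval(self, d, ir, rr):
        assert -1.0 <= phi_from_measures(d, ir, rr) <= 1.0


class TestChi2:
    def test_independence_gives_zero(self):
        assert chi2_from_table(ContingencyTable(25, 25, 25, 25)) == pytest.approx(0.0)
        assert chi2_from_measures(0.3, 0.2, 1, 5_000) == pytest.approx(0.0, abs=1e-20)

    def test_closed_form_value_and_linearity_in_n(self):
        assert chi2_from_measures(0.2, 0.1, 2, 10_000) == pytest.approx(151.5, abs=0.05)
        assert chi2_from_measures(0.2, 0.1, 2, 20_000) == pytest.approx(
            2 * chi2_from_measures(0.2, 0.1, 2, 10_000)
        )

    def test_table_statistic_matches_closed_form(self):
        t = ContingencyTable(400, 800, 1600, 7200)
        assert chi2_from_table(t) == pytest.approx(151.5, abs=0.05)

    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), dd=st.integers(1, 500),
    )
    @settings(max_examples=300)
    def test_identity_with_n_phi_squared(self, a, b, c, dd):
        t = ContingencyTable(a, b, c, dd)
        phi = phi_from_table(t)
        assert chi2_from_table(t) == pytest.approx(t.n * phi * phi, rel=1e-10)

    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), dd=st.integers(1, 500),
    )
    @settings(max_examples=200)
    def test_yates_correction_never_increases_statistic(self, a, b, c, dd):
        t = ContingencyTable(a, b, c, dd)
        assert chi2_from_table(t, corrected=True) <= chi2_from_table(t) + 1e-12

    def test_degenerate_table_flagged_nan(self):
        assert math.isnan(chi2_from_table(ContingencyTable(0, 0, 10, 90)))


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rho=0, d=0.0, ir=0.1, rr=1),
            dict(rho=0, d=1.0, ir=0.1, rr=1),
            dict(rho=0, d=0.2, ir=0.0, rr=1),
            dict(rho=0, d=0.2, ir=0.1, rr=0),
            dict(rho=0, d=0.2, ir=0.1, rr=1, n=1),
            dict(rho=-0.9, d=0.05, ir=0.1, rr=1),  # below feasibility floor
            dict(rho=1.2, d=0.2, ir=0.1, rr=1),
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Scenario(**{"n": 100, **kwargs})

    def test_feasible_negative_rho_accepted(self):
        Scenario(rho=-0.25, d=0.8, ir=0.1, rr=1, n=100)  # floor is -(1-d)/d = -0.25
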