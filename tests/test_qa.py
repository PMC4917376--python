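"""QA statistics: δ and its mm conversion, measured limits, fits, error
budget, series summaries and session evaluation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import irisqa as q
from irisqa.errors import DomainError, ValidationError


class TestDelta:
    def test_identity(self):
        assert q.delta(0.25, 0.25) == 0.0

    def test_published_worst_case(self):
        """The worst long-term deviation at 5 mm: a quotient 3.63% above
        baseline reads as δ = 3.63%."""
        assert q.delta(1.0363 * 0.017, 0.017) == pytest.approx(3.63, abs=1e-9)

    def test_halving(self):
        assert q.delta(0.5 * 0.25, 0.25) == pytest.approx(-50.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DomainError):
            q.delta(1.0, 0.0)

    @pytest.mark.parametrize("fn", [q.misalign_error, q.beamchange_error])
    def test_error_quotients_share_contract(self, fn):
        assert fn(0.25, 0.25) == 0.0
        assert fn(1.0126 * 0.9, 0.9) == pytest.approx(1.26, abs=1e-9)
        assert fn(1.0010 * 0.9, 0.9) == pytest.approx(0.10, abs=1e-9)


class TestMmConversion:
    @pytest.mark.parametrize("delta_pct, d, expected_mm", [
        (3.63, 5.0, 0.090),    # worst-case series at 5 mm
        (-0.82, 20.0, -0.082),
        (0.63, 60.0, 0.189),
        (0.2, 5.0, 0.005),     # resolution of the combined 0.2% error
        (0.0, 30.0, 0.0),
    ])
    def test_delta_to_mm_published_values(self, delta_pct, d, expected_mm):
        assert round(q.delta_to_mm(delta_pct, d), 3) == expected_mm

    @pytest.mark.parametrize("dd, d, expected_pct", [
        (0.1, 60.0, 0.33),   # 0.1 mm on a 60 mm field
        (0.1, 7.5, 2.68),    # same 0.1 mm on a 7.5 mm field
        (-0.082, 20.0, -0.82),
    ])
    def test_mm_to_delta_published_values(self, dd, d, expected_pct):
        assert round(q.mm_to_delta(dd, d), 2) == expected_pct

    @given(delta_pct=st.floats(-50.0, 100.0), d=st.floats(5.0, 60.0))
    @settings(derandomize=True, max_examples=200)
    def test_round_trip_identity(self, delta_pct, d):
        dd = q.delta_to_mm(delta_pct, d)
        back = q.mm_to_delta(dd, d)
        assert back == pytest.approx(delta_pct, rel=1e-12, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            q.delta_to_mm(-100.0, 30.0)
        with pytest.raises(DomainError):
            q.mm_to_delta(-30.0, 30.0)


class TestMeasuredLimits:
    def _baseline(self):
        return q.BaselineRecord(thetas={5.0: 0.01, 30.0: 0.25, 60.0: 0.95})

    def test_unperturbed_input_gives_zero_margin(self):
        base = self._baseline()
        # perturbed means equal to baseline would give 0 limits, which the
        # ToleranceLimits invariant (plus > 0 > minus) rightly rejects
        with pytest.raises(DomainError):
            q.measured_limits(dict(base.thetas), dict(base.thetas), base)

    def test_ideal_perturbation_recovers_closed_form(self):
        """θ means from apertures at exactly d ± 0.2 under pure area
        scaling give limits equal to mm_to_delta(±0.2, d)."""
        base = self._baseline()
        plus = {d: t * (1 + q.mm_to_delta(0.2, d) / 100) for d, t in base.thetas.items()}
        minus = {d: t * (1 + q.mm_to_delta(-0.2, d) / 100) for d, t in base.thetas.items()}
        lims = q.measured_limits(plus, minus, base)
        assert lims.source == "measured"
        assert lims.at(30.0)[0] == pytest.approx(q.mm_to_delta(0.2, 30.0), rel=1e-9)
        assert lims.at(30.0)[0] == pytest.approx(1.3378, abs=5e-4)
        assert lims.at(5.0)[1] == pytest.approx(q.mm_to_delta(-0.2, 5.0), rel=1e-9)

    def test_missing_aperture_rejected(self):
        base = self._baseline()
        plus = {d: t * 1.05 for d, t in base.thetas.items()}
        minus = {d: t * 0.95 for d, t in base.thetas.items()}
        del plus[30.0]
        with pytest.raises(ValidationError):
            q.measured_limits(plus, minus, base)


class TestCharacterizationFits:
    def test_exact_quadratic(self):
        pts = [(d, d ** 2) for d in (5.0, 10.0, 20.0, 40.0)]
        fit = q.fit_dap_power_law(pts)
        assert fit.c == pytest.approx(2.0, abs=1e-9)
        assert fit.b == pytest.approx(1.0, rel=1e-9)

    def test_published_dap_means(self):
        """Log-log fit to the three printed DAP means lands near the
        published 12-point exponent 1.935."""
        fit = q.fit_dap_power_law([(7.5, 2.41), (30.0, 35.88), (60.0, 136.33)])
        assert fit.c == pytest.approx(1.9417, abs=1e-4)

    def test_scale_equivariance(self):
        pts = [(7.5, 2.41), (30.0, 35.88), (60.0, 136.33)]
        f1 = q.fit_dap_power_law(pts)
        f2 = q.fit_dap_power_law([(d, 3.7 * v) for d, v in pts])
        assert f2.c == pytest.approx(f1.c, rel=1e-12)
        assert f2.b == pytest.approx(3.7 * f1.b, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            q.fit_dap_power_law([(5.0, 25.0), (10.0, 100.0)])

    def test_theta_linear_published_triple(self):
        b = q.fit_theta_linear([(1.77, 0.0168), (28.27, 0.2503), (113.1, 0.9509)])
        assert b == pytest.approx(0.00843, abs=5e-5)

    def test_theta_linear_single_point(self):
        assert q.fit_theta_linear([(4.0, 2.0)]) == pytest.approx(0.5)

    def test_theta_linear_ideal_model(self):
        """Ideal area scaling: θ = (d/60)², area = π(d/2)²/100 cm², so the
        through-origin slope is 1/(π·30²/100) per cm²."""
        pts = []
        for d in q.CLINICAL_IRIS_DIAMETERS_MM:
            area_cm2 = np.pi * (d / 2.0) ** 2 / 100.0
            pts.append((area_cm2, (d / 60.0) ** 2))
        b = q.fit_theta_linear(pts)
        assert b == pytest.approx(1.0 / (np.pi * 30.0 ** 2 / 100.0), rel=1e-12)

    def test_all_zero_areas_rejected(self):
        with pytest.raises(ValidationError):
            q.fit_theta_linear([(0.0, 1.0), (0.0, 2.0)])


class TestErrorBudget:
    def test_two_components(self):
        b = q.error_budget(0.04, 0.04, 0.0, 0.0)
        assert b.combined_pct == pytest.approx(np.sqrt(2) * 0.04, rel=1e-12)

    def test_three_components_published_working_point(self):
        b = q.error_budget(0.04, 0.04, 0.10, 0.0)
        assert b.combined_pct == pytest.approx(0.11489, abs=1e-5)
        assert b.envelope_pct == 0.2

    def test_single_component_passthrough(self):
        assert q.error_budget(0.0, 0.0, 0.07, 0.0).combined_pct == pytest.approx(0.07)

    @given(st.lists(st.floats(0.0, 5.0), min_size=4, max_size=4),
           st.permutations([0, 1, 2, 3]))
    @settings(derandomize=True, max_examples=100)
    def test_permutation_invariant_and_triangle(self, comps, perm):
        a = q.error_budget(*comps).combined_pct
        b = q.error_budget(*[comps[i] for i in perm]).combined_pct
        assert b == pytest.approx(a, rel=1e-12, abs=1e-12)
        assert a <= sum(comps) + 1e-12
        assert a >= max(comps) - 1e-12

    def test_negative_component_rejected(self):
        with pytest.raises(DomainError):
            q.error_budget(-0.1, 0.0, 0.0, 0.0)


def _session_from_readings(readings: dict, session_id="T01"):
    """Build a session from {(collimator, aperture): [readings]}."""
    import datetime
    rows = []
    for (col, d), vals in readings.items():
        for k, v in enumerate(vals):
            rows.append({"collimator": col, "aperture_mm": d, "mu": 100.0,
                         "repeat_index": k, "reading_nC": v})
    return q.MeasurementSession(session_id=session_id,
                                date=datetime.date(2014, 1, 15),
                                records=pd.DataFrame(rows))


class TestSeriesSummaries:
    def test_identical_readings_zero_spread(self):
        s = _session_from_readings({("iris", 30.0): [5.0, 5.0, 5.0],
                                    ("fixed", 60.0): [20.0, 20.0, 20.0]})
        t = _session_from_readings({("iris", 30.0): [5.0, 5.0, 5.0],
                                    ("fixed", 60.0): [20.0, 20.0, 20.0]}, "T02")
        summ = q.reproducibility_summary([s, t])
        assert (summ.per_aperture["sd_median_pct"] == 0).all()
        assert (summ.per_aperture["sd_median_mm"] == 0).all()

    def test_two_session_median_and_quartiles(self):
        """With exactly two per-session SDs a < b, the median is their mean
        and the quartiles bracket it."""
        s = _session_from_readings({("iris", 30.0): [10.0, 10.2],
                                    ("fixed", 60.0): [20.0, 20.0]})
        t = _session_from_readings({("iris", 30.0): [10.0, 10.6],
                                    ("fixed", 60.0): [20.0, 20.0]}, "T02")
        summ = q.reproducibility_summary([s, t])
        row = summ.per_aperture[summ.per_aperture["collimator"] == "iris"].iloc[0]
        a = np.std([10.0, 10.2], ddof=1) / np.mean([10.0, 10.2]) * 100
        b = np.std([10.0, 10.6], ddof=1) / np.mean([10.0, 10.6]) * 100
        assert row["sd_median_pct"] == pytest.approx((a + b) / 2)
        assert row["sd_q1_pct"] <= row["sd_median_pct"] <= row["sd_q3_pct"]

    def test_stability_constant_series(self):
        summ = q.stability_summary({30.0: np.full(10, 0.25)})
        row = summ.per_aperture.iloc[0]
        assert row["sd_pct"] == 0.0
        assert row["trend_slope_per_session"] == 0.0

    def test_stability_alternating_series(self):
        """±1% alternation around the mean has SD ≈ 1%."""
        theta = 0.25 * (1 + 0.01 * np.array([1, -1] * 16))
        summ = q.stability_summary({30.0: theta})
        assert summ.per_aperture.iloc[0]["sd_pct"] == pytest.approx(1.0, rel=0.02)

    def test_stability_detects_injected_trend(self):
        rng = np.random.default_rng(7)
        theta = 0.25 * (1 + 0.002 * np.arange(31)) + rng.normal(0, 1e-5, 31)
        summ = q.stability_summary({30.0: theta})
        row = summ.per_aperture.iloc[0]
        assert row["trend_slope_per_session"] == pytest.approx(0.0005, rel=0.05)
        assert row["trend_slope_per_session"] > 3 * row["trend_slope_stderr"]

    def test_insufficient_sessions_rejected(self):
        with pytest.raises(ValidationError):
            q.stability_summary({30.0: np.array([0.25])})


class TestEvaluateQa:
    def _fixture(self):
        base = q.BaselineRecord(thetas={5.0: 0.01, 30.0: 0.25, 60.0: 0.95})
        limits = q.ToleranceLimits(
            limits={5.0: (10.0, -9.5), 30.0: (1.34, -1.33), 60.0: (0.67, -0.67)},
            source="measured")
        return base, limits

    def _session(self, thetas, ref=100.0):
        readings = {("fixed", 60.0): [ref] * 3}
        for d, t in thetas.items():
            readings[("iris", d)] = [t * ref] * 3
        return _session_from_readings(readings)

    def test_self_consistent_session_passes_with_zero_delta(self):
        base, limits = self._fixture()
        res = q.evaluate_qa(self._session(dict(base.thetas)), base, limits)
        assert res.overall_pass
        assert res.table["delta_pct"].abs().max() == 0.0
        assert res.table["delta_mm"].abs().max() == 0.0

    def test_published_worst_case_within_limits(self):
        """δ(5 mm) = +3.63% is well inside the ≈ +10% measured limit."""
        base, limits = self._fixture()
        thetas = dict(base.thetas)
        thetas[5.0] *= 1.0363
        res = q.evaluate_qa(self._session(thetas), base, limits)
        row = res.table[res.table["aperture_mm"] == 5.0].iloc[0]
        assert row["delta_pct"] == pytest.approx(3.63, abs=1e-9)
        assert row["passed"]
        assert res.overall_pass

    def test_delta_on_limit_counts_as_pass(self):
        base, limits = self._fixture()
        thetas = dict(base.thetas)
        thetas[30.0] *= 1.0134  # exactly on the +1.34 limit
        res = q.evaluate_qa(self._session(thetas), base, limits)
        row = res.table[res.table["aperture_mm"] == 30.0].iloc[0]
        assert row["delta_pct"] == pytest.approx(1.34, abs=1e-12)
        assert row["passed"]

    def test_violation_fails_that_aperture(self):
        base, limits = self._fixture()
        thetas = dict(base.thetas)
        thetas[60.0] *= 1.02  # +2% >> +0.67 limit
        res = q.evaluate_qa(self._session(thetas), base, limits)
        row = res.table[res.table["aperture_mm"] == 60.0].iloc[0]
        assert not row["passed"]
        assert not res.overall_pass

    def test_missing_aperture_reported_not_skipped(self):
        base, limits = self._fixture()
        thetas = {d: t for d, t in base.thetas.items() if d != 30.0}
        res = q.evaluate_qa(self._session(thetas), base, limits)
        row = res.table[res.table["aperture_mm"] == 30.0].iloc[0]
        assert not row["passed"]
        assert "missing" in row["reason"]
        assert not res.overall_pass

    def test_missing_reference_rejected(self):
        base, limits = self._fixture()
        s = _session_from_readings({("iris", 5.0): [1.0, 1.0]})
        with pytest.raises(ValidationError):
            q.evaluate_qa(s, base, limits)

    def test_delta_equals_direct_computation(self):
        """evaluate_qa must agree exactly with delta(theta(means), baseline)
        — no hidden recomputation path."""
        base, limits = self._fixture()
        rng = np.random.default_rng(3)
        readings = {("fixed", 60.0): list(100 + rng.normal(0, 0.1, 4))}
        for d, t in base.thetas.items():
            readings[("iris", d)] = list(t * 100 + rng.normal(0, 0.05, 4))
        s = _session_from_readings(readings)
        res = q.evaluate_qa(s, base, limits)
        ref_mean = np.mean(readings[("fixed", 60.0)])
        for d in base.thetas:
            expected = q.delta(np.mean(readings[("iris", d)]) / ref_mean, base.at(d))
            row = res.table[res.table["aperture_mm"] == d].iloc[0]
            assert row["delta_pct"] == expected


class TestBaselineRecord:
    def test_rejects_nonincreasing_theta(self):
        with pytest.raises(ValidationError):
            q.BaselineRecord(thetas={5.0: 0.2, 30.0: 0.1, 60.0: 0.95})

    def test_rejects_nonpositive_theta(self):
        with pytest.raises(ValidationError):
            q.BaselineRecord(thetas={5.0: -0.1, 30.0: 0.1})
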