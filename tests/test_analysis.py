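"""Rate-constant analysis: series fits, two-step eigenvalues, table assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stopflow import (
    NoiseSpec,
    TimebaseSpec,
    TwoStepParams,
    estimate_kspont,
    fit_kobs_linear,
    fit_michaelis_menten,
    fit_one_step_binding,
    fit_substrate_inhibition,
    fit_two_step_binding,
    generate_transient,
    subtract_background,
    two_step_eigenvalues,
    two_step_kobs,
)
from stopflow.analysis import (
    ConstantsTable,
    KspontEstimate,
    MichaelisMentenFit,
    OneStepFit,
    RateSeries,
    SubstrateInhibitionFit,
    TwoStepFit,
    assemble_constants,
)

rate = st.floats(0.0, 100.0)
conc_s = st.floats(0.0, 1000.0)


class TestLinearSeries:
    def test_exact_line_recovered(self):
        S = np.array([5.0, 10.0, 25.0, 50.0, 100.0])
        fit = fit_kobs_linear(RateSeries(S, 0.88 * S + 3.41))
        assert fit.slope == pytest.approx(0.88, rel=1e-9)
        assert fit.intercept == pytest.approx(3.41, rel=1e-9)

    def test_constant_series_has_zero_slope(self):
        S = np.array([5.0, 10.0, 25.0])
        fit = fit_kobs_linear(RateSeries(S, np.full(3, 2.5)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_decreasing_series_gives_negative_slope(self):
        S = np.array([5.0, 10.0, 25.0, 50.0])
        fit = fit_kobs_linear(RateSeries(S, 10.0 - 0.05 * S))
        assert fit.slope == pytest.approx(-0.05, rel=1e-9)

    def test_weighted_fit_uses_replicate_stds(self):
        S = np.array([5.0, 10.0, 25.0, 50.0])
        y = 0.5 * S + 1.0
        y_out = y.copy()
        y_out[-1] += 5.0  # outlier that the weights should suppress
        std = np.array([0.1, 0.1, 0.1, 10.0])
        fit = fit_kobs_linear(RateSeries(S, y_out, std))
        assert fit.slope == pytest.approx(0.5, rel=0.02)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_kobs_linear(RateSeries(np.array([5.0, 5.0, 5.0]), np.ones(3)))


class TestOneStepBinding:
    def test_published_line(self):
        S = np.array([5.0, 18.0, 36.0, 54.0])
        fit = fit_one_step_binding(RateSeries(S, 0.88 * S + 3.4))
        assert fit.kon == pytest.approx(0.88, rel=1e-9)
        assert fit.koff == pytest.approx(3.4, rel=1e-9)
        assert not fit.negative_intercept

    def test_zero_slope_series(self):
        S = np.array([5.0, 18.0, 36.0])
        fit = fit_one_step_binding(RateSeries(S, np.full(3, 3.4)))
        assert fit.kon == pytest.approx(0.0, abs=1e-12)

    def test_concentration_rescaling_consistency(self):
        S = np.array([5.0, 18.0, 36.0, 54.0])
        fit1 = fit_one_step_binding(RateSeries(S, 0.88 * S + 3.4))
        fit2 = fit_one_step_binding(RateSeries(2 * S, 0.88 * (2 * S) + 3.4))
        assert fit2.kon == pytest.approx(fit1.kon, rel=1e-9)
        assert fit2.koff == pytest.approx(fit1.koff, rel=1e-9)

    def test_negative_intercept_flagged(self):
        S = np.array([5.0, 18.0, 36.0])
        with pytest.warns(UserWarning, match="negative intercept"):
            fit = fit_one_step_binding(RateSeries(S, 0.5 * S - 1.0))
        assert fit.negative_intercept


class TestSubstrateInhibition:
    S = np.array([2.0, 5.0, 10.0, 15.0, 20.0, 27.0, 35.0, 45.0, 60.0, 80.0, 100.0])

    def test_noiseless_recovery_of_published_values(self):
        truth = SubstrateInhibitionFit(1.0, 13.2, 54.9, 0, 0, 0)
        fit = fit_substrate_inhibition(RateSeries(self.S, truth.predict(self.S)))
        assert fit.kmax == pytest.approx(1.0, rel=1e-3)
        assert fit.km == pytest.approx(13.2, rel=1e-3)
        assert fit.ki == pytest.approx(54.9, rel=1e-3)

    def test_curve_maximum_at_sqrt_km_ki(self):
        truth = SubstrateInhibitionFit(1.0, 13.2, 54.9, 0, 0, 0)
        fit = fit_substrate_inhibition(RateSeries(self.S, truth.predict(self.S)))
        assert fit.s_optimum == pytest.approx(26.9, abs=0.1)
        # the analytic optimum really is the argmax of the fitted curve
        s_dense = np.linspace(1.0, 100.0, 20000)
        s_hat = s_dense[np.argmax(fit.predict(s_dense))]
        assert s_hat == pytest.approx(fit.s_optimum, abs=0.02)

    def test_large_ki_limit_is_michaelis_menten(self):
        y = 1.0 * self.S / (13.2 + self.S)
        fit = fit_substrate_inhibition(RateSeries(self.S, y))
        assert fit.km == pytest.approx(13.2, rel=0.01)
        assert np.max(np.abs(fit.predict(self.S) - y)) < 1e-8


class TestTwoStepKobs:
    paper = TwoStepParams(0.36, 0.71, 1.37, 0.90)

    def test_hand_evaluated_value_at_zero_substrate(self):
        # p = 0.71 + 1.37 + 0.90 = 2.98; r = 0.71 * 0.90 = 0.639
        # kobs = (2.98 - sqrt(2.98^2 - 4 * 0.639)) / 2 = 0.2326
        assert two_step_kobs(self.paper, 0.0) == pytest.approx(0.2326, abs=1e-4)

    def test_large_substrate_limit(self):
        # the slow eigenvalue saturates at kon2 + koff2
        assert two_step_kobs(self.paper, 1e9) == pytest.approx(2.27, rel=1e-6)

    @settings(max_examples=100, deadline=None)
    @given(kon1=rate, koff1=rate, kon2=rate, koff2=rate, S=conc_s)
    def test_closed_form_matches_eigenvalue_oracle(self, kon1, koff1, kon2, koff2, S):
        """(p -+ q)/2 are the eigenvalue magnitudes of the 2x2 kinetic matrix."""
        params = TwoStepParams(kon1, koff1, kon2, koff2)
        a = kon1 * S
        A = np.array(
            [[-(a + koff1 + kon2), -a + koff2], [kon2, -koff2]]
        )
        ev = np.sort(np.abs(np.linalg.eigvals(A)))
        slow, fast = two_step_eigenvalues(params, S)
        scale = max(fast, 1.0)
        assert abs(slow - ev[0]) <= 1e-9 * scale
        assert abs(fast - ev[1]) <= 1e-9 * scale

    @settings(max_examples=100, deadline=None)
    @given(kon1=rate, koff1=rate, kon2=rate, koff2=rate, S=conc_s)
    def test_vieta_identities(self, kon1, koff1, kon2, koff2, S):
        params = TwoStepParams(kon1, koff1, kon2, koff2)
        p = kon1 * S + koff1 + kon2 + koff2
        r = kon1 * S * kon2 + koff1 * koff2 + kon1 * S * koff2
        slow, fast = two_step_eigenvalues(params, S)
        # q is computed from p^2, so float noise scales with p^2
        assert abs((slow + fast) - p) <= 1e-9 * max(p, 1.0)
        assert abs(slow * fast - r) <= 1e-9 * max(p * p, 1.0)

    @settings(max_examples=100, deadline=None)
    @given(kon1=rate, koff1=rate, kon2=rate, koff2=rate,
           S1=conc_s, S2=conc_s)
    def test_monotone_non_decreasing_in_substrate(self, kon1, koff1, kon2, koff2, S1, S2):
        params = TwoStepParams(kon1, koff1, kon2, koff2)
        lo, hi = sorted((S1, S2))
        assert two_step_kobs(params, lo) <= two_step_kobs(params, hi) + 1e-9


class TestTwoStepFit:
    def test_noiseless_recovery_of_published_parameters(self):
        truth = TwoStepParams(0.36, 0.71, 1.37, 0.90)
        S = np.linspace(1.0, 100.0, 25)
        fit = fit_two_step_binding(RateSeries(S, two_step_kobs(truth, S)))
        assert fit.params.kon1 == pytest.approx(0.36, rel=1e-2)
        assert fit.params.koff1 == pytest.approx(0.71, rel=1e-2)
        assert fit.params.kon2 == pytest.approx(1.37, rel=1e-2)
        assert fit.params.koff2 == pytest.approx(0.90, rel=1e-2)
        assert not fit.at_boundary

    def test_degenerate_limit_flagged_not_silently_returned(self):
        truth = TwoStepParams(0.36, 0.71, 0.0, 0.0)
        S = np.linspace(1.0, 100.0, 25)
        fit = fit_two_step_binding(RateSeries(S, two_step_kobs(truth, S)))
        assert fit.at_boundary

    def test_permutation_invariance(self):
        truth = TwoStepParams(0.36, 0.71, 1.37, 0.90)
        S = np.linspace(1.0, 100.0, 15)
        y = two_step_kobs(truth, S)
        rng = np.random.default_rng(0)
        perm = rng.permutation(S.size)
        fit_a = fit_two_step_binding(RateSeries(S, y))
        fit_b = fit_two_step_binding(RateSeries(S[perm], y[perm]))
        assert fit_b.params.kon1 == pytest.approx(fit_a.params.kon1, rel=1e-6)
        assert fit_b.params.kon2 == pytest.approx(fit_a.params.kon2, rel=1e-6)


class TestMichaelisMenten:
    def test_noiseless_recovery(self):
        kcat, km = 6.94 / 60.0, 9.9
        S = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 54.0])
        fit = fit_michaelis_menten(RateSeries(S, kcat * S / (km + S)), E0=1.0)
        assert fit.kcat == pytest.approx(kcat, rel=1e-3)
        assert fit.km == pytest.approx(km, rel=1e-3)
        assert fit.kcat_per_min == pytest.approx(6.94, rel=1e-3)

    def test_saturation_limit(self):
        kcat, km = 0.1157, 9.9
        S = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 54.0])
        fit = fit_michaelis_menten(RateSeries(S, kcat * S / (km + S)), E0=1.0)
        assert fit.predict(500.0) == pytest.approx(kcat, rel=0.02)


class TestKspont:
    tb = TimebaseSpec("linear", 10.0, total_points=500)

    def test_noiseless_estimate_within_linearisation_bias(self, rc, om):
        tr = generate_transient(rc, om, 0.0, 50.0, self.tb, NoiseSpec(0.0, 0))
        est = estimate_kspont([tr], om)
        assert est.value == pytest.approx(1.25e-3, rel=0.02)

    def test_zero_kspont_gives_zero(self, rc, om):
        tr = generate_transient(rc.replace(kspont=0.0), om, 0.0, 50.0, self.tb, NoiseSpec(0.0, 0))
        est = estimate_kspont([tr], om)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_first_order_estimate_independent_of_concentration(self, rc, om):
        values = []
        for s0 in (10.0, 50.0, 100.0):
            tr = generate_transient(rc, om, 0.0, s0, self.tb, NoiseSpec(0.0, 0))
            values.append(estimate_kspont([tr], om).value)
        assert max(values) / min(values) - 1 < 0.05

    def test_rising_absorbance_rejected(self, rc, om):
        t = np.linspace(0.002, 10.0, 100)
        from stopflow import Transient

        with pytest.raises(ValueError, match="rising"):
            estimate_kspont([Transient(t, 0.1 + 0.01 * t)], om)


class TestBackgroundSubtraction:
    def test_plain_difference(self):
        assert subtract_background(0.5, 0.1) == pytest.approx(0.4)

    def test_equal_rates_give_zero(self):
        assert subtract_background(0.3, 0.3) == 0.0

    def test_floor_with_warning(self):
        with pytest.warns(UserWarning, match="floor"):
            assert subtract_background(0.1, 0.2) == 0.0


class TestAssembleConstants:
    def published_fits(self):
        one = OneStepFit(kon=0.88, koff=3.41, kon_err=0.03, koff_err=0.71)
        two = TwoStepFit(
            params=TwoStepParams(0.36, 0.71, 1.37, 0.90),
            errs={"kon1": 0.46, "koff1": 0.62, "kon2": 2.38, "koff2": 2.29},
            boundary_flags={k: False for k in ("kon1", "koff1", "kon2", "koff2")},
            ssr=0.0,
        )
        mm = MichaelisMentenFit(kcat=6.94 / 60.0, km=9.9, kcat_err=0.3 / 60.0, km_err=1.5)
        ksp = KspontEstimate(value=1.25e-3, std=1.7e-5)
        return one, two, mm, ksp

    def test_table_round_trip_reproduces_published_equilibria(self):
        table = assemble_constants(*self.published_fits())
        assert abs(table.value("K1") - 3.86) < 0.02
        assert table.value("K2") == pytest.approx(1.97, abs=0.01)
        assert abs(table.value("Kapp") - 1.3) < 0.01
        assert table.value("k6") == pytest.approx(0.1157, abs=1e-4)

    def test_kapp_recomputed_exactly(self):
        table = assemble_constants(*self.published_fits())
        assert table.value("Kapp") == table.value("K2") * table.value("K4")

    def test_provenance_of_k6_names_michaelis_menten(self):
        table = assemble_constants(*self.published_fits())
        assert "Michaelis-Menten" in table["k6"].provenance

    def test_missing_component_error_names_it(self):
        one, two, mm, ksp = self.published_fits()
        with pytest.raises(ValueError, match="Michaelis-Menten"):
            assemble_constants(one, two, None, ksp)

    def test_csv_and_json_export(self, tmp_path):
        table = assemble_constants(*self.published_fits())
        table.to_csv(tmp_path / "t.csv")
        header = (tmp_path / "t.csv").read_text().splitlines()[0]
        assert header == "name,value,std,units,provenance"
        payload = table.to_json(tmp_path / "t.json")
        assert payload["k1"]["value"] == 0.88

    def test_comparison_report_against_reference(self):
        from stopflow import load_reference_table

        table = assemble_constants(*self.published_fits())
        report = table.compare(load_reference_table())
        k1_row = report[report.name == "k1"].iloc[0]
        assert abs(k1_row.relative_deviation) < 1e-9
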