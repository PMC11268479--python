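"""Transient fitting: dead time, multi-exponential deconvolution, bursts, tails."""

import numpy as np
import pytest

from stopflow import (
    NoiseSpec,
    TimebaseSpec,
    Transient,
    absorbance_to_concentration,
    estimate_initial_concentration,
    fit_burst,
    fit_multiexponential,
    generate_transient,
    select_n_phases,
    tail_linear_fit,
    truncate_dead_time,
)


def log_grid(duration=1000.0, n=3000, start=0.002):
    return np.geomspace(start, duration, n)


class TestTruncateDeadTime:
    def test_points_before_dead_time_discarded(self):
        t = np.geomspace(0.0005, 10.0, 500)
        tr = truncate_dead_time(Transient(t, np.ones_like(t)))
        assert tr.time[0] >= 0.002
        assert tr.time.size < t.size

    def test_idempotent_on_clean_grid(self):
        t = np.geomspace(0.002, 10.0, 100)
        tr = Transient(t, np.ones_like(t))
        assert truncate_dead_time(tr) is tr

    def test_zero_dead_time_is_identity(self):
        t = np.geomspace(0.0005, 10.0, 100)
        tr = Transient(t, np.ones_like(t))
        assert truncate_dead_time(tr, 0.0) is tr

    def test_error_when_nothing_survives(self):
        t = np.linspace(0.0001, 0.001, 10)
        with pytest.raises(ValueError, match="dead time"):
            truncate_dead_time(Transient(t, np.ones_like(t)))


class TestMultiExponential:
    def test_single_phase_noiseless_recovery(self):
        t = log_grid()
        tr = Transient(t, 0.1 * np.exp(-2 * t) + 0.05)
        fit = fit_multiexponential(tr, 1)
        assert fit.amplitudes[0] == pytest.approx(0.1, rel=1e-6)
        assert fit.rates[0] == pytest.approx(2.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.05, rel=1e-6)

    def test_three_phase_noiseless_recovery(self):
        t = log_grid()
        y = 0.05 * np.exp(-50 * t) + 0.1 * np.exp(-2 * t) + 0.02 * np.exp(-0.05 * t) + 0.3
        fit = fit_multiexponential(Transient(t, y), 3)
        assert fit.rates == pytest.approx([50.0, 2.0, 0.05], rel=1e-3)
        assert fit.amplitudes == pytest.approx([0.05, 0.1, 0.02], rel=1e-3)
        assert fit.offset == pytest.approx(0.3, rel=1e-3)
        assert fit.delta_a_total == pytest.approx(0.17, rel=1e-3)

    def test_rates_reported_strictly_descending(self):
        t = log_grid(10.0, 1500)
        rng = np.random.default_rng(3)
        y = 0.04 * np.exp(-30 * t) + 0.08 * np.exp(-1.2 * t) + 0.2
        tr = Transient(t, y + rng.normal(0, 0.001, t.size))
        for n in (2, 3):
            fit = fit_multiexponential(tr, n)
            assert np.all(np.diff(fit.rates) < 0)

    def test_fit_quality_improves_with_phase_count(self, rc, om):
        tr = generate_transient(
            rc, om, 400.0, 25.0, TimebaseSpec("logarithmic", 1000.0, 15, 200),
            NoiseSpec(0.002, 21),
        )
        tr = truncate_dead_time(tr)
        sel = select_n_phases(tr)
        ssrs = [sel.fits[n].ssr for n in (1, 2, 3)]
        assert ssrs[0] >= ssrs[1] - 1e-9
        assert ssrs[1] >= ssrs[2] - 1e-9


class TestPhaseSelection:
    def test_single_exponential_with_noise_selects_one(self):
        t = log_grid(100.0, 2000)
        rng = np.random.default_rng(17)
        y = 0.25 * np.exp(-0.8 * t) + 0.1 + rng.normal(0, 0.002, t.size)
        sel = select_n_phases(Transient(t, y))
        assert sel.n_selected == 1

    def test_noiseless_two_phase_selects_two(self):
        t = log_grid(1000.0, 2000)
        y = 0.1 * np.exp(-10.0 * t) + 0.05 * np.exp(-0.1 * t) + 0.2
        sel = select_n_phases(Transient(t, y))
        assert sel.n_selected == 2

    def test_diagnostics_reported_for_every_candidate(self):
        t = log_grid(100.0, 800)
        y = 0.2 * np.exp(-1.0 * t) + 0.1
        sel = select_n_phases(Transient(t, y))
        assert [row["n_phases"] for row in sel.table] == [1, 2, 3]
        assert all("aicc" in row and "runs_pvalue" in row for row in sel.table)


class TestBurstFit:
    def test_noiseless_burst_curve_recovery(self):
        t = log_grid(10.0, 2000)
        y = 0.01 * np.exp(-50 * t) + 0.004 * np.exp(-2 * t) - 1e-4 * t + 0.65
        bf = fit_burst(Transient(t, y))
        assert bf.kburst1 == pytest.approx(50.0, rel=1e-3)
        assert bf.kburst2 == pytest.approx(2.0, rel=1e-3)
        assert bf.slope == pytest.approx(-1e-4, rel=1e-3)
        assert bf.offset == pytest.approx(0.65, rel=1e-3)

    def test_scheme_burst_amplitude_stoichiometric_with_enzyme(self, rc, om):
        tr = generate_transient(
            rc, om, 1.0, 54.0, TimebaseSpec("logarithmic", 10.0, 10, 200),
            NoiseSpec(0.0, 0),
        )
        bf = fit_burst(truncate_dead_time(tr))
        burst_um = absorbance_to_concentration(bf.total_burst_amplitude, om, "conversion")
        assert 0.5 <= burst_um <= 2.0

    def test_fitted_slope_matches_steady_state_rate(self, rc, om):
        tr = generate_transient(
            rc, om, 1.0, 54.0, TimebaseSpec("logarithmic", 10.0, 10, 200),
            NoiseSpec(0.0, 0),
        )
        bf = fit_burst(truncate_dead_time(tr))
        v_fit = absorbance_to_concentration(-bf.slope, om, "conversion")
        # steady-state conversion rate from the simulator between 5 and 9 s
        from stopflow import simulate_scheme

        traj = simulate_scheme(rc, 1.0, 54.0, np.array([5.0, 9.0]))
        total = traj.EP + traj.P
        v_true = (total[1] - total[0]) / 4.0
        assert v_fit == pytest.approx(v_true, rel=0.10)


class TestTailLinearFit:
    def test_exact_line(self):
        t = np.linspace(0.002, 10.0, 500)
        fit = tail_linear_fit(Transient(t, 0.3 - 0.001 * t))
        assert fit.slope == pytest.approx(-0.001, rel=1e-9)
        assert fit.intercept == pytest.approx(0.3, rel=1e-9)

    def test_window_excludes_decayed_exponential(self):
        t = np.linspace(0.002, 10.0, 2000)
        y = 0.1 * np.exp(-50 * t) + 0.3 - 0.001 * t
        fit = tail_linear_fit(Transient(t, y), (3.0, 10.0))
        assert fit.slope == pytest.approx(-0.001, rel=1e-6)

    def test_constant_signal_has_zero_slope(self):
        t = np.linspace(0.0, 12.0, 200)
        fit = tail_linear_fit(Transient(t, np.full_like(t, 0.2)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_in_window(self):
        t = np.linspace(0.0, 2.0, 50)
        with pytest.raises(ValueError, match="window"):
            tail_linear_fit(Transient(t, np.zeros_like(t)), (3.0, 10.0))


class TestConcentrationConversion:
    @pytest.mark.parametrize(
        "delta_a,mode,expected",
        [
            (0.132, "substrate", 10.0),
            (0.01085, "product", 10.0),
            (0.302875, "conversion", 25.0),
            (0.0, "substrate", 0.0),
        ],
    )
    def test_conversion_modes(self, om, delta_a, mode, expected):
        assert absorbance_to_concentration(delta_a, om, mode) == pytest.approx(
            expected, rel=1e-9
        )

    def test_unknown_mode_rejected(self, om):
        with pytest.raises(ValueError, match="mode"):
            absorbance_to_concentration(0.1, om, "protein")


class TestInitialConcentration:
    linear_tb = TimebaseSpec("linear", 10.0, total_points=500)

    def test_noiseless_substrate_decay_estimates_25uM(self, rc, om):
        tr = generate_transient(rc, om, 0.0, 25.0, self.linear_tb, NoiseSpec(0.0, 0))
        est = estimate_initial_concentration(tr, om, n_phases=1)
        assert est == pytest.approx(25.0, rel=1e-3)

    def test_substrate_loss_detected_from_a0(self, rc, om):
        tr = generate_transient(
            rc, om, 0.0, 50.0, self.linear_tb,
            NoiseSpec(0.0, 0, substrate_loss_fraction=0.2),
        )
        est = estimate_initial_concentration(tr, om, n_phases=1)
        assert est == pytest.approx(40.0, rel=0.02)

    def test_zero_signal_gives_zero(self, om):
        t = np.linspace(0.002, 10.0, 50)
        assert estimate_initial_concentration(Transient(t, np.zeros_like(t)), om) == 0.0

    def test_stable_under_noise_across_seeds(self, rc, om):
        clean = estimate_initial_concentration(
            generate_transient(rc, om, 0.0, 50.0, self.linear_tb, NoiseSpec(0.0, 0)),
            om, n_phases=1,
        )
        ests = []
        for seed in range(5):
            tr = generate_transient(rc, om, 0.0, 50.0, self.linear_tb, NoiseSpec(0.002, seed))
            ests.append(estimate_initial_concentration(tr, om, n_phases=1))
        # A(0) is an extrapolation of a 500-point fit; its sigma-derived
        # uncertainty is well below 1 uM
        assert np.max(np.abs(np.array(ests) - clean)) < 1.0
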