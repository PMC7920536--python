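"""Leak subtraction, trend removal, variance, and I–V model fits."""

import numpy as np
import pytest

from clampkit import get_preset, make_protocol, simulate_voltage_gated
from clampkit.errors import FitError
from clampkit.iv import (BoltzmannIV, IVCurve, LinearIV,
                         correct_junction_potential, detrend_exponential,
                         event_iv_fit, fit_boltzmann_ohmic,
                         fixed_timepoint_measures, paired_pulse_ratios,
                         subtract_leak, window_variance)
from clampkit.presets import LeakParams, cs_internal
from clampkit.pipeline import depol_family_protocol, hyperpol_family_protocol

FS = 10_000.0


class TestJunctionPotential:
    def test_command_minus60_becomes_minus70(self):
        out = correct_junction_potential(np.array([-60.0]), jp_mV=-10.0)
        assert out[0] == -70.0

    def test_zero_jp_is_identity(self):
        v = np.array([-80.0, -20.0])
        assert np.array_equal(correct_junction_potential(v, jp_mV=0.0), v)

    def test_double_application_guarded(self):
        with pytest.raises(ValueError):
            correct_junction_potential(np.array([-70.0]), already_corrected=True)


class TestLeakSubtraction:
    def test_pure_leak_cell_residual_near_zero(self, db2):
        passive = db2.replace(k_sustained=None, k_a=None, t_type=None,
                              k_ir=None, i_h=None)
        prot = depol_family_protocol(-90.0, leak_steps=True)
        b = simulate_voltage_gated(passive, prot, seed=1)
        ls, fit = subtract_leak(b, leak_window_mV=(-101.0, -94.0),
                                measure="steady", fit_intercept=True)
        assert fit.g_nS == pytest.approx(passive.leak.g_nS, rel=0.15)
        i0, i1 = prot.step_window_samples(FS)
        resid = ls.sweeps_pA[:, i0 + 50:i1].mean(axis=1)
        sem = passive.noise_sd_pA / np.sqrt(i1 - i0 - 50) * 3
        assert np.all(np.abs(resid) < 3.0)

    def test_leak_doubling_leaves_output_unchanged(self, db2):
        quiet = cs_internal(db2).replace(noise_sd_pA=0.0)
        doubled = quiet.replace(leak=LeakParams(g_nS=2.0, e_rev_mV=-55.0))
        prot = depol_family_protocol(-90.0, leak_steps=True)
        window = (-101.0, -94.0)
        a, _ = subtract_leak(simulate_voltage_gated(quiet, prot, seed=0),
                             leak_window_mV=window, measure="steady", fit_intercept=True)
        b, _ = subtract_leak(simulate_voltage_gated(doubled, prot, seed=0),
                             leak_window_mV=window, measure="steady", fit_intercept=True)
        assert np.allclose(a.sweeps_pA, b.sweeps_pA, atol=1.0)

    def test_t_transient_preserved_within_2pct(self, db2):
        quiet = cs_internal(db2).replace(noise_sd_pA=0.0)
        prot = depol_family_protocol(-90.0, leak_steps=True)
        raw = simulate_voltage_gated(quiet, prot, seed=0)
        ls, _ = subtract_leak(raw, leak_window_mV=(-101.0, -94.0),
                              measure="steady", fit_intercept=True)
        # ground-truth transient: same preset with leak removed entirely
        bare = quiet.replace(leak=LeakParams(g_nS=0.0))
        truth = simulate_voltage_gated(bare, prot, seed=0)
        i0, i1 = prot.step_window_samples(FS)
        peak_ls = ls.sweeps_pA[:, i0:i1].min(axis=1)
        peak_truth = truth.sweeps_pA[:, i0:i1].min(axis=1)
        # every sweep's transient is preserved to within 2% of the largest
        # transient in the family
        assert np.all(np.abs(peak_ls - peak_truth)
                      < 0.02 * np.abs(peak_truth).max())

    def test_too_few_leak_levels_rejected(self, db2):
        prot = depol_family_protocol(-90.0, n_steps=3, increment_mV=20.0)
        b = simulate_voltage_gated(db2, prot, seed=0)
        with pytest.raises(ValueError):
            subtract_leak(b)


class TestDetrendAndVariance:
    def test_exact_exponential_detrends_to_zero(self):
        t = np.arange(5000) / FS * 1000.0
        trace = 30.0 * np.exp(-t / 50.0) + 7.0
        resid = detrend_exponential(trace, FS)
        assert np.max(np.abs(resid)) < 1e-6

    def test_known_noise_variance_preserved(self):
        rng = np.random.default_rng(5)
        t = np.arange(10_000) / FS * 1000.0
        sigma = 2.0
        trace = 50.0 * np.exp(-t / 80.0) + rng.normal(0, sigma, t.size)
        resid = detrend_exponential(trace, FS)
        assert np.var(resid) == pytest.approx(sigma ** 2, rel=0.1)

    def test_constant_trace_zero_variance(self):
        res = window_variance(np.full(10_000, -12.0), FS, 0.1, 0.5)
        assert res.variance_pA2 == 0.0

    def test_white_noise_variance_recovered(self):
        rng = np.random.default_rng(6)
        res = window_variance(rng.normal(0, 2.0, 10_000), FS, 0.2, 0.5)
        assert res.variance_pA2 == pytest.approx(4.0, rel=0.15)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            window_variance(np.zeros(1000), FS, 0.2, 0.5)

    def test_cppg_puff_increases_variance(self, fmb):
        # focal agonist puff raises the event rate, hence the (detrended)
        # current variance during the puff window
        from clampkit import PharmacologyState, simulate_ipsc_train
        prot = make_protocol("puff", holding_mV=-10.0, sweep_duration_ms=8000,
                             puff_start_ms=4000, puff_duration_ms=3000)
        pharm = PharmacologyState.from_drug("CPPG_puff")
        b = simulate_ipsc_train(fmb.replace(ipsc_rate_Hz=4.0), prot, pharm,
                                seed=9)
        tr = b.sweeps_pA[0]
        before = window_variance(tr, FS, 3.0, 0.5).variance_pA2
        during = window_variance(tr, FS, 5.0, 0.5).variance_pA2
        assert during > before


class TestLinearIV:
    def test_noiseless_conductance_and_reversal_exact(self):
        v = np.arange(-100.0, -19.0, 10.0)
        i = 0.97 * (v - (-76.0))
        fit = event_iv_fit(IVCurve(v, i))
        assert fit.conductance_nS == pytest.approx(0.97, abs=1e-12)
        assert fit.reversal_mV == pytest.approx(-76.0, abs=1e-9)

    def test_symmetric_amplitudes_intercept_at_symmetry_point(self):
        v = np.array([-90.0, -80.0, -70.0, -60.0])
        i = np.array([-10.0, -5.0, 5.0, 10.0])  # symmetric about −75
        fit = event_iv_fit(IVCurve(v, i))
        assert fit.reversal_mV == pytest.approx(-75.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            LinearIV(IVCurve(np.array([-80.0, -70.0]), np.array([1.0, 2.0])))


class TestBoltzmannIV:
    @staticmethod
    def _curve(gmax=2.6, v_half=-66.0, z=3.6, e_ion=16.5):
        v = np.arange(-85.0, -39.0, 5.0)
        i = gmax * (v - e_ion) / (1.0 + np.exp((v_half - v) / z))
        return IVCurve(v, i)

    def test_noiseless_parameters_recovered_to_4_digits(self):
        fit = fit_boltzmann_ohmic(self._curve())
        assert fit.gmax_nS == pytest.approx(2.6, rel=1e-4)
        assert fit.v_half_mV == pytest.approx(-66.0, rel=1e-4)
        assert fit.z_mV == pytest.approx(3.6, rel=1e-4)
        assert fit.e_ion_mV == pytest.approx(16.5, rel=1e-3)

    def test_all_zero_currents_degenerate(self):
        v = np.arange(-85.0, -39.0, 5.0)
        with pytest.raises(FitError):
            fit_boltzmann_ohmic(IVCurve(v, np.zeros_like(v)))

    def test_midpoint_identity(self):
        fit = fit_boltzmann_ohmic(self._curve())
        at_vhalf = fit.predict(np.array([fit.v_half_mV]))[0]
        expect = fit.gmax_nS * (fit.v_half_mV - fit.e_ion_mV) / 2.0
        assert at_vhalf == pytest.approx(expect, rel=1e-9)

    def test_fixed_reversal_variant(self):
        fit = fit_boltzmann_ohmic(self._curve(), e_ion_mV=16.5)
        assert fit.e_ion_mV == 16.5
        assert fit.v_half_mV == pytest.approx(-66.0, rel=1e-6)


class TestFixedTimepoints:
    def test_zero_conductance_cell_measures_near_zero(self, db2):
        empty = db2.replace(k_sustained=None, k_a=None, t_type=None,
                            k_ir=None, i_h=None)
        prot = depol_family_protocol(-70.0, n_steps=8)
        b = simulate_voltage_gated(empty, prot, seed=3)
        ls, _ = subtract_leak(b, leak_window_mV=(-72.0, -55.0))
        ft = fixed_timepoint_measures(ls)
        assert np.all(np.abs(ft["outward_peak_pA"]) < 5.0)
        assert np.all(np.abs(ft["inward_pA"]) < 5.0)

    def test_db2_a_current_peak_matches_printed_scale(self, db2):
        # transient outward K at +10 mV, measured 1.8 ms after onset
        prot = depol_family_protocol(-70.0, n_steps=16)
        b = simulate_voltage_gated(db2, prot, seed=3)
        ls, _ = subtract_leak(b, leak_window_mV=(-72.0, -55.0))
        ft = fixed_timepoint_measures(ls)
        at10 = ft.iloc[int(np.argmin(np.abs(ft["level_mV"] - 10.0)))]
        assert at10["outward_peak_pA"] == pytest.approx(1132.0, rel=0.10)

    def test_kir_ih_split_matches_generative_components(self, db2):
        # instantaneous (K_IR) vs time-dependent (I_h) inward decomposition
        prot = hyperpol_family_protocol(-70.0)
        quiet = db2.replace(noise_sd_pA=0.0)
        b = simulate_voltage_gated(quiet, prot, seed=0)
        ls, _ = subtract_leak(b, leak_window_mV=(-82.0, -73.0))
        ft = fixed_timepoint_measures(ls)
        row = ft.iloc[int(np.argmin(ft["level_mV"]))]
        v = row["level_mV"]
        kir = db2.k_ir
        rect = 1.0 / (1.0 + np.exp((v - kir.rect_v_half_mV) / kir.rect_z_mV))
        kir_truth = kir.gmax_nS * rect * (v - kir.e_rev_mV)
        assert row["instantaneous_pA"] == pytest.approx(kir_truth, rel=0.10)
        assert row["time_dependent_pA"] < -25.0  # slow I_h component present

    def test_timepoint_outside_step_rejected(self, db2):
        prot = depol_family_protocol(-70.0, n_steps=4)
        b = simulate_voltage_gated(db2, prot, seed=0)
        with pytest.raises(ValueError):
            fixed_timepoint_measures(b, timepoints_ms={"late": 900.0})


class TestPairedPulse:
    def test_long_interval_full_recovery(self, db2):
        prot = make_protocol("paired_pulse", holding_mV=-80.0,
                             intervals_ms=[5000.0], tail_ms=100.0)
        b = simulate_voltage_gated(cs_internal(db2), prot, seed=1)
        _, ratios = paired_pulse_ratios(b)
        assert ratios[0] == pytest.approx(1.0, abs=0.05)

    def test_short_interval_residual_fraction(self, db2):
        prot = make_protocol("paired_pulse", holding_mV=-80.0,
                             intervals_ms=[5.0, 2000.0])
        b = simulate_voltage_gated(cs_internal(db2).replace(noise_sd_pA=0.0),
                                  prot, seed=1)
        _, ratios = paired_pulse_ratios(b)
        assert ratios[0] < 0.1  # almost nothing recovers in 5 ms

    def test_seeded_ratios_monotone_spearman(self, db2):
        from scipy.stats import spearmanr
        intervals = np.unique(np.round(np.geomspace(10, 2000, 12))).tolist()
        prot = make_protocol("paired_pulse", holding_mV=-80.0,
                             intervals_ms=intervals)
        b = simulate_voltage_gated(cs_internal(db2), prot, seed=12)
        ints, ratios = paired_pulse_ratios(b)
        rho, _ = spearmanr(ints, ratios)
        assert rho > 0.9

    def test_non_paired_bundle_rejected(self, db2):
        prot = depol_family_protocol(-90.0)
        b = simulate_voltage_gated(db2, prot, seed=0)
        with pytest.raises(ValueError):
            paired_pulse_ratios(b)
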