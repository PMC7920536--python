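"""Kinetic fits: sigmoid rise, exponential decay, double-exponential recovery."""

import numpy as np
import pytest

from clampkit import get_preset, simulate_ipsc_train
from clampkit.errors import FitError
from clampkit.filters import bessel_lowpass
from clampkit.kinetics import (ExponentialDecay, RecoveryCurve, SigmoidRise,
                               decay_vs_voltage, fit_decay_exponential,
                               fit_recovery_double_exp, fit_rise_sigmoid)
from clampkit.pipeline import ipsc_decay_experiment, membrane_hold_protocol
from clampkit.simulate import ipsc_kernel

FS = 10_000.0


class TestSigmoidRise:
    def test_logistic_closed_form(self):
        # for a pure logistic the 10–90% rise is ln(81) x slope parameter
        k = 0.7  # ms
        t = np.linspace(0.0, 20.0, 400)
        y = 5.0 + 12.0 / (1.0 + np.exp((8.0 - t) / k))
        res = SigmoidRise(t, y).fit()
        assert res.rise_10_90_us == pytest.approx(np.log(81) * k * 1000.0,
                                                  rel=0.01)
        assert res.rsquared > 0.999

    def test_ideal_step_rise_within_two_samples(self):
        w = np.concatenate([np.zeros(10), np.ones(10)])
        res = fit_rise_sigmoid(w, FS)
        assert res.rise_10_90_us <= 2 * (1e6 / FS)

    def test_synthetic_event_rises_in_physiological_band(self, fmb):
        # unfiltered noiseless events, finely sampled so the sub-ms rise is
        # resolvable: fitted rise stays in the 123–245 μs band the FMB
        # preset was built from
        fs_fine = 100_000.0
        kern = ipsc_kernel(fmb.ipsc_rise_10_90_us / 1000.0, 2.1, fs_fine)
        peak = int(np.argmax(kern))
        win = np.concatenate([np.zeros(200), -kern[: peak + 1]])
        res = fit_rise_sigmoid(win, fs_fine)
        assert 123.0 <= res.rise_10_90_us <= 245.0

    def test_filter_inflation_bounded_by_step_response(self):
        # the 2 kHz Bessel filter inflates sub-200-μs rises; the inflation is
        # bounded by quadrature with the filter's own step-response rise
        kern = ipsc_kernel(0.18, 2.1, FS)
        filt = bessel_lowpass(kern, 2000.0, FS)
        step = bessel_lowpass(np.concatenate([np.zeros(50), np.ones(400)]),
                              2000.0, FS)
        s10 = np.argmax(step > 0.1) - 50
        s90 = np.argmax(step > 0.9) - 50
        filter_rise_us = (s90 - s10) * 1e6 / FS
        res = fit_rise_sigmoid(filt[: int(np.argmax(filt)) + 1], FS)
        bound = np.hypot(180.0, filter_rise_us) * 1.5
        assert 180.0 < res.rise_10_90_us < bound


class TestExponentialDecay:
    def test_exact_exponential_recovered_to_machine_precision(self):
        t = np.arange(0, 20, 0.1)
        y = -15.0 * np.exp(-t / 2.1)
        res = ExponentialDecay(t, y).fit()
        assert res.tau_ms == pytest.approx(2.1, rel=1e-9)

    def test_grid_search_oracle_agrees_with_optimizer(self):
        # brute-force grid over tau with per-tau linear LS for (A, C)
        rng = np.random.default_rng(3)
        t = np.arange(0, 40, 0.1)
        y = 20.0 * np.exp(-t / 6.3) + 1.0 + rng.normal(0, 0.5, t.size)
        grid = np.arange(0.5, 20.0, 0.05)
        sses = []
        for tau in grid:
            X = np.column_stack([np.exp(-t / tau), np.ones_like(t)])
            beta, res_, *_ = np.linalg.lstsq(X, y, rcond=None)
            sses.append(np.sum((y - X @ beta) ** 2))
        tau_grid = grid[int(np.argmin(sses))]
        fit = ExponentialDecay(t, y).fit()
        assert abs(fit.tau_ms - tau_grid) <= 0.1  # within two grid steps

    def test_upward_trending_segment_rejected(self):
        t = np.arange(0, 10, 0.1)
        with pytest.raises(FitError):
            ExponentialDecay(t, np.exp(t / 5.0)).fit()

    def test_from_peak_handles_signed_transients(self):
        kern = ipsc_kernel(0.18, 2.1, FS)
        res = fit_decay_exponential(-23.0 * kern, FS)
        assert res.tau_ms == pytest.approx(2.1, rel=0.10)
        assert res.amplitude_pA < 0


class TestDecayVsVoltage:
    def test_fmb_decay_increases_with_depolarization(self, fmb):
        taus = []
        for i, v in enumerate((-100.0, -60.0, -20.0, 0.0)):
            r = ipsc_decay_experiment(fmb, v, duration_s=20.0, seed=20 + i)
            taus.append(r["tau_ms"])
        assert all(b > a for a, b in zip(taus, taus[1:]))

    def test_table_from_grouped_events(self):
        rng = np.random.default_rng(0)
        kern21 = ipsc_kernel(0.18, 2.1, FS)
        kern40 = ipsc_kernel(0.18, 4.0, FS)
        groups = {
            -100.0: -20 * np.tile(kern21, (8, 1)) + rng.normal(0, 0.1, (8, kern21.size)),
            0.0: 20 * np.tile(kern40, (3, 1)) + rng.normal(0, 0.1, (3, kern40.size)),
        }
        df = decay_vs_voltage(groups, FS)
        assert list(df["voltage_mV"]) == [-100.0, 0.0]
        assert df["tau_ms"].iloc[1] > df["tau_ms"].iloc[0]
        assert bool(df["flagged"].iloc[1])  # only 3 events at 0 mV

    def test_single_voltage_rejected(self):
        with pytest.raises(FitError):
            decay_vs_voltage({-100.0: np.zeros((5, 100))}, FS)


class TestRecovery:
    def test_analytic_curve_recovers_fast_tau_exactly(self):
        t = np.array([10, 20, 40, 80, 160, 320, 640, 1280, 2000.0])
        r = 1 - 0.75 * np.exp(-t / 166.0) - 0.25 * np.exp(-t / 1000.0)
        fit = fit_recovery_double_exp(t, r)
        assert fit.tau1_ms == pytest.approx(166.0, rel=1e-4)
        assert fit.tau2_ms == pytest.approx(1000.0, rel=1e-3)
        assert fit.tau1_ms < fit.tau2_ms

    def test_full_recovery_flagged_degenerate(self):
        t = np.linspace(10, 2000, 8)
        fit = fit_recovery_double_exp(t, np.ones_like(t))
        assert fit.immediate_recovery
        assert not fit.tau2_identifiable

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_recovery_double_exp([10, 20, 40], [0.1, 0.2, 0.3])

    def test_out_of_range_ratios_rejected(self):
        t = np.linspace(10, 2000, 8)
        with pytest.raises(FitError):
            fit_recovery_double_exp(t, np.full(8, 1.5))


class TestEstimatorBias:
    @pytest.mark.parametrize("rise_ms,tau_ms", [(0.1, 1.0), (0.5, 4.0), (3.0, 10.0)])
    def test_noiseless_rise_and_decay_unbiased_within_5pct(self, rise_ms, tau_ms):
        # dense sampling so the estimators, not the grid, set the accuracy
        fs_fine = 100_000.0
        kern = ipsc_kernel(rise_ms, tau_ms, fs_fine)
        decay = fit_decay_exponential(kern, fs_fine)
        assert decay.tau_ms == pytest.approx(tau_ms, rel=0.05)
        peak = int(np.argmax(kern))
        win = np.concatenate([np.zeros(200), kern[: peak + 1]])
        rise = fit_rise_sigmoid(win, fs_fine)
        assert rise.rise_10_90_us == pytest.approx(rise_ms * 1000, rel=0.05)
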