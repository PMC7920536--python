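"""Synthetic-recording generator: event statistics, biophysics, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from clampkit import (PharmacologyState, get_preset, make_protocol,
                      simulate_ipsc_train, simulate_voltage_gated)
from clampkit.pipeline import membrane_hold_protocol
from clampkit.presets import LeakParams
from clampkit.simulate import calibrate_rise_tau, product_rise_10_90


FS = 10_000.0


class TestIPSCTrains:
    def test_event_count_in_poisson_interval(self, fmb_train_m100):
        # rate 19.1 Hz x 60 s: count must fall in the Poisson 99% interval
        n = len(fmb_train_m100.ground_truth.event_times_s[0])
        lam = 19.1 * 60.0
        lo, hi = sps.poisson.ppf([0.005, 0.995], lam)
        assert lo <= n <= hi

    def test_strychnine_blocks_all_events(self, fmb):
        prot = membrane_hold_protocol(-20.0, 10_000.0)
        b = simulate_ipsc_train(fmb, prot, PharmacologyState.from_drug("STR"),
                                seed=3)
        assert len(b.ground_truth.event_times_s[0]) == 0
        # trace is flat leak + noise: no excursion beyond a few noise SDs
        tr = b.sweeps_pA[0]
        assert np.ptp(tr) < 10 * fmb.noise_sd_pA

    def test_all_events_inward_below_reversal(self, fmb_train_m100):
        # at −100 mV every event is inward: the trace min is well below
        # baseline while the max barely exceeds it
        tr = fmb_train_m100.sweeps_pA[0]
        base = np.median(tr)
        assert base - tr.min() > 5 * (tr.max() - base)

    def test_identical_seed_bit_identical(self, fmb):
        prot = membrane_hold_protocol(-70.0, 2_000.0)
        a = simulate_ipsc_train(fmb, prot, seed=11)
        b = simulate_ipsc_train(fmb, prot, seed=11)
        assert np.array_equal(a.sweeps_pA, b.sweeps_pA)
        assert np.array_equal(a.ground_truth.event_times_s[0],
                              b.ground_truth.event_times_s[0])

    def test_ground_truth_events_inside_time_base(self, fmb_train_m100):
        t = fmb_train_m100.ground_truth.event_times_s[0]
        assert np.all(t >= 0) and np.all(t <= fmb_train_m100.time_s[-1])

    def test_driving_force_linearity_reverses_at_e_cl(self, fmb):
        # noiseless, unfiltered, sparse trains: mean event peak vs potential
        # is linear with x-intercept at the preset chloride reversal ± 1 mV
        quiet = fmb.replace(noise_sd_pA=0.0, bessel_fc_Hz=None,
                            ipsc_rate_Hz=3.0, leak=LeakParams(g_nS=0.0))
        amps, volts = [], []
        for v in (-100.0, -90.0, -60.0, -40.0, -20.0, 0.0):
            prot = membrane_hold_protocol(v, 20_000.0)
            b = simulate_ipsc_train(quiet, prot, seed=17)
            tr = b.sweeps_pA[0]
            peaks = []
            for t0 in b.ground_truth.event_times_s[0]:
                i = int(t0 * FS)
                win = tr[i:i + 60]
                if win.size:
                    peaks.append(win[np.argmax(np.abs(win))])
            amps.append(np.mean(peaks))
            volts.append(v)
        slope, intercept = np.polyfit(volts, amps, 1)
        assert abs(-intercept / slope - fmb.e_cl_mV) < 1.0

    def test_puff_scoped_multiplier_only_in_window(self, fmb):
        prot = make_protocol("puff", holding_mV=-10.0, sweep_duration_ms=30_000,
                             puff_start_ms=10_000, puff_duration_ms=10_000)
        pharm = PharmacologyState.from_drug("CPPG_puff")
        b = simulate_ipsc_train(fmb, prot, pharm, seed=5)
        t = b.ground_truth.event_times_s[0]
        inside = np.sum((t >= 10.0) & (t < 20.0))
        outside = np.sum(t < 10.0) + np.sum(t >= 20.0)
        # 5x rate inside the 10-s window vs ~19 Hz over 20 s outside
        assert inside > 2.5 * outside / 2.0

    def test_negative_rate_rejected(self, fmb):
        with pytest.raises(ValueError):
            fmb.replace(ipsc_rate_Hz=-1.0)


class TestVoltageGated:
    def test_zero_conductance_zero_noise_gives_zero(self, db2):
        empty = db2.replace(k_sustained=None, k_a=None, t_type=None,
                            k_ir=None, i_h=None, leak=LeakParams(g_nS=0.0),
                            noise_sd_pA=0.0)
        prot = make_protocol("step_family", holding_mV=-80, increment_mV=5,
                             n_steps=4)
        b = simulate_voltage_gated(empty, prot, seed=0)
        assert np.allclose(b.sweeps_pA, 0.0, atol=1e-12)

    def test_db2_peak_matches_boltzmann_prediction(self, db2):
        # peak inward transient at −50 mV equals the apparent Boltzmann-ohmic
        # prediction (times availability at the −90 mV hold) within the
        # filter-induced attenuation budget of 5%; K currents blocked
        from clampkit.presets import cs_internal
        quiet = cs_internal(db2).replace(noise_sd_pA=0.0)
        prot = make_protocol("step_family", holding_mV=-80.0,
                             levels_mV=[-40.0], step_onset_ms=50,
                             step_duration_ms=200, sweep_duration_ms=300)
        b = simulate_voltage_gated(quiet, prot, seed=0)
        sw = b.sweeps_pA[0]
        base = sw[:490].mean()
        peak = (sw[500:2500] - base).min()
        p = db2.t_type
        m_inf = 1.0 / (1.0 + np.exp((p.v_half_mV + 50.0) / p.z_mV))
        h_avail = 1.0 / (1.0 + np.exp((-90.0 - p.inact_v_half_mV) / p.inact_z_mV))
        predicted = p.gmax_nS * m_inf * h_avail * (-50.0 - p.e_rev_mV)
        # leak jump from −90 to −50 adds a constant offset; remove it
        leak_jump = db2.leak.g_nS * 40.0
        assert abs((peak - leak_jump) - predicted) / abs(predicted) < 0.05

    def test_db1_hyperpolarizing_inward_is_small(self, db1):
        # slow time-dependent inward current in DB1 is on the −21 pA scale
        from clampkit.pipeline import hyperpol_family_protocol
        from clampkit.iv import subtract_leak, fixed_timepoint_measures
        prot = hyperpol_family_protocol(-70.0)
        b = simulate_voltage_gated(db1, prot, seed=2)
        ls, _ = subtract_leak(b, leak_window_mV=(-82.0, -73.0))
        ft = fixed_timepoint_measures(ls)
        td = ft.iloc[int(np.argmin(ft["level_mV"]))]["time_dependent_pA"]
        assert -40.0 < td < -8.0

    def test_paired_pulse_gates_recover_between_pulses(self, db2):
        from clampkit.presets import cs_internal
        from clampkit.iv import paired_pulse_ratios
        prot = make_protocol("paired_pulse", holding_mV=-80.0,
                             intervals_ms=[20, 100, 400, 1600])
        b = simulate_voltage_gated(cs_internal(db2).replace(noise_sd_pA=0.0),
                                  prot, seed=0)
        _, ratios = paired_pulse_ratios(b)
        assert np.all(np.diff(ratios) > 0)
        assert ratios[-1] > 0.85


class TestRiseCalibration:
    @pytest.mark.parametrize("rise,decay", [(0.18, 2.1), (0.25, 5.3), (1.0, 4.0)])
    def test_calibrated_kernel_hits_requested_rise(self, rise, decay):
        tau_r = calibrate_rise_tau(rise, decay)
        assert abs(product_rise_10_90(tau_r, decay) - rise) < 1e-6 * rise

    def test_rise_slower_than_decay_supports_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rise_tau(100.0, 1.0)
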