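"""Event detection: templates, matched filter, threshold counter, averaging."""

import numpy as np
import pytest

from clampkit import get_preset, simulate_ipsc_train
from clampkit.errors import InsufficientEventsError
from clampkit.events import (DetectedEvent, EventTemplate, build_template,
                             count_events_threshold, detect_events,
                             extract_average_event)
from clampkit.filters import bessel_lowpass
from clampkit.pipeline import membrane_hold_protocol
from clampkit.simulate import ipsc_kernel

FS = 10_000.0


class TestTemplate:
    def test_built_template_decay_matches_ground_truth(self, fmb_train_m100, fmb):
        tpl = build_template(fmb_train_m100.sweeps_pA[0], FS,
                             amplitude_threshold_pA=10.0, polarity="inward")
        truth = fmb.ipsc_decay_tau_ms(-100.0)  # 2.1 ms
        assert abs(tpl.decay_tau_ms - truth) / truth < 0.10

    def test_noise_only_raises_insufficient_events(self, noise_only_bundle):
        with pytest.raises(InsufficientEventsError):
            build_template(noise_only_bundle.sweeps_pA[0][:100_000], FS,
                           amplitude_threshold_pA=10.0, polarity="inward")

    def test_identical_noiseless_events_recover_waveform(self):
        # zero noise, constant amplitude, kinetics resolvable at 10 kHz:
        # the analytically regenerated template matches the generator shape
        kern = ipsc_kernel(1.0, 5.0, FS)
        trace = np.zeros(100_000)
        for i in range(200, 100_000 - kern.size, 800):
            trace[i:i + kern.size] -= 20.0 * kern
        tpl = build_template(trace, FS, amplitude_threshold_pA=10.0,
                             polarity="inward")
        n = min(tpl.waveform.size, kern.size)
        err = np.max(np.abs(-tpl.waveform[:n] - kern[:n]))
        assert err < 0.05  # analytic regeneration from fitted kinetics

    def test_template_unit_peak_invariant(self):
        tpl = EventTemplate.from_kinetics(180.0, 2.1, FS, "inward")
        assert np.isclose(np.abs(tpl.waveform).max(), 1.0)
        assert tpl.waveform.min() == -1.0


class TestDetection:
    def test_min_separation_merges_close_events(self):
        kern = ipsc_kernel(0.18, 2.1, FS)
        trace = np.zeros(20_000)
        for onset in (5000, 5010):  # two events 1 ms apart
            trace[onset:onset + kern.size] -= 25.0 * kern[:min(kern.size,
                                                               20_000 - onset)]
        rng = np.random.default_rng(0)
        trace = bessel_lowpass(trace + rng.normal(0, 2.0, trace.size), 2000, FS)
        tpl = EventTemplate.from_kinetics(180.0, 2.1, FS, "inward")
        events = detect_events(trace, tpl, min_separation_ms=2.0)
        assert len(events) == 1

    def test_noise_only_false_positive_rate(self, noise_only_bundle):
        tpl = EventTemplate.from_kinetics(180.0, 2.1, FS, "inward")
        events = detect_events(noise_only_bundle.sweeps_pA[0], tpl,
                               criterion_threshold=3.5)
        assert len(events) / 60.0 <= 0.2

    def test_template_longer_than_trace_rejected(self):
        tpl = EventTemplate.from_kinetics(180.0, 2.1, FS, "inward")
        with pytest.raises(ValueError):
            detect_events(np.zeros(10), tpl)

    def test_detected_frequency_monotone_in_threshold(self, fmb_train_m100):
        tpl = EventTemplate.from_kinetics(180.0, 2.1, FS, "inward")
        trace = fmb_train_m100.sweeps_pA[0][:200_000]
        counts = [len(detect_events(trace, tpl, criterion_threshold=thr))
                  for thr in (2.5, 3.5, 5.0, 8.0, 12.0)]
        assert counts == sorted(counts, reverse=True)

    def test_zero_noise_detection_matches_ground_truth_count(self, fmb):
        # sparse noiseless train: template detector and threshold counter
        # both agree exactly with the generative count
        quiet = fmb.replace(noise_sd_pA=0.0, ipsc_rate_Hz=1.0,
                            ipsc_amplitude_cv=1e-9)
        prot = membrane_hold_protocol(-100.0, 30_000.0)
        b = simulate_ipsc_train(quiet, prot, seed=5)
        n_true = len(b.ground_truth.event_times_s[0])
        tpl = EventTemplate.from_kinetics(180.0, 2.1, FS, "inward")
        det = detect_events(b.sweeps_pA[0], tpl)
        freq = count_events_threshold(b.sweeps_pA[0], FS)
        assert len(det) == n_true
        assert freq == pytest.approx(n_true / 30.0)


class TestThresholdCounter:
    def test_flat_trace_zero_hz(self):
        assert count_events_threshold(np.full(20_000, -15.0), FS) == 0.0

    def test_injected_square_events_counted(self):
        rng = np.random.default_rng(1)
        trace = rng.normal(0, 1.0, 10_000)
        for onset in (1000, 3000, 5000, 7000, 9000):
            trace[onset:onset + 20] -= 5.0  # 2-ms square events, 5x SD
        assert count_events_threshold(trace, FS) == 5.0

    def test_width_floor_rejects_narrow_spikes(self):
        rng = np.random.default_rng(2)
        trace = rng.normal(0, 1.0, 10_000)
        for onset in range(500, 9500, 1000):
            trace[onset:onset + 3] -= 8.0  # 0.3-ms spikes
        assert count_events_threshold(trace, FS, min_width_ms=1.0) == 0.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            count_events_threshold(np.zeros(5000), FS)


class TestAveraging:
    def test_identical_noiseless_events_average_exactly(self):
        kern = ipsc_kernel(0.18, 2.1, FS)
        trace = np.zeros(200_000)
        onsets = np.arange(1000, 195_000, 500)
        for i in onsets:
            trace[i:i + kern.size] -= 20.0 * kern
        events = [DetectedEvent(i / FS, -20.0, 10.0) for i in onsets]
        avg, sem, n = extract_average_event(trace, events, FS, window_ms=20.0)
        single = trace[1000 - 20:1000 + 200]
        assert np.allclose(avg, single, atol=1e-9)
        assert np.allclose(sem, 0.0, atol=1e-12)

    def test_sem_halves_when_event_count_quadruples(self):
        kern = ipsc_kernel(0.18, 2.1, FS)
        rng = np.random.default_rng(7)

        def make(n_events):
            trace = np.zeros(60_000 * 10)
            onsets = np.arange(1000, 1000 + 500 * n_events, 500)
            for i in onsets:
                trace[i:i + kern.size] -= 20.0 * kern
            trace += rng.normal(0, 2.0, trace.size)
            events = [DetectedEvent(i / FS, -20.0, 10.0) for i in onsets]
            _, sem, n = extract_average_event(trace, events, FS)
            assert n == n_events
            return sem.mean()

        ratio = make(400) / make(100)
        assert abs(ratio - 0.5) < 0.1

    def test_empty_event_list_rejected(self):
        with pytest.raises(InsufficientEventsError):
            extract_average_event(np.zeros(1000), [], FS)
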