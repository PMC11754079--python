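"""Mini-PSC detection: noise estimation, QC, detection, selection, summary."""

import numpy as np
import pytest

from eiphys import mini_events, synthetic
from eiphys.containers import SweepRecording
from eiphys.mini_events import (DetectedEvent, average_nonoverlapping,
                                detect_events, estimate_rms_noise, qc_cell,
                                select_events, summarize_cell)

FS = 10_000.0


def _noise_trace(sigma, duration=60.0, seed=0, offset=0.0):
    rng = np.random.default_rng(seed)
    return SweepRecording(
        samples=rng.normal(offset, sigma, int(duration * FS)),
        sampling_rate=FS, meta={"polarity": "outward"})


def _injected_trace(n_events=10, amp=20.0, sigma=1.5, sep=0.2, seed=0):
    """Evenly separated identical events in Gaussian noise."""
    duration = (n_events + 1) * sep
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, sigma, int(duration * FS))
    times = (np.arange(n_events) + 1) * sep
    kern = synthetic.psc_kernel(amp, 0.5, 5.0, FS)
    for t in times:
        i = int(t * FS)
        x[i:i + kern.size] += kern[: x.size - i]
    rec = SweepRecording(samples=x, sampling_rate=FS,
                         meta={"polarity": "outward"})
    return rec, times


class TestRmsNoise:
    def test_pure_gaussian_unbiased(self):
        rms = estimate_rms_noise(_noise_trace(2.0))
        assert rms == pytest.approx(2.0, abs=0.05)

    def test_all_zero_trace_gives_zero(self):
        rec = SweepRecording(samples=np.zeros(int(20 * FS)), sampling_rate=FS)
        assert estimate_rms_noise(rec) == 0.0

    def test_saturated_trace_rejected(self):
        rng = np.random.default_rng(0)
        x = np.clip(rng.normal(0, 2.0, int(20 * FS)), -3.0, 3.0)
        rec = SweepRecording(samples=x, sampling_rate=FS)
        with pytest.raises(ValueError, match="saturated"):
            estimate_rms_noise(rec)

    def test_events_excluded_by_iteration(self):
        rec, _ = synthetic.gen_mini_sweep(rate=1.0, amp_mean=30.0,
                                          noise_rms=1.5, duration=60.0,
                                          polarity="outward", seed=2)
        assert estimate_rms_noise(rec) == pytest.approx(1.5, rel=0.05)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            estimate_rms_noise(_noise_trace(1.0, duration=5.0))


class TestQc:
    @pytest.mark.parametrize("rms,cls,expected", [
        (1.9, "mEPSC", True),   # strictly below the 2 pA limit
        (2.0, "mEPSC", False),  # boundary is exclusive
        (3.9, "mIPSC", True),   # strictly below the 4 pA limit
        (4.0, "mIPSC", False),
    ])
    def test_strict_inclusion_thresholds(self, rms, cls, expected):
        assert qc_cell(rms, cls) is expected


class TestDetection:
    def test_injected_events_all_found_with_accurate_onsets(self):
        rec, times = _injected_trace()
        events = detect_events(rec, 1.5)
        assert len(events) == len(times)
        for e, t in zip(events, times):
            assert abs(e.onset_time - t) < 2e-3

    def test_false_positive_rate_on_pure_noise(self):
        fp = sum(len(detect_events(_noise_trace(2.0, seed=s), 2.0))
                 for s in range(5))
        assert fp / (5 * 60.0) < 0.1  # Hz

    def test_below_threshold_amplitude_not_detected(self):
        rec, _ = _injected_trace(amp=4.0, sigma=2.0, seed=1)
        assert detect_events(rec, 2.0) == []

    def test_monotone_in_threshold_multiplier(self):
        rec, _ = synthetic.gen_mini_sweep(rate=3.0, duration=30.0, seed=4,
                                          polarity="outward")
        n3 = len(detect_events(rec, 1.5, threshold_mult=3.0))
        n5 = len(detect_events(rec, 1.5, threshold_mult=5.0))
        assert n5 <= n3

    def test_dc_offset_invariance(self):
        rec, _ = _injected_trace(seed=3)
        shifted = rec.with_samples(rec.samples + 250.0)
        a = detect_events(rec, 1.5)
        b = detect_events(shifted, 1.5)
        assert [e.onset_time for e in a] == [e.onset_time for e in b]
        np.testing.assert_allclose([e.amplitude for e in a],
                                   [e.amplitude for e in b], rtol=1e-9)


class TestSelection:
    def _mk(self, onset, rise):
        return DetectedEvent(onset_time=onset, peak_time=onset + 1e-3,
                             amplitude=20.0, rise_time=rise,
                             preceding_interval=np.inf)

    def test_first_300_kept_chronologically(self):
        events = [self._mk(0.1 * i, 1.0) for i in range(400)]
        kept, enough = select_events(events, "mEPSC")
        assert len(kept) == 300 and enough
        assert kept[-1].onset_time == pytest.approx(0.1 * 299)

    def test_rise_time_boundary_strict(self):
        events = [self._mk(0.0, 3.0), self._mk(1.0, 2.99)]
        kept, _ = select_events(events, "mEPSC")
        assert [e.rise_time for e in kept] == [2.99]

    def test_shortfall_flagged(self):
        events = [self._mk(0.1 * i, 1.0) for i in range(150)]
        kept, enough = select_events(events, "mEPSC")
        assert len(kept) == 150 and not enough

    def test_mipsc_limit_is_5ms(self):
        events = [self._mk(0.0, 4.5)]
        assert len(select_events(events, "mIPSC")[0]) == 1
        assert len(select_events(events, "mEPSC")[0]) == 0


class TestSummary:
    def test_frequency_is_span_based(self):
        events = [DetectedEvent(onset_time=t, peak_time=t + 1e-3,
                                amplitude=20.0, rise_time=1.0,
                                preceding_interval=np.inf)
                  for t in np.linspace(0.0, 100.0, 300)]
        rec = _noise_trace(1.0, duration=105.0)
        s = summarize_cell(events, rec, 1.0, "mEPSC")
        assert s.frequency == pytest.approx(2.99)

    def test_single_event_rejected(self):
        rec = _noise_trace(1.0, duration=15.0)
        ev = [DetectedEvent(onset_time=1.0, peak_time=1.001, amplitude=10.0,
                            rise_time=1.0, preceding_interval=np.inf)]
        with pytest.raises(ValueError, match="insufficient events"):
            summarize_cell(ev, rec, 1.0, "mEPSC")

    def test_parameter_recovery_across_rates(self):
        # recovered frequency and amplitude within 10% at SNR >= 10
        for rate in (0.5, 2.0, 5.0):
            freqs, amps = [], []
            for seed in range(8):
                rec, _ = synthetic.gen_mini_sweep(rate=rate, amp_mean=25.0,
                                                  noise_rms=2.5,
                                                  duration=120.0, seed=seed)
                s = mini_events.analyze_sweep(rec, "mEPSC")
                freqs.append(s.frequency)
                amps.append(s.mean_amplitude)
            assert np.mean(freqs) == pytest.approx(rate, rel=0.10)
            assert np.mean(amps) == pytest.approx(25.0, rel=0.10)

    def test_averaged_waveform_peak_matches_mean_amplitude(self):
        rec, _ = _injected_trace(n_events=20, amp=25.0, sigma=1.0, seed=5)
        events = detect_events(rec, 1.0)
        s = summarize_cell(events, rec, 1.0, "mEPSC")
        assert s.averaged_waveform.max() == pytest.approx(s.mean_amplitude,
                                                          rel=0.10)


class TestAveraging:
    def test_close_events_excluded(self):
        rec, _ = _injected_trace(n_events=4, sep=0.3, sigma=0.5, seed=6)
        events = detect_events(rec, 0.5)
        # events 5 ms apart within a 50 ms window: neither may contribute
        e0 = events[0]
        twin = DetectedEvent(onset_time=e0.onset_time + 0.005,
                             peak_time=e0.onset_time + 0.006,
                             amplitude=20.0, rise_time=1.0,
                             preceding_interval=0.005)
        with pytest.raises(ValueError, match="non-overlapping"):
            average_nonoverlapping([e0, twin], rec)

    def test_isolated_events_average_to_kernel_peak(self):
        rec, _ = _injected_trace(n_events=20, amp=25.0, sigma=1.0, seed=7)
        events = detect_events(rec, 1.0)
        wave = average_nonoverlapping(events, rec)
        assert wave.max() == pytest.approx(25.0, rel=0.05)

    def test_empty_events_rejected(self):
        rec = _noise_trace(1.0, duration=12.0)
        with pytest.raises(ValueError, match="no events"):
            average_nonoverlapping([], rec)
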