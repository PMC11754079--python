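"""Generator contracts: normalization, closed forms, calibration, determinism."""

import numpy as np
import pytest
from scipy.integrate import quad

from eiphys import synthetic
from eiphys.synthetic import (gen_evoked_series, gen_imaging_stack,
                              gen_mini_sweep, gen_polysomnography,
                              gen_sipsc_sweep, psc_kernel,
                              psc_kernel_integral)


class TestPscKernel:
    def test_peak_equals_amplitude(self):
        w = psc_kernel(20.0, 0.5, 5.0, 10_000.0)
        # within one sample of interpolation of the continuous maximum
        assert w.max() == pytest.approx(20.0, rel=1e-3)

    def test_zero_amplitude_gives_zero_waveform(self):
        assert not psc_kernel(0.0, 0.5, 5.0).any()

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            psc_kernel(10.0, 5.0, 5.0)

    def test_closed_form_integral_matches_quadrature(self):
        # oracle: adaptive quadrature of the continuous biexponential
        amp, tr, td = 20.0, 0.5, 5.0
        a_prime = amp / (np.exp(-np.log(td / tr) * tr * td / (td - tr) / td)
                         - np.exp(-np.log(td / tr) * tr * td / (td - tr) / tr))
        oracle, _ = quad(lambda t: a_prime * (np.exp(-t / td) - np.exp(-t / tr)),
                         0, 50 * td)
        assert psc_kernel_integral(amp, tr, td) * 1000.0 == \
            pytest.approx(oracle, rel=1e-6)

    def test_sampled_integral_matches_quadrature(self):
        # 100x oversampled waveform integral vs the closed form, < 0.1%
        w = psc_kernel(20.0, 0.5, 5.0, sampling_rate=1_000_000.0,
                       n_decay_constants=30.0)
        num = w.sum() / 1_000_000.0
        assert num == pytest.approx(psc_kernel_integral(20.0, 0.5, 5.0),
                                    rel=1e-3)


class TestMiniGenerator:
    def test_poisson_event_count_calibration(self):
        # oracle: Poisson mean/SD of counts; 50 seeds, rate 2 Hz, 300 s
        counts = [gen_mini_sweep(rate=2.0, duration=300.0, noise_rms=0.0,
                                 seed=s)[1].event_times.size
                  for s in range(50)]
        assert abs(np.mean(counts) - 600) < 3 * np.sqrt(600)

    def test_zero_rate_gives_pure_noise(self):
        rec, truth = gen_mini_sweep(rate=0.0, duration=20.0, seed=0)
        assert truth.event_times.size == 0
        assert abs(rec.samples.mean()) < 0.1

    def test_same_seed_reproducible(self):
        a, _ = gen_mini_sweep(seed=7, duration=5.0)
        b, _ = gen_mini_sweep(seed=7, duration=5.0)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_polarity_convention(self):
        rec, _ = gen_mini_sweep(rate=5.0, duration=10.0, noise_rms=0.0,
                                polarity="inward", seed=0)
        assert rec.samples.min() < -5 and rec.samples.max() <= 1e-9
        assert rec.meta["polarity"] == "inward"


class TestEvokedGenerator:
    def test_true_ratio_is_ratio_of_maxima(self):
        _, truth = gen_evoked_series(e_max=200.0, i_max=400.0, seed=0)
        assert truth.true_ratio == 0.5

    def test_noiseless_peaks_equal_truth_above_onset(self):
        pairs, truth = gen_evoked_series(noise_rms=0.0, threshold_jitter=0.0,
                                         seed=0, second_peak_frac=0.0)
        for k, p in enumerate(pairs):
            assert (-p.excitatory_trace.samples).max() == \
                pytest.approx(truth.true_e_peak[k], rel=1e-3)

    def test_non_monotone_intensities_rejected(self):
        with pytest.raises(ValueError):
            gen_evoked_series(intensities=[10, 30, 20, 40], seed=0)


class TestSipscGenerator:
    def test_duration_outside_window_rejected(self):
        with pytest.raises(ValueError, match=r"\[180, 240\]"):
            gen_sipsc_sweep(duration=170.0, seed=0)

    def test_pure_drift_trace(self):
        rec, truth = gen_sipsc_sweep(rate=0.0, noise_rms=0.0,
                                     drift_amplitude=0.01, seed=0)
        assert truth.event_times.size == 0
        t = rec.times
        np.testing.assert_allclose(
            rec.samples, 0.01 * np.sin(2 * np.pi * t / 60.0), atol=1e-12)

    def test_ground_truth_charge_matches_quadrature(self):
        _, truth = gen_sipsc_sweep(seed=3)
        per_event, _ = quad(
            lambda t: (np.exp(-t / truth.kernel_decay_tau)
                       - np.exp(-t / truth.kernel_rise_tau)),
            0, 50 * truth.kernel_decay_tau)
        r = truth.kernel_rise_tau / truth.kernel_decay_tau
        m = r ** (truth.kernel_rise_tau
                  / (truth.kernel_decay_tau - truth.kernel_rise_tau)) - \
            r ** (truth.kernel_decay_tau
                  / (truth.kernel_decay_tau - truth.kernel_rise_tau))
        oracle = truth.event_amplitudes.sum() / m * per_event / 1000.0
        assert truth.total_charge == pytest.approx(oracle, rel=1e-6)


class TestSleepGenerator:
    def test_identity_chain_stays_awake(self):
        truth = synthetic.default_sleep_truth()
        truth.transition_matrices = {"light": np.eye(3), "dark": np.eye(3)}
        _, hyp = gen_polysomnography(truth, epochs_per_day=50, seed=0)
        assert set(hyp.labels) == {"WAKE"}

    def test_nrem_delta_dominates_spectrum(self):
        # oracle: Welch on the generated signal itself
        from scipy import signal as sps

        truth = synthetic.default_sleep_truth()
        truth.state_sequence = ["NREM"] * 100
        psg, _ = gen_polysomnography(truth, seed=0, epochs_per_day=100)
        f, pxx = sps.welch(psg.eeg, fs=500.0, nperseg=1000)
        assert 0.5 <= f[np.argmax(pxx)] <= 4.0

    def test_seed_reproducibility(self):
        a, ha = gen_polysomnography(seed=3, epochs_per_day=30)
        b, hb = gen_polysomnography(seed=3, epochs_per_day=30)
        np.testing.assert_array_equal(a.eeg, b.eeg)
        assert ha.labels == hb.labels

    def test_stationary_se_formula_matches_iid_limit(self):
        # for an iid chain (identical rows) the asymptotic SE must reduce
        # to the binomial SE sqrt(p(1-p)/n)
        P = np.tile([0.5, 0.3, 0.2], (3, 1))
        se = synthetic.markov_occupancy_se(P, 1000)
        expect = np.sqrt(np.array([0.5, 0.3, 0.2])
                         * np.array([0.5, 0.7, 0.8]) / 1000)
        np.testing.assert_allclose(se, expect, rtol=1e-9)


class TestImagingGenerator:
    def test_noiseless_fourier_magnitude_equals_amplitude(self, imaging_truth):
        # oracle: closed-form DFT of a cosine at a grid frequency
        imaging_truth.noise_sd = 0.0
        contra, _ = gen_imaging_stack(imaging_truth, n_cycles=4, seed=0)
        from eiphys.intrinsic_imaging import fourier_response

        resp = fourier_response(contra)
        np.testing.assert_allclose(resp.magnitude, imaging_truth.contra_amp,
                                   atol=1e-10)
        # phase recovered where amplitude is nonzero
        np.testing.assert_allclose(
            np.angle(np.exp(1j * (resp.phase - imaging_truth.phase_map)))[
                imaging_truth.contra_amp > 1e-6], 0.0, atol=0.05)

    def test_seed_reproducibility(self, imaging_truth):
        a, _ = gen_imaging_stack(imaging_truth, n_cycles=2, seed=5)
        b, _ = gen_imaging_stack(imaging_truth, n_cycles=2, seed=5)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_true_odi_formula(self):
        truth = synthetic.make_imaging_truth(contra_peak=3.0, ipsi_peak=1.0)
        assert truth.true_odi == pytest.approx(0.5)
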