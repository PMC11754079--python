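"""Seeded generators for every input modality, with known ground truth.

Each generator is a pure function of its parameters and a seed, so any
downstream quantification can be scored against the exact events, curves,
state sequences or amplitude maps that produced the data.

The signal models are deliberately minimal: Poisson-arrival biexponential
postsynaptic currents in Gaussian noise, saturating (Hill-type) evoked
input-output curves, spectrally weighted band-limited noise for sleep EEG,
and pixelwise cosines for periodic-stimulus imaging.  They contain exactly
the structure the detectors and statistics are sensitive to and nothing
more (no membrane equations, no 1/f aperiodic background, no artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .containers import (
    EPOCH_LENGTH_S,
    Hypnogram,
    ImageStack,
    PolysomnographyRecording,
    STATES,
    SweepRecording,
)

DEFAULT_SAMPLING_RATE = 10_000.0  # Hz, matches 10 kHz digitization


# ---------------------------------------------------------------------------
# ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class MiniGroundTruth:
    """Events underlying a synthetic mini/spontaneous PSC sweep."""

    event_times: np.ndarray  # s, strictly increasing
    event_amplitudes: np.ndarray  # pA (or nA for sIPSC records), > 0
    kernel_rise_tau: float  # ms
    kernel_decay_tau: float  # ms
    noise_rms: float
    true_rate: float  # Hz

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.event_amplitudes = np.asarray(self.event_amplitudes, dtype=float)
        if self.event_times.size and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")
        if np.any(self.event_amplitudes <= 0):
            raise ValueError("event amplitudes must be positive")
        if not self.kernel_decay_tau > self.kernel_rise_tau > 0:
            raise ValueError("require decay_tau > rise_tau > 0")

    @property
    def total_charge(self) -> float:
        """Closed-form summed kernel integral, amplitude-units x seconds."""
        per_unit = psc_kernel_integral(1.0, self.kernel_rise_tau,
                                       self.kernel_decay_tau)
        return float(self.event_amplitudes.sum() * per_unit)


@dataclass
class EvokedGroundTruth:
    intensities: np.ndarray
    true_e_peak: np.ndarray  # pA per intensity
    true_i_peak: np.ndarray  # pA per intensity
    true_ratio: float
    stable_onset_index: int


@dataclass
class SleepGroundTruth:
    """Markov-chain sleep model: one transition matrix per light phase.

    ``transition_matrices`` maps phase (``light``/``dark``) to a 3x3
    row-stochastic matrix over (WAKE, NREM, REM) at 4-s epoch resolution.
    ``band_weights`` holds per-state relative *power* of the delta, theta
    and gamma EEG components; ``emg_rms`` the per-state EMG level (uV).
    """

    transition_matrices: dict
    band_weights: dict
    emg_rms: dict
    eeg_scale: float = 40.0  # uV RMS of the total EEG signal
    state_sequence: Optional[list] = None

    def __post_init__(self) -> None:
        for phase, P in self.transition_matrices.items():
            P = np.asarray(P, dtype=float)
            if P.shape != (3, 3) or np.any(P < 0) or \
                    not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError(f"{phase}: transition matrix must be 3x3 "
                                 "row-stochastic with nonnegative entries")
            self.transition_matrices[phase] = P


@dataclass
class ImagingGroundTruth:
    contra_amp: np.ndarray  # per-pixel response amplitude
    ipsi_amp: np.ndarray
    phase_map: np.ndarray  # radians, retinotopy surrogate
    noise_sd: float

    def __post_init__(self) -> None:
        if np.any(self.contra_amp < 0) or np.any(self.ipsi_amp < 0):
            raise ValueError("amplitude maps must be nonnegative")

    @property
    def true_roi(self) -> np.ndarray:
        """Top 70% of pixels by true ipsilateral amplitude (row-major ties)."""
        n = self.ipsi_amp.size
        k = int(np.ceil(0.70 * n))
        order = np.argsort(-self.ipsi_amp.ravel(), kind="stable")
        mask = np.zeros(n, dtype=bool)
        mask[order[:k]] = True
        return mask.reshape(self.ipsi_amp.shape)

    @property
    def true_odi(self) -> float:
        roi = self.true_roi
        c, i = self.contra_amp[roi], self.ipsi_amp[roi]
        s = c + i
        ok = s > 0
        return float(np.mean((c[ok] - i[ok]) / s[ok]))


# ---------------------------------------------------------------------------
# PSC kernel
# ---------------------------------------------------------------------------

def _biexp_peak_factor(rise_tau: float, decay_tau: float) -> float:
    # peak of exp(-t/tau_d) - exp(-t/tau_r), attained at
    # t* = tau_r tau_d / (tau_d - tau_r) * ln(tau_d / tau_r)
    r = rise_tau / decay_tau
    return r ** (rise_tau / (decay_tau - rise_tau)) - \
        r ** (decay_tau / (decay_tau - rise_tau))


def psc_kernel(amplitude: float, rise_tau: float, decay_tau: float,
               sampling_rate: float = DEFAULT_SAMPLING_RATE,
               n_decay_constants: float = 8.0) -> np.ndarray:
    """Biexponential PSC waveform with its maximum scaled to ``amplitude``.

    ``w(t) = A' (exp(-t/tau_d) - exp(-t/tau_r))`` with ``A'`` chosen from
    the closed-form peak so that the continuous maximum equals
    ``amplitude``; taus in ms, output sampled at ``sampling_rate``.
    """
    if not decay_tau > rise_tau > 0:
        raise ValueError("require decay_tau > rise_tau > 0")
    n = max(2, int(round(n_decay_constants * decay_tau / 1000.0 * sampling_rate)))
    t = np.arange(n) / sampling_rate * 1000.0  # ms
    shape = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    return amplitude / _biexp_peak_factor(rise_tau, decay_tau) * shape


def psc_kernel_integral(amplitude: float, rise_tau: float,
                        decay_tau: float) -> float:
    """Closed-form time integral of :func:`psc_kernel`, in amplitude x s."""
    a_prime = amplitude / _biexp_peak_factor(rise_tau, decay_tau)
    return a_prime * (decay_tau - rise_tau) / 1000.0


def _lognormal_amplitudes(rng, n, mean, cv):
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _event_train(times, amplitudes, rise_tau, decay_tau, n_samples,
                 sampling_rate):
    """Sum of unit-peak kernels scaled per event, on the sample grid."""
    out = np.zeros(n_samples)
    if len(times) == 0:
        return out
    impulses = np.zeros(n_samples)
    idx = np.minimum((np.asarray(times) * sampling_rate).astype(int),
                     n_samples - 1)
    np.add.at(impulses, idx, amplitudes)
    kern = psc_kernel(1.0, rise_tau, decay_tau, sampling_rate)
    full = sps.fftconvolve(impulses, kern)[:n_samples]
    out += full
    return out


# ---------------------------------------------------------------------------
# miniature PSC sweeps
# ---------------------------------------------------------------------------

def gen_mini_sweep(rate: float = 2.0, amp_mean: float = 25.0,
                   amp_cv: float = 0.25, rise_tau: float = 0.5,
                   decay_tau: float = 5.0, noise_rms: float = 1.5,
                   duration: float = 120.0, polarity: str = "inward",
                   seed: int = 0,
                   sampling_rate: float = DEFAULT_SAMPLING_RATE,
                   meta: Optional[dict] = None):
    """Simulate a miniature-PSC sweep: Poisson events in Gaussian noise.

    Event times are a homogeneous Poisson process at ``rate``; amplitudes
    are log-normal with the given mean (pA) and coefficient of variation.
    ``polarity='inward'`` yields downward (negative) events as for mEPSCs
    at negative holding potentials; ``'outward'`` upward ones (mIPSCs at
    +10 mV).  Returns ``(SweepRecording, MiniGroundTruth)``.
    """
    if rate < 0 or duration <= 0:
        raise ValueError("rate must be >= 0 and duration positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * sampling_rate))
    n_events = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n_events))
    amps = _lognormal_amplitudes(rng, n_events, amp_mean, amp_cv)
    clean = _event_train(times, amps, rise_tau, decay_tau, n_samples,
                         sampling_rate)
    noise = rng.normal(0.0, noise_rms, size=n_samples) if noise_rms > 0 \
        else np.zeros(n_samples)
    samples = clean + noise
    if polarity == "inward":
        samples = -samples
    meta = dict(meta or {})
    meta.setdefault("polarity", polarity)
    rec = SweepRecording(samples=samples, sampling_rate=sampling_rate,
                         holding_potential=-70.0 if polarity == "inward" else 10.0,
                         units="pA", meta=meta)
    truth = MiniGroundTruth(event_times=times, event_amplitudes=amps,
                            kernel_rise_tau=rise_tau, kernel_decay_tau=decay_tau,
                            noise_rms=noise_rms, true_rate=rate)
    return rec, truth


# ---------------------------------------------------------------------------
# evoked E/I input-output series
# ---------------------------------------------------------------------------

def gen_evoked_series(intensities: Sequence[float] = (10, 20, 30, 40, 50, 60, 70, 80),
                      e_max: float = 200.0, i_max: float = 400.0,
                      half_saturation: float = 30.0, hill_n: float = 3.0,
                      threshold_jitter: float = 0.15, noise_rms: float = 5.0,
                      seed: int = 0, second_peak_frac: float = 0.5,
                      second_peak_latency: float = 0.015,
                      rise_tau: float = 1.0, decay_tau: float = 5.0,
                      stim_onset: float = 0.05, sweep_duration: float = 0.3,
                      sampling_rate: float = DEFAULT_SAMPLING_RATE,
                      meta: Optional[dict] = None):
    """Simulate a paired-holding-potential input-output series.

    Excitatory and inhibitory peak amplitudes follow Hill curves sharing
    ``half_saturation`` and ``hill_n``, so the per-intensity E/I ratio is
    ``e_max / i_max`` wherever the multiplicative recruitment jitter
    (applied below ``half_saturation``) is absent.  Each intensity yields
    an :class:`~eiphys.evoked_ei.EvokedPair`: a -55 mV sweep with a
    downward (inward) excitatory response and a +10 mV sweep with an
    upward inhibitory one.  A later polysynaptic peak of relative size
    ``second_peak_frac`` exercises the first-peak rule.
    """
    from .evoked_ei import EvokedPair

    intensities = np.asarray(intensities, dtype=float)
    if intensities.size < 4 or np.any(np.diff(intensities) <= 0):
        raise ValueError("need >= 4 strictly increasing intensities")
    rng = np.random.default_rng(seed)
    hill = intensities ** hill_n / (intensities ** hill_n + half_saturation ** hill_n)
    e_peaks = e_max * hill
    i_peaks = i_max * hill
    sub = intensities < half_saturation
    if threshold_jitter > 0 and sub.any():
        e_peaks = e_peaks.copy()
        i_peaks = i_peaks.copy()
        e_peaks[sub] *= rng.lognormal(0.0, threshold_jitter, size=sub.sum())
        i_peaks[sub] *= rng.lognormal(0.0, threshold_jitter, size=sub.sum())
    stable_onset = int(np.argmax(intensities >= half_saturation))

    n_samples = int(round(sweep_duration * sampling_rate))
    onset_idx = int(round(stim_onset * sampling_rate))
    kern = psc_kernel(1.0, rise_tau, decay_tau, sampling_rate)
    pairs = []
    for k, s in enumerate(intensities):
        traces = {}
        for which, peak in (("e", e_peaks[k]), ("i", i_peaks[k])):
            tr = np.zeros(n_samples)
            lat = onset_idx + int(round(0.002 * sampling_rate))
            stop = min(n_samples, lat + kern.size)
            tr[lat:stop] += peak * kern[: stop - lat]
            if second_peak_frac > 0:
                lat2 = lat + int(round(second_peak_latency * sampling_rate))
                stop2 = min(n_samples, lat2 + kern.size)
                tr[lat2:stop2] += second_peak_frac * peak * kern[: stop2 - lat2]
            if noise_rms > 0:
                tr += rng.normal(0.0, noise_rms, size=n_samples)
            traces[which] = tr
        pairs.append(EvokedPair(
            intensity=float(s),
            excitatory_trace=SweepRecording(
                samples=-traces["e"], sampling_rate=sampling_rate,
                holding_potential=-55.0, units="pA",
                meta=dict(meta or {}, polarity="inward")),
            inhibitory_trace=SweepRecording(
                samples=traces["i"], sampling_rate=sampling_rate,
                holding_potential=10.0, units="pA",
                meta=dict(meta or {}, polarity="outward")),
            stim_onset=stim_onset,
        ))
    truth = EvokedGroundTruth(
        intensities=intensities, true_e_peak=e_peaks, true_i_peak=i_peaks,
        true_ratio=e_max / i_max, stable_onset_index=stable_onset)
    return pairs, truth


# ---------------------------------------------------------------------------
# spontaneous IPSC sweeps (charge analysis)
# ---------------------------------------------------------------------------

def gen_sipsc_sweep(rate: float = 12.0, amp_mean: float = 0.15,
                    amp_cv: float = 0.4, rise_tau: float = 1.0,
                    decay_tau: float = 15.0, noise_rms: float = 0.003,
                    drift_amplitude: float = 0.010, drift_period: float = 60.0,
                    duration: float = 200.0, seed: int = 0,
                    sampling_rate: float = DEFAULT_SAMPLING_RATE,
                    meta: Optional[dict] = None):
    """Simulate a spontaneous-IPSC record (nA scale, outward-positive).

    Poisson events ride on a slow sinusoidal baseline drift; the total
    event charge is available in closed form from the kernel integrals
    (``truth.total_charge``).  Duration must lie in the 3-4 min window the
    charge analysis quantifies.
    """
    if not 180.0 <= duration <= 240.0:
        raise ValueError("duration must lie in [180, 240] s")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * sampling_rate))
    n_events = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n_events))
    amps = _lognormal_amplitudes(rng, n_events, amp_mean, amp_cv)
    t = np.arange(n_samples) / sampling_rate
    drift = drift_amplitude * np.sin(2 * np.pi * t / drift_period)
    clean = _event_train(times, amps, rise_tau, decay_tau, n_samples,
                         sampling_rate)
    noise = rng.normal(0.0, noise_rms, size=n_samples) if noise_rms > 0 \
        else np.zeros(n_samples)
    meta = dict(meta or {})
    meta.setdefault("polarity", "outward")
    rec = SweepRecording(samples=clean + drift + noise,
                         sampling_rate=sampling_rate, holding_potential=10.0,
                         units="nA", meta=meta)
    truth = MiniGroundTruth(event_times=times, event_amplitudes=amps,
                            kernel_rise_tau=rise_tau,
                            kernel_decay_tau=decay_tau,
                            noise_rms=noise_rms, true_rate=rate)
    return rec, truth


# ---------------------------------------------------------------------------
# sleep polysomnography
# ---------------------------------------------------------------------------

DEFAULT_BAND_EDGES = {"delta": (0.5, 4.0), "theta": (5.0, 9.0),
                      "gamma": (30.0, 80.0)}


def default_sleep_truth() -> SleepGroundTruth:
    """Nocturnal-rodent defaults: more sleep in the light phase, NREM
    dominated by delta, REM by theta with muscle atonia."""
    light = np.array([[0.92, 0.08, 0.00],
                      [0.04, 0.93, 0.03],
                      [0.06, 0.04, 0.90]])
    dark = np.array([[0.97, 0.03, 0.00],
                     [0.08, 0.90, 0.02],
                     [0.10, 0.02, 0.88]])
    band_weights = {
        "WAKE": {"delta": 1.0, "theta": 1.5, "gamma": 1.0},
        "NREM": {"delta": 8.0, "theta": 1.0, "gamma": 0.4},
        "REM": {"delta": 0.7, "theta": 6.0, "gamma": 0.8},
    }
    emg_rms = {"WAKE": 30.0, "NREM": 8.0, "REM": 3.0}
    return SleepGroundTruth(transition_matrices={"light": light, "dark": dark},
                            band_weights=band_weights, emg_rms=emg_rms)


def markov_stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix."""
    P = np.asarray(P, dtype=float)
    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    return pi / pi.sum()


def markov_occupancy_se(P: np.ndarray, n: int) -> np.ndarray:
    """Asymptotic standard error of state-occupancy fractions over ``n``
    steps of the chain, from the fundamental matrix
    ``Z = (I - P + 1 pi')^{-1}``: ``var_i = pi_i (2 Z_ii - 1 - pi_i) / n``."""
    P = np.asarray(P, dtype=float)
    pi = markov_stationary(P)
    Z = np.linalg.inv(np.eye(3) - P + np.outer(np.ones(3), pi))
    var = pi * (2 * np.diag(Z) - 1.0 - pi)
    return np.sqrt(np.maximum(var, 0.0) / n)


def _simulate_states(truth: SleepGroundTruth, n_epochs: int,
                     start_zt: float, epochs_per_day: int, rng) -> list:
    seq = []
    state = 0  # start awake
    for k in range(n_epochs):
        zt = (start_zt + k * 24.0 / epochs_per_day) % 24.0
        phase = "light" if zt < 12.0 else "dark"
        P = truth.transition_matrices[phase]
        seq.append(STATES[state])
        state = rng.choice(3, p=P[state])
    return seq


def _band_noise(rng, n, lo, hi, fs):
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    x = rng.normal(size=n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / max(np.sqrt(np.mean(y ** 2)), 1e-12)


def gen_polysomnography(truth: Optional[SleepGroundTruth] = None,
                        n_days: int = 1, seed: int = 0,
                        sampling_rate: float = 500.0,
                        epochs_per_day: int = 21_600,
                        start_zeitgeber_time: float = 0.0,
                        band_edges: Optional[dict] = None,
                        animal_id: str = "", genotype: str = ""):
    """Simulate an EEG/EMG record plus its ground-truth hypnogram.

    The per-epoch state follows the phase-appropriate Markov chain (light
    phase = ZT 0-12).  EEG is a sum of band-limited noise components whose
    per-state power weights come from ``truth.band_weights``; EMG is white
    noise at the per-state RMS.  ``epochs_per_day`` scales the day length
    (21600 x 4 s = 24 h at full scale; tests use shorter days).
    """
    truth = truth or default_sleep_truth()
    band_edges = band_edges or DEFAULT_BAND_EDGES
    rng = np.random.default_rng(seed)
    n_epochs = n_days * epochs_per_day
    if truth.state_sequence is not None:
        seq = list(truth.state_sequence)
        n_epochs = len(seq)
    else:
        seq = _simulate_states(truth, n_epochs, start_zeitgeber_time,
                               epochs_per_day, rng)
    spe = int(round(EPOCH_LENGTH_S * sampling_rate))  # samples per epoch
    n = n_epochs * spe
    bands = {name: _band_noise(rng, n, lo, hi, sampling_rate)
             for name, (lo, hi) in band_edges.items()}
    # per-sample amplitude weights from per-epoch state
    state_idx = np.array([STATES.index(s) for s in seq])
    eeg = np.zeros(n)
    total_w = {st: sum(truth.band_weights[st].values()) for st in STATES}
    for name, comp in bands.items():
        w = np.array([truth.band_weights[st].get(name, 0.0) / total_w[st]
                      for st in STATES])
        amp = np.sqrt(w)[state_idx]  # power weight -> amplitude
        eeg += np.repeat(amp, spe) * comp
    eeg *= truth.eeg_scale
    emg_lvl = np.array([truth.emg_rms[st] for st in STATES])[state_idx]
    emg = np.repeat(emg_lvl, spe) * rng.normal(size=n)
    psg = PolysomnographyRecording(
        eeg=eeg, emg=emg, sampling_rate=sampling_rate,
        start_zeitgeber_time=start_zeitgeber_time, n_days=n_days,
        animal_id=animal_id, genotype=genotype)
    hyp = Hypnogram(labels=seq, epoch_length=EPOCH_LENGTH_S,
                    start_zeitgeber_time=start_zeitgeber_time)
    return psg, hyp


# ---------------------------------------------------------------------------
# intrinsic-signal imaging stacks
# ---------------------------------------------------------------------------

def make_imaging_truth(shape=(32, 32), contra_peak: float = 1.0,
                       ipsi_peak: float = 0.5, noise_sd: float = 0.05,
                       profile_sigma_frac: float = 0.5) -> ImagingGroundTruth:
    """Ground truth for an imaged patch: both eyes drive the same smooth
    Gaussian spatial profile, scaled by eye-specific peak amplitudes, so
    the pixelwise ocular-dominance value is constant across the patch."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (yy - (h - 1) / 2) ** 2 + (xx - (w - 1) / 2) ** 2
    sigma = profile_sigma_frac * max(h, w)
    profile = np.exp(-r2 / (2 * sigma ** 2))
    phase = np.pi * xx / max(w - 1, 1)  # retinotopy surrogate: azimuth sweep
    return ImagingGroundTruth(contra_amp=contra_peak * profile,
                              ipsi_amp=ipsi_peak * profile,
                              phase_map=phase, noise_sd=noise_sd)


def gen_imaging_stack(truth: ImagingGroundTruth, f_stim: float = 0.125,
                      frame_rate: float = 10.0, n_cycles: int = 10,
                      seed: int = 0, stimulus_extent: str = "binocular_field",
                      direction: str = "up"):
    """Simulate contra- and ipsi-eye periodic-stimulus stacks.

    Each pixel's time series is ``amp * cos(2 pi f_stim t + phase)`` plus
    Gaussian noise.  Returns ``(contra_stack, ipsi_stack)``.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(n_cycles * frame_rate / f_stim))
    t = np.arange(n_frames) / frame_rate
    stacks = []
    for amp in (truth.contra_amp, truth.ipsi_amp):
        carrier = np.cos(2 * np.pi * f_stim * t[None, None, :]
                         + truth.phase_map[:, :, None])
        frames = amp[:, :, None] * carrier
        if truth.noise_sd > 0:
            frames = frames + rng.normal(0.0, truth.noise_sd, size=frames.shape)
        stacks.append(frames)
    contra = ImageStack(frames=stacks[0], frame_rate=frame_rate,
                        stimulus_frequency=f_stim, eye="contra",
                        stimulus_extent=stimulus_extent, direction=direction)
    ipsi = ImageStack(frames=stacks[1], frame_rate=frame_rate,
                      stimulus_frequency=f_stim, eye="ipsi",
                      stimulus_extent=stimulus_extent, direction=direction)
    return contra, ipsi
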