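"""Sleep architecture and state-conditioned EEG spectra.

Hypnograms carry WAKE/NREM/REM labels in 4-s epochs.  Architecture
reports percent time per state per time bin (1 h or 12 h), bout counts
and durations (a bout is a maximal run of identical labels, minimum one
epoch), and transition counts.  Per-mouse summaries are averaged over the
recording days before any statistics.

Spectra are computed per state from 2-s Hann windows (0.5 Hz resolution,
two windows per 4-s epoch, never crossing an epoch boundary, since the
epochs of one state need not be contiguous), averaged within state and
normalized so total power over 0.5-80 Hz equals 1.  Band boundaries
default to conventional rodent values bounded by the 80 Hz normalization
ceiling: delta 0.5-4 Hz, theta 5-9 Hz, gamma 30-80 Hz.

A rule-based scorer stands in for manual scoring on synthetic data:
high-EMG epochs are WAKE; among low-EMG epochs, a theta/delta power ratio
above threshold marks REM, the rest NREM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import EPOCH_LENGTH_S, Hypnogram, PolysomnographyRecording, STATES

DEFAULT_BANDS = {"delta": (0.5, 4.0), "theta": (5.0, 9.0),
                 "gamma": (30.0, 80.0)}
SPECTRUM_RANGE = (0.5, 80.0)
WINDOW_S = 2.0  # analysis window; 0.5 Hz resolution


@dataclass
class ArchitectureSummary:
    percent_time: pd.DataFrame  # rows = time bins, columns = states, %
    bout_count: Dict[str, float]
    mean_bout_duration: Dict[str, float]  # s
    transition_count: Dict[Tuple[str, str], float]
    bin_hours: float
    days_averaged: int = 1


@dataclass
class SpectralProfile:
    frequencies: np.ndarray  # 0.5 .. 80 Hz, 0.5 Hz grid
    relative_power: Dict[str, Optional[np.ndarray]]  # None = state absent
    epochs_used: Dict[str, int]


# ---------------------------------------------------------------------------
# per-epoch features and rule-based scoring
# ---------------------------------------------------------------------------

def _epoch_windows(x: np.ndarray, fs: float, n_epochs: int) -> np.ndarray:
    """Reshape a signal into (n_epochs, windows_per_epoch, window_samples)."""
    wlen = int(round(WINDOW_S * fs))
    spe = int(round(EPOCH_LENGTH_S * fs))
    per = spe // wlen
    return x[: n_epochs * spe].reshape(n_epochs, per, wlen)


def epoch_band_powers(psg: PolysomnographyRecording,
                      bands: Optional[dict] = None,
                      chunk: int = 2000) -> pd.DataFrame:
    """Per-epoch EEG band power (uV^2) and EMG RMS (uV)."""
    bands = bands or DEFAULT_BANDS
    fs = psg.sampling_rate
    n_epochs = psg.n_epochs
    wlen = int(round(WINDOW_S * fs))
    freqs = np.fft.rfftfreq(wlen, d=1.0 / fs)
    win = sps.get_window("hann", wlen)
    scale = 1.0 / (fs * (win ** 2).sum())  # Welch density scaling
    cols = {name: np.empty(n_epochs) for name in bands}
    emg_rms = np.empty(n_epochs)
    spe = int(round(EPOCH_LENGTH_S * fs))
    for lo in range(0, n_epochs, chunk):
        hi = min(lo + chunk, n_epochs)
        w = _epoch_windows(psg.eeg[lo * spe:hi * spe], fs, hi - lo)
        spec = np.abs(np.fft.rfft(w * win, axis=-1)) ** 2 * scale
        spec[..., 1:-1] *= 2.0  # one-sided density
        mean_spec = spec.mean(axis=1)  # average the epoch's windows
        for name, (b_lo, b_hi) in bands.items():
            sel = (freqs >= b_lo) & (freqs <= b_hi)
            cols[name][lo:hi] = mean_spec[:, sel].sum(axis=1) * (freqs[1] - freqs[0])
        e = psg.emg[lo * spe:hi * spe].reshape(hi - lo, spe)
        emg_rms[lo:hi] = np.sqrt(np.mean(e ** 2, axis=1))
    out = pd.DataFrame(cols)
    out["emg_rms"] = emg_rms
    return out


def score_rule_based(psg: PolysomnographyRecording,
                     emg_threshold: float = 15.0,
                     theta_delta_threshold: float = 1.0,
                     bands: Optional[dict] = None) -> Hypnogram:
    """Rule-based arousal-state scoring of a PSG record.

    WAKE when epoch EMG RMS exceeds ``emg_threshold`` (uV); otherwise REM
    when the theta/delta power ratio exceeds ``theta_delta_threshold``,
    else NREM.
    """
    if psg.n_epochs < 1:
        raise ValueError("need at least one full 4-s epoch")
    feats = epoch_band_powers(psg, bands=bands)
    labels = np.where(
        feats["emg_rms"] > emg_threshold, "WAKE",
        np.where(feats["theta"] / feats["delta"].clip(lower=1e-12)
                 > theta_delta_threshold, "REM", "NREM"))
    return Hypnogram(labels=list(labels),
                     start_zeitgeber_time=psg.start_zeitgeber_time)


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def architecture(hyp: Hypnogram, bin_hours: float = 1.0,
                 allow_partial: bool = False) -> ArchitectureSummary:
    """Percent time, bouts and transitions from a hypnogram."""
    labels = np.asarray(hyp.labels)
    epochs_per_bin = bin_hours * 3600.0 / hyp.epoch_length
    if abs(epochs_per_bin - round(epochs_per_bin)) > 1e-9:
        raise ValueError("bin size must be a whole number of epochs")
    epochs_per_bin = int(round(epochs_per_bin))
    n_bins = len(labels) / epochs_per_bin
    if abs(n_bins - round(n_bins)) > 1e-9 and not allow_partial:
        raise ValueError("hypnogram does not span a whole number of bins "
                         "(allow_partial to override)")
    n_bins = math.ceil(n_bins)
    rows = []
    for b in range(n_bins):
        chunk = labels[b * epochs_per_bin:(b + 1) * epochs_per_bin]
        rows.append({s: 100.0 * np.mean(chunk == s) for s in STATES})
    percent = pd.DataFrame(rows, columns=list(STATES))
    percent.index.name = "bin"

    bout_count = {s: 0 for s in STATES}
    bout_epochs = {s: [] for s in STATES}
    transitions: Dict[Tuple[str, str], float] = {}
    run_state, run_len = labels[0], 0
    for lab in labels:
        if lab == run_state:
            run_len += 1
        else:
            bout_count[run_state] += 1
            bout_epochs[run_state].append(run_len)
            key = (run_state, lab)
            transitions[key] = transitions.get(key, 0) + 1
            run_state, run_len = lab, 1
    bout_count[run_state] += 1
    bout_epochs[run_state].append(run_len)
    mean_dur = {s: (float(np.mean(v)) * hyp.epoch_length if v else 0.0)
                for s, v in bout_epochs.items()}
    return ArchitectureSummary(percent_time=percent, bout_count=bout_count,
                               mean_bout_duration=mean_dur,
                               transition_count=transitions,
                               bin_hours=bin_hours)


def average_days(summaries: Sequence[ArchitectureSummary],
                 n_days: int = 3) -> ArchitectureSummary:
    """Arithmetic mean of per-day summaries (the per-mouse value used for
    statistics is the 3-day average)."""
    if len(summaries) != n_days:
        raise ValueError(f"expected {n_days} per-day summaries, "
                         f"got {len(summaries)}")
    shapes = {s.percent_time.shape for s in summaries}
    bins = {s.bin_hours for s in summaries}
    if len(shapes) > 1 or len(bins) > 1:
        raise ValueError("mismatched bin structure across days")
    percent = sum(s.percent_time for s in summaries) / n_days
    keys = set().union(*(s.transition_count for s in summaries))
    return ArchitectureSummary(
        percent_time=percent,
        bout_count={st: float(np.mean([s.bout_count[st] for s in summaries]))
                    for st in STATES},
        mean_bout_duration={st: float(np.mean([s.mean_bout_duration[st]
                                               for s in summaries]))
                            for st in STATES},
        transition_count={k: float(np.mean([s.transition_count.get(k, 0)
                                            for s in summaries]))
                          for k in keys},
        bin_hours=summaries[0].bin_hours, days_averaged=n_days)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def state_spectra(psg: PolysomnographyRecording,
                  hyp: Hypnogram) -> SpectralProfile:
    """Per-state normalized EEG power density on the 0.5-80 Hz grid.

    Welch periodograms over 2-s Hann windows restricted to the epochs of
    each state, averaged, then normalized so the 0.5-80 Hz sum is 1.  A
    state with no epochs yields ``None`` (absent), not zeros.
    """
    if psg.sampling_rate < 160:
        raise ValueError("sampling rate must be >= 160 Hz")
    fs = psg.sampling_rate
    n_epochs = min(psg.n_epochs, len(hyp))
    wlen = int(round(WINDOW_S * fs))
    freqs = np.fft.rfftfreq(wlen, d=1.0 / fs)
    sel = (freqs >= SPECTRUM_RANGE[0]) & (freqs <= SPECTRUM_RANGE[1])
    win = sps.get_window("hann", wlen)
    scale = 1.0 / (fs * (win ** 2).sum())
    labels = np.asarray(hyp.labels[:n_epochs])
    w = _epoch_windows(psg.eeg, fs, n_epochs)
    power: Dict[str, Optional[np.ndarray]] = {}
    used: Dict[str, int] = {}
    for st in STATES:
        mask = labels == st
        used[st] = int(mask.sum())
        if not mask.any():
            power[st] = None
            continue
        spec = np.abs(np.fft.rfft(w[mask] * win, axis=-1)) ** 2 * scale
        spec[..., 1:-1] *= 2.0
        mean_spec = spec.mean(axis=(0, 1))[sel]
        power[st] = mean_spec / mean_spec.sum()
    return SpectralProfile(frequencies=freqs[sel], relative_power=power,
                           epochs_used=used)


def band_power(profile: SpectralProfile, band) -> Dict[str, Optional[float]]:
    """Fraction of normalized power in a band, per state.

    ``band`` is a name from :data:`DEFAULT_BANDS` or an explicit
    ``(lo, hi)`` in Hz; bins whose centers satisfy ``lo <= f <= hi``
    contribute (bands are conventionally chosen disjoint).
    """
    lo, hi = DEFAULT_BANDS[band] if isinstance(band, str) else band
    sel = (profile.frequencies >= lo) & (profile.frequencies <= hi)
    if not sel.any():
        raise ValueError(f"empty band ({lo}, {hi})")
    return {st: (float(p[sel].sum()) if p is not None else None)
            for st, p in profile.relative_power.items()}
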