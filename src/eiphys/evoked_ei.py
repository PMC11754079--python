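"""Per-cell evoked E/I ratio from paired-holding-potential responses.

At each stimulation intensity the excitatory peak is measured at -55 mV
(inward, downward) and the inhibitory peak at +10 mV (outward, upward); the
per-intensity ratio is E/I.  Two rules guard the measurement:

* first-peak rule: when the response has multiple peaks, only the first
  (monosynaptic) peak counts, and the cell's intensity is discarded when
  that first peak is not clearly separated from a later, larger one —
  operationalized as a trough dipping by at least 20% of the first peak;
* stable-range rule: the cell's scalar E/I is the mean ratio over the
  longest contiguous run of at least ``min_run`` intensities whose ratios
  have a coefficient of variation at most ``cv_limit`` (defaults 3 and
  0.2), the deterministic surrogate for the saturation plateau over which
  the ratio is read out.

Cells are pooled by light phase via the explicit mapping dark = {ZT0,
ZT18}, light = {ZT6, ZT12}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .containers import SweepRecording

PHASE_OF_ZT = {0.0: "dark", 18.0: "dark", 6.0: "light", 12.0: "light"}


@dataclass
class EvokedPair:
    """Excitatory/inhibitory sweep pair at one stimulation intensity."""

    intensity: float
    excitatory_trace: SweepRecording  # -55 mV holding, inward response
    inhibitory_trace: SweepRecording  # +10 mV holding, outward response
    stim_onset: float  # s

    def __post_init__(self) -> None:
        if self.excitatory_trace.sampling_rate != self.inhibitory_trace.sampling_rate:
            raise ValueError("paired traces must share a sampling rate")


@dataclass
class EICurve:
    intensities: np.ndarray
    e_peaks: np.ndarray
    i_peaks: np.ndarray
    ratios: np.ndarray  # nan where discarded
    valid: np.ndarray  # bool per intensity
    discard_flags: Dict[int, str] = field(default_factory=dict)
    stable_mask: Optional[np.ndarray] = None


@dataclass
class CellEIRatio:
    value: float
    n_intensities_used: int
    zeitgeber_time: Optional[float] = None
    phase: Optional[str] = None
    circuit: str = "L2/3->2/3"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("E/I ratio must be positive")
        if self.n_intensities_used < 3:
            raise ValueError("cell E/I requires >= 3 stable intensities")


# ---------------------------------------------------------------------------
# peak measurement
# ---------------------------------------------------------------------------

def measure_first_peak(trace: SweepRecording, stim_onset: float,
                       polarity: str, window_ms: float = 50.0,
                       blank_ms: float = 0.5,
                       trough_fraction: float = 0.2,
                       baseline_ms: float = 20.0) -> Tuple[float, bool]:
    """Baseline-to-first-peak amplitude within the post-stimulus window.

    Returns ``(amplitude, resolved)``.  ``resolved`` is False when a
    later, larger peak follows the first without an intervening trough of
    at least ``trough_fraction`` of the first peak's amplitude — the
    surrogate for "first peak not clearly resolved", after which the
    intensity (and downstream, the cell) is discarded.  The first
    ``blank_ms`` after the stimulus is blanked to skip the artifact.
    """
    from scipy import ndimage

    fs = trace.sampling_rate
    y = -trace.samples if polarity == "inward" else trace.samples
    # 1 ms boxcar: suppresses noise maxima that would pose as an early
    # first peak and shrinks the max-of-noise bias at the measured peak;
    # the slight peak attenuation is common to both holding potentials
    # (shared kinetics) and cancels in the E/I ratio
    y = ndimage.uniform_filter1d(y, size=max(1, int(round(1.0e-3 * fs))),
                                 mode="nearest")
    i0 = int(round(stim_onset * fs))
    start = i0 + max(1, int(round(blank_ms / 1000.0 * fs)))
    stop = min(y.size, i0 + int(round(window_ms / 1000.0 * fs)))
    if stop - start < 3:
        raise ValueError("analysis window too short")
    base = float(np.median(y[max(0, i0 - int(baseline_ms / 1000.0 * fs)):i0])) \
        if i0 > 0 else 0.0
    d = y[start:stop] - base
    if d.max() <= 0:
        return 0.0, True
    # noise scale from the pre-stimulus segment (robust MAD estimate)
    pre = y[max(0, i0 - int(baseline_ms / 1000.0 * fs)):i0] - base
    noise = 1.4826 * float(np.median(np.abs(pre))) if pre.size else 0.0
    floor = max(4.0 * noise, 0.03 * d.max(), 1e-12)
    height = max(3.0 * noise, 0.10 * d.max(), 1e-12)
    peaks, props = sps.find_peaks(d, prominence=floor, height=height)
    if peaks.size == 0:
        return float(d.max()), True
    first = int(peaks[0])
    amp = float(d[first])
    resolved = True
    for later in peaks[1:]:
        if d[later] > amp:
            trough = float(np.min(d[first:later + 1]))
            if trough > (1.0 - trough_fraction) * amp:
                resolved = False
            break
    return amp, resolved


# ---------------------------------------------------------------------------
# ratio curve and stable range
# ---------------------------------------------------------------------------

def _prestim_noise(trace: SweepRecording, stim_onset: float,
                   baseline_ms: float = 20.0) -> float:
    fs = trace.sampling_rate
    i0 = int(round(stim_onset * fs))
    pre = trace.samples[max(0, i0 - int(baseline_ms / 1000.0 * fs)):i0]
    if pre.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(pre - np.median(pre))))


def compute_ratio_curve(pairs: Sequence[EvokedPair], window_ms: float = 50.0,
                        blank_ms: float = 0.5,
                        trough_fraction: float = 0.2,
                        noise_floor_mult: float = 4.0) -> EICurve:
    """Per-intensity E/I ratios with discard codes.

    An intensity is discarded when either peak's first peak is unresolved
    (``unresolved_first_peak``) or when a measured peak does not clear
    the trace's own pre-stimulus noise floor (``no_excitatory_response``
    / ``no_inhibitory_response``) — sub-threshold stimulation produces no
    interpretable ratio.
    """
    if len(pairs) < 4:
        raise ValueError("need >= 4 intensities")
    pairs = sorted(pairs, key=lambda p: p.intensity)
    n = len(pairs)
    e = np.zeros(n)
    i = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    flags: Dict[int, str] = {}
    for k, pair in enumerate(pairs):
        e[k], e_ok = measure_first_peak(pair.excitatory_trace, pair.stim_onset,
                                        "inward", window_ms, blank_ms,
                                        trough_fraction)
        i[k], i_ok = measure_first_peak(pair.inhibitory_trace, pair.stim_onset,
                                        "outward", window_ms, blank_ms,
                                        trough_fraction)
        e_floor = noise_floor_mult * _prestim_noise(pair.excitatory_trace,
                                                    pair.stim_onset)
        i_floor = noise_floor_mult * _prestim_noise(pair.inhibitory_trace,
                                                    pair.stim_onset)
        if not (e_ok and i_ok):
            valid[k] = False
            flags[k] = "unresolved_first_peak"
        elif i[k] <= i_floor:
            valid[k] = False
            flags[k] = "no_inhibitory_response"
        elif e[k] <= e_floor:
            valid[k] = False
            flags[k] = "no_excitatory_response"
    if not valid.any():
        raise ValueError("all intensities discarded")
    ratios = np.full(n, np.nan)
    ratios[valid] = e[valid] / i[valid]
    return EICurve(intensities=np.array([p.intensity for p in pairs]),
                   e_peaks=e, i_peaks=i, ratios=ratios, valid=valid,
                   discard_flags=flags)


def find_stable_range(curve: EICurve, cv_limit: float = 0.2,
                      min_run: int = 3) -> np.ndarray:
    """Longest contiguous run of valid intensities with ratio CV <= limit.

    All contiguous windows of valid intensities are searched exhaustively;
    among qualifying windows the longest wins, ties going to the highest
    intensities.  Raises when no window of length >= ``min_run``
    qualifies.
    """
    n = curve.intensities.size
    best = None  # (length, end, start)
    for start in range(n):
        for end in range(start + min_run, n + 1):
            if not curve.valid[start:end].all():
                continue
            r = curve.ratios[start:end]
            mean = r.mean()
            cv = r.std(ddof=1) / mean if mean > 0 else np.inf
            if cv <= cv_limit:
                key = (end - start, end, start)
                if best is None or key > best:
                    best = key
    if best is None:
        raise ValueError("no stable range")
    mask = np.zeros(n, dtype=bool)
    mask[best[2]:best[2] + best[0]] = True
    curve.stable_mask = mask
    return mask


def cell_ei_ratio(curve: EICurve, cv_limit: float = 0.2, min_run: int = 3,
                  zeitgeber_time: Optional[float] = None,
                  circuit: str = "L2/3->2/3") -> CellEIRatio:
    """Scalar cell E/I: mean ratio over the stable intensity range."""
    mask = curve.stable_mask
    if mask is None:
        mask = find_stable_range(curve, cv_limit=cv_limit, min_run=min_run)
    value = float(np.mean(curve.ratios[mask]))
    phase = PHASE_OF_ZT.get(zeitgeber_time) if zeitgeber_time is not None else None
    return CellEIRatio(value=value, n_intensities_used=int(mask.sum()),
                       zeitgeber_time=zeitgeber_time, phase=phase,
                       circuit=circuit)


def pool_phase(cells: Sequence[CellEIRatio]) -> Dict[str, List[CellEIRatio]]:
    """Pool cells into dark (ZT0, 18) and light (ZT6, 12) phase groups.

    Only the four sampled time points are mapped; any other zeitgeber
    time is an error rather than being silently assigned a phase.
    """
    groups: Dict[str, List[CellEIRatio]] = {"dark": [], "light": []}
    for c in cells:
        if c.zeitgeber_time is None or float(c.zeitgeber_time) not in PHASE_OF_ZT:
            raise ValueError(f"unmapped zeitgeber time: {c.zeitgeber_time!r} "
                             "(explicit mapping covers ZT 0, 6, 12, 18 only)")
        groups[PHASE_OF_ZT[float(c.zeitgeber_time)]].append(c)
    return groups
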