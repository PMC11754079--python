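"""In-memory containers for the recording modalities the pipeline analyzes.

Every container validates its own invariants at construction time so that
downstream quantification code can assume well-formed input.  Metadata is
carried verbatim and never mutated by analysis code; in particular the
polarity convention of a voltage-clamp trace is always declared metadata,
never inferred from the samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

STATES = ("WAKE", "NREM", "REM")

EPOCH_LENGTH_S = 4.0


@dataclass
class SweepRecording:
    """One voltage-clamp current sweep.

    Parameters
    ----------
    samples
        Current trace.  Units are pA for mini/evoked sweeps; nA is the
        conventional scale for spontaneous-IPSC records (declared in
        ``units``).
    sampling_rate
        Hz.  Acquisition in the emulated experiments is 10 kHz with a
        2 kHz low-pass filter.
    holding_potential
        Command potential in mV (-55 mV isolates excitatory currents,
        +10 mV inhibitory currents, no junction-potential compensation).
    meta
        Free-form metadata: ``cell_id``, ``animal_id``, ``genotype``,
        ``zeitgeber_time`` (h in [0, 24)), ``circuit`` (``L2/3->2/3`` or
        ``L4->2/3``), ``drug`` (vehicle/WIN/SR/none), ``polarity``
        (``inward`` events are negative, ``outward`` positive).
    """

    samples: np.ndarray
    sampling_rate: float
    holding_potential: float = 0.0
    units: str = "pA"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            name = self.meta.get("cell_id", "<unnamed sweep>")
            raise ValueError(f"non-finite samples in sweep {name!r}")
        zt = self.meta.get("zeitgeber_time")
        if zt is not None and not (0 <= float(zt) < 24):
            raise ValueError("zeitgeber_time must lie in [0, 24)")

    @property
    def duration(self) -> float:
        """Sweep duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "SweepRecording":
        """Copy of this sweep with different samples, metadata preserved."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class PolysomnographyRecording:
    """Paired EEG/EMG record for sleep scoring and spectral analysis."""

    eeg: np.ndarray  # microvolts
    emg: np.ndarray  # microvolts
    sampling_rate: float  # Hz, nominally 500
    start_zeitgeber_time: float = 0.0
    n_days: int = 1
    animal_id: str = ""
    genotype: str = ""
    exclude_spectral: bool = False

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape:
            raise ValueError("eeg and emg must have equal length")
        if self.sampling_rate <= 160:
            # 80 Hz is the upper bound of the normalized spectrum; the
            # sampling rate must keep it below Nyquist.
            raise ValueError("sampling_rate must exceed 160 Hz (2 x 80 Hz)")

    @property
    def duration(self) -> float:
        return self.eeg.size / self.sampling_rate

    @property
    def n_epochs(self) -> int:
        return int(self.eeg.size // (EPOCH_LENGTH_S * self.sampling_rate))


@dataclass
class Hypnogram:
    """Per-epoch arousal-state labels (WAKE / NREM / REM), 4-s epochs."""

    labels: Sequence[str]
    epoch_length: float = EPOCH_LENGTH_S
    start_zeitgeber_time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if not self.labels:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = sorted({l for l in self.labels} - set(STATES))
        if bad:
            raise ValueError(f"unknown state label(s): {bad}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypnogram):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.epoch_length == other.epoch_length
            and self.start_zeitgeber_time == other.start_zeitgeber_time
        )


@dataclass
class ImageStack:
    """Periodic-stimulus intrinsic-signal image stack (H x W x T)."""

    frames: np.ndarray
    frame_rate: float  # Hz
    stimulus_frequency: float  # Hz
    eye: str = "contra"  # {contra, ipsi}
    stimulus_extent: str = "full_field"  # {full_field, binocular_field}
    direction: str = "up"  # {up, down}

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be an H x W x T array")
        if self.frame_rate <= 2 * self.stimulus_frequency:
            raise ValueError(
                "undersampled: frame_rate must exceed twice the stimulus frequency"
            )
        n_cycles = self.frames.shape[2] / self.frame_rate * self.stimulus_frequency
        if n_cycles < 2:
            raise ValueError("stack must span at least 2 full stimulus cycles")

    @property
    def shape(self) -> tuple:
        return self.frames.shape
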