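"""Readers and writers for the on-disk formats the pipeline touches.

Formats
-------
* Sweep container: HDF5 with layout ``/sweeps/<id>/samples`` plus an
  attribute set per sweep (``sampling_rate``, ``holding_potential``,
  ``units``, and all metadata keys).  CSV is accepted for single sweeps:
  ``#``-prefixed ``key=value`` header lines followed by one ``current``
  column.
* Polysomnography: EDF (16-bit).  Reading goes through :mod:`mne`;
  writing uses a minimal EDF writer (one data record per second,
  physical units microvolts).
* Hypnograms: two-column TSV ``epoch_index<TAB>label`` with 0-based,
  contiguous indices.
* Image stacks: multi-page TIFF with a JSON metadata sidecar
  (``<stack>.json``) declaring frame rate, stimulus frequency, eye,
  stimulus extent and direction.

All writer/reader pairs round-trip losslessly up to documented
quantization (EDF is 16-bit).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, List, Sequence

import h5py
import numpy as np
import tifffile

from .containers import (
    Hypnogram,
    ImageStack,
    PolysomnographyRecording,
    STATES,
    SweepRecording,
)

_SWEEP_ATTRS = ("sampling_rate", "holding_potential", "units")


# ---------------------------------------------------------------------------
# sweep container (HDF5 / CSV)
# ---------------------------------------------------------------------------

def write_sweeps(recs: Iterable[SweepRecording], path) -> None:
    """Write sweeps to the native HDF5 container.

    Layout: ``/sweeps/<index>/samples`` with per-group attributes.  An
    empty collection produces a valid empty container.  Mixed sampling
    rates are permitted and preserved per sweep.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        grp = f.create_group("sweeps")
        for i, rec in enumerate(recs):
            g = grp.create_group(f"{i:06d}")
            g.create_dataset("samples", data=rec.samples)
            g.attrs["sampling_rate"] = rec.sampling_rate
            g.attrs["holding_potential"] = rec.holding_potential
            g.attrs["units"] = rec.units
            for k, v in rec.meta.items():
                g.attrs[f"meta:{k}"] = v


def read_sweeps(path) -> List[SweepRecording]:
    """Read sweeps from the HDF5 container (or a single-sweep CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return [read_sweep_csv(path)]
    recs = []
    with h5py.File(path, "r") as f:
        if "sweeps" not in f:
            raise ValueError(f"{path}: not a sweep container (no /sweeps group)")
        for key in sorted(f["sweeps"]):
            g = f["sweeps"][key]
            if "sampling_rate" not in g.attrs:
                raise ValueError(f"{path}:/sweeps/{key}: sampling rate undeclared")
            meta = {
                k[len("meta:"):]: _from_h5(v)
                for k, v in g.attrs.items()
                if k.startswith("meta:")
            }
            recs.append(
                SweepRecording(
                    samples=g["samples"][()],
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    holding_potential=float(g.attrs.get("holding_potential", 0.0)),
                    units=str(g.attrs.get("units", "pA")),
                    meta=meta,
                )
            )
    return recs


def _from_h5(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v


def write_sweep_csv(rec: SweepRecording, path) -> None:
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# sampling_rate={rec.sampling_rate}\n")
        f.write(f"# holding_potential={rec.holding_potential}\n")
        f.write(f"# units={rec.units}\n")
        for k, v in rec.meta.items():
            f.write(f"# meta:{k}={v}\n")
        f.write("current\n")
        np.savetxt(f, rec.samples, fmt="%.9g")


def read_sweep_csv(path) -> SweepRecording:
    path = Path(path)
    header: dict = {}
    data_start = 0
    with open(path) as f:
        for line in f:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val.strip()
                data_start += 1
            else:
                break
    if "sampling_rate" not in header:
        raise ValueError(f"{path}: sampling rate undeclared")
    samples = np.loadtxt(path, skiprows=data_start + 1, ndmin=1)
    meta = {
        k[len("meta:"):]: _parse_scalar(v)
        for k, v in header.items()
        if k.startswith("meta:")
    }
    return SweepRecording(
        samples=samples,
        sampling_rate=float(header["sampling_rate"]),
        holding_potential=float(header.get("holding_potential", 0.0)),
        units=header.get("units", "pA"),
        meta=meta,
    )


def _parse_scalar(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    return s


# ---------------------------------------------------------------------------
# polysomnography (EDF)
# ---------------------------------------------------------------------------

def write_polysomnography(psg: PolysomnographyRecording, path) -> None:
    """Write a 2-channel (EEG, EMG) 16-bit EDF file.

    One data record per second; the record length therefore requires an
    integer sampling rate and a whole number of seconds of data (the
    trailing partial second is dropped, as acquisition systems do).
    """
    path = Path(path)
    fs = int(round(psg.sampling_rate))
    n_records = int(psg.eeg.size // fs)
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    channels = [("EEG", psg.eeg), ("EMG", psg.emg)]
    # physical range symmetric around 0, padded so the signal never clips
    phys = [max(1.0, 1.05 * np.max(np.abs(sig[: n_records * fs]), initial=0.0))
            for _, sig in channels]

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join([
        pad("0", 8),
        pad(f"subject {psg.animal_id or 'unknown'}", 80),
        pad(f"recording genotype={psg.genotype or 'unknown'} "
            f"startZT={psg.start_zeitgeber_time}", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + len(channels))), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),  # record duration, seconds
        pad(str(len(channels)), 4),
    ])
    fields = [
        ("".join, [pad(lab, 16) for lab, _ in channels]),
        ("".join, [pad("AgAgCl electrode", 80) for _ in channels]),
        ("".join, [pad("uV", 8) for _ in channels]),
        ("".join, [pad(f"{-p:.6g}"[:8], 8) for p in phys]),
        ("".join, [pad(f"{p:.6g}"[:8], 8) for p in phys]),
        ("".join, [pad("-32768", 8) for _ in channels]),
        ("".join, [pad("32767", 8) for _ in channels]),
        ("".join, [pad("", 80) for _ in channels]),
        ("".join, [pad(str(fs), 8) for _ in channels]),
        ("".join, [pad("", 32) for _ in channels]),
    ]
    sig_header = b"".join(b"".join(parts) for _, parts in fields)
    with open(path, "wb") as f:
        f.write(header + sig_header)
        for r in range(n_records):
            for (_, sig), p in zip(channels, phys):
                chunk = sig[r * fs:(r + 1) * fs]
                # mirror the EDF decode mapping (phys [-p, p] onto digital
                # [-32768, 32767]) so the round-trip error is <= 0.5 LSB
                dig = np.round((chunk + p) / (2 * p) * 65535.0 - 32768.0)
                f.write(np.clip(dig, -32768, 32767).astype("<i2").tobytes())


def read_polysomnography(path, start_zeitgeber_time: float = 0.0,
                         n_days: int = 1) -> PolysomnographyRecording:
    """Read a 2-channel EDF polysomnography file (via mne).

    Channels are mapped by label; a channel whose label contains ``EEG``
    (case-insensitive) becomes the EEG series, likewise ``EMG``.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    eeg_idx = [i for i, n in enumerate(names) if "EEG" in n.upper()]
    emg_idx = [i for i, n in enumerate(names) if "EMG" in n.upper()]
    if not eeg_idx or not emg_idx:
        raise ValueError(
            f"{path}: need channels labeled EEG and EMG; found {names}"
        )
    data = raw.get_data(units="uV")
    return PolysomnographyRecording(
        eeg=data[eeg_idx[0]],
        emg=data[emg_idx[0]],
        sampling_rate=float(raw.info["sfreq"]),
        start_zeitgeber_time=start_zeitgeber_time,
        n_days=n_days,
    )


# ---------------------------------------------------------------------------
# hypnogram (TSV)
# ---------------------------------------------------------------------------

def write_hypnogram(hyp: Hypnogram, path) -> None:
    with open(path, "w") as f:
        f.write("epoch_index\tlabel\n")
        for i, lab in enumerate(hyp.labels):
            f.write(f"{i}\t{lab}\n")


def read_hypnogram(path, epoch_length: float = 4.0,
                   start_zeitgeber_time: float = 0.0) -> Hypnogram:
    labels = []
    with open(path) as f:
        header = f.readline()
        if not header.strip().startswith("epoch_index"):
            raise ValueError(f"{path}: missing 'epoch_index\\tlabel' header")
        for lineno, line in enumerate(f):
            if not line.strip():
                continue
            idx_s, _, lab = line.rstrip("\n").partition("\t")
            idx = int(idx_s)
            if idx != len(labels):
                raise ValueError(f"{path}: non-contiguous epochs, gap at {len(labels)}")
            if lab not in STATES:
                raise ValueError(f"{path}: unknown label {lab!r} at epoch {idx}")
            labels.append(lab)
    return Hypnogram(labels=labels, epoch_length=epoch_length,
                     start_zeitgeber_time=start_zeitgeber_time)


# ---------------------------------------------------------------------------
# image stacks (TIFF + JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_image_stack(stack: ImageStack, path) -> None:
    """Write a multi-page TIFF (pages = time) plus its JSON sidecar."""
    path = Path(path)
    # TIFF pages index time; store as T x H x W
    tifffile.imwrite(path, np.moveaxis(stack.frames, 2, 0).astype(np.float32))
    meta = {
        "frame_rate": stack.frame_rate,
        "stimulus_frequency": stack.stimulus_frequency,
        "eye": stack.eye,
        "stimulus_extent": stack.stimulus_extent,
        "direction": stack.direction,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_image_stack(path) -> ImageStack:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"{path}: metadata sidecar {sidecar.name} absent")
    meta = json.loads(sidecar.read_text())
    frames = np.moveaxis(tifffile.imread(path), 0, 2)
    return ImageStack(
        frames=frames,
        frame_rate=float(meta["frame_rate"]),
        stimulus_frequency=float(meta["stimulus_frequency"]),
        eye=meta.get("eye", "contra"),
        stimulus_extent=meta.get("stimulus_extent", "full_field"),
        direction=meta.get("direction", "up"),
    )
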