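"""Event-stream data: synthetic generator, binning, and dataset readers.

The universal signal container is the `SpikeGrid`: integer event counts
on a ``[channels x timesteps]`` grid, where a bin may hold more than one
event — exactly the multiplicity that binary-spike pipelines discard.

The synthetic generator emulates the structure of event-camera /
silicon-cochlea recordings: a handful of class-specific channels at an
elevated Poisson rate switching on at a class-specific onset time, on
top of uniform background noise.  Both the rate pattern (who fires) and
the temporal pattern (when they start) carry label information, so both
rate decoding and temporal feature extraction matter for the task.

Readers for the two common neuromorphic benchmark formats are included:
the ATIS 5-byte binary event packing (event-camera digits, 34x34 pixels,
two polarity channels) and the HDF5 layout used by the spiking
Heidelberg digits (700 cochlea channels, spike times + unit ids).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .grids import SpikeGrid

__all__ = [
    "SpikeGrid", "SyntheticTaskSpec", "rate_profile", "generate",
    "bin_events", "read_nmnist", "read_nmnist_file", "write_nmnist_file",
    "read_shd", "NMNIST_SIDE", "NMNIST_CHANNELS", "SHD_CHANNELS",
]

NMNIST_SIDE = 34
NMNIST_CHANNELS = 2 * NMNIST_SIDE * NMNIST_SIDE   # two polarities, row-major
SHD_CHANNELS = 700


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Defaults give a 3-class, 100-channel, 800 ms task at 16 ms bins.

    Class k drives ``n_signal_channels`` dedicated channels (block k) at
    ``signal_rate`` from its onset time onward; every channel sees
    ``noise_rate`` background.  Rates are per-ms Poisson intensities:
    0.003125/ms background = 0.05 events per 16 ms bin, 0.0625/ms signal
    = 1.0 event per bin.
    """

    n_classes: int = 3
    n_channels: int = 100
    T: float = 800.0
    dt: float = 16.0
    n_signal_channels: int = 20
    signal_rate: float = 0.0625      # events/ms on active class channels
    noise_rate: float = 0.003125     # events/ms background on all channels
    onsets: Optional[Tuple[float, ...]] = None  # default: 0, 200, 400, ... ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_classes * self.n_signal_channels > self.n_channels:
            raise ValueError("not enough channels for disjoint class blocks")
        if self.signal_rate < 0 or self.noise_rate < 0:
            raise ValueError("rates must be non-negative")
        n_bins = self.T / self.dt
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("T must be an integer multiple of dt")

    @property
    def n_bins(self) -> int:
        return int(round(self.T / self.dt))

    def onset(self, label: int) -> float:
        if self.onsets is not None:
            return self.onsets[label]
        return label * self.T / (2 * self.n_classes - 2) if self.n_classes > 1 else 0.0


def rate_profile(spec: SyntheticTaskSpec, label: int) -> np.ndarray:
    """Mean event count per bin, ``[n_channels x n_bins]``, for one class."""
    if not 0 <= label < spec.n_classes:
        raise ValueError(f"label {label} out of range")
    prof = np.full((spec.n_channels, spec.n_bins), spec.noise_rate * spec.dt)
    lo = label * spec.n_signal_channels
    hi = lo + spec.n_signal_channels
    onset_bin = int(math.ceil(spec.onset(label) / spec.dt))
    prof[lo:hi, onset_bin:] += spec.signal_rate * spec.dt
    return prof


def generate(
    spec: SyntheticTaskSpec, n_samples: int,
    rng: Optional[np.random.Generator] = None,
) -> List[SpikeGrid]:
    """Draw labelled samples: Poisson counts around the class profile.

    Labels cycle through the classes so any prefix is near-balanced.
    Deterministic for a fixed spec seed (or a supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    profiles = [rate_profile(spec, k) for k in range(spec.n_classes)]
    out = []
    for i in range(n_samples):
        label = i % spec.n_classes
        counts = rng.poisson(profiles[label])
        out.append(SpikeGrid(counts=counts.astype(np.int64), dt=spec.dt,
                             label=label))
    return out


def bin_events(
    events: Iterable[Tuple[float, int]], T: float, dt: float,
    n_channels: Optional[int] = None,
) -> SpikeGrid:
    """Bin (time ms, channel) events into half-open-left windows.

    Window k covers ``(k*dt, (k+1)*dt]``, so an event exactly on a bin
    boundary ``t = k*dt`` belongs to bin ``k-1``; events at exactly t=0
    (in no window under that convention) go to bin 0.  Multiple events
    may stack in one cell.  Out-of-range events are rejected with their
    index.
    """
    events = list(events)
    n_bins = int(round(T / dt))
    if abs(T / dt - n_bins) > 1e-9:
        raise ValueError("T must be an integer multiple of dt")
    if n_channels is None:
        n_channels = max((c for _, c in events), default=-1) + 1
        n_channels = max(n_channels, 1)
    counts = np.zeros((n_channels, n_bins), dtype=np.int64)
    for i, (t, c) in enumerate(events):
        if not (0.0 <= t < T):
            raise ValueError(f"event {i} at t={t} ms outside [0, {T})")
        if not (0 <= c < n_channels):
            raise ValueError(f"event {i} on channel {c} outside [0, {n_channels})")
        k = int(math.ceil(t / dt)) - 1
        counts[c, max(k, 0)] += 1
    return SpikeGrid(counts=counts, dt=dt)


# -- ATIS event-camera binary format (34x34 digits) -----------------------

def _decode_atis(raw: bytes) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Decode the 5-byte/event ATIS packing into (x, y, polarity, t_us)."""
    if len(raw) % 5 != 0:
        raise ValueError(
            f"malformed event file: length {len(raw)} is not a multiple of "
            f"the 5-byte record size (first bad offset {len(raw) - len(raw) % 5})"
        )
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 5).astype(np.int64)
    x = b[:, 0]
    y = b[:, 1]
    pol = (b[:, 2] >> 7) & 1
    t_us = ((b[:, 2] & 0x7F) << 16) | (b[:, 3] << 8) | b[:, 4]
    return x, y, pol, t_us


def read_nmnist_file(
    path: str, T: float = 300.0, dt: float = 20.0, label: Optional[int] = None,
) -> SpikeGrid:
    """Read one event-camera digit recording into a count grid.

    Events are flattened to ``polarity * 1156 + y * 34 + x`` (row-major)
    and binned half-open-left; events past ``T`` are clipped, matching
    the 15 x 20 ms = 300 ms simulation window.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    x, y, pol, t_us = _decode_atis(raw)
    if len(x) and (x.max() >= NMNIST_SIDE or y.max() >= NMNIST_SIDE):
        raise ValueError(f"malformed event file {path}: pixel index out of range")
    t_ms = t_us / 1000.0
    chan = pol * (NMNIST_SIDE * NMNIST_SIDE) + y * NMNIST_SIDE + x
    keep = t_ms < T
    grid = bin_events(zip(t_ms[keep], chan[keep]), T=T, dt=dt,
                      n_channels=NMNIST_CHANNELS)
    grid.label = label
    return grid


def write_nmnist_file(path: str, events: Sequence[Tuple[int, int, int, float]]) -> None:
    """Write (x, y, polarity, t_ms) events in the 5-byte ATIS packing.

    Provided for round-trip tests and fixture construction.
    """
    rec = np.zeros((len(events), 5), dtype=np.uint8)
    for i, (x, y, pol, t_ms) in enumerate(events):
        t_us = int(round(t_ms * 1000.0))
        if not (0 <= t_us < (1 << 23)):
            raise ValueError(f"timestamp {t_ms} ms out of 23-bit range")
        rec[i] = (x, y, ((pol & 1) << 7) | ((t_us >> 16) & 0x7F),
                  (t_us >> 8) & 0xFF, t_us & 0xFF)
    with open(path, "wb") as fh:
        fh.write(rec.tobytes())


def read_nmnist(path: str, T: float = 300.0, dt: float = 20.0) -> List[SpikeGrid]:
    """Read a file, or a directory of per-class subdirectories of files.

    Directory layout ``path/<digit>/<sample>.bin`` yields labelled grids;
    a single ``.bin`` file yields one unlabelled grid.
    """
    if os.path.isfile(path):
        return [read_nmnist_file(path, T=T, dt=dt)]
    grids: List[SpikeGrid] = []
    for sub in sorted(os.listdir(path)):
        subdir = os.path.join(path, sub)
        if not os.path.isdir(subdir):
            continue
        label = int(sub) if sub.isdigit() else None
        for fname in sorted(os.listdir(subdir)):
            if fname.endswith(".bin"):
                grids.append(read_nmnist_file(os.path.join(subdir, fname),
                                              T=T, dt=dt, label=label))
    return grids


def read_shd(path: str, T: float = 800.0, dt: float = 16.0) -> List[SpikeGrid]:
    """Read a spiking-cochlea HDF5 file into 700-channel count grids.

    Expects datasets ``spikes/times`` (seconds, ragged), ``spikes/units``
    and ``labels``; the 50 x 16 ms = 800 ms window covers the longest
    recording, shorter ones leave trailing bins zero.
    """
    import h5py

    grids: List[SpikeGrid] = []
    with h5py.File(path, "r") as fh:
        for key in ("spikes", "labels"):
            if key not in fh:
                raise KeyError(f"{path} is missing required dataset {key!r}")
        times = fh["spikes"]["times"]
        units = fh["spikes"]["units"]
        labels = fh["labels"][:]
        for t_s, u, lab in zip(times, units, labels):
            t_ms = np.asarray(t_s, dtype=float) * 1000.0
            keep = t_ms < T
            grid = bin_events(zip(t_ms[keep], np.asarray(u)[keep]), T=T, dt=dt,
                              n_channels=SHD_CHANNELS)
            grid.label = int(lab)
            grids.append(grid)
    return grids
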