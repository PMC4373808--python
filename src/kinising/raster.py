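"""Spike-train I/O, binarization and burst masking.

Binarization maps spike times onto an N x T binary matrix S with half-open
bins [t0 + k*dt, t0 + (k+1)*dt); the kinetic Ising machinery downstream
assumes at most one spike per bin, so bins holding two or more spikes are
clipped to 1 and accounted for in ``collision_fraction`` (a warning is issued
when it exceeds 1%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage

from .netsim import SpikeRecord

logger = logging.getLogger(__name__)

__all__ = ["BinnedRaster", "AnalysisMask", "binarize", "detect_bursts",
           "read_spikes", "write_spikes"]


@dataclass
class BinnedRaster:
    """N x T binary spike matrix with bin width dt (ms) starting at t0."""
    S: np.ndarray
    dt: float
    t0: float = 0.0
    collision_fraction: float = 0.0
    n_ignored: int = 0

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def t(self) -> int:
        return self.S.shape[1]

    def means(self) -> np.ndarray:
        """Per-neuron mean occupancy m_i = nu_i * dt ('magnetization')."""
        return self.S.mean(axis=1)


@dataclass
class AnalysisMask:
    """Per-bin validity mask with its contiguous valid segments."""
    valid: np.ndarray
    segments: list = field(default_factory=list)

    def __post_init__(self):
        self.valid = np.asarray(self.valid, dtype=bool)
        if not self.segments:
            self.segments = _segments_of(self.valid)

    @property
    def fraction_valid(self) -> float:
        return float(self.valid.mean()) if self.valid.size else 0.0

    def segments_ms(self, dt: float, t0: float = 0.0) -> list:
        return [(t0 + a * dt, t0 + b * dt) for a, b in self.segments]


def _segments_of(valid: np.ndarray) -> list:
    """Contiguous [start, stop) runs of True."""
    if valid.size == 0:
        return []
    padded = np.concatenate([[False], valid, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    stops = np.nonzero(edges == -1)[0]
    return list(zip(starts.tolist(), stops.tolist()))


def binarize(spikes, dt: float, t0: float = 0.0, t1: float | None = None) -> BinnedRaster:
    """Bin spike trains into a binary raster.

    ``spikes`` is a SpikeRecord or a list of per-neuron spike-time arrays.
    Spikes outside [t0, t1) are ignored (counted in ``n_ignored``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if isinstance(spikes, SpikeRecord):
        trains = spikes.trains
        if t1 is None:
            t1 = spikes.duration
    else:
        trains = [np.asarray(t, dtype=float) for t in spikes]
        if t1 is None:
            t1 = max((t[-1] for t in trains if len(t)), default=0.0) + dt
    if not t1 > t0:
        raise ValueError("need t1 > t0")
    n = len(trains)
    t_bins = int(np.floor((t1 - t0) / dt))
    if t_bins < 1:
        raise ValueError("window shorter than one bin")

    S = np.zeros((n, t_bins), dtype=np.uint8)
    n_ignored = 0
    n_collisions = 0
    for i, train in enumerate(trains):
        inside = (train >= t0) & (train < t0 + t_bins * dt)
        n_ignored += int(len(train) - inside.sum())
        idx = np.floor((train[inside] - t0) / dt).astype(np.int64)
        idx = idx[idx < t_bins]
        counts = np.bincount(idx, minlength=t_bins)
        n_collisions += int(np.sum(counts > 1))
        S[i] = counts > 0
    if n_ignored:
        logger.info("binarize: ignored %d spikes outside [%g, %g)", n_ignored, t0, t1)
    collision_fraction = n_collisions / (n * t_bins)
    if collision_fraction > 0.01:
        logger.warning("binarize: %.2f%% of cells held >1 spike; consider a "
                       "smaller dt", 100 * collision_fraction)
    return BinnedRaster(S=S, dt=float(dt), t0=float(t0),
                        collision_fraction=collision_fraction, n_ignored=n_ignored)


def detect_bursts(raster: BinnedRaster, window: float = 50.0,
                  threshold_factor: float = 3.0, margin: float = 100.0) -> AnalysisMask:
    """Mark population bursts invalid, keeping the inter-burst (low-activity) bins.

    The population spike count per bin is smoothed with a boxcar of width
    ``window`` (ms); bins where it exceeds threshold_factor x median, padded
    by ``margin`` (ms) on both sides, are excluded.
    """
    if raster.S.size == 0:
        raise ValueError("empty raster")
    if window < raster.dt:
        raise ValueError("window must be at least one bin wide")
    pop = raster.S.sum(axis=0).astype(float)
    wbins = max(1, int(round(window / raster.dt)))
    smooth = ndimage.uniform_filter1d(pop, size=wbins, mode="nearest")
    ref = float(np.median(smooth))
    if ref == 0.0:
        ref = float(smooth.mean())
    burst = smooth > threshold_factor * ref
    mbins = int(round(margin / raster.dt))
    if mbins > 0 and burst.any():
        burst = ndimage.binary_dilation(burst, structure=np.ones(2 * mbins + 1, dtype=bool))
    mask = AnalysisMask(valid=~burst)
    logger.info("detect_bursts: %d burst segments, %.1f%% of bins excluded",
                len(_segments_of(burst)), 100 * (1 - mask.fraction_valid))
    return mask


# ---------------------------------------------------------------------------
# spike I/O: plain text ("neuron_index spike_time_ms") and HDF5

class SpikeFileError(ValueError):
    pass


def write_spikes(record: SpikeRecord, path) -> None:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            f.attrs["n"] = record.n
            f.attrs["duration"] = record.duration
            g = f.create_group("trains")
            for i, t in enumerate(record.trains):
                g.create_dataset(str(i), data=np.asarray(t, dtype=float))
        return
    ids, times = record.flatten()
    with open(path, "w") as f:
        f.write(f"# kinising spikes n={record.n} duration_ms={record.duration!r}\n")
        f.write("# neuron_index spike_time_ms\n")
        for i, t in zip(ids, times):
            f.write(f"{int(i)} {float(t)!r}\n")


def read_spikes(path) -> SpikeRecord:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            n = int(f.attrs["n"])
            duration = float(f.attrs["duration"])
            trains = [f["trains"][str(i)][...] for i in range(n)]
        return SpikeRecord(trains=trains, duration=duration, n=n)

    n = None
    duration = None
    ids, times = [], []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("n="):
                        n = int(tok[2:])
                    elif tok.startswith("duration_ms="):
                        duration = float(tok[12:])
                continue
            parts = line.split()
            try:
                ids.append(int(parts[0]))
                times.append(float(parts[1]))
            except (IndexError, ValueError) as exc:
                raise SpikeFileError(f"{path}:{lineno}: malformed line {line!r}") from exc
    ids = np.asarray(ids, dtype=np.int64)
    times = np.asarray(times)
    if n is None:
        n = int(ids.max()) + 1 if ids.size else 0
    if duration is None:
        duration = float(times.max()) if times.size else 0.0
    trains = []
    for i in range(n):
        t = times[ids == i]
        if np.any(np.diff(t) < 0):
            logger.warning("read_spikes: spike times of neuron %d were out of "
                           "order; sorted on read", i)
            t = np.sort(t)
        trains.append(t)
    return SpikeRecord(trains=trains, duration=duration, n=n)
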