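"""Step one of the two-step inference: per-pair delay and sign estimation.

For each ordered pair (i, j) the transmission delay is taken as the positive
lag at which |D_ij(tau)| peaks (the cross-correlogram of a connected pair
peaks near the synaptic delay, positive for excitatory and negative for
inhibitory transmission).  Lag 0 is excluded — synaptic delays are strictly
positive — and ties go to the smallest lag, i.e. to the minimum transmission
time consistent with causality.  Estimates are inherently discretized as
multiples of the bin width dt and therefore never undershoot the true delay
by more than noise allows.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .correlations import CorrelationSet

__all__ = ["DelayEstimate", "estimate_delays"]


@dataclass
class DelayEstimate:
    """Per-pair delay (bins and ms), interaction sign, and the covariance at
    the selected lag.  ``unresolved`` flags pairs whose cross-correlogram is
    identically zero on the searched grid."""
    delta_bins: np.ndarray
    sign: np.ndarray
    peak_value: np.ndarray
    dt: float
    unresolved: np.ndarray

    @property
    def delta_ms(self) -> np.ndarray:
        return self.delta_bins * self.dt

    def to_hdf5(self, path) -> None:
        with h5py.File(str(path), "w") as f:
            f.attrs["dt"] = self.dt
            f.create_dataset("delta_bins", data=self.delta_bins)
            f.create_dataset("sign", data=self.sign)
            f.create_dataset("peak_value", data=self.peak_value)
            f.create_dataset("unresolved", data=self.unresolved)


def estimate_delays(corr: CorrelationSet, max_lag_bins: int | None = None) -> DelayEstimate:
    """argmax over positive lags of |D_ij(tau)|, per ordered pair.

    The diagonal is fixed to one bin (the standard kinetic model's one-step
    self-interaction).  ``max_lag_bins`` restricts the searched grid.
    """
    pos = corr.lags_bins > 0
    if max_lag_bins is not None:
        pos &= corr.lags_bins <= max_lag_bins
    if not pos.any():
        raise ValueError("no positive lags on the correlation grid")
    lag_values = corr.lags_bins[pos]
    stack = corr.D[pos]                      # (L, N, N)
    absD = np.abs(stack)
    best = np.argmax(absD, axis=0)           # first (= smallest-lag) maximum
    n = corr.n
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    peak = stack[best, ii, jj]
    delta_bins = lag_values[best].astype(np.int64)

    unresolved = absD.max(axis=0) == 0.0
    sign = np.where(peak >= 0, 1, -1).astype(np.int8)
    sign[unresolved] = 1

    np.fill_diagonal(delta_bins, 1)
    np.fill_diagonal(unresolved, False)
    return DelayEstimate(delta_bins=delta_bins, sign=sign, peak_value=peak,
                         dt=corr.dt, unresolved=unresolved)
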