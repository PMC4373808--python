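"""Means, equal-time and time-lagged covariances of binary rasters.

D_ij(tau) = < dS_i(t+tau) dS_j(t) >_t with dS = S - m; the lag-0 matrix is
the connected covariance C (C_jj = m_j (1 - m_j) exactly on binary data).
Averages run over the valid (t, t+tau) pairs only, and are normalized by the
number of such pairs for each lag, so long lags carry no edge bias and a
validity mask never couples bins across masked-out gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np

from .raster import AnalysisMask, BinnedRaster

logger = logging.getLogger(__name__)

__all__ = ["CorrelationSet", "compute_correlations", "conditional_rate",
           "negative_lag_lookup"]

DEFAULT_MAX_LAG_MS = 50.0


@dataclass
class CorrelationSet:
    """m (N,), lag grid in bins (non-negative, ascending, starting at 0),
    lagged covariances D (n_lags, N, N) and per-lag sample counts."""
    m: np.ndarray
    lags_bins: np.ndarray
    D: np.ndarray
    dt: float
    n_samples: np.ndarray

    @property
    def n(self) -> int:
        return self.m.shape[0]

    @property
    def C(self) -> np.ndarray:
        return self.D[0]

    @property
    def max_lag_bins(self) -> int:
        return int(self.lags_bins[-1])

    def _index(self, lag_bins: int) -> int:
        idx = np.searchsorted(self.lags_bins, lag_bins)
        if idx >= len(self.lags_bins) or self.lags_bins[idx] != lag_bins:
            raise KeyError(f"lag {lag_bins} bins not on the computed grid")
        return int(idx)

    def lagged(self, lag_bins: int) -> np.ndarray:
        """D(tau) for a signed lag in bins; D(-tau) = D(tau)^T."""
        if lag_bins >= 0:
            return self.D[self._index(lag_bins)]
        return self.D[self._index(-lag_bins)].T

    def get(self, i: int, j: int, lag_bins: int) -> float:
        """Single entry D_ij(tau), signed lag."""
        return float(self.lagged(lag_bins)[i, j])

    def signed_stack(self):
        """(D(-L..L), offset) with D(-tau) = D(tau)^T, for vectorized lookups."""
        lmax = self.max_lag_bins
        full = np.empty((2 * lmax + 1,) + self.D[0].shape)
        for k, lag in enumerate(self.lags_bins):
            full[lmax + lag] = self.D[k]
            full[lmax - lag] = self.D[k].T
        return full, lmax

    def to_hdf5(self, path) -> None:
        with h5py.File(str(path), "w") as f:
            f.attrs["dt"] = self.dt
            f.create_dataset("m", data=self.m)
            f.create_dataset("lags_bins", data=self.lags_bins)
            f.create_dataset("D", data=self.D)
            f.create_dataset("n_samples", data=self.n_samples)

    @classmethod
    def from_hdf5(cls, path) -> "CorrelationSet":
        with h5py.File(str(path), "r") as f:
            return cls(m=f["m"][...], lags_bins=f["lags_bins"][...],
                       D=f["D"][...], dt=float(f.attrs["dt"]),
                       n_samples=f["n_samples"][...])


def compute_correlations(raster: BinnedRaster,
                         lags=None,
                         mask: AnalysisMask | None = None,
                         max_lag_ms: float = DEFAULT_MAX_LAG_MS) -> CorrelationSet:
    """Estimate m, C and D(tau) on the lag grid.

    ``lags`` is an iterable of non-negative lags in *bins*; by default
    0, 1, ..., floor(max_lag_ms / dt).  ``mask`` restricts the estimate to
    valid bins: m is the mean over valid bins and a (t, t+tau) product enters
    D(tau) only when both bins are valid.
    """
    S = raster.S
    n, t_bins = S.shape
    if S.size == 0:
        raise ValueError("empty raster")
    if lags is None:
        lags = np.arange(int(np.floor(max_lag_ms / raster.dt)) + 1)
    lags = np.asarray(sorted(set(int(l) for l in lags)), dtype=np.int64)
    if lags[0] != 0:
        lags = np.concatenate([[0], lags])
    if np.any(lags < 0):
        raise ValueError("lag grid must be non-negative (use CorrelationSet.lagged "
                         "for negative lags)")
    if lags[-1] >= t_bins:
        raise ValueError("largest lag must be smaller than the raster length")

    valid = mask.valid if mask is not None else None
    if valid is not None:
        if valid.shape != (t_bins,):
            raise ValueError("mask length must equal the raster length")
        if not valid.any():
            raise ValueError("all bins are masked out")

    if valid is None:
        m = S.mean(axis=1)
    else:
        m = S[:, valid].mean(axis=1)

    X = S.astype(np.float64) - m[:, None]
    D = np.empty((len(lags), n, n))
    n_samples = np.empty(len(lags), dtype=np.int64)
    for k, lag in enumerate(lags):
        if valid is None:
            a = X[:, lag:]
            b = X[:, :t_bins - lag]
            cnt = t_bins - lag
        else:
            both = valid[lag:] & valid[:t_bins - lag]
            cnt = int(both.sum())
            if cnt == 0:
                D[k] = np.nan
                n_samples[k] = 0
                continue
            a = X[:, lag:][:, both]
            b = X[:, :t_bins - lag][:, both]
        D[k] = (a @ b.T) / cnt
        n_samples[k] = cnt
    return CorrelationSet(m=m, lags_bins=lags, D=D, dt=raster.dt, n_samples=n_samples)


def conditional_rate(corr: CorrelationSet, i: int, j: int, lag_bins: int) -> float:
    """< S_i(t+tau) | S_j(t)=1 > = D_ij(tau)/m_j + m_i (inverse of the
    covariance identity D_ij = m_j (<S_i|S_j=1> - m_i))."""
    mj = corr.m[j]
    if mj <= 0.0:
        raise ValueError(f"neuron {j} never fires; conditional rate undefined")
    return float(corr.get(i, j, lag_bins) / mj + corr.m[i])


def negative_lag_lookup(corr: CorrelationSet, k: int, j: int, lag_bins: int) -> float:
    """D_kj at a (possibly negative) lag via the identity D_kj(-tau) = D_jk(tau)."""
    return corr.get(k, j, lag_bins)
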