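"""Analytic mapping between inferred couplings and synaptic efficacies.

Under the diffusion approximation the membrane potential of an LIF neuron is
an Ornstein-Uhlenbeck process with an absorbing barrier at threshold, so the
stationary density vanishes at threshold with slope p'(theta) = -2 nu/sigma^2.
Expanding the conditional firing probability <S_i | S_j = 1> around threshold
yields a piecewise-quadratic relation between the inferred coupling J_inf of
the kinetic Ising model and the physical efficacy J (mV):

  J > 0:                J_inf ~ J^2/(sigma^2 dt)
                                + [J^2 (nu_i + nu_j) + J J_ext nu_ext]/sigma^2
  -J_ext <= J < 0:      J_inf ~ (J^2 + 2 J J_ext) nu_ext / (2 sigma^2)
  -2 J_ext <= J < -J_ext:  J_inf ~ -1/2   (saturation: a single external
                                   impulse can no longer compensate the jump)

The excitatory branch diverges as 1/dt while the inhibitory branch is
dt-independent at leading order; with sigma^2 = J_ext^2 nu_ext (single
external Poisson train) the two branches join continuously at J = -J_ext with
value -1/2.  Inverting these relations turns inferred couplings into efficacy
estimates; inhibitory couplings below -1/2 lie outside the invertible
(physical) range and are flagged instead of inverted.  A short-term-depression
correction multiplies estimates by (1 + u tau_r nu_j), undoing the mean
resource depletion of a pre-synaptic neuron firing at rate nu_j.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .inference import InferenceResult

__all__ = ["PhysioParams", "RemapFlag", "RemapResult", "predict_jinf",
           "invert_to_efficacy", "std_correction", "full_eq23_rate",
           "remap_couplings"]


@dataclass(frozen=True)
class PhysioParams:
    """Physiological quantities entering the remapping.

    sigma2 (mV^2/ms) defaults to J_ext^2 * nu_ext, exact when the noisy input
    is a single external Poisson train; pass an explicit value for data with a
    different noise budget.  Rates in kHz, dt in ms.
    """
    j_ext: float = 0.9
    nu_ext: float = 1.0
    dt: float = 1.0
    sigma2: float | None = None

    @property
    def sigma2_eff(self) -> float:
        s2 = self.j_ext ** 2 * self.nu_ext if self.sigma2 is None else self.sigma2
        if s2 <= 0:
            raise ValueError("sigma2 must be positive")
        return s2


class RemapFlag(IntEnum):
    OK = 0
    UNPHYSICAL = 1     # inhibitory J_inf <= -1/2: no inverse exists
    INCONSISTENT = 2   # sign and coupling magnitude disagree
    SATURATED = 3      # J below -J_ext: prediction pinned at the -1/2 plateau


def predict_jinf(j_true, params: PhysioParams, nu_i: float = 0.0, nu_j: float = 0.0):
    """Forward map J (mV) -> expected inferred coupling (dimensionless).

    Strictly increasing on (-J_ext, inf), flat at -1/2 on [-2 J_ext, -J_ext);
    efficacies below -2 J_ext are outside the expansion and also return -1/2.
    """
    j = np.asarray(j_true, dtype=float)
    s2 = params.sigma2_eff
    je = params.j_ext
    pos = j ** 2 / (s2 * params.dt) + (j ** 2 * (nu_i + nu_j) + j * je * params.nu_ext) / s2
    neg = (j ** 2 + 2.0 * j * je) * params.nu_ext / (2.0 * s2)
    out = np.where(j >= 0, pos, np.where(j >= -je, neg, -0.5))
    return float(out) if np.isscalar(j_true) else out


def invert_to_efficacy(j_inf: float, sign: int, params: PhysioParams,
                       nu_i: float = 0.0, nu_j: float = 0.0):
    """Inverse map: inferred coupling + interaction sign -> efficacy estimate.

    Returns (j_est, flag); j_est is NaN when no inverse exists (flagged).
    sign=+1 inverts the excitatory quadratic; sign=-1 the inhibitory one,
    defined only on the physical range -1/2 < J_inf < 0.
    """
    s2 = params.sigma2_eff
    je = params.j_ext
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    if sign == 1:
        if j_inf < 0:
            return np.nan, RemapFlag.INCONSISTENT
        a = 1.0 / (s2 * params.dt) + (nu_i + nu_j) / s2
        b = je * params.nu_ext / s2
        return (-b + np.sqrt(b * b + 4.0 * a * j_inf)) / (2.0 * a), RemapFlag.OK
    if j_inf >= 0:
        return np.nan, RemapFlag.INCONSISTENT
    if j_inf <= -0.5:
        return np.nan, RemapFlag.UNPHYSICAL
    j_est = -je + je * np.sqrt(1.0 + 2.0 * j_inf)
    # the forward map flattens toward -1/2 as J -> -J_ext, so estimates in
    # the last 5% of the invertible range carry essentially no sensitivity
    flag = RemapFlag.SATURATED if j_est <= -0.95 * je else RemapFlag.OK
    return j_est, flag


def std_correction(j_est, u: float, tau_r: float, nu_pre):
    """Undo the mean short-term depression of a pre-synaptic neuron firing at
    nu_pre (kHz): multiply the estimate by (1 + u tau_r nu_pre)."""
    nu_pre = np.asarray(nu_pre, dtype=float)
    if np.any(nu_pre < 0):
        raise ValueError("nu_pre must be non-negative")
    return j_est * (1.0 + u * tau_r * nu_pre)


@dataclass
class RemapResult:
    """Efficacy estimates (mV) with per-pair flags (RemapFlag values)."""
    j_est: np.ndarray
    flags: np.ndarray
    params: PhysioParams

    @property
    def unphysical_mask(self) -> np.ndarray:
        return self.flags == RemapFlag.UNPHYSICAL


def remap_couplings(result: InferenceResult, signs: np.ndarray,
                    params: PhysioParams, nu: np.ndarray,
                    std: tuple | None = None) -> RemapResult:
    """Vectorized inversion of a full inferred-coupling matrix.

    ``signs`` comes from the delay-estimation step, ``nu`` are per-neuron
    firing rates (kHz) measured from the raster used for inference.  With
    ``std=(u, tau_r)`` the estimates are additionally rescaled by
    (1 + u tau_r nu_j) of the pre-synaptic rate.
    """
    n = result.J.shape[0]
    j_est = np.full((n, n), np.nan)
    flags = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(n):
            if i == j or not np.isfinite(result.J[i, j]):
                flags[i, j] = RemapFlag.INCONSISTENT
                continue
            est, fl = invert_to_efficacy(float(result.J[i, j]), int(signs[i, j]),
                                         params, nu_i=float(nu[i]), nu_j=float(nu[j]))
            j_est[i, j] = est
            flags[i, j] = fl
    if std is not None:
        u, tau_r = std
        j_est = std_correction(j_est, u, tau_r, nu[np.newaxis, :])
    return RemapResult(j_est=j_est, flags=flags, params=params)


# ---------------------------------------------------------------------------
# quadrature oracle for the conditional-rate expansion

def full_eq23_rate(j: float, params: PhysioParams, nu_i: float, dt: float | None = None,
                   k_max: int = 2, mu0: float = 0.0,
                   n_eps: int = 200, n_arr: int = 40) -> float:
    """Numeric evaluation of the conditional firing probability <S_i|S_j=1>.

    Averages, over the uniform arrival phase eps of the pre-synaptic spike in
    the bin and over the Poisson count k of external impulses in the remainder
    of the bin, the stationary-density mass swept across threshold, using the
    linear density p(v) ~ (2 nu_i / sigma^2)(theta - v) near threshold.  The
    k-th of k external arrival times within the remaining window is
    Beta(k, 1)-distributed; mu0 adds a constant leak drift near threshold
    (its average affects the result only at order dt^2).  Serves as the
    independent oracle for the closed-form expansions of ``predict_jinf``.
    """
    from math import factorial

    dt = params.dt if dt is None else dt
    s2 = params.sigma2_eff
    je = params.j_ext
    lam = params.nu_ext

    eps = (np.arange(n_eps) + 0.5) * dt / n_eps
    rem = dt - eps                      # window left for external arrivals
    # Beta(k, 1) quadrature nodes on [0, 1] for the k-th arrival phase
    tq = (np.arange(n_arr) + 0.5) / n_arr

    total = nu_i * dt / 2.0             # baseline firing before the spike
    acc = np.zeros_like(rem)
    for k in range(0 if j > 0 else 1, k_max + 1):
        pois = np.exp(-lam * rem) * (lam * rem) ** k / factorial(k)
        if k == 0:
            upper = np.full_like(rem, max(j, 0.0))
            mass = upper ** 2 / 2.0
        else:
            wk = k * tq ** (k - 1) / n_arr          # Beta(k,1) weights
            # upper limit of the swept interval for each (eps, arrival phase)
            upper = j + k * je + mu0 * np.outer(rem, tq)
            np.clip(upper, 0.0, None, out=upper)
            mass = (upper ** 2 / 2.0) @ wk
        acc += pois * mass
    total += (2.0 * nu_i / s2) * np.mean(acc)
    return float(total)
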