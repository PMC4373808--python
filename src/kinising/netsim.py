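"""Construction and event-driven simulation of sparsely coupled LIF networks.

The neuron model is a leaky integrate-and-fire unit with instantaneous
(delta) synapses: between impulses the membrane potential V relaxes
exponentially toward ``V_rest`` with time constant ``tau_m``; an arriving
impulse adds its efficacy (mV) instantaneously; when V reaches the threshold
``theta`` the neuron emits a spike, V is reset to ``V_rest`` and the membrane
is clamped there for an absolute refractory period.  Each recurrent spike
travels with a per-synapse transmission delay; every neuron additionally
receives an independent Poisson train of external impulses.  Synapses can be
endowed with short-term depression: a resource fraction r is multiplied into
each impulse, depleted by a fraction u per pre-synaptic spike, and recovers
toward 1 with time constant tau_r.

Conventions: times in ms, rates in kHz (= events/ms), potentials in mV.
``J[i, j]`` is the efficacy of the synapse from pre-synaptic neuron j onto
post-synaptic neuron i, so the sign of column j is set by neuron j's
excitatory/inhibitory identity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine

logger = logging.getLogger(__name__)

__all__ = [
    "NeuronParams", "ExternalDriveSpec", "STDParams", "DelaySpec",
    "EfficacySpec", "NetworkModel", "SpikeRecord",
    "make_random_network", "make_ring_network", "circular_distance",
    "spatial_connection_prob", "sample_delays", "simulate",
    "simulate_given_external", "euler_reference", "std_steady_state",
    "draw_poisson_train",
]


class ConfigurationError(ValueError):
    """Raised when a network/simulation specification is inconsistent."""


@dataclass(frozen=True)
class NeuronParams:
    """LIF membrane parameters (defaults are the standard ones used throughout)."""
    tau_m: float = 20.0          # membrane time constant (ms)
    v_rest: float = -70.0        # resting = reset potential (mV)
    theta: float = -52.0         # firing threshold (mV)
    tau_refractory: float = 2.0  # absolute refractory period (ms)

    def __post_init__(self):
        if self.tau_m <= 0:
            raise ConfigurationError("tau_m must be positive")
        if self.theta <= self.v_rest:
            raise ConfigurationError("theta must exceed v_rest")
        if self.tau_refractory < 0:
            raise ConfigurationError("tau_refractory must be >= 0")


@dataclass(frozen=True)
class ExternalDriveSpec:
    """Per-neuron external Poisson drive.

    nu_ext in kHz; each impulse has efficacy j_ext_mean, optionally jittered
    per impulse with Gaussian sd j_ext_sd.
    """
    nu_ext: float = 1.0
    j_ext_mean: float = 0.9
    j_ext_sd: float = 0.0

    def __post_init__(self):
        if self.nu_ext < 0:
            raise ConfigurationError("nu_ext must be >= 0")
        if not math.isfinite(self.j_ext_mean):
            raise ConfigurationError("j_ext_mean must be finite")
        if self.j_ext_sd < 0:
            raise ConfigurationError("j_ext_sd must be >= 0")


@dataclass(frozen=True)
class STDParams:
    """Short-term synaptic depression (resource fraction dynamics)."""
    enabled: bool = False
    tau_r: float = 800.0  # resource recovery time constant (ms)
    u: float = 0.2        # release (depletion) fraction per pre-synaptic spike

    def __post_init__(self):
        if not 0.0 <= self.u <= 1.0:
            raise ConfigurationError("u must lie in [0, 1]")
        if self.enabled and self.tau_r <= 0:
            raise ConfigurationError("tau_r must be positive when STD is enabled")


@dataclass(frozen=True)
class DelaySpec:
    """Transmission-delay distribution: a single constant, or offset + truncated exponential.

    For the truncated exponential, draws are delta_min + Exp(scale), re-sampled
    whenever they exceed delta_max.  If ``scale`` is omitted it is fixed by the
    convention that the truncation triggers a re-sample 5% of the time:
    exp(-(delta_max-delta_min)/scale) = 0.05, i.e. scale = (delta_max-delta_min)/ln 20.
    """
    kind: str = "constant"
    delta_const: float = 3.0
    delta_min: float = 1.0
    delta_max: float = 20.0
    scale: float | None = None
    resample_prob: float = 0.05

    def __post_init__(self):
        if self.kind not in ("constant", "truncated_exponential"):
            raise ConfigurationError(f"unknown delay kind {self.kind!r}")
        if self.kind == "constant":
            if self.delta_const <= 0:
                raise ConfigurationError("constant delay must be positive")
        else:
            if not (0 < self.delta_min < self.delta_max):
                raise ConfigurationError("need 0 < delta_min < delta_max")
            if self.scale is not None and self.scale <= 0:
                raise ConfigurationError("scale must be positive")

    @classmethod
    def constant(cls, delta: float) -> "DelaySpec":
        return cls(kind="constant", delta_const=delta)

    @classmethod
    def truncated_exponential(cls, delta_min: float, delta_max: float,
                              scale: float | None = None) -> "DelaySpec":
        return cls(kind="truncated_exponential", delta_min=delta_min,
                   delta_max=delta_max, scale=scale)

    @property
    def effective_scale(self) -> float:
        """The exponential scale actually used for sampling (ms)."""
        if self.kind == "constant":
            raise ConfigurationError("constant delays have no exponential scale")
        if self.scale is not None:
            return self.scale
        return (self.delta_max - self.delta_min) / math.log(1.0 / self.resample_prob)


@dataclass(frozen=True)
class EfficacySpec:
    """Distribution of synaptic efficacy *magnitudes* (mV).

    The sign is applied afterwards according to the pre-synaptic neuron's
    population (excitatory +, inhibitory -).  Gaussian draws are not
    sign-clipped; negative magnitudes are kept and logged.
    """
    kind: str = "delta"
    value: float = 0.9            # delta
    low: float = 0.0              # uniform
    high: float = 0.54
    mean: float = 0.846           # gaussian
    sd: float = 0.211

    def __post_init__(self):
        if self.kind not in ("delta", "uniform", "gaussian"):
            raise ConfigurationError(f"unknown efficacy kind {self.kind!r}")
        if self.kind == "uniform" and not self.low < self.high:
            raise ConfigurationError("uniform efficacy needs low < high")
        if self.kind == "gaussian" and self.sd < 0:
            raise ConfigurationError("gaussian efficacy needs sd >= 0")

    @classmethod
    def delta(cls, value: float) -> "EfficacySpec":
        return cls(kind="delta", value=value)

    @classmethod
    def uniform(cls, low: float, high: float) -> "EfficacySpec":
        return cls(kind="uniform", low=low, high=high)

    @classmethod
    def gaussian(cls, mean: float, sd: float) -> "EfficacySpec":
        return cls(kind="gaussian", mean=mean, sd=sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "delta":
            return np.full(n, self.value)
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        draws = rng.normal(self.mean, self.sd, size=n)
        nneg = int(np.sum(draws < 0))
        if nneg:
            logger.warning("%d of %d Gaussian efficacy draws are negative "
                           "(kept as drawn)", nneg, n)
        return draws


@dataclass
class NetworkModel:
    """Ground-truth network: efficacy matrix, delay matrix, parameters.

    j_true[i, j] != 0 marks a synapse j -> i; delays[i, j] is its
    transmission delay (ms), defined (positive) wherever j_true is non-zero.
    ``labels`` holds +1 for excitatory and -1 for inhibitory neurons;
    ``populations`` an optional per-neuron population index (ring networks).
    """
    j_true: np.ndarray
    delays: np.ndarray
    neuron: NeuronParams = field(default_factory=NeuronParams)
    external: ExternalDriveSpec = field(default_factory=ExternalDriveSpec)
    std: STDParams = field(default_factory=STDParams)
    labels: np.ndarray | None = None
    populations: np.ndarray | None = None

    def __post_init__(self):
        self.j_true = np.asarray(self.j_true, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        n = self.j_true.shape[0]
        if self.j_true.shape != (n, n) or self.delays.shape != (n, n):
            raise ConfigurationError("j_true and delays must be square and congruent")
        if np.any(np.diag(self.j_true) != 0):
            raise ConfigurationError("autapses are not allowed (diagonal must be 0)")
        mask = self.j_true != 0
        if np.any(self.delays[mask] <= 0):
            raise ConfigurationError("delays must be positive on existing synapses")
        if not np.all(np.isfinite(self.j_true)):
            raise ConfigurationError("NaN/inf in j_true")
        if self.labels is None:
            self.labels = np.ones(n, dtype=int)

    @property
    def n(self) -> int:
        return self.j_true.shape[0]

    @property
    def connection_mask(self) -> np.ndarray:
        return self.j_true != 0

    def csr(self):
        """CSR arrays (indptr, targets, weights, delays) indexed by pre-synaptic neuron."""
        n = self.n
        mask = self.j_true != 0
        counts = mask.sum(axis=0)  # out-degree of each pre-synaptic neuron
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        targets = np.empty(indptr[-1], dtype=np.int64)
        weights = np.empty(indptr[-1])
        dl = np.empty(indptr[-1])
        for j in range(n):
            tgts = np.nonzero(mask[:, j])[0]
            sl = slice(indptr[j], indptr[j + 1])
            targets[sl] = tgts
            weights[sl] = self.j_true[tgts, j]
            dl[sl] = self.delays[tgts, j]
        return indptr, targets, weights, dl


@dataclass
class SpikeRecord:
    """Per-neuron, strictly increasing spike times (ms) over [0, duration)."""
    trains: list
    duration: float
    n: int

    def __post_init__(self):
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]

    def rates(self) -> np.ndarray:
        """Per-neuron mean firing rate in kHz (spikes/ms)."""
        return np.array([len(t) for t in self.trains]) / self.duration

    def rates_hz(self) -> np.ndarray:
        return self.rates() * 1000.0

    @property
    def total_spikes(self) -> int:
        return int(sum(len(t) for t in self.trains))

    def mean_rate_hz(self) -> float:
        return self.total_spikes / (self.n * self.duration) * 1000.0

    def flatten(self):
        """(neuron_ids, times) sorted by time (stable, ties by neuron id)."""
        ids = np.concatenate([np.full(len(t), i, dtype=np.int64)
                              for i, t in enumerate(self.trains)]) \
            if self.trains else np.empty(0, dtype=np.int64)
        times = np.concatenate(self.trains) if self.trains else np.empty(0)
        order = np.lexsort((ids, times))
        return ids[order], times[order]

    @classmethod
    def from_events(cls, ids, times, n, duration) -> "SpikeRecord":
        ids = np.asarray(ids)
        times = np.asarray(times, dtype=float)
        trains = [times[ids == i] for i in range(n)]
        trains = [np.sort(t) for t in trains]
        return cls(trains=trains, duration=float(duration), n=int(n))


# ---------------------------------------------------------------------------
# topology

def circular_distance(alpha: int, beta: int, n_pop: int) -> int:
    """Distance along a ring of n_pop populations: min(|a-b|, P-|a-b|)."""
    if not (1 <= alpha <= n_pop and 1 <= beta <= n_pop):
        raise ValueError("population indices must lie in 1..P")
    d = abs(alpha - beta)
    return min(d, n_pop - d)


def spatial_connection_prob(alpha: int, beta: int, n_pop: int,
                            c0: float = 0.134,
                            pair_scale: float = 135.0,
                            ref_scale: float = 26.1) -> float:
    """Ring-kernel connection probability from population beta onto alpha.

    c0 * exp(-d(alpha,beta)/pair_scale - d(alpha,P/2)/ref_scale): connectivity
    decays with distance along the ring, and populations near the reference
    population P/2 receive more synapses than distant ones.
    """
    if n_pop % 2:
        raise ValueError("n_pop must be even (P/2 reference population)")
    d_ab = circular_distance(alpha, beta, n_pop)
    d_ref = circular_distance(alpha, n_pop // 2, n_pop)
    return c0 * math.exp(-d_ab / pair_scale - d_ref / ref_scale)


def mean_spatial_connection_prob(n_pop: int = 100, **kw) -> float:
    """Average of the ring kernel over all ordered population pairs."""
    vals = [spatial_connection_prob(a, b, n_pop, **kw)
            for a in range(1, n_pop + 1) for b in range(1, n_pop + 1)]
    return float(np.mean(vals))


def sample_delays(spec: DelaySpec, n: int, rng, count_resamples: bool = False):
    """Draw n transmission delays; truncated-exponential draws above
    delta_max are rejected and re-drawn.  With count_resamples, also return
    the number of rejected (pre-truncation) draws."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if spec.kind == "constant":
        out = np.full(n, spec.delta_const)
        return (out, 0) if count_resamples else out
    scale = spec.effective_scale
    out = spec.delta_min + rng.exponential(scale, size=n)
    n_rejected = 0
    bad = out > spec.delta_max
    while np.any(bad):
        n_rejected += int(bad.sum())
        out[bad] = spec.delta_min + rng.exponential(scale, size=int(bad.sum()))
        bad = out > spec.delta_max
    return (out, n_rejected) if count_resamples else out


def _split_seed(seed):
    """Independent named substreams so that e.g. changing the delay spec
    leaves the sampled topology untouched."""
    ss = np.random.SeedSequence(seed)
    topo, eff, dly, ext = ss.spawn(4)
    return (np.random.default_rng(topo), np.random.default_rng(eff),
            np.random.default_rng(dly), int(ext.generate_state(1)[0] % (2**31 - 1)))


def make_random_network(n: int, c: float,
                        efficacy_spec: EfficacySpec,
                        delay_spec: DelaySpec,
                        population_split: float = 1.0,
                        seed=0,
                        neuron: NeuronParams | None = None,
                        external: ExternalDriveSpec | None = None,
                        std: STDParams | None = None) -> NetworkModel:
    """Erdos-Renyi network: each ordered pair (i != j) is connected
    independently with probability c.  The first round(population_split * n)
    neurons are excitatory, the rest inhibitory; the efficacy spec gives the
    magnitude distribution and the sign follows the pre-synaptic population."""
    if not 0.0 <= c <= 1.0:
        raise ConfigurationError("connection probability must lie in [0, 1]")
    if n < 2:
        raise ConfigurationError("need at least 2 neurons")
    rng_topo, rng_eff, rng_dly, ext_seed = _split_seed(seed)

    mask = rng_topo.random((n, n)) < c
    np.fill_diagonal(mask, False)
    nsyn = int(mask.sum())

    n_exc = int(round(population_split * n))
    labels = np.where(np.arange(n) < n_exc, 1, -1)

    j = np.zeros((n, n))
    j[mask] = efficacy_spec.sample(nsyn, rng_eff)
    j *= labels[np.newaxis, :]  # sign by pre-synaptic (column) population

    d = np.zeros((n, n))
    d[mask] = sample_delays(delay_spec, nsyn, rng_dly)

    return NetworkModel(j_true=j, delays=d,
                        neuron=neuron or NeuronParams(),
                        external=external or ExternalDriveSpec(),
                        std=std or STDParams(),
                        labels=labels)


def make_ring_network(n: int, n_pop: int,
                      efficacy_spec: EfficacySpec,
                      delay_spec: DelaySpec,
                      seed=0,
                      c0: float = 0.134,
                      pair_scale: float = 135.0,
                      ref_scale: float = 26.1,
                      neuron: NeuronParams | None = None,
                      external: ExternalDriveSpec | None = None,
                      std: STDParams | None = None) -> NetworkModel:
    """Excitatory network of n_pop equal populations on a ring, connected with
    the distance-dependent kernel of ``spatial_connection_prob``."""
    if n % n_pop:
        raise ConfigurationError("n_pop must divide n")
    rng_topo, rng_eff, rng_dly, ext_seed = _split_seed(seed)
    per = n // n_pop
    pops = np.repeat(np.arange(1, n_pop + 1), per)

    cmat = np.empty((n_pop, n_pop))
    for a in range(1, n_pop + 1):
        for b in range(1, n_pop + 1):
            cmat[a - 1, b - 1] = spatial_connection_prob(
                a, b, n_pop, c0=c0, pair_scale=pair_scale, ref_scale=ref_scale)

    probs = cmat[pops[:, None] - 1, pops[None, :] - 1]
    mask = rng_topo.random((n, n)) < probs
    np.fill_diagonal(mask, False)
    nsyn = int(mask.sum())

    j = np.zeros((n, n))
    j[mask] = efficacy_spec.sample(nsyn, rng_eff)
    d = np.zeros((n, n))
    d[mask] = sample_delays(delay_spec, nsyn, rng_dly)

    return NetworkModel(j_true=j, delays=d,
                        neuron=neuron or NeuronParams(),
                        external=external or ExternalDriveSpec(),
                        std=std or STDParams(),
                        labels=np.ones(n, dtype=int),
                        populations=pops)


# ---------------------------------------------------------------------------
# simulation

def std_steady_state(u: float, tau_r: float, nu: float) -> float:
    """Mean available resource fraction under stationary Poisson pre-synaptic
    firing at rate nu (kHz): 1 / (1 + u * tau_r * nu)."""
    if u < 0 or tau_r < 0 or nu < 0:
        raise ValueError("u, tau_r, nu must be non-negative")
    return 1.0 / (1.0 + u * tau_r * nu)


def _sim_seed(network_seed) -> int:
    if network_seed is None:
        network_seed = 0
    return int(np.random.SeedSequence(network_seed).generate_state(1)[0] % (2**31 - 1))


_EMPTY_I64 = np.empty(0, dtype=np.int64)
_EMPTY_F64 = np.empty(0)


def simulate(network: NetworkModel, duration: float, seed=0) -> SpikeRecord:
    """Event-driven simulation; returns the spike record over [0, duration).

    The external Poisson realization (and, if j_ext_sd > 0, per-impulse
    efficacies) is the only source of randomness and is controlled by seed.
    """
    if not duration > 0:
        raise ConfigurationError("duration must be positive")
    indptr, targets, weights, dl = network.csr()
    p, e, s = network.neuron, network.external, network.std
    sim_seed = _sim_seed(seed)
    ids, times = _engine.run_lif(
        float(duration), sim_seed,
        indptr, targets, weights, dl,
        p.tau_m, p.v_rest, p.theta, p.tau_refractory,
        e.nu_ext, e.j_ext_mean, e.j_ext_sd,
        s.enabled, s.tau_r, s.u,
        _EMPTY_F64, np.zeros(network.n + 1, dtype=np.int64), _EMPTY_F64, False)
    return SpikeRecord.from_events(ids, times, network.n, duration)


def draw_poisson_train(rate: float, duration: float, rng) -> np.ndarray:
    """Arrival times of a Poisson process at `rate` (kHz) on [0, duration)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if rate <= 0:
        return np.empty(0)
    n_guess = int(rate * duration + 6 * math.sqrt(rate * duration) + 10)
    t = np.cumsum(rng.exponential(1.0 / rate, size=n_guess))
    while t.size and t[-1] < duration:
        t = np.concatenate([t, t[-1] + np.cumsum(rng.exponential(1.0 / rate, size=n_guess))])
    return t[t < duration]


def _pack_external(ext_times: list, ext_amps: list | None, j_ext: float):
    indptr = np.zeros(len(ext_times) + 1, dtype=np.int64)
    np.cumsum([len(t) for t in ext_times], out=indptr[1:])
    times = np.concatenate([np.asarray(t, dtype=float) for t in ext_times]) \
        if indptr[-1] else _EMPTY_F64
    if ext_amps is None:
        amps = np.full(indptr[-1], j_ext)
    else:
        amps = np.concatenate([np.asarray(a, dtype=float) for a in ext_amps]) \
            if indptr[-1] else _EMPTY_F64
    return times, indptr, amps


def simulate_given_external(network: NetworkModel, ext_times: list,
                            duration: float, ext_amps: list | None = None) -> SpikeRecord:
    """Event-driven simulation with a caller-supplied external spike
    realization (one sorted array of arrival times per neuron); used to
    compare the engine against the fixed-step reference on identical input."""
    indptr, targets, weights, dl = network.csr()
    p, s = network.neuron, network.std
    times, eindptr, amps = _pack_external(ext_times, ext_amps, network.external.j_ext_mean)
    ids, tsp = _engine.run_lif(
        float(duration), 0,
        indptr, targets, weights, dl,
        p.tau_m, p.v_rest, p.theta, p.tau_refractory,
        0.0, network.external.j_ext_mean, 0.0,
        s.enabled, s.tau_r, s.u,
        times, eindptr, amps, True)
    return SpikeRecord.from_events(ids, tsp, network.n, duration)


def euler_reference(network: NetworkModel, ext_times: list, duration: float,
                    dt_step: float = 0.01, ext_amps: list | None = None):
    """Fixed-step (default 0.01 ms) Euler integration of the same network on a
    given external realization.  Returns (SpikeRecord, v_trace)."""
    indptr, targets, weights, dl = network.csr()
    p = network.neuron
    times, eindptr, amps = _pack_external(ext_times, ext_amps, network.external.j_ext_mean)
    ids, tsp, vtr = _engine.run_lif_euler(
        float(duration), dt_step,
        indptr, targets, weights, dl,
        p.tau_m, p.v_rest, p.theta, p.tau_refractory,
        times, eindptr, amps)
    return SpikeRecord.from_events(ids, tsp, network.n, duration), vtr
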