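# Methods

## Simulator

Each neuron is a leaky integrate-and-fire unit: between synaptic events the
membrane potential relaxes exponentially toward rest,
V(t) = V_rest + (V(t₀) − V_rest)·exp(−(t−t₀)/τ_m); an arriving impulse adds
its efficacy (mV) instantaneously; when V ≥ θ the neuron spikes, V resets to
V_rest and stays clamped for the absolute refractory period.  Because
synapses are delta impulses, the trajectory is piecewise closed-form and the
simulation is event-driven: a single global queue holds external Poisson
arrivals and delayed recurrent arrivals, processed in (time, target neuron,
event kind, payload) order so that floating-point ties cannot make runs
platform-dependent.  Identical (network, duration, seed) runs are
bit-identical.  A fixed-step (0.01 ms) Euler integrator consuming the same
external spike realization serves as a validation oracle; on the 50-neuron
excitatory benchmark both produce 56.9 Hz on an identical input realization.

Default parameters (units: ms, mV, kHz): τ_m = 20, V_rest = V_reset = −70,
θ = −52, τ_refractory = 2, external Poisson drive 1 kHz of 0.9 mV impulses.
Impulses arriving during refractoriness leave the membrane unaffected;
pre-synaptic resource depletion still occurs (depression is pre-synaptic).

Short-term depression follows the standard resource model: every synapse
carries a fraction r ∈ [0,1]; an arriving impulse is scaled by r(t⁻), then
r ← r(1−u), and r recovers toward 1 with time constant τ_r (closed form
between arrivals).  Defaults u = 0.2, τ_r = 800 ms; the stationary mean is
⟨r⟩ = 1/(1 + u τ_r ν) for Poisson pre-synaptic firing at rate ν.

Network construction: Erdős–Rényi with per-ordered-pair probability c, or a
ring of P equal populations with kernel
c_αβ = 0.134·exp(−d(α,β)/135 − d(α,P/2)/26.1), d the circular distance
(mean probability 5.0% at P = 100).  Efficacy magnitudes come from a delta,
uniform or Gaussian distribution; the sign follows the pre-synaptic
population.  Gaussian draws are not sign-clipped (negative draws are kept
and logged).  Delays are constant or offset-exponential, re-sampled above
the cutoff; when no scale is given it is fixed so that re-sampling triggers
5% of the time, scale = (δ_max−δ_min)/ln 20 — for 1–20 ms this gives
6.34 ms and a post-truncation mean near 7 ms, the only self-consistent
reading of the stated truncation rule.  The master seed is split into named
substreams (topology, efficacies, delays, external input) so changing one
spec leaves the others' draws fixed.  External-impulse efficacy jitter, when
enabled, is drawn per impulse; a per-source draw would require an
unspecified source count.

## Binarization and correlations

Bins are half-open [t, t+dt); cells with ≥2 spikes clip to 1 and are counted
in a collision fraction (warning above 1% — the binary model assumes at most
one spike per bin).  D_ij(τ) = ⟨δS_i(t+τ)δS_j(t)⟩ is normalized per lag by
the number of valid (t, t+τ) pairs, so long lags carry no edge bias; with a
validity mask, a product enters only if both bins are valid, which makes the
masked estimate identical to computing on the concatenated valid segments
independently.  Negative lags use D_kj(−τ) = D_jk(τ).  The default grid is
0…50 ms: it covers the largest delay used anywhere (20 ms) plus the slow
correlation decay on the scale of the inter-spike interval.  Matrices are
dense; all studied networks have N ≤ 1000 and the inference subsets N ≤ 50.

Burst masking (for the bursting ring network) smooths the population count
with a 50 ms boxcar and excludes bins above 3× the median, padded by 100 ms
on each side.  No exclusion criterion is prescribed by the underlying
theory; these defaults are logged with every result.

## Two-step inference

Step one: δ̂_ij = argmax over positive lags of |D_ij(τ)| (smallest lag wins
ties — the minimum transmission time consistent with causality), sign from
the peak.  δ̂_ii is fixed to one bin.  Estimates are multiples of dt with no
sub-bin interpolation; with continuous true delays the correlogram peak
splits between the two adjacent bins, so roughly one pair in ten selects the
lower neighbour — the estimate never undershoots by a full bin, and the mean
error is the +dt/2-scale discretization bias.

Step two: per post-synaptic row, solve
D_ij(δ̂_ij) = m_i(1−m_i) Σ_k J_ik M⁽ⁱ⁾_kj with M⁽ⁱ⁾_kj = D_kj(δ̂_ij−δ̂_ik);
lags beyond the computed grid are clamped with a warning.  Every solve adds
a ridge λ = 10⁻⁶·tr(C)/N and logs the condition number.  When all lags are
equal the N systems share the matrix C, and the solver switches to a single
factorization with N right-hand sides — so the delay-aware solver with unit
lags *is* the classical one-step solver, bit for bit.  Fields invert the
mean-field magnetization equation in closed form,
h_i = 2 artanh(2m_i−1) − Σ_j J_ij m_j; neurons with m_i ∈ {0,1} are excluded
and reported.  Diagonal couplings are estimated (the sums run over all k)
but excluded from all detection metrics, since the simulator forbids
autapses.  Constant fields are used throughout: all studied regimes are
stationary after masking.

Naive mean-field inversion is exact only in the small-fluctuation limit; on
a strongly coupled two-unit chain (J = 1, h = −2) it overestimates by ~25%
while the optional exact-likelihood gradient ascent (cost N²T per step,
learning-rate halving on stalls) recovers the truth.  The mean-field route
is the default because all benchmark regimes are weakly coupled
(|J|·m ≪ 1).

## Efficacy remapping

With the membrane near threshold described by the absorbing-barrier
Ornstein–Uhlenbeck density (p(θ) = 0, p′(θ) = −2ν/σ²), the conditional
firing probability upon a pre-synaptic impulse expands into the
piecewise-quadratic coupling–efficacy relation quoted in the README; σ²
defaults to J_ext²·ν_ext (exact for a single external Poisson train; a
user-supplied σ² is accepted for other inputs), and ν_i, ν_j are taken from
the raster used for inference, not from ground truth.  The excitatory
inverse is the positive root of the quadratic; the inhibitory inverse
J = −J_ext + J_ext√(1+2J_inf) exists only on −1/2 < J_inf < 0 — estimates
below the floor are flagged unphysical rather than inverted, and estimates
in the last 5% of the invertible range are flagged as sensitivity-loss
(the forward map is flat there).  A sign/magnitude mismatch (e.g. an
excitatory-classified pair with negative coupling) is flagged inconsistent.
The depression correction multiplies estimates by (1 + u τ_r ν_j).

A quadrature oracle evaluates the un-truncated expansion: it averages, over
the uniform arrival phase within the bin and the Poisson count of external
impulses in the remainder, the linear-density mass swept across threshold,
optionally with a constant drift μ₀ between impulses.  Two facts shape the
accuracy of the closed forms, both established with this oracle and a
two-neuron simulation:

* The closed forms are leading order in ν_ext·dt.  The quadrature converges
  onto their coefficients linearly in dt, but the inhibitory branch carries
  a large k = 2 prefactor (~11% residual at dt = 0.1 ms, <1% by 0.003 ms).
* The printed expansion drops the leak drift.  Near threshold the leak is
  −(θ−V_rest)/τ_m = −0.9 mV/ms for the standard parameters; between the
  synaptic impulse and a compensating external impulse it shrinks the swept
  mass by an O(ν_ext·dt) factor with an order-one coefficient.  At
  dt = 1 ms the drift-free theory overpredicts the measured conditional
  rate of a single 0.54 mV synapse by ~30% (oracle with μ₀ = −0.9
  reproduces the measurement), so the excitatory inversion underestimates
  efficacies by ~20% at dt = 1 ms and more at larger dt.  The inhibitory
  branch has no 1/dt term and is unaffected at this order: inhibitory
  estimates land within a few percent of truth.

This is the package's main known limitation: excitatory efficacy estimates
inherit a systematic low bias of order ν_ext·dt that the quoted closed-form
inversion cannot remove; delays, signs, detection (ROC) and inhibitory
magnitudes are unaffected.  Note the drift μ₀ here is the *leak only* — the
mean external drive must not be added to it, because external impulses are
already counted discretely by the Poisson sum.

## Benchmarks, problem sizes and what they show

The preset experiments encode the benchmark parameter sets: a 50-neuron
excitatory network (c = 0.3, J = 0.9 mV, δ = 3 ms) firing at ~56 Hz; the
same with delays exponential on 1–20 ms; a mixed E/I network (N_E = N_I =
25, c = 0.1, |J| = 0.54 mV) firing at ~19 Hz; and a 1000-neuron ring of 100
populations with Gaussian efficacies (0.846 ± 0.211 mV), delays exponential
on 1–15 ms, short-term depression, and Gaussian external impulses
(0.9 ± 0.225 mV at 0.6 kHz), analyzed over the 50 most active neurons with
inter-burst masking.  Recordings default to the full lengths (500 s; 2 h for
the ring) with a `--scale` factor multiplying the duration.

The routine validation variant of the ring experiment uses 100 neurons and a
10-minute recording.  At that size the network cannot sustain collective
bursts (mean in-degree falls from 50 to 5), so the variant runs in the
stationary regime: depression is disabled — in a stationary regime it would
only rescale every efficacy by the same steady-state factor, removing the
correlogram signal a short recording needs, while its machinery is validated
separately and deterministically — and the external rate is raised to 1 kHz
to stand in for the missing recurrent drive, keeping the operating point in
the tens of Hz.  This variant demonstrates delay recovery (identity-line
R² ≈ 0.99) on the spatially structured topology; it does not exercise the
bursting dynamics themselves, which require the full-scale preset.

Synthetic data throughout are the package's own LIF simulations (plus exact
Glauber oracles for the inference layer); they emulate stationary,
asynchronously firing cortical-like networks with instantaneous synapses
and known ground truth.  They do not contain conductance synapses,
facilitation, jitter from spike sorting, unobserved neurons beyond the
external-drive abstraction, or non-stationarities other than
depression-driven bursts — so passing tests certify the estimators under
the model's own assumptions, not performance on real electrophysiology.
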