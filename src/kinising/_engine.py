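"""Numba kernels for the event-driven LIF simulator and the Glauber generator.

The LIF engine processes a single global event queue holding external Poisson
arrivals and delayed recurrent arrivals.  Between events the membrane potential
of a neuron decays exactly (closed-form exponential relaxation toward rest),
so no integration time-step is involved and spike times carry full float64
resolution.  Simultaneous events are ordered by (time, target neuron, kind,
payload) so that runs are bit-reproducible across platforms regardless of
floating-point ties.
"""

import numpy as np
from numba import njit

# event kinds
EXTERNAL = 0
RECURRENT = 1


@njit(cache=True, inline="always")
def _ev_less(t1, n1, k1, p1, t2, n2, k2, p2):
    if t1 != t2:
        return t1 < t2
    if n1 != n2:
        return n1 < n2
    if k1 != k2:
        return k1 < k2
    return p1 < p2


@njit(cache=True)
def _heap_push(ht, hn, hk, hp, size, t, n, k, p):
    i = size
    ht[i] = t
    hn[i] = n
    hk[i] = k
    hp[i] = p
    while i > 0:
        par = (i - 1) >> 1
        if _ev_less(ht[i], hn[i], hk[i], hp[i], ht[par], hn[par], hk[par], hp[par]):
            ht[i], ht[par] = ht[par], ht[i]
            hn[i], hn[par] = hn[par], hn[i]
            hk[i], hk[par] = hk[par], hk[i]
            hp[i], hp[par] = hp[par], hp[i]
            i = par
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(ht, hn, hk, hp, size):
    size -= 1
    ht[0], ht[size] = ht[size], ht[0]
    hn[0], hn[size] = hn[size], hn[0]
    hk[0], hk[size] = hk[size], hk[0]
    hp[0], hp[size] = hp[size], hp[0]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        best = i
        if l < size and _ev_less(ht[l], hn[l], hk[l], hp[l], ht[best], hn[best], hk[best], hp[best]):
            best = l
        if r < size and _ev_less(ht[r], hn[r], hk[r], hp[r], ht[best], hn[best], hk[best], hp[best]):
            best = r
        if best == i:
            break
        ht[i], ht[best] = ht[best], ht[i]
        hn[i], hn[best] = hn[best], hn[i]
        hk[i], hk[best] = hk[best], hk[i]
        hp[i], hp[best] = hp[best], hp[i]
        i = best
    return size


@njit(cache=True)
def run_lif(duration, seed,
            indptr, targets, weights, syn_delays,
            tau_m, v_rest, theta, tau_ref,
            nu_ext, j_ext_mean, j_ext_sd,
            std_on, tau_r, u,
            ext_times, ext_indptr, ext_amps, use_given_ext):
    """Event-driven simulation of a delta-synapse LIF network.

    Synapses are stored in CSR layout indexed by the *pre*-synaptic neuron:
    synapse s of neuron j (indptr[j] <= s < indptr[j+1]) targets neuron
    targets[s] with efficacy weights[s] (mV) after delay syn_delays[s] (ms).

    External drive is an independent Poisson train per neuron at rate
    nu_ext (kHz); each impulse adds j_ext_mean (optionally jittered with sd
    j_ext_sd, drawn per impulse).  If use_given_ext, the pre-generated
    arrival times/amplitudes in ext_times/ext_amps (CSR over neurons via
    ext_indptr) are used instead and no randomness is consumed.

    With std_on, each synapse carries a resource fraction r (initially 1):
    an arriving impulse is scaled by r just before depletion, then
    r <- r*(1-u), and r relaxes toward 1 with time constant tau_r between
    arrivals (closed-form update).  Depletion happens even if the target is
    refractory (depression is pre-synaptic).

    Returns (spike_neurons, spike_times), time-ordered.
    """
    np.random.seed(seed)
    n = len(indptr) - 1
    nsyn = len(targets)

    v = np.full(n, v_rest)
    last_t = np.zeros(n)
    ref_until = np.full(n, -1.0)

    r_res = np.ones(nsyn)
    r_last = np.zeros(nsyn)

    ext_ptr = np.zeros(n, dtype=np.int64)

    cap = 4096
    ht = np.empty(cap)
    hn = np.empty(cap, dtype=np.int64)
    hk = np.empty(cap, dtype=np.int64)
    hp = np.empty(cap, dtype=np.int64)
    hsize = 0

    scap = 4096
    sp_n = np.empty(scap, dtype=np.int64)
    sp_t = np.empty(scap)
    nsp = 0

    # seed the queue with the first external arrival of every neuron
    if use_given_ext:
        for i in range(n):
            if ext_indptr[i] < ext_indptr[i + 1]:
                p = ext_indptr[i]
                hsize = _heap_push(ht, hn, hk, hp, hsize, ext_times[p], i, EXTERNAL, p)
                ext_ptr[i] = p + 1
    elif nu_ext > 0.0:
        for i in range(n):
            t0 = np.random.exponential(1.0 / nu_ext)
            hsize = _heap_push(ht, hn, hk, hp, hsize, t0, i, EXTERNAL, i)

    while hsize > 0:
        t = ht[0]
        tgt = hn[0]
        kind = hk[0]
        payload = hp[0]
        hsize = _heap_pop(ht, hn, hk, hp, hsize)
        if t >= duration:
            break

        # grow heap if the next fan-out could overflow it
        need = hsize + 2
        if kind == RECURRENT:
            pass
        if need + nsyn // max(n, 1) + 2 > cap:
            newcap = cap * 2
            nht = np.empty(newcap)
            nhn = np.empty(newcap, dtype=np.int64)
            nhk = np.empty(newcap, dtype=np.int64)
            nhp = np.empty(newcap, dtype=np.int64)
            nht[:hsize] = ht[:hsize]
            nhn[:hsize] = hn[:hsize]
            nhk[:hsize] = hk[:hsize]
            nhp[:hsize] = hp[:hsize]
            ht, hn, hk, hp, cap = nht, nhn, nhk, nhp, newcap

        if kind == EXTERNAL:
            if use_given_ext:
                amp = ext_amps[payload]
                p = ext_ptr[tgt]
                if p < ext_indptr[tgt + 1]:
                    hsize = _heap_push(ht, hn, hk, hp, hsize, ext_times[p], tgt, EXTERNAL, p)
                    ext_ptr[tgt] = p + 1
            else:
                if j_ext_sd > 0.0:
                    amp = j_ext_mean + j_ext_sd * np.random.standard_normal()
                else:
                    amp = j_ext_mean
                tn = t + np.random.exponential(1.0 / nu_ext)
                hsize = _heap_push(ht, hn, hk, hp, hsize, tn, tgt, EXTERNAL, tgt)
        else:
            s = payload
            w = weights[s]
            if std_on:
                r = 1.0 - (1.0 - r_res[s]) * np.exp(-(t - r_last[s]) / tau_r)
                amp = w * r
                r_res[s] = r * (1.0 - u)
                r_last[s] = t
            else:
                amp = w

        if t < ref_until[tgt]:
            continue  # impulse has no effect on a refractory membrane

        v[tgt] = v_rest + (v[tgt] - v_rest) * np.exp(-(t - last_t[tgt]) / tau_m)
        v[tgt] += amp
        last_t[tgt] = t
        if v[tgt] >= theta:
            if nsp == scap:
                scap *= 2
                nn = np.empty(scap, dtype=np.int64)
                tt = np.empty(scap)
                nn[:nsp] = sp_n[:nsp]
                tt[:nsp] = sp_t[:nsp]
                sp_n, sp_t = nn, tt
            sp_n[nsp] = tgt
            sp_t[nsp] = t
            nsp += 1
            v[tgt] = v_rest
            ref_until[tgt] = t + tau_ref

            a = indptr[tgt]
            b = indptr[tgt + 1]
            if hsize + (b - a) + 2 > cap:
                newcap = cap
                while hsize + (b - a) + 2 > newcap:
                    newcap *= 2
                nht = np.empty(newcap)
                nhn = np.empty(newcap, dtype=np.int64)
                nhk = np.empty(newcap, dtype=np.int64)
                nhp = np.empty(newcap, dtype=np.int64)
                nht[:hsize] = ht[:hsize]
                nhn[:hsize] = hn[:hsize]
                nhk[:hsize] = hk[:hsize]
                nhp[:hsize] = hp[:hsize]
                ht, hn, hk, hp, cap = nht, nhn, nhk, nhp, newcap
            for s in range(a, b):
                hsize = _heap_push(ht, hn, hk, hp, hsize,
                                   t + syn_delays[s], targets[s], RECURRENT, s)

    return sp_n[:nsp].copy(), sp_t[:nsp].copy()


@njit(cache=True)
def run_lif_euler(duration, dt_step,
                  indptr, targets, weights, syn_delays,
                  tau_m, v_rest, theta, tau_ref,
                  ext_times, ext_indptr, ext_amps):
    """Fixed-step Euler reference integrator (validation oracle).

    Consumes a pre-generated external spike realization so that it can be
    compared against the event-driven engine on identical input.  Recurrent
    and external impulses are applied at the start of the step containing
    their arrival time.  Returns (spike_neurons, spike_times, v_trace) where
    v_trace is the full membrane trajectory, shape (n, n_steps).
    """
    n = len(indptr) - 1
    nsteps = int(np.ceil(duration / dt_step))
    v = np.full(n, v_rest)
    ref_steps_left = np.zeros(n, dtype=np.int64)
    vtr = np.empty((n, nsteps))

    # per-step impulse accumulator built from a delayed-arrival buffer
    maxd = 0.0
    for s in range(len(syn_delays)):
        if syn_delays[s] > maxd:
            maxd = syn_delays[s]
    buf_len = int(np.ceil(maxd / dt_step)) + 2
    buf = np.zeros((buf_len, n))

    ext_ptr = ext_indptr[:-1].copy()

    sp_n_list = np.empty(100000, dtype=np.int64)
    sp_t_list = np.empty(100000)
    nsp = 0

    ref_steps = int(np.round(tau_ref / dt_step))

    for step in range(nsteps):
        t = step * dt_step
        slot = step % buf_len
        # external arrivals due in [t, t+dt_step)
        for i in range(n):
            p = ext_ptr[i]
            while p < ext_indptr[i + 1] and ext_times[p] < t + dt_step:
                if ext_times[p] >= t:
                    buf[slot, i] += ext_amps[p]
                    p += 1
                else:
                    p += 1
            ext_ptr[i] = p
        for i in range(n):
            if ref_steps_left[i] > 0:
                ref_steps_left[i] -= 1
                v[i] = v_rest
            else:
                v[i] += (-(v[i] - v_rest) / tau_m) * dt_step + buf[slot, i]
                if v[i] >= theta:
                    if nsp < len(sp_n_list):
                        sp_n_list[nsp] = i
                        sp_t_list[nsp] = t
                        nsp += 1
                    v[i] = v_rest
                    ref_steps_left[i] = ref_steps
                    for s in range(indptr[i], indptr[i + 1]):
                        dslot = (step + int(np.round(syn_delays[s] / dt_step))) % buf_len
                        buf[dslot, targets[s]] += weights[s]
            vtr[i, step] = v[i]
        buf[slot, :] = 0.0

    return sp_n_list[:nsp].copy(), sp_t_list[:nsp].copy(), vtr


@njit(cache=True)
def run_glauber(J, h, dbins, T, seed, burn_in):
    """Parallel Glauber dynamics with per-pair interaction lags (bins).

    S_i(t) is drawn with P(S_i=1) = logistic(H_i), where
    H_i = h_i + sum_j J_ij S_j(t - dbins_ij); dbins_ij >= 1, and a matrix of
    ones recovers the standard one-step kinetic Ising update.
    """
    n = J.shape[0]
    np.random.seed(seed)
    dmax = 1
    for i in range(n):
        for j in range(n):
            if dbins[i, j] > dmax:
                dmax = dbins[i, j]
    total = T + burn_in + dmax
    S = np.zeros((n, total), dtype=np.uint8)
    for t in range(dmax, total):
        for i in range(n):
            H = h[i]
            for j in range(n):
                if J[i, j] != 0.0:
                    H += J[i, j] * S[j, t - dbins[i, j]]
            p = 1.0 / (1.0 + np.exp(-H))
            if np.random.random() < p:
                S[i, t] = 1
    return S[:, dmax + burn_in:]
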