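"""Numba inner loops for the bin-resolved simulations.

These kernels advance one chunk of a simulation at a time.  All state
(membrane potential, conductances, plasticity traces, weights) is carried
across chunk boundaries in the arrays passed in, so chunking has no effect
on the results.  Spike-pair bookkeeping uses lazily decayed traces with
last-update timestamps; a post spike sweeps over all plastic synapses,
pre-spike events touch only their own synapse.

Conventions (shared with :mod:`eibstdp.plasticity`):
 * within a bin: presynaptic events first, then the membrane/rate update,
   then a possible postsynaptic spike;
 * same-bin pre/post pairs contribute no weight change;
 * weights hard-clipped to [0, 1] after every update.
"""

import numpy as np
from numba import njit

__all__ = ["lif_euler", "lif_plastic_chunk", "linear_plastic_chunk"]


@njit(cache=True)
def lif_euler(gE, gI, dt, cm, gl, vrest, vth, vreset, eex, ein, v0):
    """Forward-Euler integration of the conductance LIF given conductances.

    Returns (spike bin indices, voltage trace of length n+1 incl. v0).
    """
    n = gE.shape[0]
    v = np.empty(n + 1)
    v[0] = v0
    spikes = np.empty(n, np.int64)
    ns = 0
    vv = v0
    for t in range(n):
        vv += (dt / cm) * (
            -gl * (vv - vrest) - gE[t] * (vv - eex) - gI[t] * (vv - ein)
        )
        if vv >= vth:
            vv = vreset
            spikes[ns] = t
            ns += 1
        v[t + 1] = vv
    return spikes[:ns], v


@njit(cache=True, inline="always")
def _depress(w, i, lam, lam_rel, alpha, mu, post_val, post_last, pop_of,
             tau_pop, dt, tg, pre_val, pre_last):
    p = pop_of[i]
    if post_val[p] > 0.0:
        pv = post_val[p] * np.exp(-(tg - post_last[p]) * dt / tau_pop[p])
        wi = w[i] - lam * lam_rel[i] * alpha[i] * (w[i] ** mu[i]) * pv
        if wi < 0.0:
            wi = 0.0
        elif wi > 1.0:
            wi = 1.0
        w[i] = wi
    # fold this pre spike into the synapse's trace
    if pre_val[i] > 0.0:
        pre_val[i] = pre_val[i] * np.exp(-(tg - pre_last[i]) * dt / tau_pop[p]) + 1.0
    else:
        pre_val[i] = 1.0
    pre_last[i] = tg


@njit(cache=True, inline="always")
def _potentiate_all(w, lam, lam_rel, mu, plastic, pop_of, tau_pop, dt, tg,
                    pre_val, pre_last, post_val, post_last):
    m = w.shape[0]
    for i in range(m):
        if plastic[i] and pre_val[i] > 0.0:
            pv = pre_val[i] * np.exp(-(tg - pre_last[i]) * dt / tau_pop[pop_of[i]])
            if pre_last[i] == tg:
                pv -= 1.0  # exclude the same-bin pre spike
            if pv > 0.0:
                wi = w[i] + lam * lam_rel[i] * ((1.0 - w[i]) ** mu[i]) * pv
                if wi > 1.0:
                    wi = 1.0
                w[i] = wi
    for p in range(tau_pop.shape[0]):
        if post_val[p] > 0.0:
            post_val[p] = post_val[p] * np.exp(-(tg - post_last[p]) * dt / tau_pop[p]) + 1.0
        else:
            post_val[p] = 1.0
        post_last[p] = tg


@njit(cache=True)
def lif_plastic_chunk(
    n_bins, t0, dt,
    ev_bin, ev_syn,
    w, g_scale, is_exc, plastic, alpha, mu, lam_rel, pop_of,
    tau_pop, lam,
    bg_exc, bg_inh,
    cm, gl, vrest, vth, vreset, eex, ein, decay_syn,
    neuron_state,
    pre_val, pre_last, post_val, post_last,
    out_spikes,
):
    """One chunk of the closed loop: inputs -> conductance LIF -> STDP.

    ``ev_bin``/``ev_syn`` are chunk-local spike events of the explicitly
    represented synapses, sorted by bin.  ``bg_exc``/``bg_inh`` are per-bin
    conductance increments (nS) of collapsed fixed-weight backgrounds.
    ``neuron_state = [V, gE, gI]`` is updated in place.  Returns the number
    of postsynaptic spikes written to ``out_spikes`` (global bin indices).
    """
    V = neuron_state[0]
    gE = neuron_state[1]
    gI = neuron_state[2]
    ns = 0
    ep = 0
    n_ev = ev_bin.shape[0]
    for t in range(n_bins):
        gE = gE * decay_syn + bg_exc[t]
        gI = gI * decay_syn + bg_inh[t]
        tg = t0 + t
        while ep < n_ev and ev_bin[ep] == t:
            i = ev_syn[ep]
            if is_exc[i]:
                gE += g_scale[i] * w[i]
            else:
                gI += g_scale[i] * w[i]
            if plastic[i]:
                _depress(w, i, lam, lam_rel, alpha, mu, post_val, post_last,
                         pop_of, tau_pop, dt, tg, pre_val, pre_last)
            ep += 1
        V += (dt / cm) * (
            -gl * (V - vrest) - gE * (V - eex) - gI * (V - ein)
        )
        if V >= vth:
            V = vreset
            out_spikes[ns] = tg
            ns += 1
            _potentiate_all(w, lam, lam_rel, mu, plastic, pop_of, tau_pop,
                            dt, tg, pre_val, pre_last, post_val, post_last)
    neuron_state[0] = V
    neuron_state[1] = gE
    neuron_state[2] = gI
    return ns


@njit(cache=True)
def linear_plastic_chunk(
    n_bins, t0, dt,
    ev_bin, ev_syn,
    w, sign_mult, plastic, alpha, mu, lam_rel, pop_of,
    tau_pop, lam,
    e_prob,
    ring, ring_pos,
    u,
    pre_val, pre_last, post_val, post_last,
    out_spikes,
):
    """One chunk of the delayed linear Poisson neuron with online STDP.

    The postsynaptic spike probability per bin is
    ``clip(e_prob + sum_j s_j w_j x_j(t - d), 0, 1)`` with ``s_j = +1`` for
    excitatory and ``-1`` for inhibitory synapses; the delayed weighted
    drive is carried in the ring buffer ``ring`` (length = delay in bins).
    ``u`` holds one uniform variate per bin.
    """
    ns = 0
    ep = 0
    n_ev = ev_bin.shape[0]
    d = ring.shape[0]
    for t in range(n_bins):
        tg = t0 + t
        s_now = 0.0
        while ep < n_ev and ev_bin[ep] == t:
            i = ev_syn[ep]
            s_now += sign_mult[i] * w[i]
            if plastic[i]:
                _depress(w, i, lam, lam_rel, alpha, mu, post_val, post_last,
                         pop_of, tau_pop, dt, tg, pre_val, pre_last)
            ep += 1
        pos = ring_pos[0]
        s_del = ring[pos]
        ring[pos] = s_now
        ring_pos[0] = (pos + 1) % d
        p = e_prob + s_del
        if p < 0.0:
            p = 0.0
        elif p > 1.0:
            p = 1.0
        if u[t] < p:
            out_spikes[ns] = tg
            ns += 1
            _potentiate_all(w, lam, lam_rel, mu, plastic, pop_of, tau_pop,
                            dt, tg, pre_val, pre_last, post_val, post_last)
    return ns
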