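"""Temporally asymmetric Hebbian STDP, additive over all spike pairs.

A pair with the presynaptic spike leading the postsynaptic one by
``s = t_post - t_pre > 0`` potentiates the weight,

    dw = +lambda * (1 - w)**mu * K(s),        K(s) = exp(-s / tau)

and the reversed order depresses it,

    dw = -lambda * alpha * w**mu * K(|s|).

``mu`` interpolates between additive (mu=0) and multiplicative (mu=1)
weight dependence; ``alpha`` is the depression/potentiation area ratio.
The same family applies to inhibitory and excitatory synapses (with their
own parameters).  The rule is additive over *all* past pre/post pairs,
which an exponential-trace bookkeeping realises exactly: on a postsynaptic
spike each weight moves by ``lambda * (1-w)**mu`` times the decayed sum of
past presynaptic spikes, and symmetrically for depression.

Conventions shared by every implementation in the package (and by the
brute-force oracle used to test them):

* simultaneous (same-bin) pre/post spikes contribute nothing -- the two
  branches of the rule disagree at s = 0 and the event has vanishing
  measure in continuous time;
* weights are hard-clipped to [0, 1] after every update (required at
  mu = 0 where the soft bounds vanish);
* within one bin, presynaptic events are processed before a postsynaptic
  spike is detected, so a pre spike never sees a same-bin post spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STDPRule",
    "SynapsePopulationState",
    "pair_update",
    "online_step",
    "allpairs_reference",
]


@dataclass(frozen=True)
class STDPRule:
    """Parameters of one plasticity rule.

    Attributes
    ----------
    learning_rate
        Maximal potentiation step ``lambda`` (the kernel has amplitude 1
        at zero lag).
    alpha
        Ratio of the depression to the potentiation scale.  ``alpha < 1``
        keeps inhibitory weights away from zero; excitatory rules
        conventionally use ``alpha`` slightly above 1 so total depression
        exceeds total potentiation.
    mu
        Weight-dependence exponent in [0, 1].
    tau
        Time constant of the exponential temporal filter, ms.
    sign
        'E' or 'I'; which conductance the synapse drives.  The update rule
        itself is identical for both.
    kernel
        'exp' (default) or 'gamma'.  The gamma-shaped filter
        ``(s/tau) * exp(1 - s/tau)`` (amplitude 1 at its peak s = tau) is
        exposed as an alternative matching measured inhibitory STDP curves
        with a delayed peak.
    """

    learning_rate: float
    alpha: float
    mu: float
    tau: float
    sign: str = "I"
    kernel: str = "exp"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive (ms)")
        if self.sign not in ("E", "I"):
            raise ValueError("sign must be 'E' or 'I'")
        if self.kernel not in ("exp", "gamma"):
            raise ValueError("kernel must be 'exp' or 'gamma'")

    def temporal_filter(self, s) -> np.ndarray:
        """K(s) for lag s >= 0 in ms."""
        s = np.asarray(s, dtype=float)
        if self.kernel == "exp":
            return np.exp(-s / self.tau)
        return (s / self.tau) * np.exp(1.0 - s / self.tau)


@dataclass
class SynapsePopulationState:
    """Weights plus the decaying pre/post spike sums of one population."""

    weights: np.ndarray
    pre_traces: np.ndarray = None  # type: ignore[assignment]
    post_trace: float = 0.0
    time: float = 0.0              # ms

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")
        if self.pre_traces is None:
            self.pre_traces = np.zeros_like(self.weights)
        else:
            self.pre_traces = np.asarray(self.pre_traces, dtype=float)


def pair_update(w: float, delta_t: float, rule: STDPRule) -> float:
    """Weight change from a single pre/post spike pair.

    Parameters
    ----------
    w
        Current weight in [0, 1].
    delta_t
        ``t_post - t_pre`` in ms.  Positive (causal) lags potentiate,
        negative lags depress, zero contributes nothing.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight {w} outside [0, 1]")
    if delta_t > 0:
        return rule.learning_rate * (1.0 - w) ** rule.mu * float(
            rule.temporal_filter(delta_t)
        )
    if delta_t < 0:
        return -rule.learning_rate * rule.alpha * w ** rule.mu * float(
            rule.temporal_filter(-delta_t)
        )
    return 0.0


def online_step(
    state: SynapsePopulationState,
    pre_bin: np.ndarray,
    post_bin: bool,
    rule: STDPRule,
    dt: float,
) -> SynapsePopulationState:
    """Advance the trace-based online update by one bin (in place).

    On a presynaptic spike at synapse i the weight is depressed against
    the postsynaptic trace; on a postsynaptic spike every weight is
    potentiated against its presynaptic trace (excluding same-bin pre
    spikes).  Traces then decay by ``exp(-dt/tau)``.  Exact for the
    all-pairs rule: the pair sum is linear in past spikes.

    Only the exponential temporal filter admits this single-trace scheme;
    a configuration error is raised otherwise.
    """
    if rule.kernel != "exp":
        raise ValueError("online trace updates require the exponential kernel")
    if dt <= 0:
        raise ValueError("dt must be positive")
    lam = rule.learning_rate
    pre_bin = np.asarray(pre_bin)
    pre_idx = np.flatnonzero(pre_bin)
    w = state.weights
    # depression at pre spikes (post trace excludes any same-bin post spike:
    # it has not been detected yet at this point within the bin)
    if pre_idx.size:
        w[pre_idx] -= lam * rule.alpha * w[pre_idx] ** rule.mu * state.post_trace
        np.clip(w, 0.0, 1.0, out=w)
    # potentiation at a post spike; traces have not been incremented with
    # this bin's pre spikes yet, so same-bin pairs are excluded automatically
    if post_bin:
        w += lam * (1.0 - w) ** rule.mu * state.pre_traces
        np.clip(w, 0.0, 1.0, out=w)
    # increment traces with this bin's spikes, then decay everything
    decay = np.exp(-dt / rule.tau)
    state.pre_traces[pre_idx] += 1.0
    state.pre_traces *= decay
    state.post_trace = (state.post_trace + (1.0 if post_bin else 0.0)) * decay
    state.time += dt
    return state


def allpairs_reference(
    pre_times: np.ndarray,
    post_times: np.ndarray,
    w0: float,
    rule: STDPRule,
) -> np.ndarray:
    """Brute-force oracle: explicit double loop over all spike pairs.

    Events (pre and post spikes) are processed in time order; at each
    event the weight is updated sequentially against every strictly
    earlier spike of the opposite train, with clipping after each pair.
    Returns the weight after each event (prepended with ``w0``).

    Sequential per-pair application differs from the trace-based update by
    O(lambda^2) when ``mu > 0`` and is identical at ``mu = 0``; this is
    what makes it an independent check.
    """
    pre_times = np.asarray(pre_times, dtype=float)
    post_times = np.asarray(post_times, dtype=float)
    if np.any(np.diff(pre_times) < 0) or np.any(np.diff(post_times) < 0):
        raise ValueError("spike times must be sorted")
    events = [(t, 0) for t in pre_times] + [(t, 1) for t in post_times]
    # at equal times process pre before post, matching the online scheme
    events.sort(key=lambda e: (e[0], e[1]))
    w = float(w0)
    traj = [w]
    for t, is_post in events:
        if is_post:
            partners = pre_times[pre_times < t]
            for tp in partners:
                w = min(1.0, max(0.0, w + pair_update(w, t - tp, rule)))
        else:
            partners = post_times[post_times < t]
            for tp in partners:
                w = min(1.0, max(0.0, w + pair_update(w, tp - t, rule)))
        traj.append(w)
    return np.asarray(traj)
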