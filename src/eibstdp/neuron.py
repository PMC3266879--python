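"""Postsynaptic response models.

Two neurons are provided:

* a conductance-based leaky integrate-and-fire cell,

      C_m dV/dt = -(V - V_rest)/R_m - g_E(t) (V - E_ex) - g_I(t) (V - E_in),

  integrated with the forward Euler method on the input bin grid; a spike
  is emitted when V crosses threshold within a bin and V is reset;

* the delayed linear Poisson neuron used by the mean-field theory, whose
  instantaneous rate is a delayed linear sum of its inputs floored at zero.

Synaptic conductances are discrete convolutions of the weighted input
spike trains with a causal exponential kernel (amplitude 1 at onset,
truncated at ``kernel_cutoff``) and carry a population-size scaling factor
``A(N) = reference_size / N`` that keeps the mean synaptic current
invariant when the number of synapses changes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .spikegen import SpikeTrainSet

__all__ = [
    "LIFParams",
    "ConductanceScaling",
    "conductance_series",
    "simulate_lif",
    "linear_neuron",
]


@dataclass(frozen=True)
class LIFParams:
    """Conductance LIF parameters (canonical cortical-cell values).

    Units: capacitance pF, resistance MOhm, potentials mV, times ms.  The
    defaults give a 20 ms membrane time constant; the membrane is reset to
    the resting potential after a spike.
    """

    membrane_capacitance: float = 200.0
    membrane_resistance: float = 100.0
    resting_potential: float = -70.0
    threshold: float = -54.0
    reset_potential: float = -70.0
    excitatory_reversal: float = 0.0
    inhibitory_reversal: float = -70.0
    synaptic_kernel_tau: float = 5.0
    kernel_cutoff: float = 50.0
    dt: float = 0.1

    def __post_init__(self):
        if not self.reset_potential <= self.resting_potential < self.threshold:
            raise ValueError("need reset <= resting < threshold")
        if not self.inhibitory_reversal <= self.resting_potential < self.excitatory_reversal:
            raise ValueError("need E_in <= V_rest < E_ex")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kernel_cutoff < 5.0 * self.synaptic_kernel_tau:
            raise ValueError("kernel_cutoff must be >= 5 * synaptic_kernel_tau")
        if self.membrane_capacitance <= 0 or self.membrane_resistance <= 0:
            raise ValueError("capacitance and resistance must be positive")

    @property
    def leak_conductance(self) -> float:
        """1/R_m in nS."""
        return 1000.0 / self.membrane_resistance

    @property
    def membrane_tau(self) -> float:
        """R_m * C_m in ms."""
        return self.membrane_resistance * self.membrane_capacitance / 1000.0

    def with_dt(self, dt: float) -> "LIFParams":
        return replace(self, dt=dt)

    def synaptic_kernel(self) -> np.ndarray:
        """Causal exponential kernel on the bin grid, amplitude 1 at onset."""
        n = int(round(self.kernel_cutoff / self.dt))
        return np.exp(-np.arange(n) * self.dt / self.synaptic_kernel_tau)


@dataclass(frozen=True)
class ConductanceScaling:
    """Population-size scaling of the peak synaptic conductances.

    The per-synapse peak conductances ``base_*`` refer to a reference
    population of ``reference_size`` synapses; a population of N synapses
    is amplified by ``A(N) = reference_size / N`` so the mean synaptic
    current is independent of N at a fixed mean weight.
    """

    n_exc: int = 1000
    n_inh: int = 200
    reference_size: int = 1000
    base_excitatory_conductance: float = 0.2  # nS
    base_inhibitory_conductance: float = 1.0  # nS

    def __post_init__(self):
        for n in (self.n_exc, self.n_inh, self.reference_size):
            if n is not None and n <= 0:
                raise ValueError("population sizes must be positive")

    def factor(self, n: int) -> float:
        """Scaling factor A(N) = reference_size / N."""
        if n <= 0:
            raise ValueError("population size must be positive")
        return self.reference_size / n

    @property
    def factor_exc(self) -> float:
        return self.factor(self.n_exc)

    @property
    def factor_inh(self) -> float:
        return self.factor(self.n_inh)

    def peak_conductance(self, sign: str, n: int | None = None) -> float:
        """A(N) * gbar for one population, nS per unit weight per spike."""
        if sign == "E":
            return self.factor(self.n_exc if n is None else n) * self.base_excitatory_conductance
        if sign == "I":
            return self.factor(self.n_inh if n is None else n) * self.base_inhibitory_conductance
        raise ValueError("sign must be 'E' or 'I'")


def conductance_series(
    trains: SpikeTrainSet,
    weights: np.ndarray,
    scaling: ConductanceScaling,
    params: LIFParams,
    sign: str = "E",
) -> np.ndarray:
    """Summed synaptic conductance (nS per bin) of one input population.

    g(t) = A(N) * gbar * sum_i w_i sum_spikes K_syn(t - t_spike) with the
    truncated exponential kernel of ``params``.  Linear in the weights and
    non-negative everywhere.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != trains.n_neurons:
        raise ValueError(
            f"{weights.shape[0]} weights for {trains.n_neurons} neurons"
        )
    if not np.isclose(trains.dt, params.dt):
        raise ValueError(f"trains.dt={trains.dt} differs from params.dt={params.dt}")
    n = trains.n_neurons
    drive = weights @ trains.bins.astype(float)
    kernel = params.synaptic_kernel()
    g = np.convolve(drive, kernel)[: trains.n_bins]
    return scaling.peak_conductance(sign, n) * g


def simulate_lif(
    params: LIFParams,
    g_exc: np.ndarray,
    g_inh: np.ndarray,
    v0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler LIF run on precomputed conductance series.

    Returns ``(spike_bins, voltage)`` where ``voltage`` has one more
    sample than the input (initial condition included).  Threshold
    crossings are detected at the end of each bin; the membrane is reset
    to ``reset_potential``.
    """
    g_exc = np.ascontiguousarray(g_exc, dtype=np.float64)
    g_inh = np.ascontiguousarray(g_inh, dtype=np.float64)
    if g_exc.shape != g_inh.shape:
        raise ValueError("g_exc and g_inh must have equal length")
    if not (np.all(np.isfinite(g_exc)) and np.all(np.isfinite(g_inh))):
        raise ValueError("conductances must be finite")
    if v0 is None:
        v0 = params.resting_potential
    spikes, v = _kernels.lif_euler(
        g_exc, g_inh, params.dt, params.membrane_capacitance,
        params.leak_conductance, params.resting_potential, params.threshold,
        params.reset_potential, params.excitatory_reversal,
        params.inhibitory_reversal, float(v0),
    )
    return spikes, v


def lif_rate_constant_input(params: LIFParams, g_exc: float, g_inh: float) -> float:
    """Closed-form firing rate (spikes/s) under constant conductances.

    With constant input the membrane relaxes exponentially towards
    ``V_inf`` with time constant ``C/g_tot``; the interspike interval is
    the time from reset to threshold, or the rate is zero when ``V_inf``
    is subthreshold.  Used as an independent oracle for the Euler
    integrator.
    """
    gl = params.leak_conductance
    g_tot = gl + g_exc + g_inh
    v_inf = (
        gl * params.resting_potential
        + g_exc * params.excitatory_reversal
        + g_inh * params.inhibitory_reversal
    ) / g_tot
    if v_inf <= params.threshold:
        return 0.0
    tau = params.membrane_capacitance / g_tot  # ms
    isi = tau * np.log(
        (v_inf - params.reset_potential) / (v_inf - params.threshold)
    )
    return 1000.0 / isi


def linear_neuron(
    excitatory_drive: float,
    weights_exc: np.ndarray | None,
    weights_inh: np.ndarray | None,
    trains_exc: SpikeTrainSet | None,
    trains_inh: SpikeTrainSet | None,
    delay: float,
    seed: int,
) -> np.ndarray:
    """Spike train of the delayed linear Poisson neuron.

    The per-bin firing probability is

        p(t) = e*dt + sum_j wE_j xE_j(t - d) - sum_j wI_j xI_j(t - d)

    clipped to [0, 1] (a neuron with net inhibitory input will not fire).
    ``excitatory_drive`` e is in spikes/s; the delay d must be at least one
    bin to preserve causality.  Returns spike bin indices.
    """
    if excitatory_drive < 0:
        raise ValueError("excitatory drive must be non-negative")
    ref = trains_exc if trains_exc is not None else trains_inh
    if ref is None:
        raise ValueError("at least one input population required")
    dt = ref.dt
    if delay < dt:
        raise ValueError("delay must be >= one bin for causality")
    d = int(round(delay / dt))
    n = ref.n_bins
    p = np.full(n, excitatory_drive * dt / 1000.0)
    for w, tr, s in ((weights_exc, trains_exc, 1.0), (weights_inh, trains_inh, -1.0)):
        if tr is None:
            continue
        w = np.asarray(w, dtype=float)
        if w.shape[0] != tr.n_neurons:
            raise ValueError("one weight per input neuron required")
        drive = w @ tr.bins.astype(float)
        p[d:] += s * drive[:-d]
    np.clip(p, 0.0, 1.0, out=p)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 5)))
    return np.flatnonzero(rng.random(n) < p)
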