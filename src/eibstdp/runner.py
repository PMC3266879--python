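"""Config-driven closed-loop learning experiments.

A run couples input generation -> postsynaptic neuron -> online STDP in
chunks of :data:`eibstdp.spikegen.CHUNK_MS` simulated milliseconds; all
random substreams are derived from one master seed with fixed offsets, so
a run is a deterministic function of (config, seed) and chunking never
affects the result.  Fixed-weight uncorrelated background populations are
collapsed to per-bin binomial spike counts, which makes the single-synapse
protocols cheap; plastic or correlated populations are simulated
neuron-by-neuron.

The figure protocols (`fig2` ... `fig10`) reproduce the study's
experiments at a configurable scale: spike-triggered-average measurement
of the linear-response dip, single-synapse weight-density evolution,
asymptotic weight versus the plasticity parameters with the mean-field
overlay, population convergence under block correlations, balance curves,
and excitatory subgroup segregation.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .neuron import ConductanceScaling, LIFParams
from .plasticity import STDPRule
from .spikegen import CHUNK_MS, CorrelationSpec, _chunk_events, _stream, _bin_probability

__all__ = [
    "PopulationConfig",
    "ExperimentConfig",
    "RunRecord",
    "learning_rate_schedule",
    "run_experiment",
    "reproduce_figure",
    "FIGURE_PROTOCOLS",
]

_KIND_BACKGROUND = 4
_KIND_NEURON = 5


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

def learning_rate_schedule(progress: float, mode: str = "accelerated",
                           base: float = 1e-3) -> float:
    """Learning rate as a function of run progress rho in [0, 1].

    ``constant`` returns ``base`` throughout.  ``accelerated`` returns

        lambda(rho) = base * (1 + 15 * exp(-rho / 0.06)),

    which starts at ``16 * base`` and decays quickly, leaving the trailing
    70% of the run within 10% of ``base``.  Used when only the asymptotic
    weights matter.
    """
    if not 0.0 <= progress <= 1.0:
        raise ValueError("progress must lie in [0, 1]")
    if mode == "constant":
        return base
    if mode == "accelerated":
        return base * (1.0 + 15.0 * np.exp(-progress / 0.06))
    raise ValueError(f"unknown schedule mode {mode!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationConfig:
    """One presynaptic population of an experiment.

    ``initial_weights`` is a scalar, an array, or the string ``'spread'``
    (evenly spaced from 1 down to 0 across the population, the convention
    of the population-learning figures).  A non-plastic single-group
    population with zero correlations and scalar weights is simulated in
    collapsed form (binomial spike counts per bin).
    """

    name: str
    sign: str                    # 'E' or 'I'
    spec: CorrelationSpec
    plastic: bool = False
    rule: STDPRule | None = None
    initial_weights: object = 0.5

    def __post_init__(self):
        if self.sign not in ("E", "I"):
            raise ValueError("sign must be 'E' or 'I'")
        if self.plastic and self.rule is None:
            raise ValueError(f"plastic population {self.name!r} needs a rule")

    @property
    def collapsible(self) -> bool:
        return (
            not self.plastic
            and len(self.spec.group_sizes) == 1
            and self.spec.within_corr[0] == 0.0
            and np.ndim(self.initial_weights) == 0
            and not isinstance(self.initial_weights, str)
        )

    def weights_array(self) -> np.ndarray:
        n = self.spec.n_neurons
        if isinstance(self.initial_weights, str):
            if self.initial_weights != "spread":
                raise ValueError(f"unknown initial weight mode {self.initial_weights!r}")
            return np.linspace(1.0, 0.0, n)
        w = np.broadcast_to(np.asarray(self.initial_weights, dtype=float), (n,)).copy()
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("initial weights must lie in [0, 1]")
        return w


@dataclass(frozen=True)
class ExperimentConfig:
    """Full specification of one closed-loop run."""

    populations: tuple[PopulationConfig, ...]
    duration: float                      # ms
    seed: int = 0
    neuron_model: str = "lif"            # 'lif' or 'linear'
    lif: LIFParams = field(default_factory=LIFParams)
    scaling: ConductanceScaling = field(default_factory=ConductanceScaling)
    drive: float = 0.0                   # spikes/s, linear neuron only
    delay: float = 0.1                   # ms, linear neuron only
    dt: float | None = None              # defaults to lif.dt
    schedule: str = "constant"
    record_post_spikes: bool = False
    record_inputs: tuple[str, ...] = ()

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.neuron_model not in ("lif", "linear"):
            raise ValueError("neuron_model must be 'lif' or 'linear'")
        if not any(p.plastic for p in self.populations) and not self.populations:
            raise ValueError("at least one population required")
        if self.neuron_model == "linear" and self.delay < self.bin_width:
            raise ValueError("linear-neuron delay must be at least one bin")

    @property
    def bin_width(self) -> float:
        return self.lif.dt if self.dt is None else self.dt


@dataclass
class RunRecord:
    """Everything a run produced, reproducible from (config, seed)."""

    config: ExperimentConfig
    times: np.ndarray                # snapshot times, ms
    weights: np.ndarray              # (n_snapshots, n_explicit_synapses)
    syn_population: np.ndarray       # population name per explicit synapse
    syn_sign: np.ndarray
    post_rate_series: np.ndarray     # spikes/s per chunk
    lambda_series: np.ndarray        # lambda multiplier per chunk
    post_spikes: np.ndarray | None = None     # ms
    input_events: dict = field(default_factory=dict)
    wall_time: float = 0.0
    n_steps: int = 0

    @property
    def post_rate(self) -> float:
        return float(self.post_rate_series.mean()) if self.post_rate_series.size else 0.0

    def final_weights(self, population: str) -> np.ndarray:
        return self.weights[-1, self.syn_population == population]

    def trajectory(self, population: str) -> np.ndarray:
        """(n_synapses, n_snapshots) weight trajectories of one population."""
        return self.weights[:, self.syn_population == population].T

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.weights).tobytes())
        h.update(np.ascontiguousarray(self.post_rate_series).tobytes())
        return h.hexdigest()

    def manifest(self) -> dict:
        return {
            "seed": self.config.seed,
            "duration_ms": self.config.duration,
            "neuron_model": self.config.neuron_model,
            "populations": [
                {"name": p.name, "sign": p.sign, "n": p.spec.n_neurons,
                 "plastic": p.plastic}
                for p in self.config.populations
            ],
            "post_rate_hz": self.post_rate,
            "hash": self.content_hash(),
            "wall_time_s": self.wall_time,
            "n_steps": self.n_steps,
        }

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times_ms", data=self.times)
            f.create_dataset("weights", data=self.weights)
            f.create_dataset("syn_population", data=self.syn_population.astype("S16"))
            f.create_dataset("post_rate_series", data=self.post_rate_series)
            f.create_dataset("lambda_series", data=self.lambda_series)
            if self.post_spikes is not None:
                f.create_dataset("post_spikes_ms", data=self.post_spikes)
            f.attrs["manifest"] = json.dumps(self.manifest())


# ---------------------------------------------------------------------------
# the run loop
# ---------------------------------------------------------------------------

def run_experiment(config: ExperimentConfig) -> RunRecord:
    """Execute one closed-loop experiment."""
    t_start = _time.perf_counter()
    dt = config.bin_width
    n_bins_total = int(round(config.duration / dt))
    bins_per_chunk = int(round(CHUNK_MS / dt))
    n_chunks = int(np.ceil(n_bins_total / bins_per_chunk))
    seed = config.seed

    # populations whose individual spikes are recorded cannot be collapsed
    explicit = [
        p for p in config.populations
        if not p.collapsible or p.name in config.record_inputs
    ]
    collapsed = [p for p in config.populations if p not in explicit]

    # --- per-synapse arrays for explicit populations
    offsets, names, signs, w0 = {}, [], [], []
    g_scale, is_exc, plastic, alpha, mu, lam_rel, pop_of = [], [], [], [], [], [], []
    tau_pop = []
    total_n = {"E": 0, "I": 0}
    for p in config.populations:
        total_n[p.sign] += p.spec.n_neurons
    sc = config.scaling
    for p in explicit:
        offsets[p.name] = len(names)
        n = p.spec.n_neurons
        w0.append(p.weights_array())
        names += [p.name] * n
        signs += [p.sign] * n
        peak = sc.peak_conductance(p.sign, total_n[p.sign])
        g_scale.append(np.full(n, peak))
        is_exc.append(np.full(n, p.sign == "E", dtype=np.bool_))
        plastic.append(np.full(n, p.plastic, dtype=np.bool_))
        rule = p.rule if p.rule is not None else STDPRule(1e-3, 1.0, 0.0, 20.0)
        alpha.append(np.full(n, rule.alpha))
        mu.append(np.full(n, rule.mu))
        lam_rel.append(np.full(n, rule.learning_rate))
        pop_of.append(np.full(n, len(tau_pop), dtype=np.int64))
        tau_pop.append(rule.tau)
    m = len(names)
    w = np.concatenate(w0) if m else np.zeros(0)
    g_scale = np.concatenate(g_scale) if m else np.zeros(0)
    is_exc = np.concatenate(is_exc) if m else np.zeros(0, np.bool_)
    plastic_arr = np.concatenate(plastic) if m else np.zeros(0, np.bool_)
    alpha = np.concatenate(alpha) if m else np.zeros(0)
    mu = np.concatenate(mu) if m else np.zeros(0)
    lam_rel = np.concatenate(lam_rel) if m else np.zeros(0)
    pop_of = np.concatenate(pop_of) if m else np.zeros(0, np.int64)
    tau_pop = np.asarray(tau_pop) if tau_pop else np.asarray([20.0])
    syn_population = np.asarray(names)
    syn_sign = np.asarray(signs)

    sign_mult = np.where(is_exc, 1.0, -1.0)

    # --- plasticity traces
    pre_val = np.zeros(m)
    pre_last = np.zeros(m, np.int64)
    post_val = np.zeros(tau_pop.shape[0])
    post_last = np.zeros(tau_pop.shape[0], np.int64)

    # --- neuron state
    lp = config.lif if config.dt is None else replace(config.lif, dt=config.dt)
    neuron_state = np.array([lp.resting_potential, 0.0, 0.0])
    decay_syn = float(np.exp(-dt / lp.synaptic_kernel_tau))
    delay_bins = max(1, int(round(config.delay / dt)))
    ring = np.zeros(delay_bins)
    ring_pos = np.zeros(1, np.int64)
    e_prob = config.drive * dt / 1000.0

    # --- collapsed backgrounds: (sign, N, q, increment per spike, tag)
    bg_defs = []
    for p in collapsed:
        q = _bin_probability(p.spec.rate, dt)
        peak = sc.peak_conductance(p.sign, total_n[p.sign])
        inc = peak * float(p.initial_weights)
        tag = config.populations.index(p)
        bg_defs.append((p.sign, p.spec.n_neurons, q, inc, tag))

    # --- outputs
    snaps = np.empty((n_chunks + 1, m))
    snaps[0] = w
    snap_times = np.empty(n_chunks + 1)
    snap_times[0] = 0.0
    post_rate_series = np.empty(n_chunks)
    lam_series = np.empty(n_chunks)
    spike_buf = np.empty(bins_per_chunk, np.int64)
    all_spikes: list[np.ndarray] = []
    input_events: dict[str, list] = {nm: [] for nm in config.record_inputs}

    n_done = 0
    for chunk in range(n_chunks):
        n_bins = min(bins_per_chunk, n_bins_total - n_done)
        rho = n_done / n_bins_total
        lam = learning_rate_schedule(rho, config.schedule, base=1.0)
        lam_series[chunk] = lam

        # inputs
        ev_parts_b, ev_parts_s = [], []
        for p in explicit:
            tag = config.populations.index(p)
            q = _bin_probability(p.spec.rate, dt)
            # full-chunk generation + truncation keeps the event streams
            # independent of where the run ends
            eb, en = _chunk_events(p.spec, q, bins_per_chunk, seed, tag, chunk)
            if n_bins < bins_per_chunk:
                keep = eb < n_bins
                eb, en = eb[keep], en[keep]
            ev_parts_b.append(eb)
            ev_parts_s.append(en + offsets[p.name])
            if p.name in input_events:
                input_events[p.name].append(
                    ((n_done + eb) * dt, en)
                )
        if ev_parts_b:
            eb = np.concatenate(ev_parts_b)
            es = np.concatenate(ev_parts_s)
            order = np.lexsort((es, eb))
            eb, es = eb[order], es[order]
        else:
            eb = np.zeros(0, np.int64)
            es = np.zeros(0, np.int64)

        bg_exc = np.zeros(n_bins)
        bg_inh = np.zeros(n_bins)
        for bsign, bn, bq, binc, btag in bg_defs:
            rng = _stream(seed, _KIND_BACKGROUND, btag, 0, chunk)
            counts = rng.binomial(bn, bq, n_bins)
            if bsign == "E":
                bg_exc += binc * counts
            else:
                bg_inh += binc * counts

        if config.neuron_model == "lif":
            ns = _kernels.lif_plastic_chunk(
                n_bins, n_done, dt, eb, es,
                w, g_scale, is_exc, plastic_arr, alpha, mu, lam_rel, pop_of,
                tau_pop, lam,
                bg_exc, bg_inh,
                lp.membrane_capacitance, lp.leak_conductance,
                lp.resting_potential, lp.threshold, lp.reset_potential,
                lp.excitatory_reversal, lp.inhibitory_reversal, decay_syn,
                neuron_state, pre_val, pre_last, post_val, post_last,
                spike_buf,
            )
        else:
            rng = _stream(seed, _KIND_NEURON, 0, 0, chunk)
            u = rng.random(n_bins)
            ns = _kernels.linear_plastic_chunk(
                n_bins, n_done, dt, eb, es,
                w, sign_mult, plastic_arr, alpha, mu, lam_rel, pop_of,
                tau_pop, lam,
                e_prob, ring, ring_pos, u,
                pre_val, pre_last, post_val, post_last,
                spike_buf,
            )
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(neuron_state)):
            raise FloatingPointError(
                f"non-finite state in chunk {chunk}: "
                f"V={neuron_state[0]:g}, w range "
                f"[{np.nanmin(w) if m else 0:g}, {np.nanmax(w) if m else 0:g}]"
            )
        post_rate_series[chunk] = ns / (n_bins * dt / 1000.0)
        if config.record_post_spikes:
            all_spikes.append(spike_buf[:ns] * dt)
        n_done += n_bins
        snaps[chunk + 1] = w
        snap_times[chunk + 1] = n_done * dt

    rec = RunRecord(
        config=config,
        times=snap_times,
        weights=snaps,
        syn_population=syn_population,
        syn_sign=syn_sign,
        post_rate_series=post_rate_series,
        lambda_series=lam_series,
        post_spikes=np.concatenate(all_spikes) if all_spikes else None,
        input_events={
            nm: (np.concatenate([t for t, _ in parts]),
                 np.concatenate([n for _, n in parts]))
            for nm, parts in input_events.items() if parts
        },
        wall_time=_time.perf_counter() - t_start,
        n_steps=n_bins_total,
    )
    return rec


# ---------------------------------------------------------------------------
# standard model setup shared by the figure protocols
# ---------------------------------------------------------------------------

#: common presynaptic rate, spikes/s
PRE_RATE = 10.0
#: background fixed weights of the non-learning populations
BG_EXC_WEIGHT = 0.5
BG_INH_WEIGHT = 0.175
#: default population sizes: excitation at the 1000-synapse reference size;
#: single-synapse experiments keep 200 inhibitory synapses (weak-coupling
#: regime where the linear-response closure holds), population-learning
#: experiments use a small plastic population of 40
N_EXC = 1000
N_INH_SINGLE = 200
N_INH = 40
#: default inhibitory rule: additive (mu=0), depression/potentiation ratio
#: below one, 20 ms filter
INH_RULE = STDPRule(learning_rate=1e-3, alpha=0.9, mu=0.0, tau=20.0, sign="I")
#: default excitatory rule: slight net depression, weak weight dependence
EXC_RULE = STDPRule(learning_rate=1e-3, alpha=1.05, mu=0.05, tau=20.0, sign="E")


def _bg_exc(weight: float = BG_EXC_WEIGHT, n: int = N_EXC) -> PopulationConfig:
    return PopulationConfig(
        name="bgE", sign="E",
        spec=CorrelationSpec([n], PRE_RATE), initial_weights=weight,
    )


def _bg_inh(n: int, weight: float = BG_INH_WEIGHT) -> PopulationConfig:
    return PopulationConfig(
        name="bgI", sign="I",
        spec=CorrelationSpec([n], PRE_RATE), initial_weights=weight,
    )


def inhibitory_population_config(
    corr_spec: CorrelationSpec,
    rule: STDPRule,
    bg_exc_weight: float = 0.6,
    gbar_inh: float = 0.4,
    duration: float = 900e3,
    seed: int = 0,
    schedule: str = "accelerated",
    initial_weights: object = "spread",
) -> ExperimentConfig:
    """A plastic inhibitory population under a fixed excitatory background.

    The excitatory synapses are held fixed ("learning only the inhibitory
    inputs"); the inhibitory population size follows ``corr_spec``.
    """
    n_inh = corr_spec.n_neurons
    pops = (
        _bg_exc(bg_exc_weight),
        PopulationConfig(
            name="inh", sign="I", spec=corr_spec, plastic=True, rule=rule,
            initial_weights=initial_weights,
        ),
    )
    sc = ConductanceScaling(
        n_exc=N_EXC, n_inh=n_inh, base_inhibitory_conductance=gbar_inh
    )
    return ExperimentConfig(
        populations=pops, duration=duration, seed=seed, scaling=sc,
        schedule=schedule,
    )


def joint_config(
    exc_spec: CorrelationSpec,
    inh_spec: CorrelationSpec | None,
    exc_rule: STDPRule,
    inh_rule: STDPRule | None,
    gbar_inh: float = 0.8,
    duration: float = 1200e3,
    seed: int = 0,
    schedule: str = "accelerated",
) -> ExperimentConfig:
    """Joint learning of excitatory and inhibitory feed-forward synapses.

    Pass ``inh_spec=None`` for the inhibition-free control.
    """
    pops = [
        PopulationConfig(
            name="exc", sign="E", spec=exc_spec, plastic=True, rule=exc_rule,
            initial_weights=0.5,
        )
    ]
    n_inh = 40
    if inh_spec is not None:
        n_inh = inh_spec.n_neurons
        pops.append(
            PopulationConfig(
                name="inh", sign="I", spec=inh_spec, plastic=True,
                rule=inh_rule, initial_weights="spread",
            )
        )
    sc = ConductanceScaling(
        n_exc=exc_spec.n_neurons, n_inh=n_inh,
        base_inhibitory_conductance=gbar_inh,
    )
    return ExperimentConfig(
        populations=tuple(pops), duration=duration, seed=seed, scaling=sc,
        schedule=schedule,
    )


def single_synapse_config(
    w_probe: float,
    plastic: bool,
    rule: STDPRule = INH_RULE,
    duration: float = 600e3,
    seed: int = 0,
    schedule: str = "constant",
    record: bool = False,
) -> ExperimentConfig:
    """One inhibitory probe synapse among fixed backgrounds (LIF).

    The probe is one of ``N_INH`` inhibitory synapses; the remaining
    inhibitory synapses and all ``N_EXC`` excitatory synapses are held at
    fixed uniform weights.
    """
    probe = PopulationConfig(
        name="probe", sign="I",
        spec=CorrelationSpec([1], PRE_RATE),
        plastic=plastic, rule=rule, initial_weights=w_probe,
    )
    sc = ConductanceScaling(n_exc=N_EXC, n_inh=N_INH_SINGLE)
    return ExperimentConfig(
        populations=(_bg_exc(), _bg_inh(N_INH_SINGLE - 1), probe),
        duration=duration, seed=seed, scaling=sc, schedule=schedule,
        record_post_spikes=record,
        record_inputs=("probe",) if record else (),
    )


# ---------------------------------------------------------------------------
# figure protocols
# ---------------------------------------------------------------------------
# Scaled-down reproductions of the study's experiments.  ``scale``
# multiplies the reference durations / repeat counts of this package
# (chosen to resolve each effect comfortably on a single CPU); the
# parameter sets below are the package defaults, frozen after a one-off
# calibration of the operating point (see docs/methods.md).

#: inhibitory rule of the single-synapse experiments
SINGLE_RULE = STDPRule(1e-3, 0.8, 0.0, 20.0, "I")
#: inhibitory rule of the population-convergence experiment
FIG5_RULE = STDPRule(7e-4, 0.7, 0.0, 20.0, "I")
#: inhibitory rule of the balance experiments
BALANCE_RULE = STDPRule(1e-3, 0.8, 0.0, 20.0, "I")
#: rules of the joint E/I experiments
JOINT_INH_RULE = STDPRule(1e-3, 0.9, 0.0, 20.0, "I")
JOINT_EXC_RULE = STDPRule(1e-3, 1.2, 0.5, 20.0, "E")
#: competitive excitatory rule of the segregation experiments: strong net
#: depression so that subgroup competition, not saturation, decides the
#: outcome
SEGREGATION_EXC_RULE = STDPRule(1e-3, 1.5, 0.05, 20.0, "E")

#: correlation structures of the population-convergence experiment
FIG5_VARIANTS = {
    "A": dict(group_sizes=[40], within_corr=0.1),
    "B": dict(group_sizes=[20, 20], within_corr=0.15, between_corr=0.05),
    "C": dict(
        group_sizes=[10, 10, 10, 10], within_corr=0.25,
        between_corr=[
            [0.0, 0.15, 0.0, 0.0],
            [0.15, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.15],
            [0.0, 0.0, 0.15, 0.0],
        ],
    ),
}


def measure_gamma(
    weights=(0.2, 0.3, 0.4, 0.5),
    duration: float = 600e3,
    seed: int = 0,
):
    """Fit the linear-response kernel from spike-triggered averages.

    Runs the single-probe configuration at several *fixed* probe weights,
    estimates the STA of the probe around postsynaptic spikes, fits the
    exponential dip for each weight and pools the fits (the dip is
    approximately linear in the weight, so the per-unit-weight amplitudes
    agree).  Returns ``(pooled GammaKernel, mean post rate, list of
    (w, STACurve, GammaKernel))``.
    """
    from . import analysis

    fits = []
    post_rates = []
    for k, w in enumerate(weights):
        cfg = single_synapse_config(
            w_probe=w, plastic=False, duration=duration,
            seed=seed * 1009 + k, record=True,
        )
        rec = run_experiment(cfg)
        pre_t = np.sort(rec.input_events["probe"][0])
        sta = analysis.spike_triggered_average(pre_t, rec.post_spikes, duration)
        g = analysis.fit_gamma(sta, w=w)
        fits.append((w, sta, g))
        post_rates.append(sta.post_rate)
    from .meanfield import GammaKernel

    pooled = GammaKernel(
        amplitude=float(np.mean([g.amplitude for _, _, g in fits])),
        decay_tau=float(np.mean([g.decay_tau for _, _, g in fits])),
        latency=float(np.mean([g.latency for _, _, g in fits])),
        fit_residual=float(np.mean([g.fit_residual for _, _, g in fits])),
    )
    return pooled, float(np.mean(post_rates)), fits


def fig2_protocol(scale: float = 1.0, seed: int = 0) -> dict:
    """Spike-triggered average of the inhibitory probe and the dip fits."""
    gamma, post_rate, fits = measure_gamma(
        weights=(0.1, 0.2, 0.3, 0.4, 0.5),
        duration=600e3 * scale, seed=seed,
    )
    return {
        "gamma": gamma,
        "post_rate": post_rate,
        "weights": [w for w, _, _ in fits],
        "stas": [s for _, s, _ in fits],
        "gammas": [g for _, _, g in fits],
    }


def fig3_protocol(
    scale: float = 1.0,
    seed: int = 0,
    n_repeats: int = 128,
    duration: float = 1800e3,
    rule: STDPRule = SINGLE_RULE,
) -> dict:
    """Weight-density evolution of a single plastic inhibitory synapse.

    ``n_repeats`` stochastic realisations start from initial conditions
    uniformly spaced in (0, 1); the empirical density over 100 weight bins
    is recorded at every trajectory snapshot.
    """
    from . import analysis

    n_rep = max(4, int(round(n_repeats * scale)))
    dur = duration * scale if scale < 1 else duration
    trajs = []
    for k in range(n_rep):
        w0 = (k + 0.5) / n_rep
        cfg = single_synapse_config(
            w_probe=w0, plastic=True, rule=rule, duration=dur,
            seed=seed * 100003 + k, schedule="accelerated",
        )
        rec = run_experiment(cfg)
        trajs.append(rec.trajectory("probe")[0])
    trajs = np.asarray(trajs)
    times_min = rec.times / 60e3
    dens = analysis.weight_density_evolution(trajs, times_min)
    finals = trajs[:, -1]
    return {
        "trajectories": trajs,
        "times_min": times_min,
        "density": dens,
        "final_mean": float(finals.mean()),
        "final_sd": float(finals.std()),
        "late_modes": analysis.count_modes(dens.density[-1], dens.bin_edges),
    }


def fig4_protocol(
    scale: float = 1.0,
    seed: int = 0,
    alphas=(0.7, 0.75, 0.8, 0.85, 0.9),
    mus=(0.0, 0.25, 0.5, 0.75, 1.0),
    base_rule: STDPRule = SINGLE_RULE,
    n_seeds: int = 4,
    duration: float = 1800e3,
    gamma=None,
    post_rate: float | None = None,
) -> dict:
    """Asymptotic weight of a single synapse vs alpha and mu, with theory.

    For every parameter value the stochastic learning is simulated
    ``n_seeds`` times (trailing-window average of the weight), and the
    drift fixed point evaluated with the fitted linear-response kernel
    provides the mean-field prediction.
    """
    from dataclasses import replace as _replace

    from . import analysis
    from .meanfield import fixed_point_single

    if gamma is None:
        gamma, post_rate, _ = measure_gamma(seed=seed, duration=600e3 * scale)
    dur = duration * scale if scale < 1 else duration
    rows = []
    for param, values in (("alpha", alphas), ("mu", mus)):
        for v in values:
            rule = _replace(base_rule, **{param: v})
            sims = []
            for s in range(n_seeds):
                cfg = single_synapse_config(
                    w_probe=0.5, plastic=True, rule=rule, duration=dur,
                    seed=seed * 7919 + hash((param, round(v, 3))) % 10000 + s,
                    schedule="accelerated",
                )
                rec = run_experiment(cfg)
                m, _sd = analysis.asymptotic_weight(rec.trajectory("probe")[0])
                sims.append(m)
            fp = fixed_point_single(rule, PRE_RATE, post_rate, gamma)
            rows.append({
                "param": param, "value": v,
                "w_sim": float(np.mean(sims)), "w_sim_sd": float(np.std(sims)),
                "w_theory": fp.weights["single"],
            })
    return {"rows": rows, "gamma": gamma, "post_rate": post_rate}


def _population_spread(rec: RunRecord, name: str = "inh") -> np.ndarray:
    return rec.trajectory(name).std(axis=0)


def fig5_protocol(
    variant: str = "A",
    scale: float = 1.0,
    seed: int = 0,
    duration: float = 1800e3,
) -> dict:
    """Convergence of 40 plastic inhibitory weights to the uniform solution.

    Variants differ in the input correlation structure: A homogeneous,
    B two blocks, C four blocks with a pairwise coupling pattern.
    """
    spec = CorrelationSpec(rate=PRE_RATE, **FIG5_VARIANTS[variant])
    cfg = inhibitory_population_config(
        spec, FIG5_RULE, duration=duration * scale if scale < 1 else duration,
        seed=seed,
    )
    rec = run_experiment(cfg)
    wf = rec.final_weights("inh")
    spread = _population_spread(rec)
    return {
        "record": rec,
        "final_mean": float(wf.mean()),
        "final_sd": float(wf.std()),
        "cv": float(wf.std() / wf.mean()),
        "spread": spread,
        "times_min": rec.times / 60e3,
    }


def convergence_time(spread: np.ndarray, times: np.ndarray,
                     threshold: float | None = None) -> float:
    """First time the across-population weight spread stays below threshold.

    The default threshold is one e-folding of the initial spread, i.e. the
    time constant of the loss of initial-condition memory.
    """
    if threshold is None:
        threshold = spread[0] / np.e
    below = spread <= threshold
    for k in range(len(below)):
        if below[k:].all():
            return float(times[k])
    return float("inf")


def fig6_protocol(
    scale: float = 1.0,
    seed: int = 0,
    drive_weights=(0.45, 0.5, 0.55, 0.6, 0.65, 0.7, 0.75),
    inh_corr: float = 0.0,
    n_seeds: int = 2,
    duration: float = 900e3,
) -> dict:
    """Asymptotic uniform inhibitory weight vs the fixed excitatory drive."""
    from . import analysis

    dur = duration * scale if scale < 1 else duration
    spec = CorrelationSpec([40], PRE_RATE, within_corr=inh_corr)
    points = []
    for we in drive_weights:
        vals = []
        for s in range(n_seeds):
            cfg = inhibitory_population_config(
                spec, BALANCE_RULE, bg_exc_weight=we, duration=dur,
                seed=seed * 6007 + int(we * 1000) + s,
            )
            rec = run_experiment(cfg)
            m, _ = analysis.asymptotic_weight(rec.trajectory("inh").mean(axis=0))
            vals.append(m)
        points.append((we, float(np.mean(vals))))
    points = np.asarray(points)
    summary = analysis.balance_regression(points)
    return {"points": points, "summary": summary}


def fig7_protocol(
    scale: float = 1.0,
    seed: int = 0,
    correlations=(0.0, 0.05, 0.1, 0.2, 0.4),
    drive_weight: float = 0.6,
    n_seeds: int = 2,
    duration: float = 900e3,
) -> dict:
    """Asymptotic inhibitory weight vs the inhibitory input correlation."""
    from . import analysis

    dur = duration * scale if scale < 1 else duration
    points = []
    for c in correlations:
        spec = CorrelationSpec([40], PRE_RATE, within_corr=c)
        vals = []
        for s in range(n_seeds):
            cfg = inhibitory_population_config(
                spec, BALANCE_RULE, bg_exc_weight=drive_weight, duration=dur,
                seed=seed * 31 + int(c * 1000) + s,
            )
            rec = run_experiment(cfg)
            m, _ = analysis.asymptotic_weight(rec.trajectory("inh").mean(axis=0))
            vals.append(m)
        points.append((c, float(np.mean(vals))))
    return {"points": np.asarray(points)}


def fig8_protocol(scale: float = 1.0, seed: int = 0, duration: float = 1200e3) -> dict:
    """Joint E/I learning with two correlated subgroups per population."""
    exc_spec = CorrelationSpec([60, 60], PRE_RATE, within_corr=0.2)
    inh_spec = CorrelationSpec([20, 20], PRE_RATE, within_corr=0.2)
    cfg = joint_config(
        exc_spec, inh_spec, SEGREGATION_EXC_RULE, JOINT_INH_RULE,
        duration=duration * scale if scale < 1 else duration, seed=seed,
    )
    rec = run_experiment(cfg)
    return {
        "record": rec,
        "exc_final": rec.final_weights("exc"),
        "inh_final": rec.final_weights("inh"),
        "inh_cv": float(rec.final_weights("inh").std()
                        / max(rec.final_weights("inh").mean(), 1e-12)),
    }


def fig9_protocol(
    scale: float = 1.0,
    seed: int = 0,
    exc_correlations=(0.0, 0.02, 0.04, 0.05, 0.055, 0.06, 0.065, 0.07),
    n_seeds: int = 2,
    duration: float = 1200e3,
) -> dict:
    """Asymptotic inhibitory weight vs asymptotic mean excitatory weight.

    The mean excitatory input is moved by varying the uniform correlation
    among the excitatory inputs; inhibitory inputs are uncorrelated.
    """
    from . import analysis

    dur = duration * scale if scale < 1 else duration
    inh_spec = CorrelationSpec([40], PRE_RATE)
    points = []
    for c in exc_correlations:
        wes, wis = [], []
        for s in range(n_seeds):
            exc_spec = CorrelationSpec([120], PRE_RATE, within_corr=c)
            cfg = joint_config(
                exc_spec, inh_spec, JOINT_EXC_RULE, JOINT_INH_RULE,
                duration=dur, seed=seed * 53 + int(c * 1000) + s,
            )
            rec = run_experiment(cfg)
            we, _ = analysis.asymptotic_weight(rec.trajectory("exc").mean(axis=0))
            wi, _ = analysis.asymptotic_weight(rec.trajectory("inh").mean(axis=0))
            wes.append(we)
            wis.append(wi)
        points.append((float(np.mean(wes)), float(np.mean(wis))))
    points = np.asarray(points)
    summary = analysis.balance_regression(points)
    return {"points": points, "summary": summary}


def fig10_protocol(
    scale: float = 1.0,
    seed: int = 0,
    within_correlations=(0.05, 0.1, 0.15, 0.2),
    mu_values=(0.05, 0.2),
    with_inhibition: bool = True,
    duration: float = 900e3,
) -> dict:
    """Segregation of two excitatory subgroups vs correlation and mu.

    Returns the absolute difference between the two subgroup mean weights
    (trailing-window average) per (mu, within-group correlation), with or
    without a plastic inhibitory population.
    """
    from dataclasses import replace as _replace

    from . import analysis

    dur = duration * scale if scale < 1 else duration
    labels = np.repeat([0, 1], 60)
    rows = []
    for mu in mu_values:
        er = _replace(SEGREGATION_EXC_RULE, mu=mu)
        for c in within_correlations:
            exc_spec = CorrelationSpec([60, 60], PRE_RATE, within_corr=c)
            inh_spec = CorrelationSpec([40], PRE_RATE) if with_inhibition else None
            cfg = joint_config(
                exc_spec, inh_spec, er,
                JOINT_INH_RULE if with_inhibition else None,
                duration=dur, seed=seed * 97 + int(c * 1000) + int(mu * 100),
            )
            rec = run_experiment(cfg)
            traj = rec.trajectory("exc")
            n = traj.shape[1]
            tail = traj[:, n - max(1, n // 4):]
            idx, sd = analysis.segregation_index(tail, labels)
            rows.append({"mu": mu, "corr": c, "index": idx, "index_sd": sd})
    return {"rows": rows, "with_inhibition": with_inhibition}


FIGURE_PROTOCOLS = {
    "fig2": fig2_protocol,
    "fig3": fig3_protocol,
    "fig4": fig4_protocol,
    "fig5": fig5_protocol,
    "fig6": fig6_protocol,
    "fig7": fig7_protocol,
    "fig8": fig8_protocol,
    "fig9": fig9_protocol,
    "fig10": fig10_protocol,
}


def reproduce_figure(name: str, scale: float = 1.0, seed: int = 0,
                     out_dir=None) -> dict:
    """Run one figure protocol and optionally write its artifacts.

    Writes tidy CSV summaries plus a ``manifest.json`` recording the scale
    factor and seed (the deviations from the full-scale protocol).
    Unknown names raise with the list of available protocols.
    """
    import pathlib

    import pandas as pd

    if name not in FIGURE_PROTOCOLS:
        raise ValueError(
            f"unknown protocol {name!r}; available: {sorted(FIGURE_PROTOCOLS)}"
        )
    result = FIGURE_PROTOCOLS[name](scale=scale, seed=seed)
    if out_dir is None:
        return result
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"protocol": name, "scale": scale, "seed": seed}
    if name == "fig2":
        df = pd.DataFrame(
            {
                "weight": result["weights"],
                "amplitude": [g.amplitude for g in result["gammas"]],
                "decay_tau_ms": [g.decay_tau for g in result["gammas"]],
                "latency_ms": [g.latency for g in result["gammas"]],
            }
        )
        df.to_csv(out / "gamma_fits.csv", index=False)
        manifest["pooled_gamma"] = {
            "amplitude": result["gamma"].amplitude,
            "decay_tau_ms": result["gamma"].decay_tau,
            "latency_ms": result["gamma"].latency,
        }
    elif name == "fig3":
        d = result["density"]
        pd.DataFrame(
            d.density,
            index=pd.Index(d.time_points, name="time_min"),
            columns=0.5 * (d.bin_edges[:-1] + d.bin_edges[1:]),
        ).to_csv(out / "weight_density.csv")
        manifest.update(
            final_mean=result["final_mean"], final_sd=result["final_sd"],
            late_modes=result["late_modes"],
        )
    elif name == "fig4":
        pd.DataFrame(result["rows"]).to_csv(out / "asymptotic_weight.csv", index=False)
    elif name == "fig5":
        rec = result["record"]
        pd.DataFrame(
            rec.trajectory("inh").T,
            index=pd.Index(rec.times / 60e3, name="time_min"),
        ).to_csv(out / "inhibitory_trajectories.csv")
        manifest.update(cv=result["cv"], final_mean=result["final_mean"])
    elif name in ("fig6", "fig7", "fig9"):
        cols = {"fig6": ("drive_weight", "w_inh"), "fig7": ("corr", "w_inh"),
                "fig9": ("w_exc", "w_inh")}[name]
        pd.DataFrame(result["points"], columns=cols).to_csv(
            out / "balance_points.csv", index=False
        )
        if "summary" in result:
            s = result["summary"]
            manifest.update(slope=s.slope, intercept=s.intercept,
                            r_squared=s.r_squared)
    elif name == "fig8":
        rec = result["record"]
        pd.DataFrame({
            "synapse": np.arange(rec.weights.shape[1]),
            "population": rec.syn_population,
            "final_weight": rec.weights[-1],
        }).to_csv(out / "final_weights.csv", index=False)
        manifest["inh_cv"] = result["inh_cv"]
    elif name == "fig10":
        pd.DataFrame(result["rows"]).to_csv(out / "segregation.csv", index=False)
        manifest["with_inhibition"] = result["with_inhibition"]
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=float)
    return result
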