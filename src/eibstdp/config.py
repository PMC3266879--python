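"""YAML/JSON experiment and model configuration.

The experiment schema mirrors :class:`eibstdp.runner.ExperimentConfig`::

    neuron_model: lif            # or linear
    duration_ms: 600000
    seed: 3
    schedule: accelerated        # or constant
    drive: 0.0                   # spikes/s, linear neuron
    delay_ms: 0.1                # linear neuron
    lif: {dt_ms: 0.1, threshold_mv: -54.0, ...}
    scaling: {n_exc: 1000, n_inh: 200,
              base_excitatory_conductance_ns: 0.2,
              base_inhibitory_conductance_ns: 1.0}
    populations:
      - name: bgE
        sign: E
        initial_weights: 0.5
        inputs: {groups: [1000], rate: 10.0}
      - name: inh
        sign: I
        plastic: true
        initial_weights: spread
        inputs: {groups: [20, 20], rate: 10.0,
                 within_corr: 0.15, between_corr: 0.05}
        plasticity: {lambda: 1.0e-3, alpha: 0.8, mu: 0.0, tau_ms: 20.0}

The mean-field schema used by ``eibstdp meanfield``::

    rate: 10.0
    drive: 100.0
    delay_ms: 1.0
    inh:
      n: 40
      corr: {groups: [40], rate: 10.0, within_corr: 0.1}
      plasticity: {lambda: 1.0e-3, alpha: 0.8, mu: 0.0, tau_ms: 20.0}
    exc: ...        # optional
"""

from __future__ import annotations

import numpy as np
import yaml

from .meanfield import MeanFieldModel, PopulationModel
from .neuron import ConductanceScaling, LIFParams
from .plasticity import STDPRule
from .runner import ExperimentConfig, PopulationConfig
from .spikegen import CorrelationSpec, build_correlation_matrix

__all__ = [
    "load_experiment_config",
    "experiment_config_from_dict",
    "load_meanfield_model",
    "meanfield_model_from_dict",
]


def _spec_from_dict(d: dict) -> CorrelationSpec:
    return CorrelationSpec(
        group_sizes=d["groups"],
        rate=float(d.get("rate", 10.0)),
        within_corr=d.get("within_corr", 0.0),
        between_corr=np.asarray(d["between_corr"], dtype=float)
        if isinstance(d.get("between_corr"), (list, tuple))
        else float(d.get("between_corr", 0.0)),
    )


def _rule_from_dict(d: dict, sign: str = "I") -> STDPRule:
    return STDPRule(
        learning_rate=float(d.get("lambda", d.get("learning_rate", 1e-3))),
        alpha=float(d["alpha"]),
        mu=float(d.get("mu", 0.0)),
        tau=float(d.get("tau_ms", d.get("tau", 20.0))),
        sign=d.get("sign", sign),
        kernel=d.get("kernel", "exp"),
    )


def _lif_from_dict(d: dict) -> LIFParams:
    keymap = {
        "capacitance_pf": "membrane_capacitance",
        "resistance_mohm": "membrane_resistance",
        "resting_mv": "resting_potential",
        "threshold_mv": "threshold",
        "reset_mv": "reset_potential",
        "e_ex_mv": "excitatory_reversal",
        "e_in_mv": "inhibitory_reversal",
        "tau_syn_ms": "synaptic_kernel_tau",
        "kernel_cutoff_ms": "kernel_cutoff",
        "dt_ms": "dt",
    }
    kwargs = {keymap.get(k, k): float(v) for k, v in d.items()}
    return LIFParams(**kwargs)


def _scaling_from_dict(d: dict) -> ConductanceScaling:
    keymap = {
        "base_excitatory_conductance_ns": "base_excitatory_conductance",
        "base_inhibitory_conductance_ns": "base_inhibitory_conductance",
    }
    kwargs = {keymap.get(k, k): v for k, v in d.items()}
    return ConductanceScaling(**kwargs)


def experiment_config_from_dict(d: dict) -> ExperimentConfig:
    pops = []
    for pd in d["populations"]:
        sign = pd["sign"]
        pops.append(
            PopulationConfig(
                name=pd["name"],
                sign=sign,
                spec=_spec_from_dict(pd["inputs"]),
                plastic=bool(pd.get("plastic", False)),
                rule=_rule_from_dict(pd["plasticity"], sign)
                if "plasticity" in pd
                else None,
                initial_weights=pd.get("initial_weights", 0.5),
            )
        )
    return ExperimentConfig(
        populations=tuple(pops),
        duration=float(d["duration_ms"]),
        seed=int(d.get("seed", 0)),
        neuron_model=d.get("neuron_model", "lif"),
        lif=_lif_from_dict(d.get("lif", {})),
        scaling=_scaling_from_dict(d.get("scaling", {})),
        drive=float(d.get("drive", 0.0)),
        delay=float(d.get("delay_ms", 0.1)),
        dt=float(d["dt_ms"]) if "dt_ms" in d else None,
        schedule=d.get("schedule", "constant"),
        record_post_spikes=bool(d.get("record_post_spikes", False)),
        record_inputs=tuple(d.get("record_inputs", ())),
    )


def load_experiment_config(path, seed: int | None = None) -> ExperimentConfig:
    with open(path) as f:
        d = yaml.safe_load(f)
    if seed is not None:
        d["seed"] = seed
    return experiment_config_from_dict(d)


def meanfield_model_from_dict(d: dict) -> MeanFieldModel:
    def pop(pd, sign):
        corr = None
        if "corr" in pd:
            corr = build_correlation_matrix(_spec_from_dict(pd["corr"]))
        return PopulationModel(
            n=int(pd["n"]),
            rule=_rule_from_dict(pd["plasticity"], sign),
            corr=corr,
        )

    return MeanFieldModel(
        rate=float(d.get("rate", 10.0)),
        drive=float(d.get("drive", 0.0)),
        inh=pop(d["inh"], "I") if "inh" in d else None,
        exc=pop(d["exc"], "E") if "exc" in d else None,
        delay_ms=float(d.get("delay_ms", 0.1)),
        bin_width_ms=float(d["bin_width_ms"]) if "bin_width_ms" in d else None,
    )


def load_meanfield_model(path) -> MeanFieldModel:
    with open(path) as f:
        return meanfield_model_from_dict(yaml.safe_load(f))
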