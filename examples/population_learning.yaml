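# Plastic inhibitory population (two correlated blocks) under a fixed
# excitatory background, conductance LIF postsynaptic cell.
neuron_model: lif
duration_ms: 600000        # 10 simulated minutes
seed: 5
schedule: accelerated
scaling:
  n_exc: 1000
  n_inh: 40
  base_excitatory_conductance_ns: 0.2
  base_inhibitory_conductance_ns: 0.4
populations:
  - name: bgE
    sign: E
    initial_weights: 0.6
    inputs: {groups: [1000], rate: 10.0}
  - name: inh
    sign: I
    plastic: true
    initial_weights: spread
    inputs:
      groups: [20, 20]
      rate: 10.0
      within_corr: 0.15
      between_corr: 0.05
    plasticity: {lambda: 7.0e-4, alpha: 0.7, mu: 0.0, tau_ms: 20.0}
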