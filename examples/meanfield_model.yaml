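# Mean-field model of an inhibitory population on the delayed linear
# Poisson neuron; solve with
#   eibstdp meanfield --config examples/meanfield_model.yaml \
#       --sweep alpha=0.5:0.9:9 --out fp.csv
rate: 10.0
drive: 100.0
delay_ms: 1.0
inh:
  n: 40
  corr: {groups: [20, 20], within_corr: 0.15, between_corr: 0.05}
  plasticity: {lambda: 1.0e-3, alpha: 0.8, mu: 0.0, tau_ms: 20.0}
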