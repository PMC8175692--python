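model: modular
t_start: 0.0
t_stop: 60.0
seed: 1
params:
  d_refrac_s: 0.5
  period_s: 2.0
  av: {d_min_s: 0.1, d_amp_s: 0.1, tau_s: 1.0}
stimulus:
  kind: switching
  choices_s: [0.4, 0.8, 1.2]
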