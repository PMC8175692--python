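model: pvc
t_start: 0.0
t_stop: 20.0
seed: 1
params:
  d_refrac_s: 0.5
  period_s: 2.0
  av: {d_min_s: 0.1, d_amp_s: 0.1, tau_s: 1.0}
  d_refrac_ventricle_s: 0.3
stimulus:
  kind: constant
  interval_s: 0.8
pvc_trigger: {times_s: [4.6, 12.3]}
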