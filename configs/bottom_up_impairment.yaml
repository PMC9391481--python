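# Impaired bottom-up drive to the perceiving module: the pooled fan-in
# from the visual and memory modules is cut to 1050 of the 2100
# candidate connections per perceiving neuron, realized in many random
# configurations; the 2100 budget is the intact control.
sweep:
  kind: bottom_up
  budgets: [2100, 1050]
  n_config: 20
seeds:
  patterns: 1
  lesion: 42
  noise: 3
input:
  noise_fraction: 0.05
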