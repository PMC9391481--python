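# Slow sinusoidal threshold fluctuation on the perceiving module
# (amplitude 0.02, period 100 steps), standing in for impaired
# neuromodulator release.  Applied to a network lesioned near its
# destabilization point (pooled perceiving fan-in 525 of 2100): probes
# are launched at every phase of the modulation cycle, and the outcome
# depends on where in the slow cycle the stimulus arrives.
thresholds:
  P:
    amplitude: 0.02
    period: 100
lesion:
  fan_in:
    P<-V+M: 525
sweep:
  kind: threshold
  n_probe: 11
seeds:
  patterns: 1
  lesion: 42
  noise: 3
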