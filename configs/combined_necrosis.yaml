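# Combined-necrosis "typical case" protocol: cell death concentrated in
# the visual module plus pruning of the two visual outflow pathways
# (inferior: visual->memory, superior: visual->perceiving), with the
# memory<->perceiving projections left intact.  Each severity cell is
# realized n_config times with independent random configurations; a
# (cell, outcome) pair occurring in at least typical_fraction of runs
# is flagged a "typical case".  The severities are qualitative
# emulations chosen around measured atrophy patterns; they are config
# parameters, not fixed model constants.
sweep:
  kind: necrosis
  n_config: 10
  typical_fraction: 0.5
  grid:
    - name: control
      lesion: {}
    - name: moderate
      lesion:
        dead_counts: {V: 90, M: 30, P: 30}
        fan_in:
          M<-V: 540
          P<-V: 540
    - name: severe
      lesion:
        dead_counts: {V: 180, M: 60, P: 60}
        fan_in:
          M<-V: 270
          P<-V: 270
seeds:
  patterns: 1
  lesion: 42
  noise: 3
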