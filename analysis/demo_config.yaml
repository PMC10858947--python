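# All-synthetic demo configuration for `loopshift run`.
seed: 0
outdir: results/demo
hic:
  simulate: true
fragments:
  simulate: true
  assay: atac
loops:
  p: 1
  w: 5
  m_min: 3
  d_min: 3
  d_max: 200
  score_min: 2.0
diffloops:
  mode: all_combinations
  alpha: 0.05
compartments:
  n_groups: 100
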