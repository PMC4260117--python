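schema_version: 1
scheme:
  name: ocn          # daily allometric-constraint scheme
  params: {}
turnover:
  u_f: 1.0
  u_w: 0.005
  u_r: 1.1
scenario:
  preset: ornl
  overrides:
    noise_cv: 0.0
seed: 1
outdir: results/ornl_functional
write_trajectories: false
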