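schema_version: 1
scheme:
  name: fixed
  params:
    base: [0.30, 0.45, 0.25]
turnover:
  u_f: 0.5     # foliage lifespan ~2 yr
  u_w: 0.008   # wood lifespan ~125 yr
  u_r: 0.28    # fine-root lifespan ~3.6 yr
scenario:
  preset: duke
  overrides:
    noise_cv: 0.0
seed: 1
outdir: results/duke_fixed
write_trajectories: false
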