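# Demonstration run: a small synthetic breeding program end to end.
# 80 end-product-assayed lines inside a 400-line NIR-predicted pool, 4 years.
#   nirblup run --config examples/demo.yaml
out_dir: scratch/demo_run
seed: 7
simulation:
  n_lines: 402
  n_markers: 300
  years:
  - '2016'
  - '2017'
  - '2018'
  - '2019'
  lines_per_year_ep:
  - 20
  - 20
  - 20
  - 20
  lines_per_year_nir:
  - 100
  - 100
  - 100
  - 100
  h2_ep: 0.6
  h2_nir: 0.7
  r_g: 0.8
  reps_per_line: 1
pca_components: 2
cv:
  k: 5
  repeats: 1
  scenarios:
  - S0
  - S2
forward:
  test_years:
  - '2018'
  - '2019'
  mode: multi
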