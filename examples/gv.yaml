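# production gas-vesicle model: 1404-vertex capsule, orthotropic shell
units:
  preset: gv
  r_c_nm: 35.0
  f_scale: 0.079
mesh:
  kind: gv
  R: 2.0
  L_cyl: 12.0
material:
  model: orthotropic
  E_l: 9.6e4
  E_t: 4.8e4
  nu_lt: 0.2
  G: 1.8e4
  h: 0.0571
  f_scale_applied: true
protocol:
  n_modes: 10
output:
  directory: results
  prefix: gv
seed: 1
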