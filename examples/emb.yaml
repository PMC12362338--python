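# desk-scale microbubble: 642-vertex sphere, isotropic polymer-like shell
units:
  preset: emb
mesh:
  kind: icosphere
  subdivisions: 3
  R: 2.0
material:
  model: isotropic
  E2d: 2000.0
  nu: 0.3333333
  h: 0.2
protocol:
  F_values: [0.0, 20.0, 40.0, 60.0]
  p_values: [0.0, 0.1, 0.2, 0.3]
output:
  directory: results
  prefix: emb
seed: 1
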