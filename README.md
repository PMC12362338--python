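# vesimeso

Mesoscale particle-based models of membrane-encapsulated micro- and
nanostructures: elastic microbubbles (EMBs, ultrasound contrast agents) and
protein-shelled gas vesicles (GVs).  The shell is a closed triangulated
surface whose vertices are dissipative-particle-dynamics (DPD) beads; its
elastic energy is the discretized continuum thin-shell energy

    U = ∫ ½ C_ijkl ε_ij ε_kl dA  +  ∫ ½ D_ijkl H_ij H_kl dA

with the rotation-invariant Green–Lagrange strain ε = (FᵀF − I)/2 measured
per triangle against the reference shape (constant-strain-triangle), and
bending discretized as the Kantor–Nelson dihedral sum Σ k_b(1 − cos Δθ),
k_b = 2κ/√3.  The elastic tensor is isotropic (bulk modulus K_a, shear
modulus μ) for EMBs, or orthotropic for GVs via one structural direction m
(in-plane shear constant μ_L and anisotropy stiffness c), connected to the
engineering constants E_l, E_t, ν_lt, G of the rib lattice.  Vertex forces
are exact analytic gradients of the discrete energy.

Around the shell the package provides: a DPD fluid engine (generalized
kernels, counter-based reproducible noise, cell lists), fluid–structure
coupling (no-slip friction γ = 2η̃(2k+1)(2k+2)(2k+3)(2k+4)/(3πr_c⁴ρ_f ρ_m),
momentum- and energy-conserving bounce-back, gas-pressure compensation
f_p = −pA·n_in/3), open-boundary molecular dynamics (buffer particle
exchange with USHER insertion, imposed normal and shear stresses), and the
standard numerical experiments: stretching, compression and buckling,
torsion, vibrational-mode analysis (elastic Hessian and quasiharmonic
covariance routes, Donnel (m, n) classification), and shear-flow tumbling
against the Jeffery orbit tan θ = (a/b)tan(abγ̇t/(a²+b²)).

Intended users: people building coarse-grained models of shelled
biomaterials (contrast agents, gas vesicles, capsules) who need a tested
elastic-shell + DPD reference implementation with reproducible protocols.

## Worked example

Lowest vibrational modes of the 1404-vertex gas vesicle preset
(70 nm radius, 12 r_c cylinder, orthotropic shell):

```python
import numpy as np
from vesimeso import io as vio, meshgen, protocols

cfg  = vio.preset_config("gv")
mesh = cfg.build_mesh()                 # 1404-vertex capsule
mat  = cfg.build_material()             # orthotropic, kappa ~ 13.6 kBT
rib  = meshgen.rib_direction_field(mesh, [0, 0, 1])
recs = protocols.hessian_modes_gv(mesh, mat, rib, L_cyl=12.0, n_modes=6)
for r in recs:
    print(f"omega = {r.omega:5.2f}/tau  (m,n) = ({r.m},{r.n})  {r.branch}")
```

prints

```
omega =  2.59/tau  (m,n) = (1,2)  radial
omega =  2.59/tau  (m,n) = (1,2)  radial
omega =  2.72/tau  (m,n) = (1,3)  radial
omega =  2.72/tau  (m,n) = (1,3)  radial
omega =  4.38/tau  (m,n) = (1,4)  radial
omega =  4.38/tau  (m,n) = (1,4)  radial
```

— the lowest mode is the doubly degenerate (m, n) = (1, 2) Donnel mode of
the cylindrical section (each pair are the same shape rotated by π/2n
about the axis), the shape the vesicle also takes at its second buckling
transition.  With the gv unit set (r_c = 35 nm, τ ≈ 65 ns) ω = 2.59 τ⁻¹
corresponds to ν = ω/2πτ ≈ 6 MHz for the documented placeholder moduli;
stiffer published shell constants shift the whole spectrum as √modulus.

The same protocols are scriptable from the shell:

```
vesimeso modes    --config examples/gv.yaml
vesimeso stretch  --config examples/emb.yaml
vesimeso compress --config examples/emb.yaml
```

Each command writes a CSV result table with a provenance header (package
version, config hash, seed) and optional VTK mesh snapshots colored by
elastic energy density.

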