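# Methods

`vesimeso` models membrane-encapsulated micro- and nanostructures — isotropic
elastic microbubbles (EMBs) and orthotropic gas vesicles (GVs) — as
triangulated elastic shells immersed in a dissipative-particle-dynamics (DPD)
solvent.  This note records the models, the numerical choices, and the limits
of what the test suite demonstrates.

## Reduced units and elastic down-scaling

All simulations use DPD reduced units: length `r_c` (the pair cutoff), mass
`m` (one water bead), energy `ε = k_B T₀` at `T₀ = 300 K`, and the derived
time `τ = √(m r_c²/ε)`.  The bead mass reproduces the density of water,
`m = 997 kg·m⁻³ · r_c³ / ρ_w` with the standard number density `ρ_w = 3 r_c⁻³`.

Real 2D shell moduli are enormous in these units (they scale as `r_c²/ε`), so
all in-plane moduli, the bending constant κ, and the solvent viscosity are
multiplied by a factor `f_scale ≪ 1` before a run.  This preserves the
Föppl–von Kármán number `FvK = E R₀²/κ` and the capillary number
`Ca = η γ̇ R/μ`, hence equilibrium shapes, buckling modes and flow regimes;
measured forces and pressures are divided by `f_scale` on output.  The
scaled κ must stay above ≈ 10 k_BT₀ or solvent fluctuations visibly
corrugate the shell (`ScalePlan.kappa_floor`).

Two named unit sets ship as presets.  Their numeric values are
reconstructions, not tabulated constants:

* **gv**: `r_c = 35 nm` — the unique length for which `Δt = 10⁻⁴ τ ≈ 6.5 ps`
  with the water-density mass rule, and for which the 140 nm GV diameter
  equals the minimum resolution of 4 `r_c`. `f_scale = 0.079` follows from
  requiring that a reduced pressure of 31.0 ε/r_c³ up-scales to ≈ 38 kPa.
* **emb**: `R₀ ≈ 1 μm` (a 64-vertex pole patch of a 2562-vertex sphere is
  ≈ 2.5 % of the surface, i.e. a 0.65 μm contact diameter), `r_c = 0.5 μm`
  at the 2 `r_c` resolution limit; `f_scale = 10⁻⁴` keeps κ ≈ 18 k_BT₀ for
  a polymer shell with `E = 1 GPa`, `h = 20 nm`.  These are documented
  placeholder defaults; any application should supply its own material data.

## Shell elasticity

The shell is a closed triangulated 2-manifold whose vertices are DPD beads.
Deformation is measured per triangle against the stored reference geometry
(constant-strain-triangle, CST): with deformed edge matrix `D` and reference
edge matrix `D_m` in a local orthonormal frame, `F = D D_m⁻¹` and the
Green–Lagrange strain is `ε = (FᵀF − I)/2` — exactly invariant under rigid
motion.  The in-plane energy density is `½ C_ijkl ε_ij ε_kl` with the
orthotropic elastic tensor built from the identity and one structural tensor
`M = m ⊗ m`:

    C = Ka δδ + μ(δδ+δδ−δδ) + (μ_L−μ)(mmδ + ...) + c mmmm

`m` is the in-plane projection of the shell axis (the GvpA ribs of a GV run
nearly circumferentially, so the stiff/compliant axes are the axis and the
rib direction).  Setting `μ_L = μ, c = 0` recovers isotropy exactly.  The
engineering constants `(E_l, E_t, ν_lt, G)` map to `(Ka, μ, μ_L, c)` by
inverting the plane-stress stiffness; in the isotropic limit
`Ka = E/2(1−ν)`, `μ = E/2(1+ν)`.

Bending uses the Kantor–Nelson dihedral sum `Σ_e k_b (1 − cos(θ_e − θ_e⁰))`
with `k_b = 2κ/√3` and reference dihedrals `θ⁰` taken from the undeformed
mesh (spontaneous curvature = reference curvature) or zero.  Two properties
of this discretization matter:

* the mapping `k_b = 2κ/√3` reproduces continuum bending for cylinder-like
  (non-Gaussian) deformations, which govern buckling and vibrational modes;
* the dihedral sum carries an implicit Gaussian modulus `κ̄ = −4κ/3`
  (Gompper & Kroll), so the energy of a closed sphere relative to a flat
  reference is `8π(κ + κ̄/2) = 8πκ/3`, not `8πκ`.  For closed shells with
  reference-shape spontaneous curvature this constant shift is irrelevant;
  the suite pins the discrete value on icospheres to 5 %.

For GVs the bending energy is kept **isotropic** with
`κ = E_t h²/12(1−ν_lt²)` built on the smaller modulus, so the
circumferential instability has the correct cost; anisotropic bending
(the `κ_μ`, `κ_c` invariants) is out of scope.

Vertex forces are exact analytic gradients of the discrete energy (CST
chain rule; standard dihedral-angle gradients), verified against central
finite differences to 10⁻⁵ relative.  The elastic Hessian is assembled by
central differences of these forces with step `10⁻⁶ r_c` and symmetrized;
it reproduces energies of small perturbations to 1 % and has exactly six
null modes.

## Meshes

EMBs are icospheres (`10·4^s + 2` vertices; `s = 4` → 2562).  GVs are built
from stacked, staggered vertex rings: a cylinder of 37 rings × 36 vertices,
each cone tapering through rings of 20, 10, 5 vertices to an apex — 1404
vertices total.  Rings of unequal size are joined by an angular-sweep
triangulation; every generated mesh is validated as a closed, consistently
oriented 2-manifold with Euler characteristic 2.  The production GV has
`R = 2 r_c` (70 nm) and cylinder length `12 r_c`; the total length
(≈ 560 nm) lies in the typical *Anabaena* range and is chosen consistent
with the observed dominance of the (m, n) = (1, 2) mode, which requires
`L/R ≳ 5.5` at these moduli (at `L/R = 4–5` the (1,3) mode is lowest).

## DPD engine

Standard DPD pair forces with kernels `ω_C = 1 − r`, `ω_R = (1−r)^k`,
`ω_D = ω_R²` and per-pair exponents `k`; `σ² = 2γ k_B T₀` enforces the
fluctuation–dissipation balance.  Integration is velocity-Verlet with
λ = ½ velocity prediction.  Pair noise comes from a counter-based
splitmix64 hash of (seed, step, i, j), so Θ_ij = Θ_ji by construction and
every trajectory is exactly reproducible; the suite checks the stream is
unit Gaussian.  Neighbor search uses half-stencil linked cells rebuilt every
step.  Momentum is conserved to round-off; the kinetic temperature of all
Table-parameter fluids stays within 2 % of T₀ at `dt ≤ 0.01 τ`.

The equation of state is quadratic, `p = ρk_BT + α a ρ²`.  At ρ = 3 the
pointwise coefficient is slightly below the canonical fitted value
(≈ 0.096 at a = 100 versus 0.101 from fits dominated by higher densities);
the three-box least-squares fit over `a ∈ {50, 100, 150}` lands at ≈ 0.096,
inside the 0.100 ± 0.005 acceptance band.

Viscosity is measured by double periodic-Poiseuille flow (opposed body
forces in the two half-boxes) with a one-parameter least-squares parabola
fit.  **Gas phases**: gas beads carry the physical gas/water mass ratio
(see the mass rule above; N₂ ≈ 1.14·10⁻³ m) and the gas-pair friction γ_gg is
interpreted in the gas bead's own mass unit.  This is the only reading
under which the DPD gas is *less* viscous than DPD water — taking
γ_gg = 11–12 in the global mass unit makes the dissipative contribution to
the gas viscosity alone exceed the whole water viscosity.  With this
choice the measured same-set ratios are η_w/η_N₂ ≈ 43 and
η_w(gv)/η_air ≈ 230 (published comparison points: 63 and 48); the
acceptance script reports every component viscosity so other pairings can
be formed.  The remaining discrepancy is a known limitation: it depends on
kernel details and per-species mass tables that are not part of this
package's inputs.

## Fluid–structure coupling

Membrane vertices are DPD beads: they feel conservative `a_ow` repulsion
and dissipative/random pair forces from the fluids.  The no-slip friction
is `γ_o{w,g} = 2η̃ (2k+1)(2k+2)(2k+3)(2k+4) / (3π r_c⁴ ρ_{w,g} ρ_m)` with
`ρ_m` the vertex area density of the *reference* mesh (recomputed if the
area changes appreciably).

No-through condition: each step, fluid segments (minimum-image unwrapped)
are intersected with the end-of-step membrane faces (Möller–Trumbore over a
cached face cell map).  A crossing particle is returned to the hit point
and collides **elastically with the face**, treating the three vertices as
a wall of effective mass `3 m_v`: the normal relative velocity reverses,
and the wall impulse is split over the face vertices.  This conserves
momentum and energy exactly and transmits the kinetic part of the fluid
pressure to the shell — without the recoil the membrane only feels the
conservative `a_ow` push and responds *wrongly* to solvent-pressure
changes.  A Maxwell-flux re-insertion variant (`maxwell=True`) implements
the thermal-wall picture literally, but re-sampling inside the soft `a_ow`
potential hill pumps ≈ 5 % excess heat into the fluid, so the elastic
collision is the default.  A closest-point "rescue" pass catches the rare
crossings swept by membrane motion within the step (the segment test
against end-of-step faces cannot see them); interior solvent counts stay
exactly zero over 10⁴-step runs.  Because the free-floating shell would
drift through the periodic boundary (tearing the unwrapped mesh), the whole
system is translated each step to pin the membrane centroid (`Recenter`).

The ideal DPD gas inside a shell has negligible pressure; mechanical
balance is restored by the face force `f_p = −p A n_inward/3` per vertex
(zero net force and torque on each triangle).  Solvent pressure is driven
through `a_ww(t)` ramps; the achieved Δp is measured from the conservative
virial rather than assumed from the EOS.

## Open boundaries and shear

OBMD buffers occupy slabs at the ±x ends.  Buffer populations relax as
`ΔN = −(Δt/τ_B)(N − α_B N₀)` with stochastic integer rounding; insertions
use a USHER steepest-descent search to the mean per-particle conservative
energy (a stalled descent — the frozen cage cannot relax — is accepted up
to `0.2 a_ww` above target), with velocities drawn as local stream plus
Maxwell; deletions remove particles nearest the open face.  The external
buffer force implements the momentum balance
`J·n A = Σf + Σ Δ(mv)/Δt`, where the exchange term includes particles that
left through the open face (omitting either the stream velocity of
insertions or the departures loses ~15 % of the imposed shear stress).
`τ_B` defaults to 10 τ: stiffer feedback (e.g. 10 Δt) exchanges several
particles per step and measurably heats the fluid.  With
`P_yx = η̃ γ̇` on both buffers the ROI develops a linear profile whose
slope matches the target within a few percent, closing the loop with the
Poiseuille viscosity.

## Protocols

Quasi-static (dry) experiments minimize `U_el + U_b − f_ext·x + p V`
with L-BFGS-B on the analytic gradients (the pressure term enters through
the exact gradient of the divergence-theorem volume).  Stretching spreads
the load over 64-vertex pole patches (EMB) or the cone vertices (GV);
wrinkling is flagged at the first discontinuous drop of the transverse
diameter, computed as twice the mean distance of equatorial vertices from
their center of mass.  GV strains are extracted from the cylindrical
section only.

Buckling: shells are seeded with a smooth pole-dimple imperfection of depth
half a thickness and width equal to the elastic boundary-layer length
`(κR²/Y)^¼`.  (A white per-vertex perturbation makes the knockdown factor
resolution-dependent: its smooth spectral content varies with mesh
density.)  The critical pressure is located by bisection; a state counts
as buckled when its volume loss exceeds 2.5× the linear extrapolation —
absolute-volume thresholds misfire on the smooth pre-buckling branch.
With these choices the knockdown factor relative to the classical
`p_c = 4√(κY)/R²` is ≈ 0.87 with ≤ 2 % spread over `R ∈ {1.5, 2, 3}`, and
the measured scaling exponent is −1.95.  Deep post-buckling minimization
is allowed to end non-converged (the pV enthalpy of an inverted shell is
unbounded); the caller judges the volume.  The GV buckles into a
multi-lobed cross-section (n = 4 at these moduli; lobe count from the
angular Fourier power of the equatorial radius) that collapses to two
lobes at roughly twice the threshold pressure.

Modes: the mass-weighted eigenproblem of the elastic Hessian gives
frequencies and shapes; GV modes are classified by projecting the radial
displacement of the cylindrical section onto the Donnel basis
`sin(λ_m z + mπ/2)·{cos,sin}(nφ)`, `λ_m = mπ/H_cyl`.  Quasiharmonic
analysis of a trajectory uses centering, least-RMSD (Kabsch) alignment,
the covariance `Σ` and `ω = √(k_BT₀/λ′)` from `Σ′ = M^½ Σ M^½` — the
equipartition-consistent resolution of the printed eigenvalue relations —
discarding the six near-null variance directions.  On the production GV
the lowest mode is the doubly degenerate (1,2) pair (split < 0.1 %); a
Gaussian/Langevin sampler of a known quadratic energy returns the Hessian
frequencies within 5–10 %.

Shear: the Jeffery orbit `tan θ = (a/b) tan(ab γ̇ t/(a²+b²))` is
implemented with branch continuation; the fit has a free time offset and
reports the aspect ratio ≥ 1 (with a free angle reference, r and 1/r
describe the same orbit).  The driven-shell experiment pins a small GV in
the OBMD shear flow; at `a_ow = 0` with the no-slip γ_ow it tumbles and
θ(t) fits the orbit within 10 % rms, while at large `a_ow` the repulsion
lubricates the interface and the shell aligns at a finite angle.

## Scaled-down study sizes

Published-scale runs (2562-vertex shells in large boxes, 4000 τ mode
trajectories) are cluster-scale.  The suite and the acceptance script use:
7³–8³ boxes (≈ 1000–1500 fluid beads), 162/642-vertex spheres and the
128-vertex GV for solvated and shear runs, the full 1404-vertex GV for
Hessian modes and dry protocols, 10⁴-step coupled runs, and 60 τ shear
trajectories (≈ a quarter Jeffery period, including one flip).  These sizes
are the package's chosen study conditions; all tolerances quoted above were
set by the protocol definitions, not adjusted to runs.

## Known limitations

* The solvated compression slope converges to the sphere/cylinder
  volume-strain coefficients
  only as the shell becomes large compared with `r_c` and stiff compared
  with k_BT; at the desk sizes above it is reproduced to ~20 %, with the
  excess compressibility consistent with thermal-wrinkle renormalization.
* The torsion slope sits ~15 % below the thin-tube closed form because the
  rigidly rotated cones do not contribute their compliance.
* Gas-phase viscosities (hence the water/gas ratios) depend on per-species
  mass conventions documented above.
* Printed-value targets that require the companion tabulated material data
  (absolute buckling pressures, the 23.1 τ⁻¹ mode frequency, the 0.099 μR₀
  wrinkling force) are reported as computed for the documented presets, not
  asserted.
* No gas permeation, no surface tension between phases (a_wg = 0), no
  nonlinear elastic coefficients, no rupture.
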