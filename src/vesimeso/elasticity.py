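"""Thin-shell elasticity on triangulated surfaces.

In-plane energy uses the constant-strain-triangle discretization of the
continuum membrane energy U_el = ∫ ½ C_ijkl ε_ij ε_kl dA with the
Green-Lagrange strain ε = (FᵀF − I)/2 per triangle; the elastic tensor is
either isotropic (bulk modulus K_a, shear modulus μ) or orthotropic with a
per-face structural direction m (in-plane shear constant μ_L along the
anisotropy and stiffness coefficient c).  Bending uses the Kantor-Nelson
dihedral discretization Σ_e k_b (1 − cos(θ_e − θ_e⁰)) with k_b = 2κ/√3.
Vertex forces are exact analytic gradients of the discrete energy; the
Hessian is obtained by central differences of those forces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._kernels import membrane_forces
from .meshgen import RibField, TriMesh

KB_FACTOR = 2.0 / math.sqrt(3.0)  # k_b = (2/sqrt 3) kappa on near-hexagonal lattices


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneMaterial:
    """2D shell material in reduced units.

    Ka, mu: isotropic bulk and shear moduli [ε/r_c²]; muL, c: orthotropic
    in-plane shear constant and anisotropy stiffness (muL = mu, c = 0 for an
    isotropic shell); kappa: bending constant [ε]; nu: 2D Poisson ratio.
    """

    Ka: float
    mu: float
    kappa: float
    nu: float = 1.0 / 3.0
    muL: float = None
    c: float = 0.0
    anisotropic: bool = False

    def __post_init__(self):
        if self.muL is None:
            object.__setattr__(self, "muL", self.mu)
        if self.Ka <= 0 or self.mu <= 0 or self.kappa < 0:
            raise ValueError("Ka, mu must be positive and kappa non-negative")
        if self.anisotropic and (self.muL <= 0 or self.c <= 0):
            raise ValueError("orthotropic stability requires muL > 0 and c > 0")

    @property
    def E2d(self) -> float:
        """2D Young modulus of the isotropic part, E = 4 Ka mu / (Ka + mu)."""
        return 4.0 * self.Ka * self.mu / (self.Ka + self.mu)

    @property
    def nu_2d(self) -> float:
        """2D Poisson ratio of the isotropic part, (Ka − mu)/(Ka + mu)."""
        return (self.Ka - self.mu) / (self.Ka + self.mu)


@dataclass(frozen=True)
class OrthotropicEngineering:
    """Engineering constants of a 2D orthotropic shell.

    E_l: Young modulus along the structural direction m (the shell axis),
    E_t: transverse modulus (along the ribs), nu_lt: Poisson ratio coupling
    them (reciprocity: nu_tl E_l = nu_lt E_t), G: in-plane shear modulus
    (equals muL), h: shell thickness in reduced length units.
    """

    E_l: float
    E_t: float
    nu_lt: float
    G: float
    h: float

    def __post_init__(self):
        if min(self.E_l, self.E_t, self.G, self.h) <= 0:
            raise ValueError("E_l, E_t, G, h must be positive")

    @property
    def nu_tl(self) -> float:
        return self.nu_lt * self.E_t / self.E_l


def engineering_to_tensor(eng: OrthotropicEngineering):
    """Invert the 2D orthotropic compliance into (Ka, mu, muL, c).

    The plane-stress stiffness in the (m, m⊥) basis is
    Q11 = E_l/Δ, Q22 = E_t/Δ, Q12 = ν_lt E_t/Δ, Q66 = G with
    Δ = 1 − ν_lt² E_t/E_l; matching against the structural-tensor form of the
    elastic tensor gives Ka = (Q22+Q12)/2, μ = (Q22−Q12)/2, μ_L = Q66,
    c = Q11 + Q22 − 2 Q12 − 4 Q66.
    """
    delta = 1.0 - eng.nu_lt ** 2 * eng.E_t / eng.E_l
    if delta <= 0:
        raise ValueError("non-invertible compliance: nu_lt^2 E_t/E_l >= 1")
    Q11 = eng.E_l / delta
    Q22 = eng.E_t / delta
    Q12 = eng.nu_lt * eng.E_t / delta
    Q66 = eng.G
    Ka = 0.5 * (Q22 + Q12)
    mu = 0.5 * (Q22 - Q12)
    muL = Q66
    c = Q11 + Q22 - 2.0 * Q12 - 4.0 * Q66
    return Ka, mu, muL, c


def tensor_to_engineering(Ka, mu, muL, c, h) -> OrthotropicEngineering:
    """Inverse of :func:`engineering_to_tensor` (round-trip oracle)."""
    Q22 = Ka + mu
    Q12 = Ka - mu
    Q66 = muL
    Q11 = c + 2.0 * Q12 - Q22 + 4.0 * Q66
    E_l = Q11 - Q12 ** 2 / Q22
    E_t = Q22 - Q12 ** 2 / Q11
    nu_lt = Q12 / Q22
    return OrthotropicEngineering(E_l=E_l, E_t=E_t, nu_lt=nu_lt, G=Q66, h=h)


def gv_material(eng: OrthotropicEngineering) -> MembraneMaterial:
    """Orthotropic membrane with isotropic bending κ = E_t h²/(12(1−ν_lt²))."""
    Ka, mu, muL, c = engineering_to_tensor(eng)
    kappa = eng.E_t * eng.h ** 2 / (12.0 * (1.0 - eng.nu_lt ** 2))
    return MembraneMaterial(Ka=Ka, mu=mu, muL=muL, c=c, kappa=kappa,
                            nu=eng.nu_lt, anisotropic=True)


def emb_material(E2d: float, nu: float, h: float) -> MembraneMaterial:
    """Isotropic membrane with thin-shell bending κ = E h²/(12(1−ν²))."""
    Ka = E2d / (2.0 * (1.0 - nu))
    mu = E2d / (2.0 * (1.0 + nu))
    kappa = E2d * h ** 2 / (12.0 * (1.0 - nu ** 2))
    return MembraneMaterial(Ka=Ka, mu=mu, kappa=kappa, nu=nu)


# ---------------------------------------------------------------------------
# Strain
# ---------------------------------------------------------------------------

def triangle_strain(inv_dm: np.ndarray, d1: np.ndarray, d2: np.ndarray):
    """Deformation gradient F (3x2) and Green-Lagrange strain ε (2x2).

    ``inv_dm`` is the inverse 2D reference edge matrix of the triangle and
    d1, d2 the deformed 3D edge vectors from vertex 0.
    """
    D = np.column_stack([d1, d2])
    F = D @ inv_dm
    C = F.T @ F
    if np.linalg.det(C) <= 0:
        raise ValueError("degenerate deformed triangle")
    eps = 0.5 * (C - np.eye(2))
    return F, eps


def strain_states(mesh: TriMesh):
    """Per-face (F, eps) arrays for the current deformed configuration."""
    x = mesh.vertices
    f = mesh.faces
    d1 = x[f[:, 1]] - x[f[:, 0]]
    d2 = x[f[:, 2]] - x[f[:, 0]]
    D = np.stack([d1, d2], axis=2)           # (F,3,2)
    F = np.einsum("fik,fkj->fij", D, mesh.inv_dm)
    C = np.einsum("fki,fkj->fij", F, F)
    eps = 0.5 * (C - np.eye(2)[None])
    return F, eps


# ---------------------------------------------------------------------------
# Energies and forces
# ---------------------------------------------------------------------------

def _kernel_args(mesh: TriMesh, material: MembraneMaterial,
                 rib: RibField | None, bend: bool):
    if material.anisotropic:
        if rib is None:
            raise ValueError("orthotropic material requires a rib field")
        m2 = rib.m2
        aniso = True
    else:
        m2 = np.zeros((mesh.n_faces, 2))
        aniso = False
    kb = KB_FACTOR * material.kappa if bend else 0.0
    return m2, aniso, kb


def elastic_energy(mesh: TriMesh, material: MembraneMaterial,
                   rib: RibField | None = None, bend: bool = True):
    """Total elastic energy U = U_el + U_b with per-face/per-edge breakdown."""
    forces = np.zeros_like(mesh.vertices)
    face_e = np.zeros(mesh.n_faces)
    edge_e = np.zeros(len(mesh.edges))
    m2, aniso, kb = _kernel_args(mesh, material, rib, bend)
    U_el, U_b = membrane_forces(
        mesh.vertices, mesh.faces, mesh.inv_dm, mesh.ref_area, m2,
        material.Ka, material.mu, material.muL, material.c, aniso,
        mesh.edges, mesh.theta0, kb, forces, face_e, edge_e)
    return {"inplane": U_el, "bending": U_b, "total": U_el + U_b,
            "face_inplane": face_e, "edge_bending": edge_e, "forces": forces}


def vertex_forces(mesh: TriMesh, material: MembraneMaterial,
                  rib: RibField | None = None, bend: bool = True) -> np.ndarray:
    """Per-vertex forces −∂U/∂x of the total elastic energy."""
    return elastic_energy(mesh, material, rib, bend)["forces"]


def inplane_energy_isotropic(mesh: TriMesh, Ka: float, mu: float) -> float:
    mat = MembraneMaterial(Ka=Ka, mu=mu, kappa=0.0)
    return elastic_energy(mesh, mat, bend=False)["inplane"]


def inplane_energy_orthotropic(mesh: TriMesh, rib: RibField, Ka: float,
                               mu: float, muL: float, c: float) -> float:
    mat = MembraneMaterial(Ka=Ka, mu=mu, muL=muL, c=c, kappa=0.0,
                           anisotropic=True)
    return elastic_energy(mesh, mat, rib=rib, bend=False)["inplane"]


def bending_energy(mesh: TriMesh, kappa: float, nu: float = 1.0 / 3.0,
                   spontaneous: bool = True) -> float:
    """Kantor-Nelson bending energy.

    ``spontaneous=True`` measures dihedral angles against the reference shape
    (spontaneous curvature equal to the reference curvature); ``False`` uses
    flat spontaneous curvature θ⁰ = 0.  The Gaussian-curvature term of the
    continuum energy is a topological constant for closed shells and is
    omitted (ν enters only through κ itself).
    """
    from .meshgen import dihedral_angles
    theta = dihedral_angles(mesh.vertices, mesh.edges)
    theta0 = mesh.theta0 if spontaneous else np.zeros_like(theta)
    kb = KB_FACTOR * kappa
    return float((kb * (1.0 - np.cos(theta - theta0))).sum())


# ---------------------------------------------------------------------------
# Hessian and normal modes
# ---------------------------------------------------------------------------

def elastic_hessian(mesh: TriMesh, material: MembraneMaterial,
                    rib: RibField | None = None, step: float = 1e-6) -> np.ndarray:
    """3V×3V Hessian of U by central differences of the analytic forces."""
    x0 = mesh.vertices.copy()
    n = x0.size
    H = np.empty((n, n))
    forces = np.zeros_like(x0)
    face_e = np.zeros(mesh.n_faces)
    edge_e = np.zeros(len(mesh.edges))
    m2, aniso, kb = _kernel_args(mesh, material, rib, bend=True)
    args = (mesh.faces, mesh.inv_dm, mesh.ref_area, m2,
            material.Ka, material.mu, material.muL, material.c, aniso,
            mesh.edges, mesh.theta0, kb)
    flat = x0.ravel()
    for k in range(n):
        orig = flat[k]
        flat[k] = orig + step
        forces[:] = 0.0
        membrane_forces(x0, *args, forces, face_e, edge_e)
        fp = forces.ravel().copy()
        flat[k] = orig - step
        forces[:] = 0.0
        membrane_forces(x0, *args, forces, face_e, edge_e)
        fm = forces.ravel()
        H[:, k] = -(fp - fm) / (2.0 * step)
        flat[k] = orig
    H = 0.5 * (H + H.T)
    return H


def normal_modes(hessian: np.ndarray, masses: np.ndarray,
                 n_rigid: int = 6, kBT: float = 1.0):
    """Mass-weighted eigenmodes of the elastic Hessian.

    Solves M ẍ + V x = 0 (no solvent/gas damping): eigenvectors of
    M^(−1/2) V M^(−1/2) give ω² directly.  Returns (omegas, modes) with the
    ``n_rigid`` rigid-body null modes discarded and frequencies ascending;
    ``modes[:, k]`` is the Cartesian displacement pattern of ω_k.
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    m3 = np.repeat(masses, 3)
    inv_sqrt_m = 1.0 / np.sqrt(m3)
    Hm = hessian * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    vals, vecs = scipy.linalg.eigh(Hm)
    order = np.argsort(np.abs(vals))
    rigid = order[:n_rigid]
    keep = np.setdiff1d(np.arange(len(vals)), rigid)
    vals_k = vals[keep]
    vecs_k = vecs[:, keep]
    if np.any(vals_k < -1e-8 * np.abs(vals).max()):
        raise ValueError("Hessian is not positive semidefinite: not at a minimum")
    omegas = np.sqrt(np.clip(vals_k, 0.0, None))
    asc = np.argsort(omegas)
    modes = (vecs_k[:, asc] * inv_sqrt_m[:, None])
    return omegas[asc], modes
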