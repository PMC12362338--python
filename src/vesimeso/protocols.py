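"""Numerical experiments on shells: stretching, compression, buckling,
torsion, vibrational modes, and shear-flow response.

Quasi-static (dry) protocols minimize the total potential — elastic energy
plus the work potential of the applied load (constant point forces, or the
pV enthalpy term for uniform pressure) — with L-BFGS using the analytic
force gradients.  Solvated protocols drive the DPD engine.  Mode analysis
offers two routes: direct diagonalization of the elastic Hessian, and the
quasiharmonic (covariance) analysis of a thermal trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from . import elasticity as el
from .meshgen import RibField, TriMesh, enclosed_volume


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class StretchRecord:
    F_tot: np.ndarray
    D: np.ndarray = None                 # transverse diameter (EMB)
    sigma_zz: np.ndarray = None          # GV stress/strain series
    eps_zz: np.ndarray = None
    eps_phiphi: np.ndarray = None
    wrinkle_force: float = None
    snapshots: list = field(default_factory=list)


@dataclass
class CompressionRecord:
    delta_p: np.ndarray
    dV_over_V0: np.ndarray
    buckled: np.ndarray
    lobe_count: np.ndarray
    critical_pressure: float = None
    snapshots: list = field(default_factory=list)


@dataclass
class ModeRecord:
    omega: float
    m: int
    n: int
    branch: str
    ambiguous: bool = False
    axial_profile: np.ndarray = None


@dataclass
class ShearRecord:
    t: np.ndarray
    theta_t: np.ndarray
    mean_theta: float
    std_theta: float
    regime: str                          # 'tumbling' | 'aligned'


# ---------------------------------------------------------------------------
# Quasi-static minimization
# ---------------------------------------------------------------------------

def minimize_shell(mesh: TriMesh, material, rib: RibField | None = None,
                   external_forces: np.ndarray | None = None,
                   pressure: float = 0.0,
                   fixed: np.ndarray | None = None,
                   x0: np.ndarray | None = None,
                   gtol: float = 1e-6, maxiter: int = 20000) -> TriMesh:
    """Minimize U_el + U_b − f_ext·x + p·V over free vertex positions.

    ``pressure`` > 0 is an external (inward) pressure acting through the
    enclosed-volume enthalpy term.  ``fixed`` vertices are held at their
    positions in ``x0`` (or the mesh's current vertices).
    """
    n = mesh.n_vertices
    start = (mesh.vertices if x0 is None else x0).copy()
    free = np.ones(n, dtype=bool)
    if fixed is not None:
        free[fixed] = False
    fidx = np.nonzero(free)[0]
    faces = mesh.faces

    def pack(x_all):
        return x_all[fidx].ravel()

    def unpack(z):
        x_all = start.copy()
        x_all[fidx] = z.reshape(-1, 3)
        return x_all

    def objective(z):
        x_all = unpack(z)
        m = mesh.with_vertices(x_all)
        res = el.elastic_energy(m, material, rib)
        U = res["total"]
        g = -res["forces"]
        if external_forces is not None:
            U -= float((external_forces * x_all).sum())
            g = g - external_forces
        if pressure != 0.0:
            v0 = x_all[faces[:, 0]]
            v1 = x_all[faces[:, 1]]
            v2 = x_all[faces[:, 2]]
            V = float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)
            U += pressure * V
            gV = np.zeros_like(x_all)
            np.add.at(gV, faces[:, 0], np.cross(v1, v2) / 6.0)
            np.add.at(gV, faces[:, 1], np.cross(v2, v0) / 6.0)
            np.add.at(gV, faces[:, 2], np.cross(v0, v1) / 6.0)
            g = g + pressure * gV
        return U, g[fidx].ravel()

    res = scipy.optimize.minimize(
        objective, pack(start), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14,
                 "maxcor": 20})
    if not res.success and "ABNORMAL" in str(res.message):
        # beyond collapse the pV enthalpy is unbounded (shell inversion);
        # return the last iterate and let the caller judge the volume
        import warnings
        warnings.warn(f"shell minimization did not converge: {res.message}")
    return mesh.with_vertices(unpack(res.x))


# ---------------------------------------------------------------------------
# Stretching
# ---------------------------------------------------------------------------

def pole_patches(mesh: TriMesh, n_per_pole: int = 64):
    """Vertex sets nearest the ±z poles of the reference shape (ties by index)."""
    z = mesh.reference_vertices[:, 2]
    top = np.argsort(-z, kind="stable")[:n_per_pole]
    bot = np.argsort(z, kind="stable")[:n_per_pole]
    return np.sort(top), np.sort(bot)


def equatorial_diameter(verts: np.ndarray, ref: np.ndarray,
                        band: float = 0.08) -> float:
    """Twice the mean distance of equatorial vertices from their COM.

    Equatorial vertices are chosen on the reference shape: |z| within
    ``band`` times the z-extent of the shell.
    """
    zc = ref[:, 2] - ref[:, 2].mean()
    sel = np.abs(zc) < band * (zc.max() - zc.min()) / 2.0
    pts = verts[sel][:, :2]
    com = pts.mean(axis=0)
    return 2.0 * float(np.linalg.norm(pts - com, axis=1).mean())


def stretch_emb(mesh: TriMesh, material, F_values, n_per_pole: int = 64,
                drop_frac: float = 0.05, keep_snapshots: bool = False,
                perturb: float = 0.0, seed: int = 0) -> StretchRecord:
    """Pole-loaded stretching of a spherical shell.

    Total force F is spread over ``n_per_pole`` vertices at each pole (±z);
    the transverse diameter D is tracked and a wrinkling transition is
    flagged at the first discontinuous drop of D exceeding ``drop_frac``
    relative to the previous load step.  Wrinkling is a symmetry-breaking
    instability: give a nonzero ``perturb`` (seeded white displacement per
    load step) so the minimizer can leave the symmetric branch.
    """
    top, bot = pole_patches(mesh, n_per_pole)
    rec = StretchRecord(F_tot=np.asarray(F_values, dtype=float),
                        D=np.zeros(len(F_values)))
    rng = np.random.default_rng(seed)
    current = mesh.vertices.copy()
    wrinkle = None
    prev_D = None
    for i, F in enumerate(rec.F_tot):
        ext = np.zeros_like(mesh.vertices)
        ext[top, 2] = F / len(top)
        ext[bot, 2] = -F / len(bot)
        start = current
        if perturb > 0:
            start = current + perturb * rng.standard_normal(current.shape)
        out = minimize_shell(mesh, material, external_forces=ext, x0=start)
        current = out.vertices
        D = equatorial_diameter(current, mesh.reference_vertices)
        rec.D[i] = D
        if keep_snapshots:
            rec.snapshots.append(current.copy())
        if prev_D is not None and wrinkle is None and D < prev_D * (1 - drop_frac):
            wrinkle = float(F)
        prev_D = D
    rec.wrinkle_force = wrinkle
    return rec


def _gv_sections(mesh: TriMesh, L_cyl: float):
    zc = mesh.reference_vertices[:, 2] - mesh.reference_vertices[:, 2].mean()
    cones = np.abs(zc) > L_cyl / 2.0 + 1e-9
    top_ring = np.abs(zc - L_cyl / 2.0) < 1e-6
    bot_ring = np.abs(zc + L_cyl / 2.0) < 1e-6
    mid = np.abs(zc) < L_cyl / 4.0
    return cones, top_ring, bot_ring, mid


def stretch_gv(mesh: TriMesh, material, rib: RibField, F_values,
               L_cyl: float, R: float) -> StretchRecord:
    """Axial stretching of a GV with forces spread over the cone vertices.

    Stress and strain are extracted from the cylindrical section only:
    sigma_zz = F/(2 pi R), eps_zz from the distance between the cylinder end
    rings, eps_phiphi from the mid-section radius.
    """
    cones, top_ring, bot_ring, mid = _gv_sections(mesh, L_cyl)
    up = cones & (mesh.reference_vertices[:, 2]
                  > mesh.reference_vertices[:, 2].mean())
    dn = cones & ~up
    H0 = (mesh.reference_vertices[top_ring, 2].mean()
          - mesh.reference_vertices[bot_ring, 2].mean())
    c0 = mesh.reference_vertices[mid, :2].mean(axis=0)
    R0 = float(np.linalg.norm(mesh.reference_vertices[mid, :2] - c0,
                              axis=1).mean())
    n = len(F_values)
    rec = StretchRecord(F_tot=np.asarray(F_values, dtype=float),
                        sigma_zz=np.zeros(n), eps_zz=np.zeros(n),
                        eps_phiphi=np.zeros(n))
    current = mesh.vertices.copy()
    for i, F in enumerate(rec.F_tot):
        ext = np.zeros_like(mesh.vertices)
        ext[up, 2] = F / up.sum()
        ext[dn, 2] = -F / dn.sum()
        out = minimize_shell(mesh, material, rib=rib, external_forces=ext,
                             x0=current)
        current = out.vertices
        H = current[top_ring, 2].mean() - current[bot_ring, 2].mean()
        c = current[mid, :2].mean(axis=0)
        Rm = float(np.linalg.norm(current[mid, :2] - c, axis=1).mean())
        rec.sigma_zz[i] = F / (2.0 * math.pi * R)
        rec.eps_zz[i] = (H - H0) / H0
        rec.eps_phiphi[i] = (Rm - R0) / R0
    return rec


# ---------------------------------------------------------------------------
# Compression / buckling (dry)
# ---------------------------------------------------------------------------

def lobe_count(verts: np.ndarray, ref: np.ndarray, band: float = 0.12,
               n_max: int = 8) -> int:
    """Dominant angular Fourier mode of the equatorial radius (0 if none)."""
    zc = ref[:, 2] - ref[:, 2].mean()
    sel = np.abs(zc) < band * (zc.max() - zc.min()) / 2.0
    pts = verts[sel][:, :2] - verts[sel][:, :2].mean(axis=0)
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    r = np.linalg.norm(pts, axis=1)
    r_mean = r.mean()
    r = r - r_mean
    if np.var(r) < (0.02 * r_mean) ** 2:   # round within 2%: no lobes
        return 0
    power = np.zeros(n_max + 1)
    for nn in range(2, n_max + 1):
        cc = (r * np.cos(nn * phi)).mean()
        ss = (r * np.sin(nn * phi)).mean()
        power[nn] = cc * cc + ss * ss
    return int(np.argmax(power))


def dimple_imperfection(mesh: TriMesh, material, delta_over_h: float = 0.5
                        ) -> np.ndarray:
    """Smooth inward pole dimple of depth delta_over_h shell thicknesses.

    The dimple width is the shell's elastic boundary-layer length
    l = (kappa R^2 / Y)^(1/4), so the imperfection couples to the buckling
    mode identically for every radius (a white per-vertex perturbation
    would not: its smooth spectral content depends on the mesh resolution).
    """
    ref = mesh.reference_vertices
    c = ref.mean(axis=0)
    r = ref - c
    R = float(np.linalg.norm(r, axis=1).mean())
    h_eff = math.sqrt(12.0 * material.kappa / material.E2d)
    ell = (material.kappa * R * R / material.E2d) ** 0.25
    rad = np.linalg.norm(r, axis=1)
    theta = np.arccos(np.clip(r[:, 2] / rad, -1.0, 1.0))
    s = R * theta
    depth = delta_over_h * h_eff * np.exp(-(s / (2.0 * ell)) ** 2)
    return -(depth / rad)[:, None] * r


def dry_buckle(mesh: TriMesh, material, rib: RibField | None, p: float,
               seed: int = 0, perturb: float | None = None,
               x0: np.ndarray | None = None) -> tuple[TriMesh, dict]:
    """Quasi-static equilibrium under uniform inward pressure p.

    A deterministic smooth imperfection (pole dimple of depth half a shell
    thickness by default) breaks the symmetry so the threshold reflects an
    imperfect shell, as real ones are.  Returns (relaxed mesh, diagnostics).
    """
    start = mesh.vertices.copy() if x0 is None else x0.copy()
    if perturb is None:
        start = start + dimple_imperfection(mesh, material)
    elif perturb > 0:
        rng = np.random.default_rng(seed)
        start = start + perturb * rng.standard_normal(start.shape)
    out = minimize_shell(mesh, material, rib=rib, pressure=p, x0=start)
    V0 = enclosed_volume(mesh.with_vertices(mesh.reference_vertices))
    V = enclosed_volume(out)
    dV = V / V0 - 1.0
    lobes = lobe_count(out.vertices, mesh.reference_vertices)
    return out, {"dV_over_V0": dV, "lobes": lobes, "V0": V0, "V": V}


def compress_dry(mesh: TriMesh, material, rib: RibField | None,
                 p_values, seed: int = 0,
                 buckle_factor: float = 3.0) -> CompressionRecord:
    """Pressure sweep with warm starts; buckling flagged when the volume
    loss exceeds ``buckle_factor`` times the extrapolated linear response."""
    p_values = np.asarray(p_values, dtype=float)
    n = len(p_values)
    rec = CompressionRecord(delta_p=p_values, dV_over_V0=np.zeros(n),
                            buckled=np.zeros(n, dtype=bool),
                            lobe_count=np.zeros(n, dtype=int))
    x = mesh.vertices.copy()
    slope = None
    crit = None
    for i, p in enumerate(p_values):
        out, diag = dry_buckle(mesh, material, rib, p, seed=seed, x0=x)
        x = out.vertices
        rec.dV_over_V0[i] = diag["dV_over_V0"]
        rec.lobe_count[i] = diag["lobes"]
        if i == 1 and p_values[1] > 0:
            slope = rec.dV_over_V0[1] / p_values[1]
        if slope is not None and p > 0:
            linear = slope * p
            if rec.dV_over_V0[i] < buckle_factor * linear and linear < 0:
                rec.buckled[i] = True
                if crit is None:
                    crit = float(p)
    rec.critical_pressure = crit
    return rec


def critical_pressure_sphere(material, R0: float,
                             knockdown: float = 1.0) -> float:
    """Classical spherical-shell buckling pressure with knockdown factor.

    p_c = knockdown * 4 sqrt(kappa Y_2d) / R0^2 (Zoelly result expressed in
    the 2D Young modulus Y_2d and bending constant kappa).
    """
    if not (0.0 < knockdown <= 1.0):
        raise ValueError("knockdown must be in (0, 1]")
    return knockdown * 4.0 * math.sqrt(material.kappa * material.E2d) / R0 ** 2


def find_critical_pressure(mesh: TriMesh, material, rib: RibField | None,
                           p_lo: float, p_hi: float, seed: int = 0,
                           tol_rel: float = 0.02,
                           deviation_factor: float = 2.5) -> float:
    """Bisect on pressure for the buckling transition of a dry shell.

    A state counts as buckled when its volume loss exceeds
    ``deviation_factor`` times the linear extrapolation from p_lo (the
    smooth pre-buckling branch tracks the linear slope closely, collapse
    overshoots it by an order of magnitude).
    """
    out, d0 = dry_buckle(mesh, material, rib, p_lo, seed=seed)
    if p_lo <= 0 or d0["dV_over_V0"] >= 0:
        raise ValueError("p_lo must give a small negative volume response")
    slope = d0["dV_over_V0"] / p_lo

    def buckled(p):
        _, d = dry_buckle(mesh, material, rib, p, seed=seed)
        return d["dV_over_V0"] < deviation_factor * slope * p

    if not buckled(p_hi):
        raise ValueError("p_hi does not buckle the shell")
    lo, hi = p_lo, p_hi
    while (hi - lo) / hi > tol_rel:
        mid = 0.5 * (lo + hi)
        if buckled(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Torsion
# ---------------------------------------------------------------------------

def torsion_gv(mesh: TriMesh, material, rib: RibField, twist_angle: float,
               L_cyl: float) -> float:
    """Restoring torque for a rigid counter-rotation of the GV ends.

    The cone sections (|z| beyond the cylinder) are rotated by ±twist/2
    about z and held fixed; the torque is evaluated from the elastic forces
    on one rotated end.  Thin-tube theory gives the small-twist slope
    2 pi R^3 mu_L / L_cyl.
    """
    zc = mesh.reference_vertices[:, 2] - mesh.reference_vertices[:, 2].mean()
    cones = np.abs(zc) > L_cyl / 2.0 + 1e-9
    up = cones & (zc > 0)
    dn = cones & (zc < 0)
    x = mesh.vertices.copy()
    for sel, ang in ((up, twist_angle / 2.0), (dn, -twist_angle / 2.0)):
        c, s = math.cos(ang), math.sin(ang)
        xy = x[sel, :2].copy()
        x[sel, 0] = c * xy[:, 0] - s * xy[:, 1]
        x[sel, 1] = s * xy[:, 0] + c * xy[:, 1]
    fixed = np.nonzero(cones)[0]
    out = minimize_shell(mesh, material, rib=rib, fixed=fixed, x0=x)
    forces = el.vertex_forces(out, material, rib=rib)
    r = out.vertices[up]
    f = forces[up]
    torque = float((r[:, 0] * f[:, 1] - r[:, 1] * f[:, 0]).sum())
    # elastic force on the held end is the internal reaction; the applied
    # torque balancing it has the opposite sign
    return -torque


# ---------------------------------------------------------------------------
# Mode analysis
# ---------------------------------------------------------------------------

def kabsch_rotation(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-RMSD rotation R such that R @ x_i aligns centered x onto ref."""
    H = x.T @ ref
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def quasiharmonic_modes(trajectory: np.ndarray, masses: np.ndarray,
                        reference: np.ndarray, kBT: float = 1.0,
                        n_rigid: int = 6):
    """Mode frequencies from the covariance of a thermal trajectory.

    Frames are centered, aligned to the reference by least-RMSD rotation,
    and the covariance Σ of the aligned coordinates is mass-weighted,
    Σ' = M^(1/2) Σ M^(1/2); eigenvalues λ' give ω = sqrt(k_B T0 / λ').
    The ``n_rigid`` near-null variance directions (removed rigid motions)
    are discarded.  Returns (omegas ascending, modes, n_usable).
    """
    traj = np.asarray(trajectory, dtype=float)
    n_frames, n_vert, _ = traj.shape
    dof = 3 * n_vert
    if n_frames < dof // 4:
        import warnings
        warnings.warn(f"short trajectory: {n_frames} frames for {dof} dof; "
                      "high modes will be unreliable")
    refc = reference - reference.mean(axis=0)
    aligned = np.empty_like(traj)
    for k in range(n_frames):
        x = traj[k] - traj[k].mean(axis=0)
        aligned[k] = x @ kabsch_rotation(x, refc).T
    flat = aligned.reshape(n_frames, dof)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / n_frames
    m3 = np.repeat(np.asarray(masses, dtype=float), 3)
    sm = np.sqrt(m3)
    covp = cov * sm[:, None] * sm[None, :]
    vals, vecs = scipy.linalg.eigh(covp)
    usable = int((vals > 1e-12 * vals.max()).sum())
    if usable < dof - n_rigid:
        import warnings
        warnings.warn(f"rank-deficient covariance: only {usable} usable modes")
    # rigid motions were removed by alignment: their variances are the
    # smallest eigenvalues; drop them
    order = np.argsort(vals)
    kept = order[n_rigid:]
    kept = kept[vals[kept] > 0]
    omega = np.sqrt(kBT / vals[kept])
    modes = vecs[:, kept] / sm[:, None]
    asc = np.argsort(omega)
    return omega[asc], modes[:, asc], usable


def classify_mode(mode: np.ndarray, mesh: TriMesh, L_cyl: float,
                  m_max: int = 5, n_max: int = 6,
                  margin: float = 0.05) -> ModeRecord:
    """Classify a GV mode by Donnel cylinder indices (m, n).

    The radial displacement u_r on the cylindrical section is projected on
    sin(λ_m z + mπ/2)·{cos, sin}(nφ) with λ_m = mπ/H_cyl; (m, n) maximizes
    the projection power.  The polarization branch is the dominant
    displacement component (r, phi, or z).
    """
    ref = mesh.reference_vertices
    zc = ref[:, 2] - ref[:, 2].mean()
    sel = np.abs(zc) < L_cyl / 2.0 - margin
    z = zc[sel]
    xy = ref[sel, :2]
    phi = np.arctan2(xy[:, 1], xy[:, 0])
    rhat = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(len(phi))])
    phat = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros(len(phi))])
    u = mode.reshape(-1, 3)[sel]
    u_r = np.einsum("ij,ij->i", u, rhat)
    u_p = np.einsum("ij,ij->i", u, phat)
    u_z = u[:, 2]
    best = (0.0, 0, 0)
    second = 0.0
    total = float((u_r ** 2).sum()) + 1e-300
    for m in range(1, m_max + 1):
        lam = m * math.pi / L_cyl
        axial = np.sin(lam * z + m * math.pi / 2.0)
        for n in range(0, n_max + 1):
            for azim in ((np.cos(n * phi),) if n == 0
                         else (np.cos(n * phi), np.sin(n * phi))):
                basis = axial * azim
                nrm = float((basis ** 2).sum())
                if nrm < 1e-12:
                    continue
                power = float((u_r * basis).sum()) ** 2 / nrm / total
                if power > best[0]:
                    second = best[0]
                    best = (power, m, n)
                elif power > second:
                    second = power
    amps = {"radial": float(np.abs(u_r).mean()),
            "azimuthal": float(np.abs(u_p).mean()),
            "axial": float(np.abs(u_z).mean())}
    branch = max(amps, key=amps.get)
    ambiguous = best[0] > 0 and second > 0.9 * best[0]
    # axial profile of u_r (binned in z)
    nb = 24
    edges = np.linspace(z.min(), z.max(), nb + 1)
    zb = np.clip(np.digitize(z, edges) - 1, 0, nb - 1)
    prof = np.zeros(nb)
    cnt = np.zeros(nb)
    np.add.at(prof, zb, u_r)
    np.add.at(cnt, zb, 1.0)
    return ModeRecord(omega=float("nan"), m=best[1], n=best[2], branch=branch,
                      ambiguous=ambiguous,
                      axial_profile=prof / np.maximum(cnt, 1.0))


def hessian_modes_gv(mesh: TriMesh, material, rib: RibField, L_cyl: float,
                     masses: np.ndarray | None = None,
                     n_modes: int = 30) -> list[ModeRecord]:
    """Lowest GV modes via the elastic Hessian, classified by (m, n)."""
    if masses is None:
        masses = np.ones(mesh.n_vertices)
    H = el.elastic_hessian(mesh, material, rib=rib)
    omegas, modes = el.normal_modes(H, masses)
    records = []
    for k in range(min(n_modes, len(omegas))):
        rec = classify_mode(modes[:, k], mesh, L_cyl)
        rec.omega = float(omegas[k])
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Shear flow / Jeffery orbits
# ---------------------------------------------------------------------------

def jeffery_theta(a: float, b: float, gamma_dot: float,
                  t: np.ndarray) -> np.ndarray:
    """Jeffery orbit inclination tan(θ) = (a/b) tan(ab γ̇ t/(a²+b²)).

    Continuous (unwrapped) across the tangent singularities; θ(0) = 0.
    Period T = 2π(a²+b²)/(a b γ̇).
    """
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    t = np.asarray(t, dtype=float)
    if gamma_dot == 0:
        return np.zeros_like(t)
    phase = a * b * gamma_dot * t / (a * a + b * b)
    theta = np.arctan2((a / b) * np.sin(phase), np.cos(phase))
    return np.unwrap(theta)


def jeffery_period(a: float, b: float, gamma_dot: float) -> float:
    return 2.0 * math.pi * (a * a + b * b) / (a * b * gamma_dot)


def fit_jeffery(t: np.ndarray, theta: np.ndarray, gamma_dot: float):
    """Fit (aspect ratio, time offset) of a Jeffery orbit to θ(t).

    Returns (r = a/b, t0, relative rms residual).
    """
    theta = np.unwrap(np.asarray(theta, dtype=float))
    span = max(theta.max() - theta.min(), 1e-12)

    def make_resid(sign):
        def resid(params):
            r, t0 = params
            r = abs(r) + 1e-6
            return sign * jeffery_theta(r, 1.0, gamma_dot, t - t0) - theta
        return resid

    best = None
    for sign in (1.0, -1.0):
        for r0 in (1.5, 2.0, 3.0, 4.0):
            sol = scipy.optimize.least_squares(make_resid(sign), [r0, 0.0],
                                               method="lm")
            if best is None or sol.cost < best.cost:
                best = sol
    r, t0 = abs(best.x[0]) + 1e-6, best.x[1]
    if r < 1.0:
        # with a free angle reference, r and 1/r describe the same orbit
        # (theta shifted by pi/2): report the aspect ratio >= 1
        r = 1.0 / r
    rms = math.sqrt(2.0 * best.cost / len(t)) / span
    return r, t0, rms


def inclination_angle(verts: np.ndarray, flow_axis: int = 1,
                      grad_axis: int = 0) -> float:
    """Angle of the principal gyration axis against the flow direction,
    measured in the (flow, gradient) shear plane."""
    x = verts - verts.mean(axis=0)
    g = x.T @ x / len(x)
    vals, vecs = np.linalg.eigh(g)
    axis = vecs[:, -1]
    return math.atan2(axis[grad_axis], axis[flow_axis])


def unwrap_headless(angles: np.ndarray) -> np.ndarray:
    """Unwrap a time series of axis angles (defined modulo π)."""
    out = np.asarray(angles, dtype=float).copy()
    for k in range(1, len(out)):
        while out[k] - out[k - 1] > math.pi / 2:
            out[k] -= math.pi
        while out[k] - out[k - 1] < -math.pi / 2:
            out[k] += math.pi
    return out


# ---------------------------------------------------------------------------
# Solvated systems
# ---------------------------------------------------------------------------

def build_solvated_shell(mesh: TriMesh, material, rib: RibField | None,
                         box, pairs: dict, seed: int = 0, dt: float = 0.0025,
                         p_comp: float = 0.0, kBT: float = 1.0,
                         clearance: float = 0.1, maxwell: bool = False):
    """Assemble a DPD water box around a centered shell.

    Water fills the exterior at density 3; the shell interior is empty and
    held up by the gas-pressure compensation ``p_comp``.  Returns a running
    :class:`~vesimeso.dpd.Simulation` with membrane forces, bounce-back and
    recentering attached, plus a handle dict.
    """
    from . import coupling as cp
    from . import dpd as dd
    box = np.asarray(box, dtype=float)
    m = mesh.copy()
    shift = box / 2.0 - m.reference_vertices.mean(axis=0)
    m.vertices = m.vertices + shift
    m.reference_vertices = m.reference_vertices + shift
    rng = np.random.default_rng(seed)
    inside_fn = None

    def excluded(pts):
        from scipy.spatial import cKDTree
        mask = cp.points_inside(m, pts)
        tree = cKDTree(m.reference_vertices)
        d, _ = tree.query(pts, k=1)
        return mask | (d < clearance)

    fl = dd.fill_box(box, 3.0, rng, exclude=excluded, kBT=kBT)
    nf = fl.n
    nv = m.n_vertices
    pos = np.vstack([fl.positions, m.vertices])
    vel = np.vstack([fl.velocities, np.zeros((nv, 3))])
    species = np.concatenate([np.zeros(nf, np.int8), np.full(nv, 2, np.int8)])
    system = dd.DPDSystem(pos, vel, species, box)
    field_ = dd.PairForceField(pairs, box, kBT=kBT, seed=seed)
    mem_idx = np.arange(nf, nf + nv)
    mem = cp.MembraneForces(m, material, mem_idx, rib=rib, p_comp=p_comp)
    bb = cp.BounceBack(m, None, mem_idx, kBT=kBT, seed=seed + 1,
                       fluid_species=0, maxwell=maxwell)
    rc = cp.Recenter(mem_idx, box / 2.0)
    sim = dd.Simulation(system, field_, dt=dt, extra_forces=[mem],
                        post_step=[bb, rc])
    return sim, {"mesh": m, "mem_idx": mem_idx, "membrane": mem,
                 "bounce": bb, "recenter": rc, "n_fluid": nf}


def compress_solvated(mesh: TriMesh, material, rib: RibField | None,
                      box, pairs: dict, delta_a: float, alpha_eos: float,
                      seed: int = 0, dt: float = 0.0025,
                      n_equil: int = 2000, n_ramp: int = 3000,
                      n_hold: int = 4000, rho: float = 3.0):
    """Volume response to a solvent-pressure increase driven through a_ww.

    The water-water conservative amplitude ramps linearly by ``delta_a``
    and holds; the achieved pressure increase is measured from the
    time-averaged conservative virial.  Returns (delta_p, dV_over_V0).
    """
    from . import dpd as dd
    from .coupling import ramp_aww
    from .meshgen import enclosed_volume as vol
    a0 = pairs[(0, 0)].a
    p0_est = rho + alpha_eos * a0 * rho ** 2
    sim, h = build_solvated_shell(mesh, material, rib, box, pairs, seed=seed,
                                  dt=dt, p_comp=p0_est)
    V_box = float(np.prod(box))
    sim.step(n_equil)
    msh = h["mesh"]
    V0_samples, p0_samples = [], []
    for _ in range(40):
        sim.step(10)
        msh.vertices = sim.system.positions[h["mem_idx"]]
        V0_samples.append(vol(msh))
        p0_samples.append(rho + sim.field.last_virial / (3.0 * V_box))
    V0 = float(np.mean(V0_samples))
    p_start = float(np.mean(p0_samples))
    t_ramp = n_ramp * sim.dt
    a_tab = sim.field.a_tab
    for k in range(n_ramp):
        a_tab[0, 0] = ramp_aww(k * sim.dt, (a0, a0 + delta_a, t_ramp, t_ramp))
        sim.step(1)
    a_tab[0, 0] = a0 + delta_a
    sim.step(n_hold // 2)
    V_samples, p_samples = [], []
    for _ in range(n_hold // 2 // 10):
        sim.step(10)
        msh.vertices = sim.system.positions[h["mem_idx"]]
        V_samples.append(vol(msh))
        p_samples.append(rho + sim.field.last_virial / (3.0 * V_box))
    V = float(np.mean(V_samples))
    dp = float(np.mean(p_samples)) - p_start
    return dp, V / V0 - 1.0


def shear_flow_gv(mesh: TriMesh, material, rib: RibField | None,
                  a_ow: float, gamma_dot: float, eta_w: float,
                  box=(12.0, 8.0, 8.0), t_total: float = 60.0,
                  dt: float = 0.005, seed: int = 0, alpha_eos: float = 0.096,
                  a_ww: float = 100.0, gamma_ww: float = 3.5,
                  k_ww: float = 0.25, sample_every: int = 40,
                  k_fsi: float = 0.5):
    """Inclination dynamics of a shell pinned in an OBMD shear flow.

    The shell's long axis starts in the shear plane along the flow (y);
    water is driven by buffer stresses P_yx = eta_w * gamma_dot (opposite
    interface normals), P_xx set to the equation-of-state pressure.  The
    membrane-water friction follows the no-slip formula; ``a_ow`` sets the
    repulsion (0 = pure no-slip coupling).  Returns (times, theta(t) series
    unwrapped, ShearRecord).
    """
    from . import coupling as cp
    from . import dpd as dd
    from . import obmd as ob
    box = np.asarray(box, dtype=float)
    # orient the shell axis (z in the reference mesh) along the flow (y)
    m = mesh.copy()
    rot = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])
    m.vertices = mesh.vertices @ rot.T
    m.reference_vertices = mesh.reference_vertices @ rot.T
    m._cache = {}
    rib_r = None
    if rib is not None:
        from .meshgen import rib_direction_field
        rib_r = rib_direction_field(m, rot @ np.array([0.0, 0.0, 1.0]))
    rho_m = cp.membrane_area_density(m)
    g_ow = cp.no_slip_gamma(eta_w, 3.0, rho_m, k_fsi)
    pairs = {
        (dd.WATER, dd.WATER): dd.DPDPairParams(a=a_ww, gamma=gamma_ww, k=k_ww),
        (dd.OBJECT, dd.WATER): dd.DPDPairParams(a=a_ow, gamma=g_ow, k=k_fsi),
        (dd.OBJECT, dd.OBJECT): dd.DPDPairParams(a=0.0, gamma=0.0),
    }
    p_eos = 3.0 + alpha_eos * a_ww * 9.0
    sim, h = build_solvated_shell(m, material, rib_r, box, pairs, seed=seed,
                                  dt=dt, p_comp=p_eos)
    sim.field.periodic = np.array([False, True, True])
    sim.system.periodic = np.array([False, True, True])
    # preload the steady linear profile to skip the startup transient
    # (P_yx > 0 drives +y flow at the left buffer: negative slope)
    x = sim.system.positions[:, 0]
    sim.system.velocities[:, 1] -= gamma_dot * (x - box[0] / 2.0)
    open_b = ob.OpenBoundary(box, buffer_fraction=0.15, rho=3.0, a_ww=a_ww,
                             P_xx=p_eos, seed=seed + 7, dt=dt)
    ob.impose_shear(open_b, gamma_dot, eta_w)
    sim.extra_forces.append(open_b.apply_forces)
    sim.post_step.append(open_b.exchange)
    n_steps = int(round(t_total / dt))
    thetas = []
    times = []
    mem_handle = h["membrane"]
    for k in range(n_steps // sample_every):
        sim.step(sample_every)
        verts = sim.system.positions[mem_handle.mem_idx]
        thetas.append(inclination_angle(verts))
        times.append(sim.step_index * dt)
    th = unwrap_headless(np.array(thetas))
    rec = classify_shear_regime(np.array(times), th)
    return np.array(times), th, rec


def classify_shear_regime(t: np.ndarray, theta_unwrapped: np.ndarray
                          ) -> ShearRecord:
    """Tumbling vs aligned from the unwrapped inclination time series.

    Tumbling if θ advances by more than π over the run; otherwise aligned,
    with mean/std taken over the second half.
    """
    t = np.asarray(t, dtype=float)
    th = np.asarray(theta_unwrapped, dtype=float)
    half = len(th) // 2
    tail = th[half:]
    swept = abs(th[-1] - th[0])
    regime = "tumbling" if swept > math.pi else "aligned"
    fold = np.arctan2(np.sin(tail), np.cos(tail))
    return ShearRecord(t=t, theta_t=th, mean_theta=float(np.mean(fold)),
                       std_theta=float(np.std(fold)), regime=regime)
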