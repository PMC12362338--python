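"""Fluid-structure interaction between DPD fluids and triangulated shells.

Membrane vertices are ordinary DPD beads (species "object") that exchange
conservative, dissipative and random pair forces with the fluids; the
dissipative coefficient that enforces no-slip at the interface follows from
the analytic kinetic-theory expression.  The no-through condition is a
bounce-back: fluid beads whose path crosses a membrane face are returned to
the crossing point and re-inserted with a Maxwell flux velocity at T0 in the
local membrane frame.  The near-zero pressure of the ideal DPD gas inside a
shell is compensated by an outward force -p A n_inward / 3 on each vertex of
every face.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .elasticity import MembraneMaterial, elastic_energy
from .meshgen import RibField, TriMesh


# ---------------------------------------------------------------------------
# No-slip dissipative coefficient
# ---------------------------------------------------------------------------

def no_slip_gamma(eta_scaled: float, rho_fluid: float, rho_m: float,
                  k_fsi: float = 0.5, r_c: float = 1.0) -> float:
    """Membrane-fluid friction enforcing no-slip.

    gamma = 2 eta (2k+1)(2k+2)(2k+3)(2k+4) / (3 pi r_c^4 rho_fluid rho_m)
    with rho_m the membrane vertex area density and eta the (scaled-down)
    fluid viscosity.
    """
    if min(eta_scaled, rho_fluid, rho_m, r_c) <= 0 or k_fsi < 0:
        raise ValueError("inputs must be positive")
    k2 = 2.0 * k_fsi
    comb = (k2 + 1.0) * (k2 + 2.0) * (k2 + 3.0) * (k2 + 4.0)
    return 2.0 * eta_scaled * comb / (3.0 * math.pi * r_c ** 4 * rho_fluid * rho_m)


def membrane_area_density(mesh: TriMesh, reference: bool = True) -> float:
    """Vertex count per unit membrane area (reference geometry by default)."""
    return mesh.n_vertices / mesh.total_area(reference=reference)


# ---------------------------------------------------------------------------
# Gas pressure compensation
# ---------------------------------------------------------------------------

def gas_pressure_forces(mesh: TriMesh, p: float) -> np.ndarray:
    """Outward per-vertex forces -p A n_inward / 3 on every face.

    Each face pushes its three vertices outward with equal shares, giving zero
    torque on the triangle; the vector sum over a closed mesh vanishes.
    """
    if p < 0:
        raise ValueError("compensation pressure must be non-negative")
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    an_out = 0.5 * np.cross(v1 - v0, v2 - v0)   # area-weighted outward normal
    contrib = (p / 3.0) * an_out
    forces = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(forces, mesh.faces[:, k], contrib)
    return forces


def ramp_aww(t: float, schedule: tuple[float, float, float, float]) -> float:
    """Linear a_ww(t): a_start -> a_end over t_ramp, then constant."""
    a_start, a_end, t_ramp, t_total = schedule
    if t_ramp > t_total:
        raise ValueError("t_ramp must not exceed t_total")
    if t <= 0.0:
        return a_start
    if t >= t_ramp:
        return a_end
    return a_start + (a_end - a_start) * t / t_ramp


# ---------------------------------------------------------------------------
# Bounce-back
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _closest_on_tri(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Closest point on triangle (a, b, c) to p (Ericson, Real-Time CD)."""
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return ax, ay, az
    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bx, by, bz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        t = d1 / (d1 - d3)
        return ax + t * abx, ay + t * aby, az + t * abz
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cx, cy, cz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        t = d2 / (d2 - d6)
        return ax + t * acx, ay + t * acy, az + t * acz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return (bx + t * (cx - bx), by + t * (cy - by), bz + t * (cz - bz))
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return (ax + abx * v + acx * w, ay + aby * v + acy * w,
            az + abz * v + acz * w)


@njit(cache=True)
def _bounce_kernel(old_pos, new_pos, vel, masses, fluid_idx, tri_a, tri_b,
                   tri_c, tri_vel, faces, mem_map, face_cells_start,
                   face_cells, nc, origin, cell_edge, kBT, seed, step,
                   max_iter, home_side, rescue_depth, maxwell):
    """Reflect fluid particles crossing membrane faces (Maxwell re-insertion).

    Returns the number of reflections performed; positions/velocities are
    modified in place.  ``face_cells`` maps spatial cells to candidate faces.
    ``home_side`` (+1 outside, -1 inside) enables a rescue pass: a particle
    found within ``rescue_depth`` on the wrong side of its nearest face (a
    crossing swept by membrane motion during the step, which the segment test
    against end-of-step faces cannot see) is reflected back.
    """
    n_ref = 0
    ncx, ncy, ncz = nc[0], nc[1], nc[2]
    for fi in range(fluid_idx.shape[0]):
        i = fluid_idx[fi]
        for it in range(max_iter):
            p0x, p0y, p0z = old_pos[i, 0], old_pos[i, 1], old_pos[i, 2]
            p1x, p1y, p1z = new_pos[i, 0], new_pos[i, 1], new_pos[i, 2]
            dx, dy, dz = p1x - p0x, p1y - p0y, p1z - p0z
            # candidate cells along the segment: use the old-position cell +-1
            cx = int((p0x - origin[0]) / cell_edge)
            cy = int((p0y - origin[1]) / cell_edge)
            cz = int((p0z - origin[2]) / cell_edge)
            best_t = 2.0
            best_f = -1
            for ox in range(-1, 2):
                gx = cx + ox
                if gx < 0 or gx >= ncx:
                    continue
                for oy in range(-1, 2):
                    gy = cy + oy
                    if gy < 0 or gy >= ncy:
                        continue
                    for oz in range(-1, 2):
                        gz = cz + oz
                        if gz < 0 or gz >= ncz:
                            continue
                        c = (gx * ncy + gy) * ncz + gz
                        for s in range(face_cells_start[c], face_cells_start[c + 1]):
                            f = face_cells[s]
                            ax, ay, az = tri_a[f, 0], tri_a[f, 1], tri_a[f, 2]
                            e1x = tri_b[f, 0] - ax
                            e1y = tri_b[f, 1] - ay
                            e1z = tri_b[f, 2] - az
                            e2x = tri_c[f, 0] - ax
                            e2y = tri_c[f, 1] - ay
                            e2z = tri_c[f, 2] - az
                            # Moller-Trumbore
                            hx = dy * e2z - dz * e2y
                            hy = dz * e2x - dx * e2z
                            hz = dx * e2y - dy * e2x
                            det = e1x * hx + e1y * hy + e1z * hz
                            if abs(det) < 1e-14:
                                continue
                            inv = 1.0 / det
                            sx, sy, sz = p0x - ax, p0y - ay, p0z - az
                            u = (sx * hx + sy * hy + sz * hz) * inv
                            if u < -1e-9 or u > 1.0 + 1e-9:
                                continue
                            qx = sy * e1z - sz * e1y
                            qy = sz * e1x - sx * e1z
                            qz = sx * e1y - sy * e1x
                            v = (dx * qx + dy * qy + dz * qz) * inv
                            if v < -1e-9 or u + v > 1.0 + 1e-9:
                                continue
                            t = (e2x * qx + e2y * qy + e2z * qz) * inv
                            if 1e-12 < t <= 1.0 and t < best_t:
                                best_t = t
                                best_f = f
            if best_f < 0:
                break
            f = best_f
            # face outward normal
            ax, ay, az = tri_a[f, 0], tri_a[f, 1], tri_a[f, 2]
            e1x = tri_b[f, 0] - ax
            e1y = tri_b[f, 1] - ay
            e1z = tri_b[f, 2] - az
            e2x = tri_c[f, 0] - ax
            e2y = tri_c[f, 1] - ay
            e2z = tri_c[f, 2] - az
            nx = e1y * e2z - e1z * e2y
            ny = e1z * e2x - e1x * e2z
            nz = e1x * e2y - e1y * e2x
            nn = math.sqrt(nx * nx + ny * ny + nz * nz)
            nx /= nn
            ny /= nn
            nz /= nn
            # side of approach (sign of incoming motion against the normal)
            side = -1.0 if (dx * nx + dy * ny + dz * nz) > 0.0 else 1.0
            hitx = p0x + best_t * dx
            hity = p0y + best_t * dy
            hitz = p0z + best_t * dz
            eps = 1e-3
            new_pos[i, 0] = hitx + side * eps * nx
            new_pos[i, 1] = hity + side * eps * ny
            new_pos[i, 2] = hitz + side * eps * nz
            old_pos[i, 0] = new_pos[i, 0]
            old_pos[i, 1] = new_pos[i, 1]
            old_pos[i, 2] = new_pos[i, 2]
            vox, voy, voz = vel[i, 0], vel[i, 1], vel[i, 2]
            if maxwell:
                # Maxwell flux re-insertion in the local membrane frame
                sgm = math.sqrt(kBT / masses[i])
                key = (np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
                       + np.uint64(step) * np.uint64(0xC2B2AE3D27D4EB4F)
                       + np.uint64(i) * np.uint64(0x165667B19E3779F9)
                       + np.uint64(it + 1) * np.uint64(0x27D4EB2F165667C5))
                z1 = _hash_u01(key)
                z2 = _hash_u01(key ^ np.uint64(0xA5A5A5A5A5A5A5A5))
                z3 = _hash_u01(key ^ np.uint64(0x5A5A5A5A5A5A5A5A))
                vn = sgm * math.sqrt(-2.0 * math.log(z1))      # flux (Rayleigh)
                g1 = math.sqrt(-2.0 * math.log(z2)) * math.cos(2.0 * math.pi * z3)
                g2 = math.sqrt(-2.0 * math.log(z2)) * math.sin(2.0 * math.pi * z3)
                # tangent basis
                if abs(nx) < 0.9:
                    tx, ty, tz = 1.0 - nx * nx, -nx * ny, -nx * nz
                else:
                    tx, ty, tz = -ny * nx, 1.0 - ny * ny, -ny * nz
                tn = math.sqrt(tx * tx + ty * ty + tz * tz)
                tx /= tn
                ty /= tn
                tz /= tn
                bx = ny * tz - nz * ty
                by = nz * tx - nx * tz
                bz = nx * ty - ny * tx
                vel[i, 0] = tri_vel[f, 0] + side * vn * nx \
                    + sgm * (g1 * tx + g2 * bx)
                vel[i, 1] = tri_vel[f, 1] + side * vn * ny \
                    + sgm * (g1 * ty + g2 * by)
                vel[i, 2] = tri_vel[f, 2] + side * vn * nz \
                    + sgm * (g1 * tz + g2 * bz)
                # recoil of the re-insertion impulse, split over the face
                ipx = masses[i] * (vel[i, 0] - vox) / 3.0
                ipy = masses[i] * (vel[i, 1] - voy) / 3.0
                ipz = masses[i] * (vel[i, 2] - voz) / 3.0
                for kk in range(3):
                    gv_ = mem_map[faces[f, kk]]
                    vel[gv_, 0] -= ipx / masses[gv_]
                    vel[gv_, 1] -= ipy / masses[gv_]
                    vel[gv_, 2] -= ipz / masses[gv_]
            else:
                # elastic collision with the face (effective mass = the
                # three vertices): conserves momentum and energy exactly,
                # reverses the normal relative velocity, and transmits the
                # kinetic part of the fluid pressure to the shell
                rvn = ((vel[i, 0] - tri_vel[f, 0]) * nx
                       + (vel[i, 1] - tri_vel[f, 1]) * ny
                       + (vel[i, 2] - tri_vel[f, 2]) * nz)
                mw = (masses[mem_map[faces[f, 0]]]
                      + masses[mem_map[faces[f, 1]]]
                      + masses[mem_map[faces[f, 2]]])
                mf = masses[i]
                dv_p = -2.0 * mw / (mf + mw) * rvn
                vel[i, 0] += dv_p * nx
                vel[i, 1] += dv_p * ny
                vel[i, 2] += dv_p * nz
                # wall impulse 2 mf mw rvn/(mf+mw), one third per vertex
                imp = 2.0 * mf * mw * rvn / (mf + mw) / 3.0
                for kk in range(3):
                    gv_ = mem_map[faces[f, kk]]
                    vel[gv_, 0] += imp * nx / masses[gv_]
                    vel[gv_, 1] += imp * ny / masses[gv_]
                    vel[gv_, 2] += imp * nz / masses[gv_]
            n_ref += 1
        else:
            raise RuntimeError("bounce-back did not resolve within max_iter")
        # rescue pass: signed distance to the closest membrane point; catches
        # crossings swept by membrane motion that the segment test misses
        px, py, pz = new_pos[i, 0], new_pos[i, 1], new_pos[i, 2]
        cx = int((px - origin[0]) / cell_edge)
        cy = int((py - origin[1]) / cell_edge)
        cz = int((pz - origin[2]) / cell_edge)
        best_d2 = rescue_depth * rescue_depth
        bf = -1
        bqx = bqy = bqz = 0.0
        for ox in range(-1, 2):
            gx = cx + ox
            if gx < 0 or gx >= ncx:
                continue
            for oy in range(-1, 2):
                gy = cy + oy
                if gy < 0 or gy >= ncy:
                    continue
                for oz in range(-1, 2):
                    gz = cz + oz
                    if gz < 0 or gz >= ncz:
                        continue
                    c = (gx * ncy + gy) * ncz + gz
                    for s in range(face_cells_start[c], face_cells_start[c + 1]):
                        ff = face_cells[s]
                        qx, qy, qz = _closest_on_tri(
                            px, py, pz,
                            tri_a[ff, 0], tri_a[ff, 1], tri_a[ff, 2],
                            tri_b[ff, 0], tri_b[ff, 1], tri_b[ff, 2],
                            tri_c[ff, 0], tri_c[ff, 1], tri_c[ff, 2])
                        d2 = ((px - qx) ** 2 + (py - qy) ** 2
                              + (pz - qz) ** 2)
                        if d2 < best_d2:
                            best_d2 = d2
                            bf = ff
                            bqx, bqy, bqz = qx, qy, qz
        if bf >= 0:
            f = bf
            ax, ay, az = tri_a[f, 0], tri_a[f, 1], tri_a[f, 2]
            e1x = tri_b[f, 0] - ax
            e1y = tri_b[f, 1] - ay
            e1z = tri_b[f, 2] - az
            e2x = tri_c[f, 0] - ax
            e2y = tri_c[f, 1] - ay
            e2z = tri_c[f, 2] - az
            nx = e1y * e2z - e1z * e2y
            ny = e1z * e2x - e1x * e2z
            nz = e1x * e2y - e1y * e2x
            nn = math.sqrt(nx * nx + ny * ny + nz * nz)
            nx /= nn
            ny /= nn
            nz /= nn
            sd = (px - bqx) * nx + (py - bqy) * ny + (pz - bqz) * nz
            if sd * home_side < 0.0:
                # place back on the home side and reflect the normal velocity
                # in the membrane frame (energy-neutral, avoids re-heating
                # surface-hugging particles)
                d = max(math.sqrt(best_d2), 0.01)
                new_pos[i, 0] = bqx + home_side * d * nx
                new_pos[i, 1] = bqy + home_side * d * ny
                new_pos[i, 2] = bqz + home_side * d * nz
                old_pos[i, 0] = new_pos[i, 0]
                old_pos[i, 1] = new_pos[i, 1]
                old_pos[i, 2] = new_pos[i, 2]
                rvn = ((vel[i, 0] - tri_vel[f, 0]) * nx
                       + (vel[i, 1] - tri_vel[f, 1]) * ny
                       + (vel[i, 2] - tri_vel[f, 2]) * nz)
                if rvn * home_side < 0.0:
                    # same elastic particle-face collision as above
                    mw = (masses[mem_map[faces[f, 0]]]
                          + masses[mem_map[faces[f, 1]]]
                          + masses[mem_map[faces[f, 2]]])
                    mf = masses[i]
                    dv_p = -2.0 * mw / (mf + mw) * rvn
                    vel[i, 0] += dv_p * nx
                    vel[i, 1] += dv_p * ny
                    vel[i, 2] += dv_p * nz
                    imp = 2.0 * mf * mw * rvn / (mf + mw) / 3.0
                    for kk in range(3):
                        gv_ = mem_map[faces[f, kk]]
                        vel[gv_, 0] += imp * nx / masses[gv_]
                        vel[gv_, 1] += imp * ny / masses[gv_]
                        vel[gv_, 2] += imp * nz / masses[gv_]
                n_ref += 1
    return n_ref


@njit(cache=True, inline="always")
def _hash_u01(x):
    z = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return (float(z >> np.uint64(11)) + 1.0) / 9007199254740993.0


def maxwell_flux_speed(u: np.ndarray, kBT: float, mass: float) -> np.ndarray:
    """Normal-speed quantile function of the Maxwell flux distribution.

    p(v) dv ∝ v exp(-m v²/(2 k_B T)) dv, i.e. a Rayleigh distribution with
    scale sqrt(k_B T/m); used by the bounce-back and testable directly.
    """
    return np.sqrt(kBT / mass) * np.sqrt(-2.0 * np.log(1.0 - np.asarray(u)))


class BounceBack:
    """Post-step no-through boundary for fluid beads at a membrane.

    Builds a face cell map on a grid of edge >= max face circumradius plus the
    largest expected single-step displacement and resolves up to ``max_iter``
    crossings per particle per step.
    """

    def __init__(self, mesh: TriMesh, fluid_indices: np.ndarray | None,
                 membrane_indices: np.ndarray, kBT: float = 1.0,
                 seed: int = 0, max_iter: int = 5, margin: float = 0.3,
                 home_side: int = 1, rescue_depth: float = 0.25,
                 maxwell: bool = False, fluid_species: int | None = None):
        self.mesh = mesh
        self.fluid_species = fluid_species
        if fluid_indices is None:
            if fluid_species is None:
                raise ValueError("give fluid_indices or fluid_species")
            fluid_indices = np.empty(0, dtype=np.int64)
        self.fluid_idx = np.ascontiguousarray(fluid_indices, dtype=np.int64)
        self.mem_idx = np.ascontiguousarray(membrane_indices, dtype=np.int64)
        self.kBT = kBT
        self.seed = int(seed) & 0x7FFFFFFF
        self.max_iter = max_iter
        self.margin = margin
        self.home_side = int(home_side)
        self.rescue_depth = float(rescue_depth)
        self.maxwell = bool(maxwell)
        self.n_reflections = 0
        self.rebuild_every = 10
        self._map = None
        self._map_verts = None
        self._calls = 0

    def _face_map(self, verts):
        f = self.mesh.faces
        tri = verts[f]                      # (F,3,3)
        lo = tri.min(axis=1) - self.margin
        hi = tri.max(axis=1) + self.margin
        edge = max(1.0, float((hi - lo).max(axis=0).max() / 8.0))
        origin = lo.min(axis=0) - edge
        extent = hi.max(axis=0) + edge - origin
        nc = np.maximum((extent / edge).astype(np.int64) + 1, 1)
        ncells = int(nc.prod())
        lo_c = np.floor((lo - origin) / edge).astype(np.int64)
        hi_c = np.floor((hi - origin) / edge).astype(np.int64)
        entries = []
        for fi in range(len(f)):
            for gx in range(lo_c[fi, 0], hi_c[fi, 0] + 1):
                for gy in range(lo_c[fi, 1], hi_c[fi, 1] + 1):
                    for gz in range(lo_c[fi, 2], hi_c[fi, 2] + 1):
                        entries.append(((gx * nc[1] + gy) * nc[2] + gz, fi))
        entries.sort()
        cells = np.array([e[0] for e in entries], dtype=np.int64)
        faces = np.array([e[1] for e in entries], dtype=np.int64)
        start = np.searchsorted(cells, np.arange(ncells + 1))
        return start, faces, nc, origin, edge

    def __call__(self, sim, old_positions: np.ndarray) -> None:
        sys_ = sim.system
        if self.fluid_species is not None:
            self.fluid_idx = np.nonzero(
                sys_.species == self.fluid_species)[0].astype(np.int64)
        verts = sys_.positions[self.mem_idx]
        self.mesh.vertices = verts  # keep the mesh view current
        # the cell map is rebuilt only every few steps: the margin exceeds
        # the membrane displacement accumulated in between
        if (self._map is None or self._calls % self.rebuild_every == 0
                or np.abs(verts - self._map_verts).max() > 0.5 * self.margin):
            self._map = self._face_map(verts)
            self._map_verts = verts.copy()
        self._calls += 1
        start, fmap, nc, origin, edge = self._map
        f = self.mesh.faces
        tri_a = np.ascontiguousarray(verts[f[:, 0]])
        tri_b = np.ascontiguousarray(verts[f[:, 1]])
        tri_c = np.ascontiguousarray(verts[f[:, 2]])
        tri_vel = np.ascontiguousarray(
            sys_.velocities[self.mem_idx][f].mean(axis=1))
        old = np.ascontiguousarray(old_positions)
        # unwrap the step displacement (minimum image) so boundary-crossing
        # segments do not spuriously sweep across the domain interior
        disp = sys_.positions - old
        for d in range(3):
            if sys_.periodic[d]:
                disp[:, d] -= sys_.box[d] * np.round(disp[:, d] / sys_.box[d])
        end = np.ascontiguousarray(old + disp)
        self.n_reflections += _bounce_kernel(
            old, end, sys_.velocities, sys_.masses, self.fluid_idx,
            tri_a, tri_b, tri_c, tri_vel, f, self.mem_idx, start, fmap, nc,
            origin.astype(np.float64), edge, self.kBT, self.seed,
            sim.step_index, self.max_iter, self.home_side,
            self.rescue_depth, self.maxwell)
        sys_.positions[self.fluid_idx] = end[self.fluid_idx]
        for d in range(3):
            if sys_.periodic[d]:
                sys_.positions[:, d] %= sys_.box[d]


def _segment_hits(mesh: TriMesh, p0: np.ndarray, seg: np.ndarray):
    """All (t, face) intersections of segment p0 + t*seg, t in (0, 1]."""
    f = mesh.faces
    a = mesh.vertices[f[:, 0]]
    e1 = mesh.vertices[f[:, 1]] - a
    e2 = mesh.vertices[f[:, 2]] - a
    h = np.cross(np.broadcast_to(seg, e2.shape), e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = p0[None, :] - a
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    v = np.einsum("j,ij->i", seg, q) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) \
        & (t > 1e-12) & (t <= 1.0)
    return t[hit], np.nonzero(hit)[0]


def bounce_back(old_pos, new_pos, velocity, mesh: TriMesh, T0: float,
                rng: np.random.Generator, mass: float = 1.0,
                max_iter: int = 5):
    """Single-particle bounce-back (reference path for the batched kernel).

    Returns (position, velocity); identity when the segment does not cross
    any membrane face.  Crossings are resolved nearest-first with Maxwell
    flux re-insertion at temperature T0.
    """
    p0 = np.asarray(old_pos, dtype=float).copy()
    p1 = np.asarray(new_pos, dtype=float).copy()
    vel = np.asarray(velocity, dtype=float).copy()
    sgm = math.sqrt(T0 / mass)
    for it in range(max_iter):
        seg = p1 - p0
        ts, fs = _segment_hits(mesh, p0, seg)
        if len(ts) == 0:
            return p1, vel
        k = int(np.argmin(ts))
        fidx = int(fs[k])
        hit = p0 + ts[k] * seg
        fa, fb, fc = mesh.faces[fidx]
        nrm = np.cross(mesh.vertices[fb] - mesh.vertices[fa],
                       mesh.vertices[fc] - mesh.vertices[fa])
        nrm = nrm / np.linalg.norm(nrm)
        side = -1.0 if float(np.dot(seg, nrm)) > 0 else 1.0
        vn = sgm * math.sqrt(-2.0 * math.log(1.0 - rng.random()))
        t1 = np.cross(nrm, [1.0, 0.0, 0.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(nrm, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(nrm, t1)
        vel = (side * vn * nrm + sgm * rng.normal() * t1
               + sgm * rng.normal() * t2)
        p0 = hit + side * 1e-6 * nrm
        p1 = p0.copy()
    return p1, vel


def points_inside(mesh: TriMesh, points: np.ndarray) -> np.ndarray:
    """Boolean mask: which points lie inside the closed mesh (ray parity)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    # common anchor strictly outside the mesh bounding box
    anchor = mesh.vertices.max(0) + np.array([1.2345, 0.6789, 0.4321])
    inside = np.empty(len(points), dtype=bool)
    for i, p in enumerate(points):
        ts, _ = _segment_hits(mesh, p, anchor - p)
        inside[i] = (len(ts) % 2) == 1
    return inside


class Recenter:
    """Post-step callback pinning the membrane COM to a target point.

    The shell is free-floating; left alone it drifts until vertices wrap
    through the periodic boundary, which would tear the mesh.  A uniform
    translation of the whole system is physically inert, so every step the
    box is shifted to keep the membrane centered, and fluid coordinates are
    re-wrapped.
    """

    def __init__(self, mem_idx: np.ndarray, target: np.ndarray):
        self.mem_idx = np.asarray(mem_idx, dtype=np.int64)
        self.target = np.asarray(target, dtype=float)

    def __call__(self, sim, old_positions) -> None:
        sys_ = sim.system
        delta = sys_.positions[self.mem_idx].mean(axis=0) - self.target
        if np.any(np.abs(delta) > 1e-12):
            sys_.positions -= delta
            mask = np.ones(sys_.n, dtype=bool)
            mask[self.mem_idx] = False
            for d in range(3):
                if sys_.periodic[d]:
                    sys_.positions[mask, d] %= sys_.box[d]


# ---------------------------------------------------------------------------
# Membrane force aggregation
# ---------------------------------------------------------------------------

class MembraneForces:
    """Extra-force callback adding elastic + gas-pressure-compensation forces.

    The mesh's vertices alias a slice of the DPD system (``mem_idx``); scaled
    material moduli are assumed (down-scaling happens upstream).
    """

    def __init__(self, mesh: TriMesh, material: MembraneMaterial,
                 mem_idx: np.ndarray, rib: RibField | None = None,
                 p_comp: float = 0.0):
        self.mesh = mesh
        self.material = material
        self.rib = rib
        self.mem_idx = np.asarray(mem_idx, dtype=np.int64)
        self.p_comp = p_comp
        self.last_energy = None

    def __call__(self, system, step_, forces) -> None:
        self.mesh.vertices = system.positions[self.mem_idx]
        res = elastic_energy(self.mesh, self.material, self.rib)
        self.last_energy = res
        f = res["forces"]
        if self.p_comp != 0.0:
            f = f + gas_pressure_forces(self.mesh, self.p_comp)
        np.add.at(forces, self.mem_idx, f)
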