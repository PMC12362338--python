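"""DPD particle engine: pair forces, thermostat, integrator, measurements.

Pairwise forces between beads of species alpha, beta within a cutoff r_c = 1:

    F_C = a (1 - r) r_hat                        conservative
    F_D = -gamma (1 - r)^(2k) (v_ij . r_hat) r_hat   dissipative
    F_R = sigma (1 - r)^k Theta / sqrt(dt) r_hat      random

with sigma^2 = 2 gamma k_B T0 (fluctuation-dissipation) and Theta a zero-mean
unit-variance Gaussian symmetric in (i, j), drawn from a counter-based hash of
(seed, step, i, j) so that trajectories are exactly reproducible.  The
integrator is the DPD velocity-Verlet with lambda = 1/2 velocity prediction.
Species are 0 = water, 1 = gas, 2 = object (membrane vertex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

WATER, GAS, OBJECT = 0, 1, 2
FREEZING_A = 250.0  # conservative amplitudes above this freeze the DPD fluid


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DPDPairParams:
    """Per-pair DPD coefficients (reduced units; r_cut = 1 r_c)."""

    a: float
    gamma: float
    k: float = 0.25
    kBT: float = 1.0
    r_cut: float = 1.0

    def __post_init__(self):
        if self.a < 0 or self.gamma < 0:
            raise ValueError("a and gamma must be non-negative")
        if self.a >= FREEZING_A:
            raise ValueError(f"a = {self.a} >= {FREEZING_A} k_B T0/r_c "
                             "freezes the DPD fluid")

    @property
    def sigma(self) -> float:
        return fd_sigma(self.gamma, self.kBT)


def fd_sigma(gamma: float, kBT: float = 1.0) -> float:
    """Random-force amplitude sigma = sqrt(2 gamma k_B T0)."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return math.sqrt(2.0 * gamma * kBT)


def pair_tables(pairs: dict[tuple[int, int], DPDPairParams], kBT: float = 1.0):
    """Build symmetric (3,3) coefficient tables from a species-pair dict."""
    a = np.zeros((3, 3))
    g = np.zeros((3, 3))
    k = np.full((3, 3), 0.25)
    for (si, sj), p in pairs.items():
        for (u, v) in ((si, sj), (sj, si)):
            a[u, v] = p.a
            g[u, v] = p.gamma
            k[u, v] = p.k
    s = np.sqrt(2.0 * g * kBT)
    return a, g, s, k


def table1_pairs(unit_set: str) -> dict[tuple[int, int], DPDPairParams]:
    """Published DPD parameter sets for the EMB and GV unit systems."""
    if unit_set == "emb":
        g_ww, g_gg, g_ow, g_og = 3.5, 11.0, 7.4, 0.2
        k_ww, k_gg = 0.25, 0.25
    elif unit_set == "gv":
        g_ww, g_gg, g_ow, g_og = 18.0, 12.0, 19.5, 0.5
        k_ww, k_gg = 0.125, 0.0
    else:
        raise ValueError(f"unknown unit set {unit_set!r}")
    k_fsi = 0.5
    return {
        (WATER, WATER): DPDPairParams(a=100.0, gamma=g_ww, k=k_ww),
        (WATER, GAS): DPDPairParams(a=0.0, gamma=0.0, k=0.25),
        (GAS, GAS): DPDPairParams(a=0.0, gamma=g_gg, k=k_gg),
        (OBJECT, OBJECT): DPDPairParams(a=0.0, gamma=0.0, k=0.25),
        (OBJECT, WATER): DPDPairParams(a=40.0, gamma=g_ow, k=k_fsi),
        (OBJECT, GAS): DPDPairParams(a=0.0, gamma=g_og, k=k_fsi),
    }


# ---------------------------------------------------------------------------
# System
# ---------------------------------------------------------------------------

@dataclass
class DPDSystem:
    """Particles in a periodic (or x-open) orthorhombic box."""

    positions: np.ndarray    # (N, 3)
    velocities: np.ndarray   # (N, 3)
    species: np.ndarray      # (N,) int8
    box: np.ndarray          # (3,)
    masses: np.ndarray = None
    periodic: np.ndarray = None  # (3,) bool; open dims skip wraparound pairs

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int8)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.masses is None:
            self.masses = np.ones(len(self.positions))
        self.masses = np.ascontiguousarray(self.masses, dtype=np.float64)
        if self.periodic is None:
            self.periodic = np.ones(3, dtype=np.bool_)
        self.periodic = np.asarray(self.periodic, dtype=np.bool_)

    @property
    def n(self) -> int:
        return len(self.positions)

    def kinetic_temperature(self) -> float:
        ke = 0.5 * (self.masses[:, None] * self.velocities ** 2).sum()
        return 2.0 * ke / (3.0 * self.n)

    def momentum(self) -> np.ndarray:
        return (self.masses[:, None] * self.velocities).sum(axis=0)


def fill_box(box, density: float, rng: np.random.Generator,
             species: int = WATER, kBT: float = 1.0, mass: float = 1.0,
             exclude=None) -> DPDSystem:
    """Uniform random fluid at the given number density, zero net momentum."""
    box = np.asarray(box, dtype=float)
    n = int(round(density * box.prod()))
    pos = rng.random((n, 3)) * box
    if exclude is not None:
        keep = ~exclude(pos)
        pos = pos[keep]
        n = len(pos)
    vel = rng.normal(0.0, math.sqrt(kBT / mass), (n, 3))
    vel -= vel.mean(axis=0)
    return DPDSystem(pos, vel, np.full(n, species, dtype=np.int8), box,
                     masses=np.full(n, mass))


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _splitmix64(x):
    z = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _pair_gaussian(seed, step, i, j):
    """Symmetric unit Gaussian for pair (i, j) at a given step."""
    lo = i if i < j else j
    hi = j if i < j else i
    key = (np.uint64(seed) * np.uint64(0x9E3779B97F4A7C15)
           + np.uint64(step) * np.uint64(0xC2B2AE3D27D4EB4F)
           + np.uint64(lo) * np.uint64(0x165667B19E3779F9)
           + np.uint64(hi) * np.uint64(0x27D4EB2F165667C5))
    h1 = _splitmix64(key)
    h2 = _splitmix64(key ^ np.uint64(0xD6E8FEB86659FD93))
    u1 = (float(h1 >> np.uint64(11)) + 1.0) / 9007199254740993.0
    u2 = float(h2 >> np.uint64(11)) / 9007199254740992.0
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)


@njit(cache=True)
def _cell_index(pos, box, nc):
    n = pos.shape[0]
    idx = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * nc[0])
        cy = int(pos[i, 1] / box[1] * nc[1])
        cz = int(pos[i, 2] / box[2] * nc[2])
        if cx >= nc[0]:
            cx = nc[0] - 1
        if cy >= nc[1]:
            cy = nc[1] - 1
        if cz >= nc[2]:
            cz = nc[2] - 1
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        idx[i] = (cx * nc[1] + cy) * nc[2] + cz
    return idx


_STENCIL = np.array([
    (0, 0, 0),
    (1, 0, 0), (-1, 1, 0), (0, 1, 0), (1, 1, 0),
    (-1, -1, 1), (0, -1, 1), (1, -1, 1),
    (-1, 0, 1), (0, 0, 1), (1, 0, 1),
    (-1, 1, 1), (0, 1, 1), (1, 1, 1)], dtype=np.int64)


@njit(cache=True)
def _pair_forces(pos, vel, species, order, cell_start, nc, box, periodic,
                 a_tab, g_tab, s_tab, k_tab, inv_sqrt_dt, step, seed,
                 forces, stencil):
    """Half-stencil cell-list DPD pair loop.  Returns conservative virial."""
    virial = 0.0
    ncx, ncy, ncz = nc[0], nc[1], nc[2]
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                for sidx in range(stencil.shape[0]):
                    ox, oy, oz = stencil[sidx, 0], stencil[sidx, 1], stencil[sidx, 2]
                    nx, ny, nz = cx + ox, cy + oy, cz + oz
                    if periodic[0]:
                        nx = nx % ncx
                    elif nx < 0 or nx >= ncx:
                        continue
                    if periodic[1]:
                        ny = ny % ncy
                    elif ny < 0 or ny >= ncy:
                        continue
                    if periodic[2]:
                        nz = nz % ncz
                    elif nz < 0 or nz >= ncz:
                        continue
                    c2 = (nx * ncy + ny) * ncz + nz
                    same = c2 == c
                    if same and sidx > 0:
                        continue  # periodic image of itself (tiny cell counts)
                    for ii in range(cell_start[c], cell_start[c + 1]):
                        i = order[ii]
                        jj0 = ii + 1 if same else cell_start[c2]
                        for jj in range(jj0, cell_start[c2 + 1]):
                            j = order[jj]
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            if periodic[0]:
                                dx -= box[0] * round(dx / box[0])
                            if periodic[1]:
                                dy -= box[1] * round(dy / box[1])
                            if periodic[2]:
                                dz -= box[2] * round(dz / box[2])
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 >= 1.0 or r2 < 1e-24:
                                continue
                            r = math.sqrt(r2)
                            si = species[i]
                            sj = species[j]
                            a = a_tab[si, sj]
                            g = g_tab[si, sj]
                            s = s_tab[si, sj]
                            if a == 0.0 and g == 0.0:
                                continue
                            ex = dx / r
                            ey = dy / r
                            ez = dz / r
                            omc = 1.0 - r
                            f = a * omc
                            virial += f * r
                            if g != 0.0:
                                wr = omc ** k_tab[si, sj]
                                vdote = ((vel[i, 0] - vel[j, 0]) * ex
                                         + (vel[i, 1] - vel[j, 1]) * ey
                                         + (vel[i, 2] - vel[j, 2]) * ez)
                                theta = _pair_gaussian(seed, step, i, j)
                                f += (-g * wr * wr * vdote
                                      + s * wr * theta * inv_sqrt_dt)
                            forces[i, 0] += f * ex
                            forces[i, 1] += f * ey
                            forces[i, 2] += f * ez
                            forces[j, 0] -= f * ex
                            forces[j, 1] -= f * ey
                            forces[j, 2] -= f * ez
    return virial


class PairForceField:
    """Cell-list DPD force evaluator bound to coefficient tables and a seed."""

    def __init__(self, pairs: dict, box, kBT: float = 1.0, seed: int = 0,
                 periodic=(True, True, True)):
        self.a_tab, self.g_tab, self.s_tab, self.k_tab = pair_tables(pairs, kBT)
        self.kBT = kBT
        self.seed = int(seed) & 0x7FFFFFFF
        box = np.asarray(box, dtype=float)
        self.nc = np.maximum(box.astype(np.int64), 1)
        if np.any((self.nc < 3) & np.asarray(periodic)):
            raise ValueError("periodic box must be at least 3 r_c in each "
                             "periodic dimension for the half-stencil cell list")
        self.box = box
        self.periodic = np.asarray(periodic, dtype=np.bool_)
        self.last_virial = 0.0

    def __call__(self, system: DPDSystem, step: int, dt: float,
                 forces: np.ndarray) -> None:
        pos = system.positions
        idx = _cell_index(pos, self.box, self.nc)
        order = np.argsort(idx, kind="stable")
        ncell = int(self.nc.prod())
        cell_start = np.searchsorted(idx[order], np.arange(ncell + 1))
        self.last_virial = _pair_forces(
            pos, system.velocities, system.species, order,
            cell_start.astype(np.int64), self.nc, self.box, self.periodic,
            self.a_tab, self.g_tab, self.s_tab, self.k_tab,
            1.0 / math.sqrt(dt), step, self.seed, forces, _STENCIL)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def pair_force(ri, rj, vi, vj, params: DPDPairParams, noise: float,
               dt: float = 1.0) -> np.ndarray:
    """Single DPD pair force on particle i (reference implementation).

    The production path is the cell-list kernel; this direct evaluation is the
    public single-pair contract (and the test oracle for antisymmetry).
    """
    rij = np.asarray(ri, dtype=float) - np.asarray(rj, dtype=float)
    r = float(np.linalg.norm(rij))
    if r >= params.r_cut:
        return np.zeros(3)
    if r < 1e-12:
        import warnings
        warnings.warn("coincident particles; conservative force capped")
        return np.zeros(3)
    e = rij / r
    omc = 1.0 - r / params.r_cut
    wr = omc ** params.k
    vdote = float(np.dot(np.asarray(vi) - np.asarray(vj), e))
    f = (params.a * omc - params.gamma * wr * wr * vdote
         + params.sigma * wr * noise / math.sqrt(dt))
    return f * e


@dataclass
class Simulation:
    """Velocity-Verlet DPD driver with pluggable extra forces.

    ``extra_forces`` callables have signature (system, step, forces) and add
    in place (body forces, membrane elasticity, pressure compensation, OBMD).
    ``post_step`` callables run after each step (bounce-back, OBMD exchange).
    """

    system: DPDSystem
    field: PairForceField
    dt: float = 0.01
    extra_forces: list = field(default_factory=list)
    post_step: list = field(default_factory=list)
    step_index: int = 0
    _forces: np.ndarray = None

    def compute_forces(self) -> np.ndarray:
        f = np.zeros_like(self.system.positions)
        self.field(self.system, self.step_index, self.dt, f)
        for cb in self.extra_forces:
            cb(self.system, self.step_index, f)
        return f

    def step(self, n: int = 1) -> None:
        sys_ = self.system
        if self._forces is None:
            self._forces = self.compute_forces()
        for _ in range(n):
            m = sys_.masses[:, None]  # particle count may change (OBMD)
            f0 = self._forces
            dx = self.dt * sys_.velocities + 0.5 * self.dt ** 2 * f0 / m
            if np.max(np.abs(dx)) > 0.5 * sys_.box.min():
                raise RuntimeError("instability: particle moved more than half "
                                   "a box edge in one step")
            old = sys_.positions.copy()
            sys_.positions += dx
            for d in range(3):
                if sys_.periodic[d]:
                    sys_.positions[:, d] %= sys_.box[d]
            v_old = sys_.velocities.copy()
            sys_.velocities = v_old + 0.5 * self.dt * f0 / m  # lambda = 1/2
            self.step_index += 1
            f1 = self.compute_forces()
            sys_.velocities = v_old + 0.5 * self.dt * (f0 + f1) / m
            self._forces = f1
            for cb in self.post_step:
                cb(self, old)


def step(system: DPDSystem, dt: float, forces_callback) -> DPDSystem:
    """Advance one DPD velocity-Verlet step with a user force callback."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    m = system.masses[:, None]
    f0 = forces_callback(system)
    dx = dt * system.velocities + 0.5 * dt * dt * f0 / m
    if np.max(np.abs(dx)) > 0.5 * system.box.min():
        raise RuntimeError("instability: displacement exceeds half box")
    system.positions += dx
    for d in range(3):
        if system.periodic[d]:
            system.positions[:, d] %= system.box[d]
    v_old = system.velocities.copy()
    system.velocities = v_old + 0.5 * dt * f0 / m
    f1 = forces_callback(system)
    system.velocities = v_old + 0.5 * dt * (f0 + f1) / m
    return system


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def virial_pressure(system: DPDSystem, field: PairForceField) -> float:
    """p = rho k_B T + (1/3V) sum r_ij . F^C_ij (conservative virial).

    Uses the virial accumulated in the last force evaluation; dissipative and
    random contributions time-average to zero and are omitted.
    """
    f = np.zeros_like(system.positions)
    field(system, 0, 1.0, f)
    V = float(system.box.prod())
    rho = system.n / V
    return rho * system.kinetic_temperature() + field.last_virial / (3.0 * V)


def equilibrate_fluid(box, density, pairs, *, kBT=1.0, dt=0.01, seed=0,
                      species=WATER, mass=1.0, n_steps=500) -> tuple:
    rng = np.random.default_rng(seed)
    system = fill_box(box, density, rng, species=species, kBT=kBT, mass=mass)
    fld = PairForceField(pairs, box, kBT=kBT, seed=seed)
    sim = Simulation(system, fld, dt=dt)
    sim.step(n_steps)
    return sim


def measure_eos_pressure(a_ww: float, rho: float = 3.0, box=(5.0, 5.0, 5.0),
                         gamma: float = 3.5, k: float = 0.25, kBT: float = 1.0,
                         seed: int = 0, dt: float = 0.01,
                         n_equil: int = 500, n_sample: int = 1500,
                         sample_every: int = 10) -> float:
    """Time-averaged virial pressure of a pure water box at given a_ww."""
    pairs = {(WATER, WATER): DPDPairParams(a=a_ww, gamma=gamma, k=k, kBT=kBT)}
    sim = equilibrate_fluid(box, rho, pairs, kBT=kBT, dt=dt, seed=seed,
                            n_steps=n_equil)
    V = float(np.prod(box))
    rho_actual = sim.system.n / V
    acc = []
    for _ in range(n_sample // sample_every):
        sim.step(sample_every)
        acc.append(rho_actual * sim.system.kinetic_temperature()
                   + sim.field.last_virial / (3.0 * V))
    return float(np.mean(acc))


def fit_eos_alpha(state_points) -> tuple[float, float]:
    """Least-squares alpha from p = rho kBT + alpha a rho^2 (kBT = 1).

    ``state_points`` is a list of (a, rho, p); returns (alpha, rms residual).
    """
    pts = np.asarray(state_points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 state points")
    a, rho, p = pts[:, 0], pts[:, 1], pts[:, 2]
    X = (a * rho ** 2)[:, None]
    y = p - rho
    if np.linalg.matrix_rank(X) < 1 or np.allclose(X, 0):
        raise ValueError("rank-deficient design: vary a*rho^2")
    alpha, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = math.sqrt(float(((X @ alpha - y) ** 2).mean()))
    return float(alpha[0]), resid


def measure_viscosity(pairs: dict, box=(6.0, 6.0, 6.0), rho: float = 3.0,
                      species: int = WATER, mass: float = 1.0,
                      body_force: float = 0.02, kBT: float = 1.0,
                      dt: float = 0.01, seed: int = 0, n_equil: int = 1000,
                      n_sample: int = 6000, n_bins: int = 24):
    """Dynamic viscosity from a double periodic-Poiseuille flow.

    Opposed body forces of magnitude ``body_force`` (per particle) act along y
    in the two x-halves of the box; the steady velocity profile in each half
    is the parabola v(xi) = n g xi (w - xi) / (2 eta) with w = Lx/2, fitted by
    least squares.  Returns (eta, r_squared).
    """
    box = np.asarray(box, dtype=float)
    sim = equilibrate_fluid(box, rho, pairs, kBT=kBT, dt=dt, seed=seed,
                            species=species, mass=mass, n_steps=n_equil)
    half = box[0] / 2.0

    def body(system, step_, forces):
        sgn = np.where(system.positions[:, 0] < half, 1.0, -1.0)
        forces[:, 1] += sgn * body_force

    sim.extra_forces.append(body)
    sim.step(n_equil)  # develop the profile
    edges = np.linspace(0.0, box[0], n_bins + 1)
    vsum = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    for _ in range(n_sample // 10):
        sim.step(10)
        xb = np.clip(np.digitize(sim.system.positions[:, 0], edges) - 1,
                     0, n_bins - 1)
        np.add.at(vsum, xb, sim.system.velocities[:, 1])
        np.add.at(cnt, xb, 1.0)
    prof = vsum / np.maximum(cnt, 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_density = sim.system.n / float(box.prod())
    # design: v = A * shape(x), shape = +xi(w-xi) in the forced half, - in other
    xi = np.where(centers < half, centers, centers - half)
    sgn = np.where(centers < half, 1.0, -1.0)
    shape = sgn * xi * (half - xi)
    A = float(shape @ prof / (shape @ shape))
    fit = A * shape
    ss_res = float(((prof - fit) ** 2).sum())
    ss_tot = float(((prof - prof.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    eta = n_density * body_force / (2.0 * A)
    if r2 < 0.99:
        import warnings
        warnings.warn(f"non-parabolic Poiseuille profile (R^2 = {r2:.3f})")
    return eta, r2
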