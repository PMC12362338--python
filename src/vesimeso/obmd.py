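"""Open-boundary molecular dynamics: buffers, particle exchange, shear.

The box is open along x: a buffer slab at each end exchanges particles with a
reservoir and carries external forces that impose the momentum flux
J.n = P_xx n + P_yx e_y + P_zx e_z through the buffer-ROI interface.  The
buffer population relaxes as dN = -(dt/tau_B)(N - alpha_B N0); insertions use
the USHER steepest-descent search so new particles start near the mean
conservative potential energy, deletions remove particles nearest the open
face.  Imposing P_yx = eta * gamma_dot with opposite interface normals drives
a linear shear profile across the region of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .dpd import DPDSystem, Simulation


@dataclass
class ObmdBuffer:
    """One open-boundary buffer slab at an x end of the box."""

    lo: float
    hi: float
    n_inward: float          # +1 for the left buffer, -1 for the right
    N0: float
    tau_B: float
    alpha_B: float
    P_xx: float
    P_yx: float = 0.0
    P_zx: float = 0.0


def buffer_delta_n(N: float, N0: float, dt: float, tau_B: float,
                   alpha_B: float, rng: np.random.Generator | None = None):
    """Feedback particle-number change dN = -(dt/tau_B)(N - alpha_B N0).

    With an rng, rounds stochastically to an integer whose expectation equals
    the real value; otherwise returns the real value.
    """
    if tau_B <= 0:
        raise ValueError("tau_B must be positive")
    dn = -(dt / tau_B) * (N - alpha_B * N0)
    if rng is None:
        return dn
    base = math.floor(dn)
    return int(base + (1 if rng.random() < dn - base else 0))


def buffer_forces(stress_row, A: float, n_inward, inserted_momentum,
                  dt: float, n_particles: int) -> np.ndarray:
    """Per-particle external force satisfying the buffer momentum balance.

    total = (P_xx n + P_yx e_y + P_zx e_z) A - d(m v)_exchange / dt, split
    equally over the buffer particles.
    """
    if n_particles <= 0:
        raise ValueError("empty buffer cannot carry a boundary force")
    P_xx, P_yx, P_zx = stress_row
    n = np.asarray(n_inward, dtype=float)
    total = (P_xx * n + P_yx * np.array([0.0, 1.0, 0.0])
             + P_zx * np.array([0.0, 0.0, 1.0])) * A
    total = total - np.asarray(inserted_momentum, dtype=float) / dt
    return total / n_particles


@njit(cache=True)
def _trial_energy_grad(pos, box, periodic, trial, a_ww, skip):
    """Conservative DPD energy a/2 (1-r)^2 and gradient at a trial point."""
    U = 0.0
    gx = gy = gz = 0.0
    n = pos.shape[0]
    for j in range(n):
        if j == skip:
            continue
        dx = trial[0] - pos[j, 0]
        dy = trial[1] - pos[j, 1]
        dz = trial[2] - pos[j, 2]
        if periodic[0]:
            dx -= box[0] * round(dx / box[0])
        if periodic[1]:
            dy -= box[1] * round(dy / box[1])
        if periodic[2]:
            dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= 1.0 or r2 < 1e-20:
            continue
        r = math.sqrt(r2)
        omr = 1.0 - r
        U += 0.5 * a_ww * omr * omr
        coef = -a_ww * omr / r
        gx += coef * dx
        gy += coef * dy
        gz += coef * dz
    return U, gx, gy, gz


def insert_particle(positions, box, periodic, region_lo, region_hi,
                    a_ww: float, target_energy: float,
                    rng: np.random.Generator, max_iter: int = 200,
                    tol: float = 1.0, stall_tol: float | None = None):
    """USHER insertion: steepest descent to the target potential energy.

    Descent stops at ``target_energy + tol`` when reachable.  In a dense
    frozen configuration the best local minimum for a new particle sits
    above the equilibrated per-particle mean (the cage cannot relax), so a
    stalled descent is accepted up to ``stall_tol`` (default 0.2 a_ww)
    above the target; the soft DPD fluid relaxes the excess within a few
    steps.  Returns a position or None if not converged.  For an ideal gas
    (a_ww = 0) any uniform draw is accepted immediately.
    """
    lo = np.asarray(region_lo, dtype=float)
    hi = np.asarray(region_hi, dtype=float)
    trial = lo + rng.random(3) * (hi - lo)
    if a_ww == 0.0:
        return trial
    if stall_tol is None:
        stall_tol = 0.2 * a_ww
    per = np.asarray(periodic, dtype=np.bool_)
    box = np.asarray(box, dtype=float)
    ds_max = 0.1
    best_U = np.inf
    best = trial.copy()
    since_improved = 0
    for _ in range(max_iter):
        U, gx, gy, gz = _trial_energy_grad(positions, box, per, trial,
                                           a_ww, -1)
        if U <= target_energy + tol:
            return trial
        if U < best_U - 1e-3:
            best_U = U
            best = trial.copy()
            since_improved = 0
        else:
            since_improved += 1
        gnorm = math.sqrt(gx * gx + gy * gy + gz * gz)
        if gnorm < 1e-10 or since_improved > 15:
            if best_U <= target_energy + stall_tol:
                return best
            trial = lo + rng.random(3) * (hi - lo)  # restart elsewhere
            since_improved = 0
            continue
        ds = min((U - target_energy) / gnorm, ds_max)
        trial = trial - ds * np.array([gx, gy, gz]) / gnorm
        trial = np.minimum(np.maximum(trial, lo), hi)
    if best_U <= target_energy + stall_tol:
        return best
    return None


class OpenBoundary:
    """OBMD controller: two x-buffers with particle exchange and stresses.

    Register ``.apply_forces`` in ``Simulation.extra_forces`` and
    ``.exchange`` in ``Simulation.post_step``.  Membrane/object beads are
    never exchanged (only ``species == exchange_species``).
    """

    def __init__(self, box, buffer_fraction: float, rho: float,
                 a_ww: float, kBT: float = 1.0, P_xx: float = 0.0,
                 P_yx: float = 0.0, tau_B: float | None = None,
                 alpha_B: float = 1.0, seed: int = 0, dt: float = 0.01,
                 exchange_species: int = 0, mass: float = 1.0):
        box = np.asarray(box, dtype=float)
        self.box = box
        self.w = buffer_fraction * box[0]
        A = box[1] * box[2]
        self.A = A
        N0 = rho * self.w * A
        # gentle relaxation: strong feedback (tau_B ~ dt) causes constant
        # insertion/deletion churn that measurably heats the fluid
        tau_B = 10.0 if tau_B is None else tau_B
        self.buffers = [
            ObmdBuffer(0.0, self.w, +1.0, N0, tau_B, alpha_B, P_xx, P_yx),
            ObmdBuffer(box[0] - self.w, box[0], -1.0, N0, tau_B, alpha_B,
                       P_xx, P_yx),
        ]
        self.a_ww = a_ww
        self.kBT = kBT
        self.mass = mass
        self.rng = np.random.default_rng(seed)
        self.exchange_species = exchange_species
        self.exchange_momentum = [np.zeros(3), np.zeros(3)]
        self.n_failed_insertions = 0
        self.n_inserted = 0
        self.n_deleted = 0

    # -- force phase -------------------------------------------------------
    def apply_forces(self, system: DPDSystem, step: int,
                     forces: np.ndarray) -> None:
        x = system.positions[:, 0]
        for bi, buf in enumerate(self.buffers):
            mask = (x >= buf.lo) & (x < buf.hi)
            n_in = int(mask.sum())
            if n_in == 0:
                if buf.P_xx != 0 or buf.P_yx != 0:
                    raise RuntimeError("empty buffer with imposed stress")
                continue
            n_vec = np.array([buf.n_inward, 0.0, 0.0])
            per = buffer_forces((buf.P_xx, buf.P_yx * buf.n_inward, buf.P_zx
                                 * buf.n_inward),
                                self.A, n_vec, self.exchange_momentum[bi],
                                self._dt, n_in)
            forces[mask] += per
        self.exchange_momentum = [np.zeros(3), np.zeros(3)]

    _dt: float = 0.01

    # -- exchange phase ----------------------------------------------------
    def exchange(self, sim: Simulation, old_positions) -> None:
        self._dt = sim.dt
        sys_ = sim.system
        x = sys_.positions[:, 0]
        exch = sys_.species == self.exchange_species
        # drop particles that left through the open ends; their momentum is
        # part of the exchange term in the buffer momentum balance
        gone = exch & ((x < 0.0) | (x >= self.box[0]))
        if gone.any():
            idx = np.nonzero(gone)[0]
            left = sys_.positions[idx, 0] < 0.0
            for bi, side in ((0, left), (1, ~left)):
                sel = idx[side]
                mom = (sys_.masses[sel, None]
                       * sys_.velocities[sel]).sum(axis=0)
                self.exchange_momentum[bi] = self.exchange_momentum[bi] - mom
            self._remove(sim, idx)
            x = sys_.positions[:, 0]
            exch = sys_.species == self.exchange_species
        for bi, buf in enumerate(self.buffers):
            in_buf = exch & (x >= buf.lo) & (x < buf.hi)
            N = int(in_buf.sum())
            dn = buffer_delta_n(N, buf.N0, sim.dt, buf.tau_B, buf.alpha_B,
                                self.rng)
            if dn < 0:
                idx = np.nonzero(in_buf)[0]
                # delete nearest the open face first
                face = 0.0 if buf.n_inward > 0 else self.box[0]
                order = np.argsort(np.abs(sys_.positions[idx, 0] - face))
                kill = idx[order[:min(-dn, len(idx))]]
                mom = (sys_.masses[kill, None]
                       * sys_.velocities[kill]).sum(axis=0)
                self.exchange_momentum[bi] = self.exchange_momentum[bi] - mom
                self._remove(sim, kill)
                x = sys_.positions[:, 0]
                exch = sys_.species == self.exchange_species
            elif dn > 0:
                target = self._mean_energy(sys_, exch)
                lo = np.array([buf.lo, 0.0, 0.0])
                hi = np.array([buf.hi, self.box[1], self.box[2]])
                new_pos = []
                for _ in range(dn):
                    p = insert_particle(sys_.positions, self.box,
                                        sys_.periodic, lo, hi, self.a_ww,
                                        target, self.rng)
                    if p is None:
                        self.n_failed_insertions += 1
                    else:
                        new_pos.append(p)
                if new_pos:
                    # thermal velocity superposed on the local stream (a
                    # zero-stream draw would exert a systematic drag on
                    # sheared buffers)
                    stream = (sys_.velocities[in_buf].mean(axis=0)
                              if N > 0 else np.zeros(3))
                    vel = stream + self.rng.normal(
                        0.0, math.sqrt(self.kBT / self.mass),
                        (len(new_pos), 3))
                    mom = (self.mass * vel).sum(axis=0)
                    self.exchange_momentum[bi] = self.exchange_momentum[bi] + mom
                    self._insert(sim, np.asarray(new_pos), vel)
                    x = sys_.positions[:, 0]
                    exch = sys_.species == self.exchange_species

    def _mean_energy(self, sys_: DPDSystem, exch_mask) -> float:
        idx = np.nonzero(exch_mask)[0]
        if len(idx) == 0 or self.a_ww == 0.0:
            return 0.0
        sample = self.rng.choice(idx, size=min(24, len(idx)), replace=False)
        vals = []
        for i in sample:
            U, *_ = _trial_energy_grad(sys_.positions, self.box,
                                       sys_.periodic, sys_.positions[i],
                                       self.a_ww, int(i))
            vals.append(U)
        return float(np.mean(vals))

    def _remove(self, sim: Simulation, idx) -> None:
        sys_ = sim.system
        keep = np.ones(sys_.n, dtype=bool)
        keep[idx] = False
        self.n_deleted += int(len(idx))
        sys_.positions = sys_.positions[keep]
        sys_.velocities = sys_.velocities[keep]
        sys_.species = sys_.species[keep]
        sys_.masses = sys_.masses[keep]
        if sim._forces is not None:
            sim._forces = sim._forces[keep]
        self._reindex(sim, keep)

    def _insert(self, sim: Simulation, pos, vel) -> None:
        sys_ = sim.system
        n_new = len(pos)
        self.n_inserted += n_new
        sys_.positions = np.vstack([sys_.positions, pos])
        sys_.velocities = np.vstack([sys_.velocities, vel])
        sys_.species = np.concatenate(
            [sys_.species, np.full(n_new, self.exchange_species, np.int8)])
        sys_.masses = np.concatenate(
            [sys_.masses, np.full(n_new, self.mass)])
        if sim._forces is not None:
            sim._forces = np.vstack([sim._forces, np.zeros((n_new, 3))])

    def _reindex(self, sim: Simulation, keep) -> None:
        """Remap index arrays held by other callbacks after deletions."""
        new_index = np.cumsum(keep) - 1
        for cb in list(sim.extra_forces) + list(sim.post_step):
            for attr in ("mem_idx", "fluid_idx"):
                if hasattr(cb, attr):
                    old = getattr(cb, attr)
                    kept = keep[old]
                    setattr(cb, attr, new_index[old[kept]].astype(np.int64))


def impose_shear(ob: OpenBoundary, gamma_dot: float, eta_scaled: float,
                 c0: float | None = None) -> None:
    """Set the buffer shear stresses for a target shear rate.

    P_yx = eta * gamma_dot with opposite interface normals produces a linear
    v_y(x) profile of slope gamma_dot across the ROI.  Warns when the edge
    velocity implies a Mach number above 0.2.
    """
    P_yx = eta_scaled * gamma_dot
    for buf in ob.buffers:
        buf.P_yx = P_yx
    if c0 is not None:
        u = 0.5 * gamma_dot * ob.box[0]
        if u / c0 > 0.2:
            import warnings
            warnings.warn(f"Mach number {u / c0:.2f} > 0.2 for the imposed shear")


def shear_profile(system: DPDSystem, n_bins: int = 16,
                  species: int | None = 0):
    """Binned v_y(x) profile (one snapshot); average over calls for statistics."""
    mask = (np.ones(system.n, dtype=bool) if species is None
            else system.species == species)
    edges = np.linspace(0.0, system.box[0], n_bins + 1)
    xb = np.clip(np.digitize(system.positions[mask, 0], edges) - 1,
                 0, n_bins - 1)
    v = np.zeros(n_bins)
    c = np.zeros(n_bins)
    np.add.at(v, xb, system.velocities[mask, 1])
    np.add.at(c, xb, 1.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, v, c
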