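"""Numba kernels for membrane elasticity.

Constant-strain-triangle (CST) in-plane energy with a general orthotropic
elastic tensor, and Kantor-Nelson dihedral bending.  Forces are the exact
analytic gradients of the discrete energy.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def membrane_forces(x, faces, inv_dm, area, m2, Ka, mu, muL, c, aniso,
                    edges, theta0, kb, forces, face_energy, edge_energy):
    """Accumulate elastic forces; returns (U_inplane, U_bend).

    ``forces`` must be zeroed by the caller; per-face in-plane energies and
    per-edge bending energies are written to the output arrays.
    """
    nf = faces.shape[0]
    U_el = 0.0
    for f in range(nf):
        i0, i1, i2 = faces[f, 0], faces[f, 1], faces[f, 2]
        # deformed edge matrix D (3x2) and deformation gradient F = D invDm
        d10 = x[i1, 0] - x[i0, 0]
        d11 = x[i1, 1] - x[i0, 1]
        d12 = x[i1, 2] - x[i0, 2]
        d20 = x[i2, 0] - x[i0, 0]
        d21 = x[i2, 1] - x[i0, 1]
        d22 = x[i2, 2] - x[i0, 2]
        a00 = inv_dm[f, 0, 0]
        a01 = inv_dm[f, 0, 1]
        a10 = inv_dm[f, 1, 0]
        a11 = inv_dm[f, 1, 1]
        F00 = d10 * a00 + d20 * a10
        F01 = d10 * a01 + d20 * a11
        F10 = d11 * a00 + d21 * a10
        F11 = d11 * a01 + d21 * a11
        F20 = d12 * a00 + d22 * a10
        F21 = d12 * a01 + d22 * a11
        # Green-Lagrange strain eps = (F^T F - I)/2   (2x2 symmetric)
        C00 = F00 * F00 + F10 * F10 + F20 * F20
        C01 = F00 * F01 + F10 * F11 + F20 * F21
        C11 = F01 * F01 + F11 * F11 + F21 * F21
        e00 = 0.5 * (C00 - 1.0)
        e01 = 0.5 * C01
        e11 = 0.5 * (C11 - 1.0)
        tr = e00 + e11
        tr2 = e00 * e00 + 2.0 * e01 * e01 + e11 * e11  # tr(eps^2)
        W = 0.5 * (Ka * tr * tr + mu * (2.0 * tr2 - tr * tr))
        # 2nd Piola-Kirchhoff stress S = dW/deps
        S00 = (Ka - mu) * tr + 2.0 * mu * e00
        S01 = 2.0 * mu * e01
        S11 = (Ka - mu) * tr + 2.0 * mu * e11
        if aniso:
            m0 = m2[f, 0]
            m1 = m2[f, 1]
            # (eps m) vector
            em0 = e00 * m0 + e01 * m1
            em1 = e01 * m0 + e11 * m1
            mem = m0 * em0 + m1 * em1            # m^T eps m
            me2m = em0 * em0 + em1 * em1         # m^T eps^2 m
            dml = muL - mu
            W += 2.0 * dml * me2m + 0.5 * c * mem * mem
            # d(m eps^2 m)/deps = (M eps + eps M) symmetrized
            S00 += 2.0 * dml * (2.0 * m0 * em0) + c * mem * m0 * m0
            S01 += 2.0 * dml * (m0 * em1 + m1 * em0) + c * mem * m0 * m1
            S11 += 2.0 * dml * (2.0 * m1 * em1) + c * mem * m1 * m1
        A = area[f]
        face_energy[f] = W * A
        U_el += W * A
        # dU/dD = A * F S invDm^T  (3x2); forces are the negatives
        FS00 = F00 * S00 + F01 * S01
        FS01 = F00 * S01 + F01 * S11
        FS10 = F10 * S00 + F11 * S01
        FS11 = F10 * S01 + F11 * S11
        FS20 = F20 * S00 + F21 * S01
        FS21 = F20 * S01 + F21 * S11
        g10 = A * (FS00 * a00 + FS01 * a01)
        g11 = A * (FS10 * a00 + FS11 * a01)
        g12 = A * (FS20 * a00 + FS21 * a01)
        g20 = A * (FS00 * a10 + FS01 * a11)
        g21 = A * (FS10 * a10 + FS11 * a11)
        g22 = A * (FS20 * a10 + FS21 * a11)
        forces[i1, 0] -= g10
        forces[i1, 1] -= g11
        forces[i1, 2] -= g12
        forces[i2, 0] -= g20
        forces[i2, 1] -= g21
        forces[i2, 2] -= g22
        forces[i0, 0] += g10 + g20
        forces[i0, 1] += g11 + g21
        forces[i0, 2] += g12 + g22

    U_b = 0.0
    if kb != 0.0:
        ne = edges.shape[0]
        for eidx in range(ne):
            ia, ib, ic, id_ = edges[eidx, 0], edges[eidx, 1], edges[eidx, 2], edges[eidx, 3]
            e0 = x[ib, 0] - x[ia, 0]
            e1 = x[ib, 1] - x[ia, 1]
            e2 = x[ib, 2] - x[ia, 2]
            c10 = x[ic, 0] - x[ia, 0]
            c11 = x[ic, 1] - x[ia, 1]
            c12 = x[ic, 2] - x[ia, 2]
            d10 = x[id_, 0] - x[ia, 0]
            d11 = x[id_, 1] - x[ia, 1]
            d12 = x[id_, 2] - x[ia, 2]
            # n1 = e x c1 ; n2 = d1 x e
            n10 = e1 * c12 - e2 * c11
            n11 = e2 * c10 - e0 * c12
            n12 = e0 * c11 - e1 * c10
            n20 = d11 * e2 - d12 * e1
            n21 = d12 * e0 - d10 * e2
            n22 = d10 * e1 - d11 * e0
            l = math.sqrt(e0 * e0 + e1 * e1 + e2 * e2)
            n1sq = n10 * n10 + n11 * n11 + n12 * n12
            n2sq = n20 * n20 + n21 * n21 + n22 * n22
            inv_n1 = 1.0 / math.sqrt(n1sq)
            inv_n2 = 1.0 / math.sqrt(n2sq)
            cos_t = (n10 * n20 + n11 * n21 + n12 * n22) * inv_n1 * inv_n2
            # sin from (n1 x n2) . e_hat
            cx0 = n11 * n22 - n12 * n21
            cx1 = n12 * n20 - n10 * n22
            cx2 = n10 * n21 - n11 * n20
            sin_t = (cx0 * e0 + cx1 * e1 + cx2 * e2) * inv_n1 * inv_n2 / l
            theta = math.atan2(sin_t, cos_t)
            dth = theta - theta0[eidx]
            edge_energy[eidx] = kb * (1.0 - math.cos(dth))
            U_b += edge_energy[eidx]
            dUdth = kb * math.sin(dth)
            # gradients of theta
            s1 = l / n1sq
            s2 = l / n2sq
            # xb - xc  and  xb - xd projections on e
            bc_e = ((x[ib, 0] - x[ic, 0]) * e0 + (x[ib, 1] - x[ic, 1]) * e1
                    + (x[ib, 2] - x[ic, 2]) * e2)
            bd_e = ((x[ib, 0] - x[id_, 0]) * e0 + (x[ib, 1] - x[id_, 1]) * e1
                    + (x[ib, 2] - x[id_, 2]) * e2)
            ca_e = ((x[ic, 0] - x[ia, 0]) * e0 + (x[ic, 1] - x[ia, 1]) * e1
                    + (x[ic, 2] - x[ia, 2]) * e2)
            da_e = ((x[id_, 0] - x[ia, 0]) * e0 + (x[id_, 1] - x[ia, 1]) * e1
                    + (x[id_, 2] - x[ia, 2]) * e2)
            inv_l = 1.0 / l
            c_c = s1  # coeff for grad at xc: (l/|n1|^2) n1
            c_d = s2
            ca0 = -bc_e * inv_l / n1sq
            ca1 = -ca_e * inv_l / n1sq
            cb0 = -bd_e * inv_l / n2sq
            cb1 = -da_e * inv_l / n2sq
            # accumulate: f = -dU/dtheta * grad(theta); with this normal
            # convention grad(theta) carries an overall minus sign
            forces[ic, 0] += dUdth * c_c * n10
            forces[ic, 1] += dUdth * c_c * n11
            forces[ic, 2] += dUdth * c_c * n12
            forces[id_, 0] += dUdth * c_d * n20
            forces[id_, 1] += dUdth * c_d * n21
            forces[id_, 2] += dUdth * c_d * n22
            forces[ia, 0] += dUdth * (ca0 * n10 + cb0 * n20)
            forces[ia, 1] += dUdth * (ca0 * n11 + cb0 * n21)
            forces[ia, 2] += dUdth * (ca0 * n12 + cb0 * n22)
            forces[ib, 0] += dUdth * (ca1 * n10 + cb1 * n20)
            forces[ib, 1] += dUdth * (ca1 * n11 + cb1 * n21)
            forces[ib, 2] += dUdth * (ca1 * n12 + cb1 * n22)
    return U_el, U_b
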