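import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesimeso import elasticity as el
from vesimeso import meshgen as mg


def random_strain(rng, scale=0.05):
    e = scale * rng.standard_normal((2, 2))
    return 0.5 * (e + e.T)


def energy_density_brute(eps, Ka, mu, muL, c, m):
    """Direct contraction of the elastic tensor (independent oracle)."""
    d = np.eye(2)
    M = np.outer(m, m)
    C = np.zeros((2, 2, 2, 2))
    for i in range(2):
        for j in range(2):
            for k in range(2):
                for l in range(2):
                    C[i, j, k, l] = (
                        Ka * d[i, j] * d[k, l]
                        + mu * (d[i, k] * d[j, l] + d[i, l] * d[j, k]
                                - d[i, j] * d[k, l])
                        + (muL - mu) * (m[i] * m[l] * d[j, k]
                                        + m[j] * m[l] * d[i, k]
                                        + m[i] * m[k] * d[j, l]
                                        + m[j] * m[k] * d[i, l])
                        + c * m[i] * m[j] * m[k] * m[l])
    return 0.5 * np.einsum("ijkl,ij,kl->", C, eps, eps)


class TestStrain:
    def test_zero_at_reference(self, emb_mesh):
        F, eps = el.strain_states(emb_mesh)
        assert np.abs(eps).max() < 1e-12

    def test_rigid_rotation_invariance(self, emb_mesh, rng):
        q = rng.standard_normal(3)
        q /= np.linalg.norm(q)
        ang = 1.1
        K = np.array([[0, -q[2], q[1]], [q[2], 0, -q[0]], [-q[1], q[0], 0]])
        R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * K @ K
        rot = emb_mesh.with_vertices(emb_mesh.vertices @ R.T + [1.0, 2.0, 3.0])
        _, eps = el.strain_states(rot)
        assert np.abs(eps).max() < 1e-9

    def test_biaxial_stretch_closed_form(self, emb_mesh):
        lam = 1.07
        stretched = emb_mesh.with_vertices(emb_mesh.vertices * lam)
        _, eps = el.strain_states(stretched)
        expect = 0.5 * (lam ** 2 - 1.0)
        assert np.allclose(eps[:, 0, 0], expect, atol=1e-10)
        assert np.allclose(eps[:, 1, 1], expect, atol=1e-10)
        assert np.allclose(eps[:, 0, 1], 0.0, atol=1e-10)

    def test_degenerate_triangle_rejected(self):
        inv_dm = np.eye(2)
        with pytest.raises(ValueError):
            el.triangle_strain(inv_dm, np.array([1.0, 0, 0]),
                               np.array([2.0, 0, 0]))


class TestInplaneEnergy:
    def test_pure_shear_and_dilation(self):
        """Single-triangle closed forms: traceless shear 2 mu e0^2 A and
        dilation 2 Ka e0^2 A."""
        verts = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0],
                          [0.7, 0.7, 1.0]])
        faces = np.array([[0, 1, 2], [1, 0, 3], [2, 1, 3], [0, 2, 3]])
        mesh = mg.TriMesh(verts, faces)
        Ka, mu = 37.0, 11.0
        e0 = 0.03
        # engineered deformation acting only on face 0 is impractical on a
        # closed mesh; instead check the analytic density via the brute
        # tensor contraction on random strains
        rng = np.random.default_rng(0)
        for _ in range(100):
            eps = random_strain(rng)
            dens_iso = 0.5 * (Ka * np.trace(eps) ** 2
                              + mu * (2 * np.trace(eps @ eps)
                                      - np.trace(eps) ** 2))
            brute = energy_density_brute(eps, Ka, mu, mu, 0.0,
                                         np.array([1.0, 0.0]))
            assert dens_iso == pytest.approx(brute, rel=1e-12)
        shear = np.array([[e0, 0], [0, -e0]])
        assert energy_density_brute(shear, Ka, mu, mu, 0.0,
                                    np.array([1.0, 0.0])) == \
            pytest.approx(2 * mu * e0 ** 2)
        dila = e0 * np.eye(2)
        assert energy_density_brute(dila, Ka, mu, mu, 0.0,
                                    np.array([1.0, 0.0])) == \
            pytest.approx(2 * Ka * e0 ** 2)

    def test_orthotropic_reduces_to_isotropic(self, gv_small, rng):
        mesh, rib = gv_small
        x = mesh.vertices + 0.03 * rng.standard_normal(mesh.vertices.shape)
        m = mesh.with_vertices(x)
        e_iso = el.inplane_energy_isotropic(m, 50.0, 20.0)
        e_ort = el.inplane_energy_orthotropic(m, rib, 50.0, 20.0, 20.0,
                                              1e-300)
        assert e_iso == pytest.approx(e_ort, rel=1e-12)

    @given(st.floats(-0.05, 0.05), st.floats(-0.05, 0.05),
           st.floats(-0.05, 0.05))
    @settings(max_examples=200, deadline=None)
    def test_orthotropic_density_vs_brute_tensor(self, a, b, c_):
        eps = np.array([[a, c_], [c_, b]])
        Ka, mu, muL, c = 40.0, 15.0, 22.0, 9.0
        m = np.array([math.cos(0.7), math.sin(0.7)])
        em = eps @ m
        dens = 0.5 * (Ka * np.trace(eps) ** 2
                      + mu * (2 * np.trace(eps @ eps) - np.trace(eps) ** 2)
                      + 4 * (muL - mu) * float(em @ em)
                      + c * float(m @ eps @ m) ** 2)
        brute = energy_density_brute(eps, Ka, mu, muL, c, m)
        assert dens == pytest.approx(brute, rel=1e-10, abs=1e-14)

    def test_rib_aligned_strain_closed_form(self):
        Ka, mu, muL, c = 40.0, 15.0, 22.0, 9.0
        e0 = 0.04
        m = np.array([1.0, 0.0])
        eps = e0 * np.outer(m, m)
        assert energy_density_brute(eps, Ka, mu, muL, c, m) == \
            pytest.approx(0.5 * (Ka - 3 * mu + 4 * muL + c) * e0 ** 2)
        mp = np.array([0.0, 1.0])
        epsp = e0 * np.outer(mp, mp)
        assert energy_density_brute(epsp, Ka, mu, muL, c, m) == \
            pytest.approx(0.5 * (Ka + mu) * e0 ** 2)


class TestEngineeringConversion:
    def test_isotropic_limit(self):
        E, nu = 1000.0, 0.3
        eng = el.OrthotropicEngineering(E_l=E, E_t=E, nu_lt=nu,
                                        G=E / (2 * (1 + nu)), h=0.1)
        Ka, mu, muL, c = el.engineering_to_tensor(eng)
        assert Ka == pytest.approx(E / (2 * (1 - nu)))
        assert mu == pytest.approx(E / (2 * (1 + nu)))
        assert muL == pytest.approx(mu)
        assert c == pytest.approx(0.0, abs=1e-9)

    def test_round_trip(self):
        eng = el.OrthotropicEngineering(E_l=4000.0, E_t=1500.0, nu_lt=0.25,
                                        G=600.0, h=0.2)
        back = el.tensor_to_engineering(*el.engineering_to_tensor(eng), h=0.2)
        assert back.E_l == pytest.approx(eng.E_l, rel=1e-12)
        assert back.E_t == pytest.approx(eng.E_t, rel=1e-12)
        assert back.nu_lt == pytest.approx(eng.nu_lt, rel=1e-12)
        assert back.G == pytest.approx(eng.G, rel=1e-12)

    def test_stability_of_generic_inputs(self):
        eng = el.OrthotropicEngineering(E_l=4000.0, E_t=1500.0, nu_lt=0.25,
                                        G=600.0, h=0.2)
        Ka, mu, muL, c = el.engineering_to_tensor(eng)
        assert muL > 0 and c > 0 and Ka > 0 and mu > 0

    def test_noninvertible_rejected(self):
        eng = el.OrthotropicEngineering(E_l=100.0, E_t=900.0, nu_lt=0.99,
                                        G=50.0, h=0.1)
        with pytest.raises(ValueError):
            el.engineering_to_tensor(eng)


class TestBending:
    def test_zero_at_reference_and_flat(self, emb_mesh):
        assert el.bending_energy(emb_mesh, 5.0, spontaneous=True) == \
            pytest.approx(0.0, abs=1e-20)

    def test_sphere_continuum_limit(self):
        """The dihedral (Kantor-Nelson) sum on a closed sphere tends to
        8*pi*kappa/3: the discretization carries an implicit Gaussian
        modulus -4 kappa/3, so the continuum value is
        8 pi (kappa + kappa_bar/2)."""
        expect = 8 * math.pi / 3.0
        for s in (2, 3, 4):
            ub = el.bending_energy(mg.icosphere(s, 1.0), 1.0,
                                   spontaneous=False)
            assert ub == pytest.approx(expect, rel=0.05)

    def test_scale_free(self):
        # bending energy of a sphere is independent of its radius
        u1 = el.bending_energy(mg.icosphere(3, 1.0), 2.0, spontaneous=False)
        u2 = el.bending_energy(mg.icosphere(3, 5.0), 2.0, spontaneous=False)
        assert u1 == pytest.approx(u2, rel=1e-9)


class TestForces:
    def test_zero_at_reference(self, emb_mesh, emb_material):
        f = el.vertex_forces(emb_mesh, emb_material)
        scale = emb_material.E2d
        assert np.abs(f).max() < 1e-10 * scale

    def test_finite_difference_oracle(self, emb_mesh, emb_material, rng):
        x = emb_mesh.vertices + 0.02 * rng.standard_normal(
            emb_mesh.vertices.shape)
        m = emb_mesh.with_vertices(x)
        F = el.vertex_forces(m, emb_material)
        h = 1e-6
        worst = 0.0
        for k in rng.choice(x.size, 40, replace=False):
            xp = x.copy().ravel()
            xm = x.copy().ravel()
            xp[k] += h
            xm[k] -= h
            up = el.elastic_energy(emb_mesh.with_vertices(xp.reshape(-1, 3)),
                                   emb_material)["total"]
            um = el.elastic_energy(emb_mesh.with_vertices(xm.reshape(-1, 3)),
                                   emb_material)["total"]
            fd = -(up - um) / (2 * h)
            worst = max(worst, abs(fd - F.ravel()[k]) / max(1e-9, abs(fd)))
        assert worst < 1e-5

    def test_momentum_and_torque_free(self, gv_small, gv_small_material, rng):
        mesh, rib = gv_small
        x = mesh.vertices + 0.05 * rng.standard_normal(mesh.vertices.shape)
        m = mesh.with_vertices(x)
        F = el.vertex_forces(m, gv_small_material, rib=rib)
        fscale = np.abs(F).max()
        assert np.abs(F.sum(axis=0)).max() < 1e-9 * fscale
        assert np.abs(np.cross(x, F).sum(axis=0)).max() < 1e-8 * fscale

    def test_energy_rigid_motion_invariance(self, gv_small,
                                            gv_small_material, rng):
        mesh, rib = gv_small
        x = mesh.vertices + 0.05 * rng.standard_normal(mesh.vertices.shape)
        u0 = el.elastic_energy(mesh.with_vertices(x), gv_small_material,
                               rib=rib)["total"]
        q = rng.standard_normal(3)
        q /= np.linalg.norm(q)
        K = np.array([[0, -q[2], q[1]], [q[2], 0, -q[0]], [-q[1], q[0], 0]])
        R = np.eye(3) + math.sin(0.8) * K + (1 - math.cos(0.8)) * K @ K
        u1 = el.elastic_energy(mesh.with_vertices(x @ R.T + [5, -3, 1.0]),
                               gv_small_material, rib=rib)["total"]
        assert u1 == pytest.approx(u0, rel=1e-10)


class TestHessianModes:
    @pytest.fixture(scope="class")
    def hessian(self, emb_mesh, emb_material):
        return el.elastic_hessian(emb_mesh, emb_material)

    def test_symmetry(self, hessian):
        assert np.abs(hessian - hessian.T).max() <= \
            1e-8 * np.abs(hessian).max()

    def test_six_rigid_modes(self, hessian):
        vals = np.linalg.eigvalsh(hessian)
        assert np.abs(vals[:6]).max() < 1e-6 * vals.max()
        assert vals[6] > 1e-4 * vals.max()

    def test_quadratic_form(self, hessian, emb_mesh, emb_material, rng):
        d = 1e-3 * rng.standard_normal(hessian.shape[0])
        u0 = el.elastic_energy(emb_mesh, emb_material)["total"]
        u1 = el.elastic_energy(
            emb_mesh.with_vertices(emb_mesh.vertices + d.reshape(-1, 3)),
            emb_material)["total"]
        quad = 0.5 * d @ hessian @ d
        assert (u1 - u0) == pytest.approx(quad, rel=0.01)

    def test_one_dof_spring_analogue(self):
        k, m = 7.3, 2.1
        H = np.diag([k, 1.0, 1.0])  # one soft + fillers
        om, modes = el.normal_modes(H, np.array([m]), n_rigid=0)
        assert om[0] == pytest.approx(math.sqrt(1.0 / m))
        assert om[-1] == pytest.approx(math.sqrt(k / m))

    def test_nonnegative_at_minimum(self, hessian, emb_mesh):
        om, _ = el.normal_modes(hessian, np.ones(emb_mesh.n_vertices))
        assert np.all(om >= 0)
        assert np.all(np.diff(om) >= -1e-12)

    def test_gv_degenerate_partners(self, gv_small, gv_small_material):
        """Every n != 0 GV mode has a near-degenerate partner (rotated copy).

        On this deliberately coarse 128-vertex capsule the discrete mesh
        breaks the rotational symmetry at the few-percent level; the
        production 1404-vertex mesh pairs to < 0.1 % (acceptance suite).
        """
        mesh, rib = gv_small
        H = el.elastic_hessian(mesh, gv_small_material, rib=rib)
        om, _ = el.normal_modes(H, np.ones(mesh.n_vertices))
        for k in range(4):
            others = np.delete(om[:8], k)
            assert np.abs(others - om[k]).min() / om[k] < 0.06
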