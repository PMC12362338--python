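import math

import numpy as np
import pytest
import scipy.integrate

from vesimeso import elasticity as el
from vesimeso import meshgen as mg
from vesimeso import protocols as pr


class TestJeffery:
    def test_sphere_limit(self):
        t = np.linspace(0, 5, 50)
        th = pr.jeffery_theta(1.0, 1.0, 0.8, t)
        assert np.allclose(th, 0.8 * t / 2, atol=1e-12)

    def test_starts_at_zero(self):
        assert pr.jeffery_theta(2, 1, 1, np.array([0.0]))[0] == 0.0

    def test_period_closed_form(self):
        assert pr.jeffery_period(2, 1, 1) == pytest.approx(5 * math.pi)

    def test_matches_ode_oracle(self):
        """d(theta)/dt = gdot (a^2 cos^2 + b^2 sin^2)/(a^2+b^2), the exact
        orbit equation for the printed closed form."""
        a, b, gd = 2.0, 1.0, 1.0

        def rhs(t, th):
            return gd * (a * a * np.cos(th) ** 2
                         + b * b * np.sin(th) ** 2) / (a * a + b * b)

        t = np.linspace(0, 20, 400)
        sol = scipy.integrate.solve_ivp(rhs, (0, 20), [0.0], t_eval=t,
                                        rtol=1e-10, atol=1e-12)
        th = pr.jeffery_theta(a, b, gd, t)
        assert np.abs(sol.y[0] - th).max() < 1e-6

    def test_zero_shear(self):
        th = pr.jeffery_theta(2, 1, 0.0, np.linspace(0, 10, 11))
        assert np.all(th == 0)

    def test_fit_recovers_aspect_ratio(self):
        t = np.linspace(0, 40, 300)
        th = pr.jeffery_theta(3.0, 1.0, 0.3, t - 4.0)
        r, t0, rms = pr.fit_jeffery(t, th, 0.3)
        assert r == pytest.approx(3.0, rel=1e-4)
        assert rms < 1e-8


class TestClassifyMode:
    def test_synthetic_2_3(self):
        g = mg.gv_mesh_preset()
        L = 12.0
        ref = g.reference_vertices
        zc = ref[:, 2] - ref[:, 2].mean()
        phi = np.arctan2(ref[:, 1], ref[:, 0])
        ur = np.sin(2 * np.pi / L * zc + np.pi) * np.cos(3 * phi)
        mode = (np.column_stack([np.cos(phi), np.sin(phi),
                                 np.zeros(len(phi))]) * ur[:, None]).ravel()
        rec = pr.classify_mode(mode, g, L)
        assert (rec.m, rec.n) == (2, 3)
        assert rec.branch == "radial"
        assert not rec.ambiguous


class TestQuasiharmonic:
    def test_gaussian_sampler_recovery(self, emb_mesh):
        """Frames drawn from exp(-E/kT) for a known quadratic E recover the
        Hessian frequencies (parameter-recovery oracle)."""
        mat = el.emb_material(E2d=500.0, nu=1 / 3, h=0.25)
        H = el.elastic_hessian(emb_mesh, mat)
        om_ref, _ = el.normal_modes(H, np.ones(emb_mesh.n_vertices))
        vals, vecs = np.linalg.eigh(H)
        keep = vals > 1e-6 * vals.max()
        rng = np.random.default_rng(0)
        coeffs = rng.standard_normal((12000, int(keep.sum())))
        coeffs /= np.sqrt(vals[keep])
        traj = emb_mesh.vertices[None] + (coeffs @ vecs[:, keep].T).reshape(
            12000, -1, 3)
        om_q, _, usable = pr.quasiharmonic_modes(
            traj, np.ones(emb_mesh.n_vertices), emb_mesh.vertices)
        err = np.abs(om_q[:30] - om_ref[:30]) / om_ref[:30]
        assert err.max() < 0.05

    def test_kabsch_matches_mdanalysis(self, rng):
        """Own SVD alignment against the MDAnalysis rotation (oracle)."""
        mda = pytest.importorskip("MDAnalysis.analysis.align")
        x = rng.standard_normal((50, 3))
        ang = 0.7
        R0 = np.array([[math.cos(ang), -math.sin(ang), 0],
                       [math.sin(ang), math.cos(ang), 0], [0, 0, 1.0]])
        y = x @ R0.T + 0.01 * rng.standard_normal((50, 3))
        R_own = pr.kabsch_rotation(y - y.mean(0), x - x.mean(0))
        R_ref, rmsd = mda.rotation_matrix(y - y.mean(0), x - x.mean(0))
        assert np.allclose(R_own, R_ref, atol=1e-8)

    def test_short_trajectory_warns(self, emb_mesh, rng):
        traj = emb_mesh.vertices[None] + 0.01 * rng.standard_normal(
            (20, emb_mesh.n_vertices, 3))
        with pytest.warns(UserWarning):
            pr.quasiharmonic_modes(traj, np.ones(emb_mesh.n_vertices),
                                   emb_mesh.vertices)


class TestStretch:
    def test_unloaded_shell_keeps_diameter(self, emb_mesh, emb_material):
        rec = pr.stretch_emb(emb_mesh, emb_material, [0.0])
        assert rec.D[0] == pytest.approx(4.0, rel=5e-3)

    def test_pole_patch_selection(self):
        mesh = mg.icosphere(4, 2.0)
        top, bot = pr.pole_patches(mesh, 64)
        assert len(top) == len(bot) == 64
        assert mesh.reference_vertices[top, 2].min() > 1.5
        assert mesh.reference_vertices[bot, 2].max() < -1.5

    def test_gv_zero_force_zero_strain(self, gv_small, gv_small_material):
        mesh, rib = gv_small
        rec = pr.stretch_gv(mesh, gv_small_material, rib, [0.0],
                            L_cyl=4.0, R=1.2)
        assert abs(rec.eps_zz[0]) < 1e-6
        assert abs(rec.eps_phiphi[0]) < 1e-6


class TestTorsion:
    def test_zero_twist_zero_torque(self, gv_small, gv_small_material):
        mesh, rib = gv_small
        tq = pr.torsion_gv(mesh, gv_small_material, rib, 0.0, L_cyl=4.0)
        assert abs(tq) < 1e-6

    def test_antisymmetric_in_twist(self, gv_small, gv_small_material):
        mesh, rib = gv_small
        t1 = pr.torsion_gv(mesh, gv_small_material, rib, 0.05, L_cyl=4.0)
        t2 = pr.torsion_gv(mesh, gv_small_material, rib, -0.05, L_cyl=4.0)
        assert t1 == pytest.approx(-t2, rel=0.02)
        assert t1 != 0


class TestBuckling:
    def test_zero_pressure_keeps_shape(self, emb_mesh, emb_material):
        out, d = pr.dry_buckle(emb_mesh, emb_material, None, 0.0, seed=1)
        assert abs(d["dV_over_V0"]) < 1e-3

    def test_classical_pressure_formula(self):
        mat = el.MembraneMaterial(Ka=1.0, mu=1.0, kappa=1.0)
        # Ka = mu = 1 -> E2d = 2; direct evaluation of 4 sqrt(kappa Y)/R^2
        assert pr.critical_pressure_sphere(mat, 1.0) == \
            pytest.approx(4 * math.sqrt(2.0))
        assert pr.critical_pressure_sphere(mat, 2.0) == \
            pytest.approx(math.sqrt(2.0))

    def test_knockdown_range_guard(self, emb_material):
        with pytest.raises(ValueError):
            pr.critical_pressure_sphere(emb_material, 1.0, knockdown=1.5)

    def test_lobe_count_synthetic(self):
        mesh = mg.icosphere(3, 2.0)
        ref = mesh.reference_vertices
        phi = np.arctan2(ref[:, 1], ref[:, 0])
        r = np.linalg.norm(ref[:, :2], axis=1)
        verts = ref.copy()
        bump = 0.3 * np.cos(3 * phi) * (r / 2.0)
        verts[:, 0] += bump * np.cos(phi)
        verts[:, 1] += bump * np.sin(phi)
        assert pr.lobe_count(verts, ref) == 3


class TestShearRegime:
    def test_tumbling_vs_aligned_classification(self):
        t = np.linspace(0, 10, 200)
        tumb = pr.classify_shear_regime(t, 0.5 * t)  # sweeps > pi
        assert tumb.regime == "tumbling"
        alig = pr.classify_shear_regime(t, 0.4 + 0.02 * np.sin(t))
        assert alig.regime == "aligned"
        assert alig.mean_theta == pytest.approx(0.4, abs=0.02)

    def test_headless_unwrap(self):
        raw = np.array([0.0, 1.0, -1.5, -0.5, 1.2, -1.8])
        un = pr.unwrap_headless(raw)
        assert np.all(np.abs(np.diff(un)) <= math.pi / 2 + 1e-12)
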