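import numpy as np
import pytest

from vesimeso import dpd


class TestPairForce:
    def test_zero_beyond_cutoff(self, rng):
        p = dpd.DPDPairParams(a=50.0, gamma=4.5)
        for _ in range(20):
            ri = rng.standard_normal(3)
            d = rng.standard_normal(3)
            rj = ri + 1.001 * d / np.linalg.norm(d)
            f = dpd.pair_force(ri, rj, rng.standard_normal(3),
                               rng.standard_normal(3), p, rng.standard_normal())
            assert np.all(f == 0)

    def test_antisymmetry(self, rng):
        p = dpd.DPDPairParams(a=80.0, gamma=4.5, k=0.25)
        for _ in range(200):
            ri, rj = rng.standard_normal((2, 3)) * 0.4
            vi, vj = rng.standard_normal((2, 3))
            th = rng.standard_normal()
            fij = dpd.pair_force(ri, rj, vi, vj, p, th)
            fji = dpd.pair_force(rj, ri, vj, vi, p, th)
            assert np.allclose(fij, -fji, atol=1e-12)

    def test_conservative_magnitude(self):
        p = dpd.DPDPairParams(a=100.0, gamma=0.0)
        f = dpd.pair_force([0, 0, 0], [0.5, 0, 0], [0, 0, 0], [0, 0, 0],
                           p, 0.0)
        assert np.allclose(f, [-50.0, 0, 0])

    def test_freezing_guard(self):
        with pytest.raises(ValueError):
            dpd.DPDPairParams(a=300.0, gamma=1.0)


class TestFluctuationDissipation:
    def test_sigma_formula(self):
        assert dpd.fd_sigma(0.0) == 0.0
        assert dpd.fd_sigma(2.0, 1.0) == pytest.approx(2.0)
        assert dpd.fd_sigma(4.5, 2.0) == pytest.approx(np.sqrt(18.0))

    def test_table1_presets(self):
        emb = dpd.table1_pairs("emb")
        assert emb[(dpd.WATER, dpd.WATER)].a == 100.0
        assert emb[(dpd.WATER, dpd.WATER)].gamma == 3.5
        assert emb[(dpd.GAS, dpd.GAS)].gamma == 11.0
        assert emb[(dpd.OBJECT, dpd.WATER)].a == 40.0
        gv = dpd.table1_pairs("gv")
        assert gv[(dpd.WATER, dpd.WATER)].gamma == 18.0
        assert gv[(dpd.WATER, dpd.WATER)].k == 0.125
        assert gv[(dpd.OBJECT, dpd.GAS)].gamma == 0.5

    def test_pair_noise_symmetric_and_gaussian(self):
        from vesimeso.dpd import _pair_gaussian
        vals = []
        for step in range(200):
            for i in range(10):
                for j in range(i + 1, 10):
                    a = _pair_gaussian(7, step, i, j)
                    b = _pair_gaussian(7, step, j, i)
                    assert a == b
                    vals.append(a)
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 3.0 / np.sqrt(len(vals))
        assert abs(vals.std() - 1.0) < 0.02


class TestIntegration:
    def test_ballistic_with_zero_forces(self):
        sys_ = dpd.DPDSystem(np.array([[1.0, 1.0, 1.0]]),
                             np.array([[0.5, 0.2, -0.1]]),
                             np.zeros(1, np.int8), np.array([4.0, 4.0, 4.0]))
        dpd.step(sys_, 0.1, lambda s: np.zeros((1, 3)))
        assert np.allclose(sys_.positions[0], [1.05, 1.02, 0.99])

    def test_momentum_conservation(self):
        pairs = {(0, 0): dpd.DPDPairParams(a=100.0, gamma=3.5, k=0.25)}
        sim = dpd.equilibrate_fluid((5, 5, 5), 3.0, pairs, seed=11,
                                    n_steps=0)
        p0 = sim.system.momentum()
        sim.step(1000)
        drift = np.abs(sim.system.momentum() - p0).max()
        assert drift < 1e-9

    def test_thermostat(self):
        pairs = {(0, 0): dpd.DPDPairParams(a=100.0, gamma=3.5, k=0.25)}
        sim = dpd.equilibrate_fluid((6, 6, 6), 3.0, pairs, seed=5, dt=0.005,
                                    n_steps=600)
        Ts = []
        for _ in range(40):
            sim.step(10)
            Ts.append(sim.system.kinetic_temperature())
        assert 0.98 < np.mean(Ts) < 1.02

    def test_instability_guard(self):
        sys_ = dpd.DPDSystem(np.array([[1.0, 1.0, 1.0]]),
                             np.array([[100.0, 0.0, 0.0]]),
                             np.zeros(1, np.int8), np.array([4.0, 4.0, 4.0]))
        with pytest.raises(RuntimeError):
            dpd.step(sys_, 1.0, lambda s: np.zeros((1, 3)))


class TestPressure:
    def test_ideal_gas_limit(self):
        pairs = {(0, 0): dpd.DPDPairParams(a=0.0, gamma=3.5, k=0.25)}
        sim = dpd.equilibrate_fluid((6, 6, 6), 3.0, pairs, seed=2,
                                    n_steps=400)
        p = dpd.virial_pressure(sim.system, sim.field)
        assert p == pytest.approx(3.0, rel=0.03)

    def test_pressure_monotone_in_a(self):
        ps = [dpd.measure_eos_pressure(a, box=(5, 5, 5), seed=3, dt=0.01,
                                       n_equil=300, n_sample=700)
              for a in (25.0, 75.0, 150.0)]
        assert ps[0] < ps[1] < ps[2]

    def test_eos_fit_exact_synthetic(self):
        alpha_true = 0.1234
        pts = [(a, rho, rho + alpha_true * a * rho ** 2)
               for a, rho in ((25, 3.0), (50, 3.0), (100, 4.0))]
        alpha, resid = dpd.fit_eos_alpha(pts)
        assert alpha == pytest.approx(alpha_true, rel=1e-12)
        assert resid < 1e-12

    def test_eos_fit_guards(self):
        with pytest.raises(ValueError):
            dpd.fit_eos_alpha([(25, 3, 25.0), (50, 3, 48.0)])
        with pytest.raises(ValueError):
            dpd.fit_eos_alpha([(0, 3, 3.0), (0, 3, 3.0), (0, 3, 3.0)])


class TestViscosity:
    def test_monotone_in_gamma(self):
        etas = []
        for g in (2.0, 8.0):
            pairs = {(0, 0): dpd.DPDPairParams(a=0.0, gamma=g, k=0.25)}
            eta, r2 = dpd.measure_viscosity(
                pairs, box=(6, 5, 5), body_force=0.05, seed=4, dt=0.01,
                n_equil=800, n_sample=3000)
            etas.append(eta)
        assert etas[1] > etas[0] > 0
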