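"""FDE machinery: kinetic functionals and their functional derivatives,
non-additive bifunctional closure, gridded electrostatics, embedding-potential
assembly, and freeze-and-thaw relaxation."""

import numpy as np
import pytest
from scipy.special import erf

from polembed.fde import (C_TF, EmbeddingPotential, GridDensity, GridError,
                          build_embedding_potential,
                          coulomb_potential_of_density, density_change,
                          freeze_and_thaw, kinetic_energy_density,
                          nonadditive_bifunctional)
from polembed.fixtures import GaussianModelDensity, model_density_on_grid
from polembed.system import AtomSite, GeometryError


def _random_grid(n=50, seed=1, with_gradients=True):
    rng = np.random.default_rng(seed)
    return GridDensity(points=rng.normal(size=(n, 3)),
                       weights=rng.random(n) + 0.1,
                       values=rng.random(n) + 0.05,
                       gradients=rng.normal(0, 0.3, (n, 3))
                       if with_gradients else None)


class TestKineticFunctionals:
    def test_thomas_fermi_uniform_density(self):
        n = 40
        rho = GridDensity(points=np.random.default_rng(0).normal(size=(n, 3)),
                          weights=np.ones(n), values=np.ones(n))
        e, v = kinetic_energy_density(rho, "thomas_fermi")
        assert e == pytest.approx(C_TF * n)
        assert np.allclose(v, (5.0 / 3.0) * C_TF)

    def test_pw91k_reduces_to_tf_at_zero_gradient(self):
        rho = _random_grid(seed=3)
        flat = rho.replace_values(rho.values, np.zeros((50, 3)))
        e_gga, v_gga = kinetic_energy_density(flat, "pw91k")
        e_tf, v_tf = kinetic_energy_density(flat, "thomas_fermi")
        assert e_gga == pytest.approx(e_tf, abs=1e-14)
        assert np.array_equal(v_gga, v_tf)

    @pytest.mark.parametrize("functional", ["thomas_fermi", "pw91k"])
    def test_potential_is_fd_functional_derivative(self, functional):
        rho = _random_grid(seed=5)
        _, v = kinetic_energy_density(rho, functional)
        h = 1e-6
        for g in range(0, 50, 6):
            bump = np.zeros(50)
            bump[g] = h
            ep = kinetic_energy_density(rho.replace_values(rho.values + bump),
                                        functional)[0]
            em = kinetic_energy_density(rho.replace_values(rho.values - bump),
                                        functional)[0]
            fd = (ep - em) / (2 * h) / rho.weights[g]
            assert v[g] == pytest.approx(fd, abs=1e-6)

    def test_tf_energy_nonnegative(self):
        rho = _random_grid(seed=8, with_gradients=False)
        e, _ = kinetic_energy_density(rho, "thomas_fermi")
        assert e >= 0

    def test_pw91k_requires_gradients(self):
        rho = _random_grid(with_gradients=False)
        with pytest.raises(GridError):
            kinetic_energy_density(rho, "pw91k")


class TestNonadditive:
    def test_vanishes_when_frozen_density_is_zero(self):
        rho = _random_grid(seed=2)
        zero = rho.replace_values(np.zeros(50), np.zeros((50, 3)))
        for fun in ("thomas_fermi", "pw91k"):
            e, v = nonadditive_bifunctional(rho, zero, fun)
            assert abs(e) < 1e-12
            assert np.max(np.abs(v)) < 1e-12

    def test_energy_symmetric_under_subsystem_swap(self):
        a = _random_grid(seed=4)
        b = a.replace_values(np.random.default_rng(9).random(50) + 0.02,
                             np.random.default_rng(10).normal(0, 0.2, (50, 3)))
        for fun in ("thomas_fermi", "pw91k"):
            e_ab = nonadditive_bifunctional(a, b, fun)[0]
            e_ba = nonadditive_bifunctional(b, a, fun)[0]
            assert e_ab == pytest.approx(e_ba, abs=1e-12)

    def test_matches_direct_quadrature_of_definition(self):
        # two overlapping Gaussians, Thomas-Fermi: compare against the
        # defining difference evaluated by direct quadrature
        m1 = GaussianModelDensity([[0, 0, 0]], [2.0], [1.0])
        m2 = GaussianModelDensity([[0.8, 0, 0]], [3.0], [1.3])
        g1 = model_density_on_grid(m1, n_per_dim=10, scale=2.0,
                                   center=(0.4, 0, 0))
        g2 = g1.replace_values(m2.density(g1.points), m2.gradient(g1.points))
        e, _ = nonadditive_bifunctional(g1, g2, "thomas_fermi")
        w, r1, r2 = g1.weights, g1.values, g2.values
        direct = C_TF * float(w @ ((r1 + r2) ** (5 / 3)
                                   - r1 ** (5 / 3) - r2 ** (5 / 3)))
        assert e == pytest.approx(direct, abs=1e-10)

    def test_mismatched_grids_rejected(self):
        a = _random_grid(seed=1)
        b = _random_grid(seed=2)
        b.points[0, 0] += 0.5
        with pytest.raises(GridError):
            nonadditive_bifunctional(a, b, "thomas_fermi")


class TestCoulombPotential:
    def test_unit_gaussian_matches_analytic_potential(self):
        m = GaussianModelDensity([[0, 0, 0]], [1.0], [0.7])
        g = model_density_on_grid(m, n_per_dim=16)
        pt = np.array([[10 * 0.7, 0, 0]])
        v = coulomb_potential_of_density(g, pt, include_nuclei=False)
        analytic = erf(7.0 / (np.sqrt(2) * 0.7)) / 7.0
        assert v[0] == pytest.approx(analytic, abs=1e-6)

    def test_zero_density_no_nuclei_gives_zero(self):
        g = _random_grid(seed=6)
        g = g.replace_values(np.zeros(50))
        v = coulomb_potential_of_density(g, np.array([[3.0, 2.0, 1.0]]))
        assert v[0] == 0.0

    def test_far_field_monopole_reproduces_total_charge(self):
        m = GaussianModelDensity([[0, 0, 0], [0.5, 0.3, 0]], [3.0, 2.0],
                                 [0.8, 0.6])
        nuc = [AtomSite("O", np.zeros(3), 8)]
        g = model_density_on_grid(m, n_per_dim=14, nuclei=nuc)
        r = 300.0
        v = coulomb_potential_of_density(g, np.array([[r, 0, 0]]))
        total = g.electron_count() + 8.0
        assert abs(v[0] * r - total) / total < 1e-3

    def test_electron_sign_flips_density_term(self):
        m = GaussianModelDensity([[0, 0, 0]], [2.0], [0.8])
        g = model_density_on_grid(m, n_per_dim=10)
        pt = np.array([[5.0, 0, 0]])
        vp = coulomb_potential_of_density(g, pt, include_nuclei=False)
        vm = coulomb_potential_of_density(g, pt, include_nuclei=False,
                                          electron_sign=True)
        assert vm[0] == pytest.approx(-vp[0], abs=1e-15)

    def test_point_on_grid_node_rejected_when_undamped(self):
        g = _random_grid(seed=7)
        with pytest.raises(GeometryError):
            coulomb_potential_of_density(g, g.points[3][None, :])


class TestEmbeddingPotential:
    def test_empty_environment_gives_zero_potential(self):
        rho = _random_grid(seed=11)
        v = build_embedding_potential(rho, None, None)
        assert np.array_equal(v.values, np.zeros(50))
        zero_env = rho.replace_values(np.zeros(50), np.zeros((50, 3)))
        v2 = build_embedding_potential(rho, zero_env, None)
        assert np.max(np.abs(v2.values)) < 1e-12

    def test_mm_only_is_passthrough(self):
        rho = _random_grid(seed=12)
        mm = np.random.default_rng(0).normal(size=50)
        v = build_embedding_potential(rho, None, mm)
        assert np.array_equal(v.values, mm)

    def test_assembly_is_sum_of_parts(self):
        m1 = GaussianModelDensity([[0, 0, 0]], [2.0], [0.9])
        m2 = GaussianModelDensity([[3.0, 0, 0]], [2.0], [0.9])
        g1 = model_density_on_grid(m1, n_per_dim=8)
        g2 = GridDensity(g1.points, g1.weights, m2.density(g1.points),
                         m2.gradient(g1.points),
                         nuclei=[AtomSite("O", np.array([3.0, 0, 0]), 8)])
        mm = 0.01 * np.ones(len(g1.points))
        full = build_embedding_potential(g1, g2, mm, "thomas_fermi",
                                         damping=0.5)
        v_elst = coulomb_potential_of_density(g2, g1.points, damping=0.5,
                                              electron_sign=True)
        _, v_t = nonadditive_bifunctional(g1, g2, "thomas_fermi")
        assert np.max(np.abs(full.values - (v_elst + v_t + mm))) < 1e-12


class TestFreezeAndThaw:
    @staticmethod
    def _linear_callback(base_values, kappa):
        # linear-response stand-in anchored to a fixed base density:
        # relax(rho, v_emb) = rho_base + kappa * v_emb
        def relax(rho, v_emb):
            return rho.replace_values(
                np.maximum(base_values + kappa * v_emb.values, 0.0))
        return relax

    @staticmethod
    def _offset_pair(separation, n_per_dim=8):
        # two Gaussian densities on one shared supersystem grid, lifted by a
        # constant background so the TF potential stays Lipschitz-mild
        m1 = GaussianModelDensity([[0, 0, 0]], [2.0], [1.0])
        m2 = GaussianModelDensity([[separation, 0, 0]], [2.0], [1.0])
        g1 = model_density_on_grid(m1, n_per_dim=n_per_dim,
                                   scale=max(1.5, separation / 2.5),
                                   center=(separation / 2, 0, 0))
        base1 = m1.density(g1.points) + 0.05
        base2 = m2.density(g1.points) + 0.05
        ga = g1.replace_values(base1, m1.gradient(g1.points))
        gb = g1.replace_values(base2, m2.gradient(g1.points))
        return ga, gb, base1, base2

    def test_noninteracting_limit_one_cycle(self):
        ga, gb, base1, base2 = self._offset_pair(50.0)
        # zero response: densities never move, change is 0 in the first cycle
        res = freeze_and_thaw(ga, gb, self._linear_callback(ga.values, 0.0),
                              max_cycles=5, tol=1e-6,
                              functional="thomas_fermi", damping=0.5)
        assert res.converged and res.cycles_used == 1
        # the relaxed callback never altered normalization
        assert res.rho_i.electron_count() == pytest.approx(
            ga.electron_count(), abs=1e-12)

    def test_symmetric_subsystems_converge_to_symmetric_densities(self):
        m = GaussianModelDensity([[0, 0, 0]], [2.0], [1.0])
        g = model_density_on_grid(m, n_per_dim=8)
        base = g.values + 0.05
        ga = g.replace_values(base.copy(), g.gradients.copy())
        gb = g.replace_values(base.copy(), g.gradients.copy())
        res = freeze_and_thaw(ga, gb, self._linear_callback(base, 2e-4),
                              max_cycles=50, tol=1e-12,
                              functional="thomas_fermi", damping=0.5)
        assert res.converged
        assert np.max(np.abs(res.rho_i.values - res.rho_ii.values)) < 1e-10

    def test_fixed_point_self_consistency(self):
        # at convergence one more relax step must leave the density unchanged
        ga, gb, base1, base2 = self._offset_pair(1.5)
        cb1 = self._linear_callback(base1, 2e-4)
        res = freeze_and_thaw(ga, gb, cb1, max_cycles=80, tol=1e-12,
                              functional="thomas_fermi", damping=0.5)
        assert res.converged
        from polembed.fde import build_embedding_potential as bep
        v = bep(res.rho_i, res.rho_ii, None, "thomas_fermi", damping=0.5)
        again = cb1(res.rho_i, v)
        assert density_change(res.rho_i, again) < 1e-10

    def test_nonconvergence_is_flagged(self):
        ga, gb, _, _ = self._offset_pair(1.5, n_per_dim=6)

        def runaway(rho, v_emb):
            return rho.replace_values(rho.values * 1.5)

        res = freeze_and_thaw(ga, gb, runaway, max_cycles=3, tol=1e-14,
                              functional="thomas_fermi", damping=0.5)
        assert not res.converged
        assert res.cycles_used == 3
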