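"""Finite-element solver: contact, assembly consistency, equilibria."""

import numpy as np
import pytest

import asamesh as am
from asamesh.geometry import PillarLayout
from asamesh.mechanics import AS_PRINTED
from asamesh.solver import ActivationSchedule, ContractionProblem, contact_gap


@pytest.fixture(scope="module")
def small_free_domain():
    lay = PillarLayout(centers=np.zeros((0, 2)), radius=200.0, height=200.0,
                       substrate_bounds=(0.0, 0.0, 400.0, 400.0))
    return lay, am.triangulate_domain(lay, 50.0)


class TestContactGap:
    def test_point_on_circle(self):
        assert contact_gap(np.array([200.0, 0.0]), np.array([0.0, 0.0]), 200.0) \
            == pytest.approx(0.0)

    def test_point_outside(self):
        g = contact_gap(np.array([300.0, 0.0]), np.array([0.0, 0.0]), 200.0)
        assert g == pytest.approx(100.0)

    def test_penalty_force_matches_energy_gradient(self, material):
        # contact residual = d(penalty energy)/dx at penetrating points
        lay = am.build_square_layout(2, 2, 400.0, 200.0)
        dom = am.triangulate_domain(lay, 60.0)
        prob = ContractionProblem(dom, lay, material)
        rng = np.random.default_rng(2)
        u = rng.normal(0.0, 0.05, (dom.n_nodes, 2))  # pushes some nodes in
        h = 1e-7
        R, _ = prob.assemble(u, 0.0, need_tangent=False)
        for _ in range(6):
            i = rng.integers(dom.n_nodes)
            j = rng.integers(2)
            up, um = u.copy(), u.copy()
            up[i, j] += h
            um[i, j] -= h
            fd = (prob.total_energy(up, 0.0) - prob.total_energy(um, 0.0)) / (2 * h)
            assert R[i, j] == pytest.approx(fd, rel=2e-4, abs=1e-7)


class TestAssembly:
    def test_rest_state_zero_residual(self, small_free_domain, material):
        lay, dom = small_free_domain
        prob = ContractionProblem(dom, lay, material)
        R, K = prob.assemble(np.zeros((dom.n_nodes, 2)), 0.0)
        assert np.abs(R).max() < 1e-12

    def test_as_printed_rest_equilibrium_at_any_activation(self, small_free_domain):
        # the printed active term is minimised at J = 1: no residual at rest
        lay, dom = small_free_domain
        mat = am.MaterialParams(active_mode=AS_PRINTED)
        prob = ContractionProblem(dom, lay, mat)
        R, _ = prob.assemble(np.zeros((dom.n_nodes, 2)), 0.8)
        assert np.abs(R).max() < 1e-12 * mat.mu * dom.element_size

    def test_tangent_matches_residual_directional_derivative(
            self, small_free_domain, material):
        lay, dom = small_free_domain
        prob = ContractionProblem(dom, lay, material)
        rng = np.random.default_rng(4)
        u = rng.normal(0.0, 1.0, (dom.n_nodes, 2))
        R, K = prob.assemble(u, 0.6)
        dv = rng.normal(0.0, 1.0, (dom.n_nodes, 2))
        s = 1e-6
        Rp, _ = prob.assemble(u + s * dv, 0.6, need_tangent=False)
        Rm, _ = prob.assemble(u - s * dv, 0.6, need_tangent=False)
        fd = (Rp - Rm).ravel() / (2 * s)
        Kdv = K @ dv.ravel()
        assert np.abs(fd - Kdv).max() / np.abs(fd).max() < 1e-4

    def test_tangent_symmetric(self, small_free_domain, material):
        lay, dom = small_free_domain
        prob = ContractionProblem(dom, lay, material)
        rng = np.random.default_rng(6)
        u = rng.normal(0.0, 0.5, (dom.n_nodes, 2))
        _, K = prob.assemble(u, 0.4)
        asym = abs(K - K.T).max()
        assert asym < 1e-8 * abs(K).max()


class TestSolveContraction:
    def test_as_printed_null_solution(self, material):
        lay = am.build_square_layout(2, 2, 400.0, 200.0)
        dom = am.triangulate_domain(lay, 66.0)
        mat = am.MaterialParams(active_mode=AS_PRINTED)
        states = am.solve_contraction(dom, lay, mat,
                                      ActivationSchedule.uniform(1.0, 5))
        size = max(lay.bounds_size())
        for st in states:
            assert st.max_displacement < 1e-8 * size

    def test_free_square_matches_homogeneous_oracle(self, free_square_solved,
                                                    material):
        dom, states = free_square_solved
        st = states[-1]
        J2 = st.fields["F11"] * st.fields["F22"] \
            - st.fields["F12"] * st.fields["F21"]
        stretch = np.sqrt(J2)
        lbar = am.homogeneous_contraction_oracle(material, 1.0)
        assert abs(stretch.mean() - lbar) / lbar < 0.005
        assert stretch.std() < 0.01 * lbar

    def test_determinism_bitwise(self, material):
        lay = am.build_square_layout(2, 2, 400.0, 200.0)
        dom = am.triangulate_domain(lay, 66.0)
        s1 = am.solve_contraction(dom, lay, material,
                                  ActivationSchedule.uniform(0.6, 4))
        s2 = am.solve_contraction(dom, lay, material,
                                  ActivationSchedule.uniform(0.6, 4))
        for a, b in zip(s1, s2):
            assert np.array_equal(a.u, b.u)

    def test_energy_monotone_along_newton_iterates(self, material):
        lay = am.build_square_layout(2, 2, 400.0, 200.0)
        dom = am.triangulate_domain(lay, 66.0)
        states = am.solve_contraction(dom, lay, material,
                                      ActivationSchedule.uniform(0.8, 4))
        for st in states:
            trace = np.array(st.energy_trace)
            if len(trace) > 1:
                assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]))

    def test_moduli_scale_invariance_of_displacement(self, material):
        # scaling (E, beta) together leaves u unchanged, scales stress
        lay = am.build_square_layout(2, 2, 400.0, 200.0)
        dom = am.triangulate_domain(lay, 66.0)
        sched = ActivationSchedule.uniform(1.0, 5)
        base = am.solve_contraction(dom, lay, material, schedule=sched)
        scaled = am.solve_contraction(dom, lay, material.scaled(7.0),
                                      schedule=sched)
        assert np.allclose(base[-1].u, scaled[-1].u, atol=1e-7)
        assert np.allclose(scaled[-1].fields["sigma11"],
                           7.0 * base[-1].fields["sigma11"], rtol=1e-6)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            ActivationSchedule(np.array([0.1, 0.5]))
        with pytest.raises(ValueError):
            ActivationSchedule(np.array([0.0, 0.5, 0.4]))
        with pytest.raises(ValueError):
            ActivationSchedule(np.array([0.0, 1.2]))


class TestBenchmark4x4:
    """Properties of the shared 4x4 solve (session fixture)."""

    def test_contact_at_zero_activation_matches_mesh_tagging(self, benchmark_4x4):
        layout, domain, states = benchmark_4x4
        st0 = states[0]
        for k, nodes in domain.pillar_nodes.items():
            assert set(nodes).issubset(set(st0.contact_nodes[k]))

    def test_displacement_field_d4_symmetric(self, benchmark_4x4):
        layout, domain, states = benchmark_4x4
        st = states[-1]
        c = 1300.0  # domain center
        X = domain.nodes

        def match(Xm):
            # node correspondence under an isometry of the reference domain
            from scipy.spatial import cKDTree
            d, idx = cKDTree(X).query(Xm)
            assert d.max() < 1e-6
            return idx

        unorm = np.abs(st.u).max()
        # mirror about the vertical axis
        idx = match(np.column_stack([2 * c - X[:, 0], X[:, 1]]))
        um = st.u[idx] * np.array([-1.0, 1.0])
        assert np.abs(um - st.u).max() < 1e-6 * unorm
        # 90-degree rotation: u(QX) = Q u(X)
        idx = match(np.column_stack([c - (X[:, 1] - c), c + (X[:, 0] - c)]))
        Qu = np.column_stack([-st.u[:, 1], st.u[:, 0]])
        assert np.abs(st.u[idx] - Qu).max() < 1e-6 * unorm

    def test_penetration_within_tolerance(self, benchmark_4x4, material):
        layout, domain, states = benchmark_4x4
        prob = ContractionProblem(domain, layout, material)
        assert prob.max_penetration(states[-1].u) <= 1e-3 * layout.radius

    def test_inner_contact_counts_non_increasing(self, benchmark_4x4):
        layout, domain, states = benchmark_4x4
        _, inner = am.classify_pillars(layout)
        for k in inner:
            counts = [len(s.contact_nodes[k]) for s in states]
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_probe_displacements_mesh_converged(self, benchmark_4x4, material):
        # halving the element size moves probe displacements by < 2%
        layout, domain, states = benchmark_4x4
        coarse_dom = am.triangulate_domain(layout, 100.0)
        coarse = am.solve_contraction(coarse_dom, layout, material)
        probes = np.array([[1300.0, 2500.0], [700.0, 700.0], [2500.0, 2500.0]])
        from scipy.spatial import cKDTree

        def probe_u(dom, st):
            _, idx = cKDTree(dom.nodes).query(probes)
            return st.u[idx]

        u_c = probe_u(coarse_dom, coarse[-1])
        u_f = probe_u(domain, states[-1])
        scale = np.abs(u_f).max()
        assert np.abs(u_c - u_f).max() < 0.02 * scale
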