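"""Unit and property tests for the force kernels and element types."""

import numpy as np
import pytest

from stromasim import model_core as mc
from stromasim import units

from conftest import numerical_gradient


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------


class TestExtension:
    def test_zero_at_rest_length(self):
        fa, fb = mc.extensional_forces(1.0, 1.0, 5.0, np.array([1.0, 0, 0]))
        assert np.all(fa == 0) and np.all(fb == 0)

    def test_hand_calculated_magnitude(self):
        # 0.277 N/m stretched by +0.01 um: 0.277 N/m * 1e-8 m = 2.77e-9 N
        # = 2770 pN, computed independently by unit conversion
        ks = 0.277 * units.N_PER_M
        expected_pn = 0.277 * 0.01e-6 * 1e12
        fa, fb = mc.extensional_forces(1.01, 1.0, ks, np.array([1.0, 0, 0]))
        assert np.linalg.norm(fa) == pytest.approx(expected_pn, rel=1e-12)
        assert np.linalg.norm(fa) == pytest.approx(2770.0, rel=1e-12)

    @pytest.mark.parametrize("r", [0.2, 1.0, 3.7])
    def test_newtons_third_law(self, r):
        axis = np.array([0.6, 0.8, 0.0])
        fa, fb = mc.extensional_forces(r, 1.0, 2.0, axis)
        np.testing.assert_allclose(fa + fb, 0.0, atol=1e-15)

    def test_zero_length_warns_and_zero_force(self):
        with pytest.warns(mc.DegenerateGeometryWarning):
            fa, fb = mc.extensional_forces(0.0, 1.0, 2.0, np.array([1.0, 0, 0]))
        assert np.all(fa == 0) and np.all(fb == 0)

    def test_matches_negative_gradient(self, rng):
        ks, r0 = 3.1, 0.8
        for _ in range(20):
            pos = rng.normal(size=(2, 3))

            def potential(p):
                return 0.5 * ks * (np.linalg.norm(p[1] - p[0]) - r0) ** 2

            out = np.zeros((2, 3))
            mc.spring_forces(pos, [[0, 1]], np.array([ks]), np.array([r0]), out)
            grad = numerical_gradient(potential, pos)
            np.testing.assert_allclose(out, -grad, rtol=1e-4, atol=1e-9)


# ---------------------------------------------------------------------------
# bending
# ---------------------------------------------------------------------------


def _bend_angle(p):
    u = p[1] - p[0]
    v = p[2] - p[1]
    return np.arctan2(np.linalg.norm(np.cross(u, v)), u @ v)


class TestBending:
    def test_zero_at_rest_angle(self, rng):
        p = rng.normal(size=(3, 3))
        theta = _bend_angle(p)
        forces = mc.bending_forces(p[0], p[1], p[2], kb=2.0, theta0=theta)
        for f in forces:
            np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_restoring_torque_small_perturbation(self):
        # straight chain along x, middle node nudged by delta in y
        kb, delta = 0.5, 1e-3
        p = np.array([[0.0, 0, 0], [1.0, delta, 0], [2.0, 0, 0]])

        def potential(q):
            return 0.5 * kb * _bend_angle(q) ** 2

        forces = mc.bending_forces(p[0], p[1], p[2], kb=kb, theta0=0.0)
        grad = numerical_gradient(potential, p)
        np.testing.assert_allclose(np.vstack(forces), -grad, rtol=1e-4, atol=1e-10)
        # the bend angle for this geometry is ~2*delta; restoring force on
        # the middle node ~ kb * theta * dtheta/dy ~ kb * (2 delta) * 2
        assert forces[1][1] < 0
        assert abs(forces[1][1]) == pytest.approx(4.0 * kb * delta, rel=1e-2)

    def test_force_set_sums_to_zero(self, rng):
        for _ in range(20):
            p = rng.normal(size=(3, 3))
            forces = mc.bending_forces(p[0], p[1], p[2], kb=1.3, theta0=0.4)
            np.testing.assert_allclose(np.sum(forces, axis=0), 0.0, atol=1e-9)

    def test_torque_sums_to_zero(self, rng):
        for _ in range(10):
            p = rng.normal(size=(3, 3))
            forces = mc.bending_forces(p[0], p[1], p[2], kb=1.3, theta0=0.4)
            torque = sum(np.cross(pi, fi) for pi, fi in zip(p, forces))
            np.testing.assert_allclose(torque, 0.0, atol=1e-9)

    def test_degenerate_geometry_warns(self):
        p = np.zeros((3, 3))
        with pytest.warns(mc.DegenerateGeometryWarning):
            forces = mc.bending_forces(p[0], p[1], p[2], kb=1.0, theta0=0.0)
        assert np.all(np.vstack(forces) == 0)

    def test_matches_negative_gradient_random(self, rng):
        kb, theta0 = 1.7, 0.3
        for _ in range(30):
            p = rng.normal(size=(3, 3))

            def potential(q):
                return 0.5 * kb * (_bend_angle(q) - theta0) ** 2

            forces = np.vstack(mc.bending_forces(p[0], p[1], p[2], kb, theta0))
            grad = numerical_gradient(potential, p)
            scale = max(np.abs(grad).max(), 1e-9)
            np.testing.assert_allclose(forces / scale, -grad / scale, atol=1e-4)


def _dihedral_angle(p):
    n1 = np.cross(p[1] - p[0], p[2] - p[0])
    n2 = np.cross(p[2] - p[3], p[1] - p[3])
    return np.arctan2(np.linalg.norm(np.cross(n1, n2)), n1 @ n2)


class TestDihedral:
    def test_flat_quad_zero_force(self):
        p = np.array([[0.0, 0, 0], [1, 1, 0], [1, -1, 0], [2, 0, 0]])
        forces = mc.dihedral_forces(*p, kb=1.0, theta0=0.0)
        np.testing.assert_allclose(np.vstack(forces), 0.0, atol=1e-12)

    def test_matches_negative_gradient_random(self, rng):
        kb, theta0 = 0.9, 0.2
        for _ in range(30):
            p = rng.normal(size=(4, 3))

            def potential(q):
                return 0.5 * kb * (_dihedral_angle(q) - theta0) ** 2

            forces = np.vstack(mc.dihedral_forces(*p, kb=kb, theta0=theta0))
            grad = numerical_gradient(potential, p)
            scale = max(np.abs(grad).max(), 1e-9)
            np.testing.assert_allclose(forces / scale, -grad / scale, atol=1e-4)

    def test_momentum_conserved(self, rng):
        for _ in range(20):
            p = rng.normal(size=(4, 3))
            forces = mc.dihedral_forces(*p, kb=0.7, theta0=0.1)
            np.testing.assert_allclose(np.sum(forces, axis=0), 0.0, atol=1e-9)


# ---------------------------------------------------------------------------
# drag and thermal forces
# ---------------------------------------------------------------------------


class TestDrag:
    def test_collapses_to_stokes_like_form(self):
        mu = 0.86
        rc = 0.5
        assert mc.drag_coefficient(rc, rc, mu) == pytest.approx(3 * np.pi * mu * rc)

    def test_fiber_segment_value(self):
        # rc = 0.060 um, r0 = 1.0 um: zeta = 3 pi mu rc (3 + 2 r0/rc) / 5
        mu = 0.86
        expected = 3 * np.pi * mu * 0.060 * (3 + 2 * (1.0 / 0.060)) / 5
        assert mc.drag_coefficient(0.060, 1.0, mu) == pytest.approx(expected)

    def test_linear_in_viscosity(self):
        assert mc.drag_coefficient(0.06, 1.0, 2.0) == pytest.approx(
            2.0 * mc.drag_coefficient(0.06, 1.0, 1.0)
        )

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, 0, 1), (1, 1, 0), (-1, 1, 1)])
    def test_rejects_non_positive(self, bad):
        with pytest.raises(ValueError):
            mc.drag_coefficient(*bad)


class TestStochasticForce:
    def test_zero_mean(self, rng):
        consts = mc.PhysicalConstants(dt=1e-3)
        draws = mc.stochastic_forces(
            np.full(10**5, 2.0), consts.kBT, consts.dt, rng
        )
        sigma = np.sqrt(2 * consts.kBT * 2.0 / consts.dt)
        se = sigma / np.sqrt(10**5)
        assert np.all(np.abs(draws.mean(axis=0)) < 4 * se)

    def test_variance_matches_fluctuation_dissipation(self, rng):
        zeta, kBT, dt = 3.0, 4.11e-3, 1e-3
        draws = mc.stochastic_forces(np.full(10**5, zeta), kBT, dt, rng)
        expected = 2 * kBT * zeta / dt
        assert draws.var() == pytest.approx(expected, rel=0.03)

    def test_free_node_msd_einstein(self, rng):
        # free node under thermal force only: MSD(t) = 6 D t, D = kBT/zeta
        zeta, kBT, dt = 1.5, 4.11e-3, 1e-3
        n_nodes, n_steps = 1000, 100
        pos = np.zeros((n_nodes, 3))
        for _ in range(n_steps):
            f = mc.stochastic_forces(np.full(n_nodes, zeta), kBT, dt, rng)
            pos += f / zeta * dt
        msd = (pos**2).sum(axis=1).mean()
        expected = 6 * (kBT / zeta) * n_steps * dt
        assert msd == pytest.approx(expected, rel=0.1)


# ---------------------------------------------------------------------------
# minimum distance
# ---------------------------------------------------------------------------


class TestMinDistance:
    def test_parallel_unit_segments(self):
        a = mc.Segment(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]))
        b = mc.Segment(np.array([0.0, 0.5, 0]), np.array([1.0, 0.5, 0]))
        d, pa, pb = mc.min_distance(a, b)
        assert d == pytest.approx(0.5)

    def test_segment_through_triangle_interior(self):
        seg = mc.Segment(np.array([0.3, 0.3, -1.0]), np.array([0.3, 0.3, 1.0]))
        tri = mc.Triangle(
            np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([0.0, 1, 0])
        )
        d, _, _ = mc.min_distance(seg, tri)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(5, 3))
            seg = mc.Segment(pts[0], pts[1])
            tri = mc.Triangle(pts[2], pts[3], pts[4])
            d1, _, _ = mc.min_distance(seg, tri)
            d2, _, _ = mc.min_distance(tri, seg)
            assert d1 == pytest.approx(d2)

    def test_against_dense_sampling_oracle(self, rng):
        ts = np.linspace(0.0, 1.0, 100)
        for _ in range(100):
            pts = rng.normal(size=(4, 3))
            d, pa, pb = mc.min_distance(mc.Segment(pts[0], pts[1]), mc.Segment(pts[2], pts[3]))
            sampled_a = pts[0] + ts[:, None] * (pts[1] - pts[0])
            sampled_b = pts[2] + ts[:, None] * (pts[3] - pts[2])
            oracle = np.linalg.norm(
                sampled_a[:, None, :] - sampled_b[None, :, :], axis=2
            ).min()
            assert d <= oracle + 1e-6
            assert np.linalg.norm(pa - pb) == pytest.approx(d, abs=1e-9)

    def test_segment_triangle_against_sampling(self, rng):
        ts = np.linspace(0.0, 1.0, 40)
        u, v = np.meshgrid(ts, ts)
        keep = (u + v) <= 1.0
        for _ in range(50):
            pts = rng.normal(size=(5, 3))
            seg = mc.Segment(pts[0], pts[1])
            tri = mc.Triangle(pts[2], pts[3], pts[4])
            d, _, _ = mc.min_distance(seg, tri)
            tri_pts = pts[2] + u[keep][:, None] * (pts[3] - pts[2]) + v[keep][
                :, None
            ] * (pts[4] - pts[2])
            seg_pts = pts[0] + ts[:, None] * (pts[1] - pts[0])
            oracle = np.linalg.norm(
                seg_pts[:, None, :] - tri_pts[None, :, :], axis=2
            ).min()
            assert d <= oracle + 1e-6


# ---------------------------------------------------------------------------
# repulsion
# ---------------------------------------------------------------------------


class TestRepulsion:
    rule = mc.RepulsionRule(strength=4.0, threshold=0.8)

    def test_zero_outside_threshold(self):
        a = mc.Segment(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]))
        b = mc.Segment(np.array([0.0, 1.2, 0]), np.array([1.0, 1.2, 0]))
        forces = mc.repulsive_forces(a, b, self.rule)
        assert all(np.all(f == 0) for _, f in forces)

    def test_continuous_at_cutoff(self):
        a = mc.Segment(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]))
        eps = 1e-6
        b = mc.Segment(
            np.array([0.0, self.rule.threshold - eps, 0]),
            np.array([1.0, self.rule.threshold - eps, 0]),
        )
        forces = mc.repulsive_forces(a, b, self.rule)
        total = np.abs(np.vstack([f for _, f in forces])).max()
        assert total < self.rule.strength * 2 * eps

    def test_parallel_segments_at_half_threshold(self):
        gap = self.rule.threshold / 2
        a = mc.Segment(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]))
        b = mc.Segment(np.array([0.0, gap, 0]), np.array([1.0, gap, 0]))
        forces = dict(mc.repulsive_forces(a, b, self.rule))
        net_a = forces["a0"] + forces["a1"]
        expected = self.rule.strength * (self.rule.threshold - gap)
        assert np.linalg.norm(net_a) == pytest.approx(expected, rel=1e-9)
        # brute-force sampled minimum distance confirms the gap
        ts = np.linspace(0, 1, 400)
        sa = a.p + ts[:, None] * (a.q - a.p)
        sb = b.p + ts[:, None] * (b.q - b.p)
        oracle = np.linalg.norm(sa[:, None] - sb[None, :], axis=2).min()
        assert oracle == pytest.approx(gap, abs=1e-9)

    def test_momentum_conserved(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(4, 3)) * 0.4
            forces = mc.repulsive_forces(
                mc.Segment(pts[0], pts[1]), mc.Segment(pts[2], pts[3]), self.rule
            )
            total = np.sum([f for _, f in forces], axis=0)
            np.testing.assert_allclose(total, 0.0, atol=1e-9)

    def test_torque_conserved_segment_triangle(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(5, 3)) * 0.4
            seg = mc.Segment(pts[0], pts[1])
            tri = mc.Triangle(pts[2], pts[3], pts[4])
            labelled = mc.repulsive_forces(seg, tri, self.rule)
            positions = {"a0": pts[0], "a1": pts[1], "t0": pts[2], "t1": pts[3], "t2": pts[4]}
            net = np.sum([f for _, f in labelled], axis=0)
            torque = np.sum(
                [np.cross(positions[k], f) for k, f in labelled], axis=0
            )
            np.testing.assert_allclose(net, 0.0, atol=1e-9)
            np.testing.assert_allclose(torque, 0.0, atol=1e-9)

    def test_matches_negative_gradient(self, rng):
        tested = 0
        while tested < 20:
            pts = rng.normal(size=(4, 3)) * 0.4
            d, _, _ = mc.min_distance(mc.Segment(pts[0], pts[1]), mc.Segment(pts[2], pts[3]))
            if not 0.05 < d < 0.95 * self.rule.threshold:
                continue
            tested += 1

            def potential(p):
                dd, _, _ = mc.min_distance(
                    mc.Segment(p[0], p[1]), mc.Segment(p[2], p[3])
                )
                return 0.5 * self.rule.strength * max(0.0, self.rule.threshold - dd) ** 2

            out = np.zeros((4, 3))
            mc.segment_segment_repulsion(pts, [[0, 1]], [[2, 3]], self.rule, out)
            grad = numerical_gradient(potential, pts)
            scale = max(np.abs(grad).max(), 1e-9)
            np.testing.assert_allclose(out / scale, -grad / scale, atol=1e-3)

    def test_exact_overlap_deterministic_fallback(self):
        a = mc.Segment(np.array([0.0, 0, 0]), np.array([1.0, 0, 0]))
        forces1 = mc.repulsive_forces(a, a, self.rule)
        forces2 = mc.repulsive_forces(a, a, self.rule)
        for (_, f1), (_, f2) in zip(forces1, forces2):
            np.testing.assert_array_equal(f1, f2)


# ---------------------------------------------------------------------------
# relaxation / diffusion invariants
# ---------------------------------------------------------------------------


class TestDynamicsInvariants:
    def test_stretched_segment_relaxes_exponentially(self):
        # two-body relaxation: separation decays to r0 with tau = zeta_red/ks
        ks, r0 = 5.0, 1.0
        za, zb = 2.0, 3.0
        dt = 1e-4
        pos = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        drags = np.array([za, zb])
        seps = []
        n_steps = 4000
        for _ in range(n_steps):
            out = np.zeros((2, 3))
            mc.spring_forces(pos, [[0, 1]], np.array([ks]), np.array([r0]), out)
            pos += out / drags[:, None] * dt
            seps.append(pos[1, 0] - pos[0, 0])
        t = np.arange(1, n_steps + 1) * dt
        tau = 1.0 / (ks * (1 / za + 1 / zb))
        expected = r0 + 0.5 * np.exp(-t / tau)
        np.testing.assert_allclose(seps, expected, rtol=0.01)

    def test_free_diffusion_coefficient(self, rng):
        # deterministic forces off: D = kBT / zeta within 5%
        zeta, kBT, dt = 2.0, 4.11e-3, 1e-3
        n_nodes, n_steps = 2000, 50
        pos = np.zeros((n_nodes, 3))
        for _ in range(n_steps):
            pos += mc.stochastic_forces(np.full(n_nodes, zeta), kBT, dt, rng) / zeta * dt
        msd = (pos**2).sum(axis=1).mean()
        D = msd / (6 * n_steps * dt)
        assert D == pytest.approx(kBT / zeta, rel=0.05)


class TestTypes:
    def test_node_rejects_nonpositive_drag(self):
        with pytest.raises(ValueError):
            mc.Node(0, np.zeros(3), drag=0.0)

    def test_segment_rejects_self_loop(self):
        with pytest.raises(ValueError):
            mc.FiberSegment(3, 3)

    def test_fiber_requires_shared_nodes(self):
        with pytest.raises(ValueError):
            mc.Fiber([mc.FiberSegment(0, 1), mc.FiberSegment(2, 3)])

    def test_crosslinker_distinct_nodes(self):
        with pytest.raises(ValueError):
            mc.CrossLinker(hinge=1, end_a=1, end_b=2)

    def test_repulsion_rule_invariants(self):
        with pytest.raises(ValueError):
            mc.RepulsionRule(strength=-1.0, threshold=0.1)
        with pytest.raises(ValueError):
            mc.RepulsionRule(strength=1.0, threshold=0.0)
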