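"""Engine tests: stepping, determinism, protocol, neighbor search, IO."""

import numpy as np
import pytest

from stromasim import boundary as bnd
from stromasim import engine
from stromasim import io as sio
from stromasim import model_core as mc
from stromasim.cell_dynamics import BondKinetics
from stromasim.config import ConfigError, SimConfig, load_config, reduced_preset


def tiny_config(**overrides) -> SimConfig:
    cfg = reduced_preset(d_c_um=6.0, seed=4, extents=(14.0, 14.0, 8.0))
    cfg.fiber.count = 25
    cfg.fiber.segments_per_fiber = 2
    cfg.protocol.assembly_duration_s = 0.5
    cfg.protocol.interaction_duration_s = 0.5
    cfg.protocol.snapshot_stride_s = 0.25
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def make_state(cfg=None):
    cfg = cfg or tiny_config()
    return engine.build_state(cfg)


def empty_state() -> engine.SimState:
    """A system with no nodes at all."""
    return engine.SimState(
        time=0.0,
        pos=np.zeros((0, 3)),
        drag=np.zeros(0),
        kind=np.zeros(0, np.int8),
        anchored_to=np.zeros(0, np.int64) - 1,
        force=np.zeros((0, 3)),
        spring_pairs=np.zeros((0, 2), np.int64),
        spring_k=np.zeros(0),
        spring_r0=np.zeros(0),
        spring_class=np.zeros(0, np.int8),
        bend_triples=np.zeros((0, 3), np.int64),
        bend_k=np.zeros(0),
        bend_theta0=np.zeros(0),
        dihedrals=np.zeros((0, 4), np.int64),
        dihedral_k=np.zeros(0),
        dihedral_theta0=np.zeros(0),
        fiber_segments=np.zeros((0, 2), np.int64),
        triangles=np.zeros((0, 3), np.int64),
        membrane_vertex_ids=np.zeros(0, np.int64),
        fiber_endpoint_ids=np.zeros(0, np.int64),
        cells=[],
        box=bnd.DomainBox(extents=np.array([10.0, 10, 10])),
        kinetics=BondKinetics(k_off0=0.1, x_bell=1e-4),
        rule_ff=mc.RepulsionRule(1.0, 0.06),
        rule_fm=mc.RepulsionRule(1.0, 0.13),
        dt=0.01,
        kBT=4.11e-3,
        thermal=False,
        cells_active=False,
        rng=np.random.default_rng(0),
    )


def two_node_state(stretch=0.5, ks=5.0, r0=1.0, drags=(2.0, 3.0), dt=1e-3):
    state = empty_state()
    state.pos = np.array([[2.0, 5.0, 5.0], [2.0 + r0 + stretch, 5.0, 5.0]])
    state.drag = np.array(drags, dtype=float)
    state.kind = np.zeros(2, np.int8)
    state.anchored_to = np.full(2, -1, np.int64)
    state.force = np.zeros((2, 3))
    state.spring_pairs = np.array([[0, 1]])
    state.spring_k = np.array([ks])
    state.spring_r0 = np.array([r0])
    state.spring_class = np.array([engine.SPRING_FIBER], np.int8)
    state.fiber_segments = np.array([[0, 1]])
    state.fiber_endpoint_ids = np.arange(2)
    state.fiber_spring_force = np.zeros((2, 3))
    state.dt = dt
    return state


class TestStep:
    def test_empty_system_only_time_advances(self):
        state = empty_state()
        engine.step(state)
        assert state.time == pytest.approx(0.01)

    def test_prestretched_segment_matches_discrete_closed_form(self):
        # Euler recurrence: (sep_n - r0) = (sep_0 - r0) * (1 - ks*(1/za+1/zb)*dt)^n
        ks, r0, za, zb, dt, stretch = 5.0, 1.0, 2.0, 3.0, 1e-3, 0.5
        state = two_node_state(stretch, ks, r0, (za, zb), dt)
        factor = 1.0 - ks * (1 / za + 1 / zb) * dt
        for n in range(1, 200):
            engine.step(state)
            sep = state.pos[1, 0] - state.pos[0, 0]
            expected = r0 + stretch * factor**n
            assert sep == pytest.approx(expected, rel=1e-6)

    def test_anchored_nodes_do_not_move(self):
        state = two_node_state()
        state.anchored_to[0] = 0
        state.box.youngs_modulus = np.inf
        p0 = state.pos[0].copy()
        for _ in range(10):
            engine.step(state)
        np.testing.assert_array_equal(state.pos[0], p0)

    def test_determinism_bit_identical(self):
        cfg = tiny_config()
        s1 = engine.build_state(cfg)
        s2 = engine.build_state(cfg)
        for _ in range(20):
            engine.step(s1)
            engine.step(s2)
        np.testing.assert_array_equal(s1.pos, s2.pos)

    def test_over_displacement_aborts(self):
        state = two_node_state(stretch=0.5, ks=1e9, dt=1.0)
        with pytest.raises(engine.SimulationUnstable):
            engine.step(state)

    def test_global_internal_force_balance(self):
        """Summed internal forces vanish; only walls/thermal are external."""
        cfg = tiny_config()
        state = engine.build_state(cfg)
        state.thermal = False
        state.cells_active = True
        for _ in range(10):
            engine.step(state)
            breakdown = engine.compute_forces(state)
            total = breakdown["internal"].sum(axis=0)
            np.testing.assert_allclose(total, 0.0, atol=1e-9)


class TestNeighborSearch:
    def test_accelerated_matches_brute_force(self):
        cfg = tiny_config()
        state_fast = engine.build_state(cfg)
        state_brute = engine.build_state(cfg)
        state_brute.brute_force_neighbors = True
        for s in (state_fast, state_brute):
            s.thermal = False
        for _ in range(5):
            engine.step(state_fast)
            engine.step(state_brute)
        np.testing.assert_array_equal(state_fast.pos, state_brute.pos)
        f1 = engine.compute_forces(state_fast)["internal"]
        f2 = engine.compute_forces(state_brute)["internal"]
        np.testing.assert_array_equal(f1, f2)


class TestProtocol:
    def test_zero_durations_initial_state_only(self):
        cfg = tiny_config()
        cfg.protocol.assembly_duration_s = 0.0
        cfg.protocol.interaction_duration_s = 0.0
        state, traj = engine.run_protocol(cfg)
        assert len(traj.snapshots) == 1
        assert traj.times == [0.0]

    def test_snapshot_times_strictly_increasing(self):
        cfg = tiny_config()
        state, traj = engine.run_protocol(cfg)
        assert all(b > a for a, b in zip(traj.times, traj.times[1:]))

    def test_permanent_links_created_after_relaxation(self):
        cfg = tiny_config()
        cfg.coupling_radius_um = 2.0  # generous so some links form
        state, _ = engine.run_protocol(cfg)
        assert np.any(state.spring_class == engine.SPRING_PERMANENT)

    def test_cells_inert_in_phase_one(self):
        cfg = tiny_config()
        cfg.protocol.interaction_duration_s = 0.0
        state, _ = engine.run_protocol(cfg)
        assert all(not c.links for c in state.cells)

    def test_timestep_auto_rule(self):
        cfg = tiny_config()
        cfg.constants.dt_s = None
        state = engine.build_state(cfg)
        mu = cfg.constants.viscosity_pa_s
        zf = mc.drag_coefficient(cfg.fiber.diameter_um, cfg.fiber.rest_length_um, mu)
        zx = mc.drag_coefficient(
            cfg.fiber.diameter_um, cfg.crosslinker.rest_length_um, mu
        )
        zm = mc.drag_coefficient(
            cfg.membrane.thickness_um, cfg.membrane.edge_length_um, mu
        )
        expected = 0.1 * min(
            zf / cfg.fiber_ks, zx / cfg.crosslinker_ks, zm / cfg.membrane_ks
        )
        assert state.dt == pytest.approx(expected)


class TestIO:
    def test_state_roundtrip_bit_exact(self, tmp_path):
        cfg = tiny_config()
        state = engine.build_state(cfg)
        for _ in range(3):
            engine.step(state)
        sio.save_state(state, tmp_path / "snap")
        loaded = sio.load_state(tmp_path / "snap")
        np.testing.assert_array_equal(state.pos, loaded.pos)
        np.testing.assert_array_equal(state.spring_r0, loaded.spring_r0)
        assert state.time == loaded.time
        assert state.rng.bit_generator.state == loaded.rng.bit_generator.state
        # stepping both produces identical successors
        engine.step(state)
        engine.step(loaded)
        np.testing.assert_array_equal(state.pos, loaded.pos)

    def test_vtk_counts_match_topology(self, tmp_path):
        cfg = tiny_config()
        state, traj = engine.run_protocol(cfg)
        sio.write_trajectory(traj, tmp_path)
        text = (tmp_path / "snapshot_00000.vtk").read_text()
        n_tri = len(traj.triangles)
        assert f"POLYGONS {n_tri} {4 * n_tri}" in text
        n_seg = len(traj.fiber_segments)
        assert f"LINES {n_seg} {3 * n_seg}" in text

    def test_trajectory_roundtrip(self, tmp_path):
        cfg = tiny_config()
        _, traj = engine.run_protocol(cfg)
        sio.write_trajectory(traj, tmp_path)
        loaded = sio.read_trajectory(tmp_path)
        np.testing.assert_allclose(loaded.times, traj.times)
        np.testing.assert_array_equal(
            loaded.snapshots[-1].pos, traj.snapshots[-1].pos
        )

    def test_scalar_log_columns(self):
        cfg = tiny_config()
        _, traj = engine.run_protocol(cfg)
        frame = traj.scalar_frame()
        assert {"time", "separation", "n_links"} <= set(frame.columns)


class TestConfig:
    def test_missing_kinetic_parameter_is_named(self):
        raw = SimConfig(
            cells={"k_off0_per_s": 0.1, "x_bell_um": 1e-4}
        ).model_dump(mode="json")
        del raw["cells"]["k_off0_per_s"]
        with pytest.raises(ConfigError, match="k_off0_per_s"):
            load_config(raw)

    def test_schema_version_mismatch(self):
        raw = SimConfig(cells={"k_off0_per_s": 0.1, "x_bell_um": 1e-4}).model_dump(
            mode="json"
        )
        raw["schema_version"] = 99
        with pytest.raises(ConfigError):
            load_config(raw)

    def test_yaml_roundtrip(self, tmp_path):
        from stromasim.config import dump_config

        cfg = tiny_config()
        dump_config(cfg, tmp_path / "run.yaml")
        loaded = load_config(tmp_path / "run.yaml")
        assert loaded == cfg

    def test_rejects_bad_extents(self):
        raw = SimConfig(cells={"k_off0_per_s": 0.1, "x_bell_um": 1e-4}).model_dump(
            mode="json"
        )
        raw["domain"]["extents_um"] = [0.0, 10.0, 10.0]
        with pytest.raises(ConfigError, match="extents"):
            load_config(raw)


class TestRigidBoxLimit:
    def test_infinite_modulus_matches_fixed_box(self):
        cfg = tiny_config()
        cfg.constants.thermal = False
        rigid = cfg.model_copy(deep=True)
        rigid.domain.youngs_modulus_pa = float("inf")
        s1, _ = engine.run_protocol(cfg.model_copy(deep=True))
        s2, _ = engine.run_protocol(rigid)
        # with thermal off and modest forces the elastic box barely moves,
        # but the rigid box must stay exactly at rest
        np.testing.assert_array_equal(s2.box.offsets, 0.0)
        assert s1.pos.shape == s2.pos.shape
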