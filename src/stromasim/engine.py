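"""Overdamped Euler integrator, two-phase protocol, and state containers.

The full system is held in flat node arrays; mechanical topology is a set
of index arrays (extension springs, three-node bends, dihedrals, fiber
segments for repulsion, membrane triangles).  Per step:

1. zero force accumulators,
2. deterministic forces (springs, bends, dihedrals, repulsion, cell
   contraction, walls),
3. stochastic forces,
4. Euler displacement ``(F + F_T) / zeta * dt`` for every non-anchored node,
5. kinetic link events (unbind then bind),
6. elastic boundary update (anchored nodes ride their face).

Execution is single threaded; given a seed the trajectory is bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import assembly as asm
from . import boundary as bnd
from . import model_core as mc
from .cell_dynamics import (
    BondKinetics,
    Cell,
    apply_contractile_forces,
    bind_links,
    candidate_fiber_points,
    unbind_links,
)
from .config import SimConfig

__all__ = [
    "SimState",
    "Snapshot",
    "Trajectory",
    "SimulationUnstable",
    "build_state",
    "compute_forces",
    "step",
    "run_protocol",
    "choose_timestep",
]

SPRING_FIBER = 0
SPRING_XLINK = 1
SPRING_MEMBRANE = 2
SPRING_PERMANENT = 3


class SimulationUnstable(RuntimeError):
    """Raised on NaN positions or per-step over-displacement."""


@dataclass
class _NeighborCache:
    """Conservative candidate pair lists, rebuilt on large displacements."""

    ref_pos: np.ndarray | None = None
    margin: float = 1.0
    ff_idx: np.ndarray | None = None  # (n, 2) fiber segment index pairs
    fm_idx: tuple[np.ndarray, np.ndarray] | None = None  # seg idx, tri idx


@dataclass
class SimState:
    """Complete mutable system snapshot in internal pN-um-s units."""

    time: float
    pos: np.ndarray
    drag: np.ndarray
    kind: np.ndarray
    anchored_to: np.ndarray  # face index or -1
    force: np.ndarray
    spring_pairs: np.ndarray
    spring_k: np.ndarray
    spring_r0: np.ndarray
    spring_class: np.ndarray
    bend_triples: np.ndarray
    bend_k: np.ndarray
    bend_theta0: np.ndarray
    dihedrals: np.ndarray
    dihedral_k: np.ndarray
    dihedral_theta0: np.ndarray
    fiber_segments: np.ndarray
    triangles: np.ndarray
    membrane_vertex_ids: np.ndarray
    fiber_endpoint_ids: np.ndarray
    cells: list[Cell]
    box: bnd.DomainBox
    kinetics: BondKinetics
    rule_ff: mc.RepulsionRule
    rule_fm: mc.RepulsionRule
    dt: float
    kBT: float
    thermal: bool
    cells_active: bool
    rng: np.random.Generator
    config: SimConfig | None = None
    fiber_spring_force: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    _nbr: _NeighborCache = field(default_factory=_NeighborCache, repr=False)
    brute_force_neighbors: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.pos)

    @property
    def anchored(self) -> np.ndarray:
        return self.anchored_to >= 0

    def validate(self) -> None:
        if not np.all(np.isfinite(self.pos)):
            raise SimulationUnstable(f"non-finite positions at t={self.time}")


@dataclass
class Snapshot:
    """Light per-stride record: positions plus scalar bookkeeping."""

    time: float
    pos: np.ndarray
    cell_links: list[dict[int, float]]
    face_offsets: np.ndarray


@dataclass
class Trajectory:
    """Snapshot series plus static topology and a per-step scalar log."""

    times: list[float] = field(default_factory=list)
    snapshots: list[Snapshot] = field(default_factory=list)
    fiber_segments: np.ndarray | None = None
    triangles: np.ndarray | None = None
    membrane_vertex_ids: np.ndarray | None = None
    fiber_endpoint_ids: np.ndarray | None = None
    cell_node_ids: np.ndarray | None = None
    membrane_z0: float = 0.0
    scalars: list[dict] = field(default_factory=list)

    def add(self, state: SimState) -> None:
        if self.times and state.time <= self.times[-1]:
            raise ValueError("snapshot times must be strictly increasing")
        self.times.append(state.time)
        self.snapshots.append(
            Snapshot(
                time=state.time,
                pos=state.pos.copy(),
                cell_links=[dict(c.links) for c in state.cells],
                face_offsets=state.box.offsets.copy(),
            )
        )

    def scalar_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scalars)

    def cell_positions(self, i: int) -> np.ndarray:
        """(n_snapshots, 3) positions of cell ``i``."""
        idx = self.cell_node_ids[i]
        return np.array([s.pos[idx] for s in self.snapshots])


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def choose_timestep(config: SimConfig, drag_fiber, drag_hinge, drag_membrane) -> float:
    """Stability-bounded timestep: ``dt_safety * min(zeta / k_s)``."""
    if config.constants.dt_s is not None:
        return config.constants.dt_s
    candidates = [drag_fiber / config.fiber_ks]
    if config.crosslinker_ks > 0:
        candidates.append(drag_hinge / config.crosslinker_ks)
    if config.membrane_ks > 0:
        candidates.append(drag_membrane / config.membrane_ks)
    return config.constants.dt_safety * min(candidates)


def build_state(config: SimConfig, rng: np.random.Generator | None = None) -> SimState:
    """Construct the initial (unrelaxed) system from a validated config."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu = config.constants.viscosity_pa_s
    ext = np.asarray(config.domain.extents_um, dtype=float)

    mesh = asm.build_membrane(
        ext[:2],
        config.membrane.z_um,
        config.membrane.edge_length_um,
        ks=config.membrane_ks,
        kb=config.membrane_kb,
        thickness=config.membrane.thickness_um,
    )
    params = asm.AssemblyParams(
        n_fibers=config.fiber.count,
        segments_per_fiber=config.fiber.segments_per_fiber,
        n_crosslinkers=config.crosslinker.max_count,
        crosslink_rest_length=config.crosslinker.rest_length_um,
        crosslink_max_distance=config.crosslinker.max_distance_um,
        membrane_z=config.membrane.z_um,
        membrane_edge_length=config.membrane.edge_length_um,
        coupling_radius=config.coupling_radius_um,
        assembly_duration=config.protocol.assembly_duration_s,
        fiber_rest_length=config.fiber.rest_length_um,
        fiber_diameter=config.fiber.diameter_um,
        seed=config.seed,
    )
    fib_pos, fibers, crosslinkers = asm.assemble_matrix(params, ext, rng)
    n_hinges = len(crosslinkers)
    n_fib_nodes = len(fib_pos) - n_hinges

    n_cells = 2 if config.cells.enabled else 0
    if n_cells:
        cell_z = (
            config.cells.z_um
            if config.cells.z_um is not None
            else config.membrane.z_um / 2.0
        )
        cell_pos = asm.place_cells(
            config.cells.d_c_um, ext, cell_z, config.cells.radius_um
        )
    else:
        cell_pos = np.zeros((0, 3))

    # node layout: [fiber endpoints | crosslink hinges | membrane | cells]
    mem_offset = len(fib_pos)
    cell_offset = mem_offset + mesh.n_vertices
    pos = np.vstack([fib_pos, mesh.positions, cell_pos])
    n = len(pos)

    kind = np.empty(n, dtype=np.int8)
    kind[:n_fib_nodes] = mc.NodeKind.FIBER_END
    kind[n_fib_nodes:mem_offset] = mc.NodeKind.CROSSLINK_HINGE
    kind[mem_offset:cell_offset] = mc.NodeKind.MEMBRANE_VERTEX
    kind[cell_offset:] = mc.NodeKind.CELL_CENTER

    drag = np.empty(n)
    drag_fiber = mc.drag_coefficient(
        config.fiber.diameter_um, config.fiber.rest_length_um, mu
    )
    drag_hinge = mc.drag_coefficient(
        config.fiber.diameter_um, config.crosslinker.rest_length_um, mu
    )
    drag_mem = mc.drag_coefficient(
        config.membrane.thickness_um, config.membrane.edge_length_um, mu
    )
    drag[:n_fib_nodes] = drag_fiber
    drag[n_fib_nodes:mem_offset] = drag_hinge
    drag[mem_offset:cell_offset] = drag_mem
    cell_template = Cell(
        node=0,
        radius=config.cells.radius_um,
        interaction_distance=config.cells.interaction_distance_um,
        contractile_force=config.cells.force_pn,
        drag=config.cells.drag_pn_s_per_um,
    )
    drag[cell_offset:] = cell_template.stokes_drag(mu)

    # springs
    pair_rows, k_rows, r0_rows, cls_rows = [], [], [], []
    seg_rows = []
    for fiber in fibers:
        for seg in fiber.segments:
            pair_rows.append((seg.node_a, seg.node_b))
            k_rows.append(config.fiber_ks)
            r0_rows.append(seg.rest_length)
            cls_rows.append(SPRING_FIBER)
            seg_rows.append((seg.node_a, seg.node_b))
    for xl in crosslinkers:
        for end in (xl.end_a, xl.end_b):
            pair_rows.append((end, xl.hinge))
            k_rows.append(config.crosslinker_ks)
            r0_rows.append(config.crosslinker.rest_length_um)
            cls_rows.append(SPRING_XLINK)
    mem_edge_rest = asm.membrane_edge_rest_lengths(mesh)
    for (u, v), rest in zip(mesh.edges, mem_edge_rest):
        pair_rows.append((mem_offset + u, mem_offset + v))
        k_rows.append(config.membrane_ks)
        r0_rows.append(float(rest))
        cls_rows.append(SPRING_MEMBRANE)

    # bends: fiber internal hinges + cross-linker hinges
    bend_rows, bk_rows, bt_rows = [], [], []
    for fiber in fibers:
        ids = fiber.node_ids
        for a, b, c in zip(ids, ids[1:], ids[2:]):
            bend_rows.append((a, b, c))
            bk_rows.append(config.fiber_kb)
            bt_rows.append(0.0)
    for xl in crosslinkers:
        bend_rows.append((xl.end_a, xl.hinge, xl.end_b))
        bk_rows.append(config.crosslinker_kb)
        bt_rows.append(0.0)

    dihedrals = mesh.dihedrals + mem_offset
    triangles = mesh.triangles + mem_offset

    anchored_to = np.full(n, -1, dtype=np.int64)

    cells = [
        Cell(
            node=cell_offset + i,
            radius=config.cells.radius_um,
            interaction_distance=config.cells.interaction_distance_um,
            contractile_force=config.cells.force_pn,
            drag=config.cells.drag_pn_s_per_um,
        )
        for i in range(n_cells)
    ]

    rc_f = config.fiber.diameter_um
    rule_ff = mc.RepulsionRule(config.kr_fiber_fiber, rc_f, "fiber-fiber")
    rule_fm = mc.RepulsionRule(
        config.kr_fiber_membrane,
        rc_f / 2.0 + config.membrane.thickness_um / 2.0,
        "fiber-membrane",
    )

    state = SimState(
        time=0.0,
        pos=pos,
        drag=drag,
        kind=kind,
        anchored_to=anchored_to,
        force=np.zeros((n, 3)),
        spring_pairs=np.array(pair_rows, dtype=np.int64).reshape(-1, 2),
        spring_k=np.array(k_rows),
        spring_r0=np.array(r0_rows),
        spring_class=np.array(cls_rows, dtype=np.int8),
        bend_triples=np.array(bend_rows, dtype=np.int64).reshape(-1, 3),
        bend_k=np.array(bk_rows),
        bend_theta0=np.array(bt_rows),
        dihedrals=dihedrals,
        dihedral_k=np.full(len(dihedrals), config.membrane_kb),
        dihedral_theta0=np.zeros(len(dihedrals)),
        fiber_segments=np.array(seg_rows, dtype=np.int64).reshape(-1, 2),
        triangles=triangles,
        membrane_vertex_ids=np.arange(mem_offset, cell_offset),
        fiber_endpoint_ids=np.arange(n_fib_nodes),
        cells=cells,
        box=bnd.DomainBox(
            extents=ext,
            youngs_modulus=config.domain.youngs_modulus_pa,
            elastic_thickness=config.domain.elastic_thickness_um,
            relax_rate=config.domain.relax_rate_per_s,
            wall_strength=config.domain.wall_strength_pn_per_um,
        ),
        kinetics=BondKinetics(
            k_on=config.cells.k_on_per_s,
            k_off0=config.cells.k_off0_per_s,
            x_bell=config.cells.x_bell_um,
            kBT=config.constants.kBT_pn_um,
        ),
        rule_ff=rule_ff,
        rule_fm=rule_fm,
        dt=choose_timestep(config, drag_fiber, drag_hinge, drag_mem),
        kBT=config.constants.kBT_pn_um,
        thermal=config.constants.thermal,
        cells_active=False,
        rng=rng,
        config=config,
        fiber_spring_force=np.zeros((n, 3)),
    )

    # membrane perimeter vertices are always anchored (to their nearest face)
    mem_boundary = np.zeros(n, dtype=bool)
    mem_boundary[state.membrane_vertex_ids[mesh.boundary_mask]] = True
    state.anchored_to = bnd.anchor_elements(
        state.box, pos, np.zeros(n, dtype=bool), 0.0, force_mask=mem_boundary
    )
    return state


def anchor_matrix_to_boundaries(state: SimState, tolerance: float) -> None:
    """Permanently anchor fiber endpoints near domain faces (post-assembly)."""
    candidates = np.zeros(state.n_nodes, dtype=bool)
    candidates[state.fiber_endpoint_ids] = True
    already = state.anchored
    new = bnd.anchor_elements(state.box, state.pos, candidates, tolerance)
    state.anchored_to = np.where(already, state.anchored_to, new)


def add_permanent_links(state: SimState, links: list[asm.PermanentLink]) -> None:
    """Append membrane-matrix coupling springs (membrane stiffness)."""
    if not links:
        return
    ks = state.config.membrane_ks if state.config else 1.0
    pairs = np.array(
        [(l.membrane_vertex, l.fiber_endpoint) for l in links], dtype=np.int64
    )
    state.spring_pairs = np.vstack([state.spring_pairs, pairs])
    state.spring_k = np.concatenate([state.spring_k, np.full(len(links), ks)])
    state.spring_r0 = np.concatenate(
        [state.spring_r0, np.array([l.rest_length for l in links])]
    )
    state.spring_class = np.concatenate(
        [state.spring_class, np.full(len(links), SPRING_PERMANENT, dtype=np.int8)]
    )


# ---------------------------------------------------------------------------
# neighbor search
# ---------------------------------------------------------------------------


def _segment_geometry(state: SimState):
    segs = state.fiber_segments
    p = state.pos[segs[:, 0]]
    q = state.pos[segs[:, 1]]
    mid = 0.5 * (p + q)
    half = 0.5 * np.linalg.norm(q - p, axis=1)
    return mid, half


def _rebuild_neighbors(state: SimState) -> None:
    cache = state._nbr
    cache.ref_pos = state.pos.copy()
    segs = state.fiber_segments
    if len(segs) == 0:
        cache.ff_idx = np.zeros((0, 2), np.int64)
        cache.fm_idx = (np.zeros(0, np.int64), np.zeros(0, np.int64))
        return
    mid, half = _segment_geometry(state)
    hmax = half.max() if len(half) else 0.0
    radius_ff = state.rule_ff.threshold + 2.0 * hmax + cache.margin
    if state.brute_force_neighbors:
        ii, jj = np.triu_indices(len(segs), k=1)
        pairs = np.column_stack([ii, jj])
    else:
        tree = cKDTree(mid)
        pairs = tree.query_pairs(radius_ff, output_type="ndarray")
    if len(pairs):
        # skip segment pairs sharing a node (bonded neighbours)
        a, b = segs[pairs[:, 0]], segs[pairs[:, 1]]
        share = (
            (a[:, 0] == b[:, 0])
            | (a[:, 0] == b[:, 1])
            | (a[:, 1] == b[:, 0])
            | (a[:, 1] == b[:, 1])
        )
        pairs = pairs[~share]
    pairs = pairs.astype(np.int64).reshape(-1, 2)
    # canonical ordering so force accumulation order (and hence bitwise
    # results) is independent of the search structure
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    cache.ff_idx = pairs

    tris = state.triangles
    if len(tris) == 0:
        cache.fm_idx = (np.zeros(0, np.int64), np.zeros(0, np.int64))
        return
    tv = state.pos[tris]
    cen = tv.mean(axis=1)
    rtri = np.linalg.norm(tv - cen[:, None, :], axis=2).max()
    radius_fm = state.rule_fm.threshold + hmax + rtri + cache.margin
    if state.brute_force_neighbors:
        si = np.repeat(np.arange(len(segs)), len(tris))
        ti = np.tile(np.arange(len(tris)), len(segs))
    else:
        tree_t = cKDTree(cen)
        tree_s = cKDTree(mid)
        pairs_st = tree_s.query_ball_tree(tree_t, radius_fm)
        counts = [len(h) for h in pairs_st]
        si = np.repeat(np.arange(len(segs)), counts)
        ti = (
            np.concatenate([h for h in pairs_st if h]).astype(np.int64)
            if any(counts)
            else np.zeros(0, np.int64)
        )
    si = si.astype(np.int64)
    order = np.lexsort((ti, si))
    cache.fm_idx = (si[order], ti[order])


def _neighbors_current(state: SimState) -> bool:
    cache = state._nbr
    if cache.ref_pos is None or cache.ref_pos.shape != state.pos.shape:
        return False
    moved = np.abs(state.pos - cache.ref_pos).max() if len(state.pos) else 0.0
    return moved <= cache.margin / 8.0


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


def compute_forces(state: SimState, include_thermal: bool = False) -> dict:
    """Accumulate all forces into ``state.force``; returns a breakdown.

    The breakdown holds the summed internal force (springs, bends,
    dihedrals, repulsion, cell action/reaction), the wall force array, and
    the per-node fiber-spring elastic force used by the catch-bond law.
    """
    state.force[:] = 0.0
    n = state.n_nodes
    internal = np.zeros((n, 3))

    tension, _ = mc.spring_forces(
        state.pos, state.spring_pairs, state.spring_k, state.spring_r0, internal
    )
    mc.angle_forces(
        state.pos, state.bend_triples, state.bend_k, state.bend_theta0, internal
    )
    if len(state.dihedrals):
        mc.dihedral_bend_forces(
            state.pos, state.dihedrals, state.dihedral_k, state.dihedral_theta0, internal
        )

    # fiber-spring elastic force per node (Bell-law load)
    state.fiber_spring_force[:] = 0.0
    fib = state.spring_class == SPRING_FIBER
    if np.any(fib):
        mc.spring_forces(
            state.pos,
            state.spring_pairs[fib],
            state.spring_k[fib],
            state.spring_r0[fib],
            state.fiber_spring_force,
        )

    if not _neighbors_current(state):
        _rebuild_neighbors(state)
    segs = state.fiber_segments
    if len(segs):
        mid, half = _segment_geometry(state)
        pairs = state._nbr.ff_idx
        if len(pairs):
            ia, ib = pairs[:, 0], pairs[:, 1]
            # cheap lower bound on segment-segment distance
            lb = (
                np.linalg.norm(mid[ia] - mid[ib], axis=1) - half[ia] - half[ib]
            )
            fine = lb < state.rule_ff.threshold
            if np.any(fine):
                mc.segment_segment_repulsion(
                    state.pos, segs[ia[fine]], segs[ib[fine]], state.rule_ff, internal
                )
        si, ti = state._nbr.fm_idx
        if len(si) and len(state.triangles):
            # axis-aligned bounding-box gap: a cheap distance lower bound
            sv = state.pos[segs[si]]  # (n, 2, 3)
            tv = state.pos[state.triangles[ti]]  # (n, 3, 3)
            gap = np.maximum(
                0.0,
                np.maximum(
                    tv.min(axis=1) - sv.max(axis=1), sv.min(axis=1) - tv.max(axis=1)
                ),
            )
            lb = np.sqrt((gap**2).sum(axis=1))
            fine = lb < state.rule_fm.threshold
            if np.any(fine):
                mc.segment_triangle_repulsion(
                    state.pos,
                    segs[si[fine]],
                    state.triangles[ti[fine]],
                    state.rule_fm,
                    internal,
                )

    reactions = []
    if state.cells_active:
        for cell in state.cells:
            reactions.append(
                apply_contractile_forces(
                    cell, state.pos[cell.node], state.pos, internal
                )
            )

    wall = np.zeros((n, 3))
    free = ~state.anchored
    wall[free] = bnd.wall_repulsion(state.box, state.pos[free])

    state.force += internal + wall
    if include_thermal and state.thermal:
        thermal = mc.stochastic_forces(state.drag, state.kBT, state.dt, state.rng)
        state.force += thermal
    return {
        "internal": internal,
        "wall": wall,
        "spring_tension": tension,
        "cell_reactions": reactions,
    }


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------


def step(state: SimState) -> SimState:
    """Advance the system by one timestep in place; returns the state."""
    compute_forces(state, include_thermal=True)

    # forces transmitted to each face by its anchored elements
    anchor_forces = state.force.copy()

    free = ~state.anchored
    disp = np.zeros_like(state.pos)
    disp[free] = state.force[free] / state.drag[free, None] * state.dt
    max_disp = np.abs(disp).max() if len(disp) else 0.0
    limit = max(state.spring_r0.max() if len(state.spring_r0) else 1.0, 1.0)
    if not np.isfinite(max_disp) or max_disp > limit:
        raise SimulationUnstable(
            f"over-displacement {max_disp:.3g} um in one step at t={state.time:.6g}s "
            f"(limit {limit:.3g} um); reduce dt or stiffness"
        )
    state.pos += disp
    # cells stay inside the box
    for cell in state.cells:
        np.clip(state.pos[cell.node], 0.0, state.box.extents, out=state.pos[cell.node])

    if state.cells_active:
        ep_ids = state.fiber_endpoint_ids
        load = np.linalg.norm(state.fiber_spring_force, axis=1)
        for cell in state.cells:
            if cell.links:
                forces = {int(e): float(load[e]) for e in cell.links}
                unbind_links(cell, forces, state.kinetics, state.dt, state.rng)
            cands = candidate_fiber_points(
                cell, state.pos[cell.node], state.pos[ep_ids], ep_ids
            )
            bind_links(cell, cands, state.kinetics, state.dt, state.time, state.rng)

    prev_offsets = state.box.offsets.copy()
    bnd.boundary_update(state.box, state.anchored_to, anchor_forces, state.dt)
    delta = state.box.offsets - prev_offsets
    if np.any(delta != 0.0):
        anch = state.anchored
        faces = state.anchored_to[anch]
        axes = bnd.FACE_AXES[faces]
        signs = bnd.FACE_SIGNS[faces]
        moved = state.pos[anch]
        moved[np.arange(len(moved)), axes] += signs * delta[faces]
        state.pos[anch] = moved

    state.time += state.dt
    state.validate()
    return state


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------


def run_protocol(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    progress: bool = False,
) -> tuple[SimState, Trajectory]:
    """Assembly/relaxation phase then cell-interaction phase.

    Phase 1 relaxes the freshly assembled system for
    ``assembly_duration_s`` with cells inert; the membrane is then coupled
    to nearby fiber endpoints and matrix endpoints near faces are anchored.
    Phase 2 activates cell kinetics for ``interaction_duration_s``.
    Snapshots are recorded every ``snapshot_stride_s`` of simulated time.
    """
    state = build_state(config, rng)
    traj = Trajectory(
        fiber_segments=state.fiber_segments.copy(),
        triangles=state.triangles.copy(),
        membrane_vertex_ids=state.membrane_vertex_ids.copy(),
        fiber_endpoint_ids=state.fiber_endpoint_ids.copy(),
        cell_node_ids=np.array([c.node for c in state.cells], dtype=np.int64),
        membrane_z0=config.membrane.z_um,
    )
    stride = max(config.protocol.snapshot_stride_s, state.dt)
    traj.add(state)
    _log_scalars(traj, state, phase=1)

    def _run_phase(duration: float, phase: int) -> None:
        if duration <= 0:
            return
        n_steps = int(round(duration / state.dt))
        next_snap = state.time + stride
        for k in range(n_steps):
            step(state)
            if state.time + 1e-12 >= next_snap or k == n_steps - 1:
                traj.add(state)
                _log_scalars(traj, state, phase)
                next_snap = state.time + stride

    _run_phase(config.protocol.assembly_duration_s, phase=1)

    links = asm.couple_membrane_matrix(
        state.pos[state.membrane_vertex_ids],
        state.membrane_vertex_ids,
        state.pos[state.fiber_endpoint_ids],
        state.fiber_endpoint_ids,
        config.coupling_radius_um,
    )
    add_permanent_links(state, links)
    anchor_matrix_to_boundaries(state, config.domain.anchor_tolerance_um)

    state.cells_active = config.cells.enabled
    _run_phase(config.protocol.interaction_duration_s, phase=2)
    return state, traj


def _log_scalars(traj: Trajectory, state: SimState, phase: int) -> None:
    row = {
        "time": state.time,
        "phase": phase,
        "n_links": sum(len(c.links) for c in state.cells),
    }
    for i, cell in enumerate(state.cells):
        p = state.pos[cell.node]
        row[f"cell{i}_x"], row[f"cell{i}_y"], row[f"cell{i}_z"] = p
    if len(state.cells) == 2:
        row["separation"] = float(
            np.linalg.norm(state.pos[state.cells[0].node] - state.pos[state.cells[1].node])
        )
    for f in range(6):
        row[f"face{f}_offset"] = state.box.offsets[f]
    traj.scalars.append(row)
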