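"""Initial system construction.

Builds the flat triangulated membrane, seeds the fiber/cross-linker
matrix, couples membrane vertices to nearby fiber endpoints with
permanent springs, and places the two cells.  Relaxation of the
assembled state is performed by the engine protocol, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .model_core import CrossLinker, Fiber, FiberSegment, MembraneMesh

__all__ = [
    "AssemblyParams",
    "PermanentLink",
    "build_membrane",
    "seed_fibers",
    "place_crosslinkers",
    "assemble_matrix",
    "couple_membrane_matrix",
    "place_cells",
]


@dataclass
class AssemblyParams:
    """Geometric and stochastic parameters of system construction."""

    n_fibers: int = 300
    segments_per_fiber: int = 3
    n_crosslinkers: int | None = None  # None: as many eligible pairs as found
    crosslink_rest_length: float = 0.230
    crosslink_max_distance: float | None = None  # default: 1.5 * rest length
    membrane_z: float = 30.0
    membrane_edge_length: float = 1.0
    coupling_radius: float = 0.380
    assembly_duration: float = 100.0
    fiber_rest_length: float = 1.0
    fiber_diameter: float = 0.060
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_radius < 0:
            raise ValueError("coupling radius must be non-negative")
        if self.assembly_duration < 0:
            raise ValueError("assembly duration must be non-negative")
        if self.crosslink_max_distance is None:
            self.crosslink_max_distance = 1.5 * self.crosslink_rest_length


@dataclass(frozen=True)
class PermanentLink:
    """Permanent spring between a membrane vertex and a fiber endpoint.

    Created once during coupling and never removed; the rest length is the
    separation at creation time.
    """

    membrane_vertex: int
    fiber_endpoint: int
    rest_length: float


def build_membrane(
    footprint: Sequence[float],
    z_mem: float,
    edge_length: float,
    **mesh_kwargs,
) -> MembraneMesh:
    """Flat triangulated membrane covering ``[0, Lx] x [0, Ly]`` at z_mem.

    A regular vertex grid with uniform diagonals: every interior vertex has
    six neighbours, the summed triangle area equals the footprint exactly,
    and all dihedral angles start at zero.  Grid spacing is chosen so the
    lattice lands exactly on the footprint boundary.
    """
    lx, ly = float(footprint[0]), float(footprint[1])
    if edge_length > min(lx, ly):
        raise ValueError("edge length exceeds the domain footprint")
    nx = max(2, int(round(lx / edge_length)) + 1)
    ny = max(2, int(round(ly / edge_length)) + 1)
    xs = np.linspace(0.0, lx, nx)
    ys = np.linspace(0.0, ly, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    positions = np.column_stack(
        [gx.ravel(), gy.ravel(), np.full(nx * ny, float(z_mem))]
    )

    def vid(i, j):
        return i * ny + j

    triangles = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            # two triangles per grid square, consistent CCW orientation
            triangles.append((vid(i, j), vid(i + 1, j), vid(i + 1, j + 1)))
            triangles.append((vid(i, j), vid(i + 1, j + 1), vid(i, j + 1)))
    triangles = np.array(triangles, dtype=np.int64)

    # unique edges + edge -> incident triangle map
    edge_map: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for t_idx, (a, b, c) in enumerate(triangles):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (min(u, v), max(u, v))
            edge_map.setdefault(key, []).append((t_idx, ({a, b, c} - {u, v}).pop()))
    edges = np.array(sorted(edge_map), dtype=np.int64)

    dihedrals = []
    for (u, v), incident in edge_map.items():
        if len(incident) == 2:
            (_, opp1), (_, opp2) = incident
            dihedrals.append((opp1, u, v, opp2))
        elif len(incident) > 2:
            raise ValueError("non-manifold membrane edge")
    dihedrals = np.array(sorted(dihedrals), dtype=np.int64)

    ii, jj = np.divmod(np.arange(nx * ny), ny)
    boundary = (ii == 0) | (ii == nx - 1) | (jj == 0) | (jj == ny - 1)

    return MembraneMesh(
        positions=positions,
        edges=edges,
        triangles=triangles,
        dihedrals=dihedrals,
        boundary_mask=boundary,
        edge_rest_length=edge_length,
        **mesh_kwargs,
    )


def membrane_edge_rest_lengths(mesh: MembraneMesh) -> np.ndarray:
    """As-built edge lengths, used as rest lengths so the flat mesh is
    stress free (grid diagonals are longer than axis edges)."""
    d = mesh.positions[mesh.edges[:, 1]] - mesh.positions[mesh.edges[:, 0]]
    return np.linalg.norm(d, axis=1)


def seed_fibers(
    params: AssemblyParams,
    extents: Sequence[float],
    rng: np.random.Generator,
    max_attempts_per_fiber: int = 200,
) -> tuple[np.ndarray, list[Fiber]]:
    """Straight fiber chains at uniform random positions and orientations.

    Fibers must lie within ``0 <= x,y <= extents`` and ``0 <= z <= z_mem``
    (the matrix occupies the space below the membrane); candidates crossing
    those bounds are rejected and resampled.  Returns the stacked endpoint
    positions and the fiber topologies (node indices are local, 0-based).
    """
    lx, ly = float(extents[0]), float(extents[1])
    z_hi = min(float(extents[2]), params.membrane_z)
    length = params.segments_per_fiber * params.fiber_rest_length
    positions: list[np.ndarray] = []
    fibers: list[Fiber] = []
    placed = 0
    for _ in range(params.n_fibers):
        for _attempt in range(max_attempts_per_fiber):
            origin = rng.uniform([0, 0, 0], [lx, ly, z_hi])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            end = origin + length * direction
            if (
                0 <= end[0] <= lx
                and 0 <= end[1] <= ly
                and 0 <= end[2] <= z_hi
            ):
                break
        else:
            continue
        base = len(positions)
        ts = np.arange(params.segments_per_fiber + 1)[:, None]
        pts = origin + ts * params.fiber_rest_length * direction
        positions.extend(pts)
        segments = [
            FiberSegment(
                base + k,
                base + k + 1,
                rest_length=params.fiber_rest_length,
                diameter=params.fiber_diameter,
            )
            for k in range(params.segments_per_fiber)
        ]
        fibers.append(Fiber(segments=segments))
        placed += 1
    if placed < params.n_fibers:
        warnings.warn(
            f"placed only {placed}/{params.n_fibers} fibers within domain bounds",
            stacklevel=2,
        )
    pos = np.array(positions) if positions else np.zeros((0, 3))
    return pos, fibers


def place_crosslinkers(
    endpoint_positions: np.ndarray,
    endpoint_fiber_ids: np.ndarray,
    params: AssemblyParams,
) -> list[tuple[int, int]]:
    """Greedy closest-pair cross-linking of fiber endpoints.

    Eligible pairs join endpoints of distinct fibers separated by at most
    ``crosslink_max_distance`` (default 1.5x the cross-linker rest length);
    pairs are taken in increasing-distance order, each endpoint used at most
    once, up to ``n_crosslinkers`` if set.  Returns endpoint index pairs.
    """
    if len(endpoint_positions) == 0:
        return []
    tree = cKDTree(endpoint_positions)
    pairs = tree.query_pairs(params.crosslink_max_distance, output_type="ndarray")
    if len(pairs) == 0:
        return []
    fid = np.asarray(endpoint_fiber_ids)
    pairs = pairs[fid[pairs[:, 0]] != fid[pairs[:, 1]]]
    d = np.linalg.norm(
        endpoint_positions[pairs[:, 0]] - endpoint_positions[pairs[:, 1]], axis=1
    )
    order = np.argsort(d, kind="stable")
    used: set[int] = set()
    chosen: list[tuple[int, int]] = []
    limit = params.n_crosslinkers if params.n_crosslinkers is not None else np.inf
    for i, j in pairs[order]:
        if len(chosen) >= limit:
            break
        if i in used or j in used:
            continue
        used.update((int(i), int(j)))
        chosen.append((int(i), int(j)))
    return chosen


def assemble_matrix(
    params: AssemblyParams,
    extents: Sequence[float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[Fiber], list[CrossLinker]]:
    """Seed fibers and cross-link them; hinge nodes are appended last.

    Returns ``(positions, fibers, crosslinkers)`` where positions stacks
    fiber endpoints followed by one hinge node per cross-linker (at the
    midpoint of its pair).  Dynamic relaxation of this state is the
    engine's job.
    """
    pos, fibers = seed_fibers(params, extents, rng)
    fid = np.concatenate(
        [np.full(len(f.node_ids), i) for i, f in enumerate(fibers)]
    ) if fibers else np.zeros(0, dtype=int)
    pairs = place_crosslinkers(pos, fid, params)
    crosslinkers: list[CrossLinker] = []
    hinge_positions = []
    n0 = len(pos)
    for k, (i, j) in enumerate(pairs):
        hinge_positions.append(0.5 * (pos[i] + pos[j]))
        crosslinkers.append(
            CrossLinker(hinge=n0 + k, end_a=i, end_b=j, r0=params.crosslink_rest_length)
        )
    if hinge_positions:
        pos = np.vstack([pos, np.array(hinge_positions)])
    return pos, fibers, crosslinkers


def couple_membrane_matrix(
    mesh_positions: np.ndarray,
    membrane_vertex_ids: np.ndarray,
    endpoint_positions: np.ndarray,
    endpoint_ids: np.ndarray,
    coupling_radius: float,
) -> list[PermanentLink]:
    """One pass linking every (vertex, fiber endpoint) pair within radius.

    Links are harmonic springs at their creation length; they are never
    removed.  A zero radius yields no links.
    """
    if coupling_radius <= 0 or len(endpoint_positions) == 0 or len(mesh_positions) == 0:
        return []
    tree = cKDTree(endpoint_positions)
    links: list[PermanentLink] = []
    neighbours = tree.query_ball_point(mesh_positions, coupling_radius)
    for vi, found in enumerate(neighbours):
        for ei in found:
            rest = float(
                np.linalg.norm(mesh_positions[vi] - endpoint_positions[ei])
            )
            links.append(
                PermanentLink(
                    membrane_vertex=int(membrane_vertex_ids[vi]),
                    fiber_endpoint=int(endpoint_ids[ei]),
                    rest_length=rest,
                )
            )
    return links


def place_cells(
    d_c: float,
    extents: Sequence[float],
    cell_z: float,
    cell_radius: float = 2.0,
) -> np.ndarray:
    """Two cell centres symmetric about the domain centre along x.

    Centres sit at ``(Lx/2 - d_c/2, Ly/2, z)`` and ``(Lx/2 + d_c/2, Ly/2, z)``.
    """
    lx, ly = float(extents[0]), float(extents[1])
    if d_c >= lx:
        raise ValueError("initial cell distance exceeds the domain x extent")
    if d_c <= 2.0 * cell_radius:
        raise ValueError("initial cell distance must exceed one cell diameter")
    return np.array(
        [
            [lx / 2.0 - d_c / 2.0, ly / 2.0, cell_z],
            [lx / 2.0 + d_c / 2.0, ly / 2.0, cell_z],
        ]
    )
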