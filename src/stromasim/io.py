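"""File interfaces: state snapshots, trajectory export, VTK polydata.

* Full state round-trips losslessly through an ``.npz`` (arrays) plus a
  JSON sidecar (scalars, cell links, RNG state).
* Trajectories are exported as a legacy-ASCII VTK polydata series (fiber
  segments and cross-linker arms as lines, the membrane as polygons,
  cells as vertices), a ``scalars.csv`` log, and a compact
  ``trajectory.npz`` consumed by the analysis CLI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import boundary as bnd
from .cell_dynamics import BondKinetics, Cell
from .config import load_config
from .engine import SimState, Snapshot, Trajectory, _NeighborCache
from . import model_core as mc

__all__ = [
    "save_state",
    "load_state",
    "write_trajectory",
    "read_trajectory",
    "write_vtk_polydata",
]

_ARRAY_FIELDS = [
    "pos",
    "drag",
    "kind",
    "anchored_to",
    "force",
    "spring_pairs",
    "spring_k",
    "spring_r0",
    "spring_class",
    "bend_triples",
    "bend_k",
    "bend_theta0",
    "dihedrals",
    "dihedral_k",
    "dihedral_theta0",
    "fiber_segments",
    "triangles",
    "membrane_vertex_ids",
    "fiber_endpoint_ids",
    "fiber_spring_force",
]


def save_state(state: SimState, path: str | Path) -> None:
    """Write a lossless snapshot: ``<path>.npz`` + ``<path>.json``."""
    path = Path(path)
    arrays = {f: getattr(state, f) for f in _ARRAY_FIELDS}
    arrays["box_offsets"] = state.box.offsets
    arrays["box_extents"] = state.box.extents
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "time": state.time,
        "dt": state.dt,
        "kBT": state.kBT,
        "thermal": state.thermal,
        "cells_active": state.cells_active,
        "box": {
            "youngs_modulus": state.box.youngs_modulus,
            "elastic_thickness": state.box.elastic_thickness,
            "relax_rate": state.box.relax_rate,
            "wall_strength": state.box.wall_strength,
        },
        "kinetics": {
            "k_on": state.kinetics.k_on,
            "k_off0": state.kinetics.k_off0,
            "x_bell": state.kinetics.x_bell,
            "kBT": state.kinetics.kBT,
        },
        "rule_ff": [state.rule_ff.strength, state.rule_ff.threshold],
        "rule_fm": [state.rule_fm.strength, state.rule_fm.threshold],
        "cells": [
            {
                "node": c.node,
                "radius": c.radius,
                "interaction_distance": c.interaction_distance,
                "contractile_force": c.contractile_force,
                "drag": c.drag,
                "links": {str(k): v for k, v in c.links.items()},
            }
            for c in state.cells
        ],
        "rng_state": state.rng.bit_generator.state,
        "config": state.config.model_dump(mode="json") if state.config else None,
    }
    # floats survive JSON round-trips exactly via repr (Python uses shortest
    # round-trippable repr); infinities need special handling
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_state(path: str | Path) -> SimState:
    """Rebuild a :class:`SimState` saved by :func:`save_state`."""
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        arrays = {k: data[k].copy() for k in data.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    box = bnd.DomainBox(
        extents=arrays.pop("box_extents"),
        offsets=arrays.pop("box_offsets"),
        **meta["box"],
    )
    cells = [
        Cell(
            node=c["node"],
            radius=c["radius"],
            interaction_distance=c["interaction_distance"],
            contractile_force=c["contractile_force"],
            drag=c["drag"],
            links={int(k): v for k, v in c["links"].items()},
        )
        for c in meta["cells"]
    ]
    rng = np.random.default_rng()
    rng.bit_generator.state = meta["rng_state"]
    state = SimState(
        time=meta["time"],
        cells=cells,
        box=box,
        kinetics=BondKinetics(**meta["kinetics"]),
        rule_ff=mc.RepulsionRule(*meta["rule_ff"], "fiber-fiber"),
        rule_fm=mc.RepulsionRule(*meta["rule_fm"], "fiber-membrane"),
        dt=meta["dt"],
        kBT=meta["kBT"],
        thermal=meta["thermal"],
        cells_active=meta["cells_active"],
        rng=rng,
        config=load_config(meta["config"]) if meta["config"] else None,
        **{f: arrays[f] for f in _ARRAY_FIELDS},
    )
    state._nbr = _NeighborCache()
    return state


# ---------------------------------------------------------------------------
# VTK polydata (legacy ASCII)
# ---------------------------------------------------------------------------


def write_vtk_polydata(
    path: str | Path,
    points: np.ndarray,
    lines: np.ndarray | None = None,
    polygons: np.ndarray | None = None,
    vertices: np.ndarray | None = None,
    point_scalars: dict[str, np.ndarray] | None = None,
) -> None:
    """Minimal legacy-ASCII VTK polydata writer."""
    points = np.asarray(points, dtype=float)
    out = [
        "# vtk DataFile Version 3.0",
        "stromasim snapshot",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} double",
    ]
    out += [" ".join(f"{v:.9g}" for v in p) for p in points]
    if vertices is not None and len(vertices):
        out.append(f"VERTICES {len(vertices)} {2 * len(vertices)}")
        out += [f"1 {int(v)}" for v in np.asarray(vertices).ravel()]
    if lines is not None and len(lines):
        lines = np.asarray(lines, dtype=np.int64).reshape(-1, 2)
        out.append(f"LINES {len(lines)} {3 * len(lines)}")
        out += [f"2 {a} {b}" for a, b in lines]
    if polygons is not None and len(polygons):
        polygons = np.asarray(polygons, dtype=np.int64).reshape(-1, 3)
        out.append(f"POLYGONS {len(polygons)} {4 * len(polygons)}")
        out += [f"3 {a} {b} {c}" for a, b, c in polygons]
    if point_scalars:
        out.append(f"POINT_DATA {len(points)}")
        for name, vals in point_scalars.items():
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out += [f"{v:.9g}" for v in np.asarray(vals, dtype=float)]
    Path(path).write_text("\n".join(out) + "\n")


def write_trajectory(traj: Trajectory, out_dir: str | Path) -> None:
    """Export a trajectory: VTK series + scalars.csv + trajectory.npz."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_lines = traj.fiber_segments
    for i, snap in enumerate(traj.snapshots):
        write_vtk_polydata(
            out_dir / f"snapshot_{i:05d}.vtk",
            snap.pos,
            lines=all_lines,
            polygons=traj.triangles,
            vertices=traj.cell_node_ids,
        )
    traj.scalar_frame().to_csv(out_dir / "scalars.csv", index=False)
    np.savez(
        out_dir / "trajectory.npz",
        times=np.array(traj.times),
        positions=np.array([s.pos for s in traj.snapshots]),
        face_offsets=np.array([s.face_offsets for s in traj.snapshots]),
        fiber_segments=traj.fiber_segments,
        triangles=traj.triangles,
        membrane_vertex_ids=traj.membrane_vertex_ids,
        fiber_endpoint_ids=traj.fiber_endpoint_ids,
        cell_node_ids=traj.cell_node_ids,
        membrane_z0=traj.membrane_z0,
    )


def read_trajectory(out_dir: str | Path) -> Trajectory:
    """Load the compact trajectory written by :func:`write_trajectory`."""
    out_dir = Path(out_dir)
    with np.load(out_dir / "trajectory.npz") as data:
        traj = Trajectory(
            fiber_segments=data["fiber_segments"].copy(),
            triangles=data["triangles"].copy(),
            membrane_vertex_ids=data["membrane_vertex_ids"].copy(),
            fiber_endpoint_ids=data["fiber_endpoint_ids"].copy(),
            cell_node_ids=data["cell_node_ids"].copy(),
            membrane_z0=float(data["membrane_z0"]),
        )
        for t, pos, off in zip(
            data["times"], data["positions"], data["face_offsets"]
        ):
            traj.times.append(float(t))
            traj.snapshots.append(
                Snapshot(
                    time=float(t),
                    pos=pos.copy(),
                    cell_links=[],
                    face_offsets=off.copy(),
                )
            )
    return traj
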