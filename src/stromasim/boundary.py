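"""Rectangular simulation domain with repulsive, elastically moving walls.

Each of the six faces can carry permanently anchored elements; the normal
force those elements transmit is converted to a stress, the stress to a
strain through the face's Young's modulus, and the strain to a target
displacement through the elastic thickness.  The face relaxes toward the
target with a first-order rate.  ``youngs_modulus = inf`` makes the box
rigid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FACE_AXES", "FACE_SIGNS", "DomainBox", "wall_repulsion", "anchor_elements"]

# face order: x-, x+, y-, y+, z-, z+
FACE_AXES = np.array([0, 0, 1, 1, 2, 2])
FACE_SIGNS = np.array([-1, +1, -1, +1, -1, +1])


@dataclass
class DomainBox:
    """Axis-aligned box ``[0, Lx] x [0, Ly] x [0, Lz]`` at rest.

    ``offsets`` are the current outward normal displacements of the six
    faces from their rest positions (um); faces move only along their
    normals.  Moduli in pN/um^2 (numerically Pa), thickness in um,
    relaxation rate in 1/s, wall repulsion strength in pN/um.
    """

    extents: np.ndarray = field(default_factory=lambda: np.array([120.0, 120.0, 60.0]))
    youngs_modulus: float = 100.0
    elastic_thickness: float = 10.0
    relax_rate: float = 1.0
    wall_strength: float = 100.0
    offsets: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self) -> None:
        self.extents = np.asarray(self.extents, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if np.any(self.extents <= 0):
            raise ValueError("domain extents must be positive")
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")

    def face_positions(self) -> np.ndarray:
        """Current coordinate of each face along its axis."""
        rest = np.where(FACE_SIGNS > 0, self.extents[FACE_AXES], 0.0)
        return rest + FACE_SIGNS * self.offsets

    def face_areas(self) -> np.ndarray:
        lx, ly, lz = self.extents
        return np.array([ly * lz, ly * lz, lx * lz, lx * lz, lx * ly, lx * ly])

    @property
    def rigid(self) -> bool:
        return not np.isfinite(self.youngs_modulus)


def wall_repulsion(
    box: DomainBox, pos: np.ndarray, out: np.ndarray | None = None
) -> np.ndarray:
    """Linear push-back on nodes beyond any face; zero strictly inside.

    Returns the (n, 3) wall force array (also accumulated into ``out``).
    """
    pos = np.atleast_2d(pos)
    faces = box.face_positions()
    f = np.zeros_like(pos)
    for face in range(6):
        ax = FACE_AXES[face]
        pen = FACE_SIGNS[face] * (pos[:, ax] - faces[face])  # >0 when outside
        f[:, ax] -= box.wall_strength * np.maximum(0.0, pen) * FACE_SIGNS[face]
    if out is not None:
        out += f
    return f


def anchor_elements(
    box: DomainBox,
    pos: np.ndarray,
    candidate_mask: np.ndarray,
    tolerance: float,
    force_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Assign nodes to faces: (n,) array of face index or -1.

    ``candidate_mask`` selects nodes eligible for anchoring (fiber
    endpoints and membrane vertices); ``force_mask`` marks nodes anchored
    regardless of distance (membrane perimeter vertices), attached to the
    nearest face.  Ties go to the lowest face index.  Anchoring is meant
    to be permanent: call once, after assembly.
    """
    pos = np.atleast_2d(pos)
    n = pos.shape[0]
    faces = box.face_positions()
    dist = np.empty((n, 6))
    for face in range(6):
        dist[:, face] = np.abs(pos[:, FACE_AXES[face]] - faces[face])
    nearest = np.argmin(dist, axis=1)
    near_enough = dist[np.arange(n), nearest] <= tolerance
    anchored_to = np.full(n, -1, dtype=np.int64)
    take = np.asarray(candidate_mask, dtype=bool) & near_enough
    if force_mask is not None:
        take |= np.asarray(force_mask, dtype=bool)
    anchored_to[take] = nearest[take]
    return anchored_to


def boundary_update(
    box: DomainBox,
    anchored_to: np.ndarray,
    anchor_forces: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Advance the six face offsets one step; returns per-face targets.

    Stress on a face is the outward normal component of the summed forces
    its anchored elements transmit, divided by face area.  Target outward
    displacement = stress / E * thickness; the offset relaxes toward it
    with the configured first-order rate.
    """
    targets = np.zeros(6)
    if box.rigid:
        box.offsets[:] = 0.0
        return targets
    areas = box.face_areas()
    for face in range(6):
        mask = anchored_to == face
        if np.any(mask):
            normal_force = FACE_SIGNS[face] * anchor_forces[mask, FACE_AXES[face]].sum()
            stress = normal_force / areas[face]
            targets[face] = stress / box.youngs_modulus * box.elastic_thickness
    box.offsets += box.relax_rate * (targets - box.offsets) * dt
    return targets
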