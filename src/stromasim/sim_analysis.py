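"""Quantification of simulation output.

Top-down (x-y) gridded maps of membrane deformation, fiber endpoint
density, fiber alignment relative to the cell-cell axis, and the local
nematic order parameter; plus two-cell separation time series.

Orientation statistics are axial: both alignment ``<cos^2 theta>`` and
order ``<2 cos^2 phi - 1>`` are invariant under reversal of any segment
direction.  Angles use the x-y projection by default (maps are top-down
views); full 3D variants are available via ``projected=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import griddata

__all__ = [
    "GridMap",
    "membrane_deformation_map",
    "fiber_density_map",
    "alignment_map",
    "order_parameter_map",
    "cell_separation_series",
]


@dataclass
class GridMap:
    """A 2D scalar field on a uniform x-y grid.

    ``values[i, j]`` covers ``[origin + (i, j) * cell_size,
    origin + (i+1, j+1) * cell_size)``; missing cells are NaN.
    """

    origin: np.ndarray
    cell_size: float
    values: np.ndarray
    semantics: str = "density"

    VALID = ("deformation", "density", "alignment", "order")

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.semantics not in self.VALID:
            raise ValueError(f"semantics must be one of {self.VALID}")
        finite = self.values[np.isfinite(self.values)]
        if self.semantics == "alignment" and finite.size:
            if finite.min() < -1e-9 or finite.max() > 1 + 1e-9:
                raise ValueError("alignment values must lie in [0, 1]")
        if self.semantics == "order" and finite.size:
            if finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9:
                raise ValueError("order values must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys


def _grid_geometry(extent, cell_size, origin):
    origin = np.zeros(2) if origin is None else np.asarray(origin, dtype=float)
    nx = int(np.ceil((extent[0] - origin[0]) / cell_size - 1e-9))
    ny = int(np.ceil((extent[1] - origin[1]) / cell_size - 1e-9))
    return origin, max(nx, 1), max(ny, 1)


def _bin_indices(xy, origin, cell_size, nx, ny):
    ij = np.floor((xy - origin) / cell_size).astype(np.int64)
    ok = (ij[:, 0] >= 0) & (ij[:, 0] < nx) & (ij[:, 1] >= 0) & (ij[:, 1] < ny)
    return ij, ok


def membrane_deformation_map(
    vertex_positions: np.ndarray,
    reference_height: float,
    extent,
    cell_size: float = 1.0,
    origin=None,
) -> GridMap:
    """Mean vertex z-displacement from the reference height per grid cell.

    Cells not covered by any vertex are filled by linear interpolation over
    the vertex cloud (nearest-neighbour at the fringe), mirroring the
    triangle coverage of the mesh.
    """
    origin, nx, ny = _grid_geometry(extent, cell_size, origin)
    vals = np.full((nx, ny), np.nan)
    dz = vertex_positions[:, 2] - reference_height
    ij, ok = _bin_indices(vertex_positions[:, :2], origin, cell_size, nx, ny)
    flat = ij[ok, 0] * ny + ij[ok, 1]
    sums = np.bincount(flat, weights=dz[ok], minlength=nx * ny)
    counts = np.bincount(flat, minlength=nx * ny)
    filled = counts > 0
    vals.ravel()[filled] = sums[filled] / counts[filled]
    if np.any(~filled) and np.any(filled):
        xs, ys = np.meshgrid(
            origin[0] + (np.arange(nx) + 0.5) * cell_size,
            origin[1] + (np.arange(ny) + 0.5) * cell_size,
            indexing="ij",
        )
        pts = vertex_positions[:, :2]
        targets = np.column_stack([xs.ravel(), ys.ravel()])
        interp = griddata(pts, dz, targets, method="linear")
        nn = griddata(pts, dz, targets, method="nearest")
        interp = np.where(np.isfinite(interp), interp, nn)
        v = vals.ravel()
        v[~filled] = interp[~filled]
        vals = v.reshape(nx, ny)
    return GridMap(origin, cell_size, vals, "deformation")


def fiber_density_map(
    endpoint_positions: np.ndarray,
    extent,
    cell_size: float = 1.0,
    origin=None,
    relative: bool = True,
) -> GridMap:
    """Endpoint counts per grid cell (x-y projection).

    With ``relative=True`` counts are normalised by the map mean, giving a
    relative density of 1 for a uniform field.
    """
    origin, nx, ny = _grid_geometry(extent, cell_size, origin)
    ij, ok = _bin_indices(endpoint_positions[:, :2], origin, cell_size, nx, ny)
    flat = ij[ok, 0] * ny + ij[ok, 1]
    counts = np.bincount(flat, minlength=nx * ny).astype(float).reshape(nx, ny)
    if relative and counts.mean() > 0:
        counts = counts / counts.mean()
    return GridMap(origin, cell_size, counts, "density")


def _segment_directions(positions, segments, projected: bool):
    d = positions[segments[:, 1]] - positions[segments[:, 0]]
    if projected:
        d = d.copy()
        d[:, 2] = 0.0
    n = np.linalg.norm(d, axis=1)
    good = n > 1e-12
    return d[good] / n[good, None], 0.5 * (
        positions[segments[:, 0]] + positions[segments[:, 1]]
    )[good]


def alignment_map(
    positions: np.ndarray,
    segments: np.ndarray,
    axis: np.ndarray,
    extent,
    cell_size: float = 1.0,
    origin=None,
    projected: bool = True,
) -> GridMap:
    """Per-cell mean of cos^2(theta) against the cell-cell axis.

    theta is the (axial) angle between each fiber segment direction and
    ``axis``; 1 means fully aligned with the axis, 0 perpendicular.  Cells
    containing no segment midpoint are NaN (missing, not zero).
    """
    origin, nx, ny = _grid_geometry(extent, cell_size, origin)
    axis = np.asarray(axis, dtype=float).copy()
    if projected:
        axis = np.array([axis[0], axis[1], 0.0])
    axis = axis / np.linalg.norm(axis)
    dirs, mids = _segment_directions(positions, segments, projected)
    cos2 = (dirs @ axis) ** 2
    ij, ok = _bin_indices(mids[:, :2], origin, cell_size, nx, ny)
    flat = ij[ok, 0] * ny + ij[ok, 1]
    sums = np.bincount(flat, weights=cos2[ok], minlength=nx * ny)
    counts = np.bincount(flat, minlength=nx * ny)
    vals = np.full(nx * ny, np.nan)
    filled = counts > 0
    vals[filled] = sums[filled] / counts[filled]
    return GridMap(origin, cell_size, np.clip(vals, 0.0, 1.0).reshape(nx, ny), "alignment")


def order_parameter_map(
    positions: np.ndarray,
    segments: np.ndarray,
    extent,
    cell_size: float = 1.0,
    origin=None,
    projected: bool = True,
) -> GridMap:
    """Per-cell nematic order ``<2 cos^2 phi - 1>``.

    phi is the angle between each segment and the grid cell's mean fiber
    orientation, taken as the principal eigenvector of the local
    second-moment orientation tensor (axial statistics).  Single-segment
    cells give order 1 by construction.
    """
    origin, nx, ny = _grid_geometry(extent, cell_size, origin)
    dirs, mids = _segment_directions(positions, segments, projected)
    ij, ok = _bin_indices(mids[:, :2], origin, cell_size, nx, ny)
    flat = ij[ok, 0] * ny + ij[ok, 1]
    dirs = dirs[ok]
    dim = 2 if projected else 3
    d = dirs[:, :dim]
    # second-moment tensor accumulated per grid cell
    vals = np.full(nx * ny, np.nan)
    ncell = nx * ny
    counts = np.bincount(flat, minlength=ncell)
    moment = np.zeros((ncell, dim, dim))
    for i in range(dim):
        for j in range(dim):
            moment[:, i, j] = np.bincount(
                flat, weights=d[:, i] * d[:, j], minlength=ncell
            )
    filled = np.flatnonzero(counts > 0)
    if len(filled):
        m = moment[filled] / counts[filled, None, None]
        _, vecs = np.linalg.eigh(m)
        principal = vecs[:, :, -1]  # eigenvector of the largest eigenvalue
        # mean of 2 cos^2 phi - 1 = 2 e^T M e - 1
        proj = np.einsum("ki,kij,kj->k", principal, m, principal)
        vals[filled] = np.clip(2.0 * proj - 1.0, -1.0, 1.0)
    return GridMap(origin, cell_size, vals.reshape(nx, ny), "order")


@dataclass
class SeparationSummary:
    """Two-cell separation series and its normalised migration summary."""

    times: np.ndarray
    separation: np.ndarray
    initial_separation: float
    final_separation: float
    cell_diameter: float
    approach: float = field(init=False)  # final - initial (< 0: approach)
    normalized_initial_distance: float = field(init=False)

    def __post_init__(self) -> None:
        self.approach = self.final_separation - self.initial_separation
        self.normalized_initial_distance = self.initial_separation / self.cell_diameter


def cell_separation_series(traj, cell_radius: float = 2.0) -> SeparationSummary:
    """Separation |r1 - r2| versus time for a two-cell trajectory."""
    if traj.cell_node_ids is None or len(traj.cell_node_ids) != 2:
        raise ValueError("cell_separation_series requires exactly two cells")
    p0 = traj.cell_positions(0)
    p1 = traj.cell_positions(1)
    sep = np.linalg.norm(p0 - p1, axis=1)
    return SeparationSummary(
        times=np.asarray(traj.times, dtype=float),
        separation=sep,
        initial_separation=float(sep[0]),
        final_separation=float(sep[-1]),
        cell_diameter=2.0 * cell_radius,
    )
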