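"""Mechanical element types and force kernels.

All quantities are in internal pN-um-s units (see :mod:`stromasim.units`).
The force laws implemented here are harmonic potentials:

* extension      ``U_s = 1/2 k_s (r - r0)^2`` along an element axis,
* bending        ``U_b = 1/2 k_b (theta - theta0)^2`` at a three-node hinge
  or at the dihedral between two adjacent triangles,
* repulsion      ``U_r = 1/2 k_r (r12 - rc)^2`` for ``r12 < rc`` and zero
  otherwise, where ``r12`` is the shortest distance between two primitives.

Every public force routine returns forces that are the exact negative
gradient of its potential, so internal forces conserve linear momentum
and torque by construction.  Kernels are vectorised over a leading batch
axis; thin scalar wrappers with the per-element signatures are provided
for direct use and testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import NamedTuple

import numpy as np

from . import units

__all__ = [
    "NodeKind",
    "Node",
    "FiberSegment",
    "Fiber",
    "CrossLinker",
    "MembraneMesh",
    "RepulsionRule",
    "PhysicalConstants",
    "Segment",
    "Triangle",
    "drag_coefficient",
    "extensional_forces",
    "bending_forces",
    "dihedral_forces",
    "repulsive_forces",
    "stochastic_force",
    "stochastic_forces",
    "min_distance",
    "spring_forces",
    "angle_forces",
    "dihedral_bend_forces",
    "segment_segment_closest",
    "point_triangle_closest",
    "segment_triangle_closest",
    "scatter_add",
]

_TINY = 1e-12


class DegenerateGeometryWarning(UserWarning):
    """Raised (as a warning) when a force direction is undefined."""


# ---------------------------------------------------------------------------
# element types
# ---------------------------------------------------------------------------


class NodeKind(IntEnum):
    FIBER_END = 0
    MEMBRANE_VERTEX = 1
    CELL_CENTER = 2
    CROSSLINK_HINGE = 3


@dataclass
class Node:
    """A mobile point advanced by the integrator.

    Positions in um, drag in pN*s/um, forces in pN.
    """

    id: int
    position: np.ndarray
    drag: float
    kind: NodeKind = NodeKind.FIBER_END
    anchored: bool = False
    force_accumulator: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("node position must be finite")
        if self.drag <= 0:
            raise ValueError("drag must be positive")


@dataclass
class FiberSegment:
    """A cylindrical segment between two node indices."""

    node_a: int
    node_b: int
    rest_length: float = 1.0
    diameter: float = 0.060

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError("segment endpoints must differ")
        if self.rest_length <= 0 or self.diameter <= 0:
            raise ValueError("rest_length and diameter must be positive")


@dataclass
class Fiber:
    """A chain of segments sharing extensional/bending parameters.

    Default stiffnesses are the fiber values converted to internal units
    (0.277 N/m and 8.12e-20 N*m).
    """

    segments: list[FiberSegment]
    ks: float = 0.277 * units.N_PER_M
    kb: float = 8.12e-20 * units.N_M
    theta0: float = 0.0

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.segments, self.segments[1:]):
            if prev.node_b != nxt.node_a:
                raise ValueError("consecutive segments must share a node")

    @property
    def node_ids(self) -> list[int]:
        ids = [self.segments[0].node_a]
        ids += [s.node_b for s in self.segments]
        return ids


@dataclass
class CrossLinker:
    """Two harmonic arms joined at a central hinge node.

    The arm ends are fiber endpoint nodes; the hinge carries the bending
    potential between the two arms.
    """

    hinge: int
    end_a: int
    end_b: int
    ks: float = 2.0e-3 * units.N_PER_M
    kb: float = 1.04e-19 * units.N_M
    r0: float = 0.230
    theta0: float = 0.0

    def __post_init__(self) -> None:
        if len({self.hinge, self.end_a, self.end_b}) != 3:
            raise ValueError("cross-linker nodes must be distinct")
        if self.r0 <= 0:
            raise ValueError("rest length must be positive")


@dataclass
class MembraneMesh:
    """A triangulated membrane: vertices, edge springs and dihedral hinges.

    ``dihedrals`` rows are (a, b, c, d): the shared edge is (b, c) and the
    opposite vertices are a (first triangle) and d (second triangle).
    """

    positions: np.ndarray
    edges: np.ndarray
    triangles: np.ndarray
    dihedrals: np.ndarray
    boundary_mask: np.ndarray
    edge_rest_length: float = 1.0
    ks: float = 0.001 * units.N_PER_M
    kb: float = 10e-19 * units.N_M
    theta0: float = 0.0
    thickness: float = 0.2

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.edges = np.asarray(self.edges, dtype=np.int64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.dihedrals = (
            np.asarray(self.dihedrals, dtype=np.int64).reshape(-1, 4)
        )
        self.boundary_mask = np.asarray(self.boundary_mask, dtype=bool)

    @property
    def n_vertices(self) -> int:
        return len(self.positions)


@dataclass
class RepulsionRule:
    """Strength and cutoff of a volume-exclusion pair class."""

    strength: float
    threshold: float
    pair_class: str = "fiber-fiber"

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("repulsion strength must be non-negative")
        if self.threshold <= 0:
            raise ValueError("repulsion threshold must be positive")


@dataclass
class PhysicalConstants:
    """Thermal energy (pN*um), medium viscosity (pN*s/um^2) and timestep (s).

    The default viscosity (0.86 Pa*s, cytoplasm-like) is a configurable
    stand-in: no medium viscosity is printed in the source model.
    """

    kBT: float = units.KBT_300K
    viscosity: float = 0.86
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.kBT <= 0 or self.viscosity <= 0 or self.dt <= 0:
            raise ValueError("all physical constants must be positive")


class Segment(NamedTuple):
    """Geometric line segment primitive."""

    p: np.ndarray
    q: np.ndarray


class Triangle(NamedTuple):
    """Geometric triangle primitive."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray


# ---------------------------------------------------------------------------
# small array helpers
# ---------------------------------------------------------------------------


def scatter_add(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """Accumulate ``vals`` rows into ``out`` at integer rows ``idx``."""
    idx = np.asarray(idx)
    vals = np.asarray(vals)
    n = out.shape[0]
    for k in range(out.shape[1]):
        out[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise 3-vector cross product (faster than np.cross for (n, 3))."""
    out = np.empty(np.broadcast(a, b).shape)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _norm(v: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("...i,...i->...", v, v))


def _dot(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.einsum("...i,...i->...", a, b)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    den = np.asarray(den, dtype=float)
    out = np.zeros(np.broadcast(num, den).shape)
    good = np.abs(den) > _TINY
    np.divide(num, den, out=out, where=good)
    return out


# ---------------------------------------------------------------------------
# drag and thermal forces
# ---------------------------------------------------------------------------


def drag_coefficient(diameter: float, rest_length: float, viscosity: float):
    """Approximate drag of a cylindrical segment endpoint.

    ``zeta = 3 pi mu r_c (3 + 2 r0 / r_c) / 5`` (slender-cylinder
    approximation).  Accepts scalars or arrays; all inputs must be > 0.
    """
    diameter = np.asarray(diameter, dtype=float)
    rest_length = np.asarray(rest_length, dtype=float)
    if np.any(diameter <= 0) or np.any(rest_length <= 0) or np.any(
        np.asarray(viscosity) <= 0
    ):
        raise ValueError("drag_coefficient arguments must be positive")
    return 3.0 * np.pi * viscosity * diameter * (3.0 + 2.0 * rest_length / diameter) / 5.0


def stochastic_forces(
    drag: np.ndarray, kBT: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Thermal force draws, one 3-vector per drag entry.

    Each component is N(0, 2 kBT zeta / dt) per the fluctuation-dissipation
    relation for Euler time stepping.
    """
    drag = np.atleast_1d(np.asarray(drag, dtype=float))
    sigma = np.sqrt(2.0 * kBT * drag / dt)
    return rng.normal(size=(drag.shape[0], 3)) * sigma[:, None]


def stochastic_force(
    zeta: float, constants: PhysicalConstants, rng: np.random.Generator
) -> np.ndarray:
    """Single thermal force vector for a node with drag ``zeta``."""
    return stochastic_forces(zeta, constants.kBT, constants.dt, rng)[0]


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------


def spring_forces(
    pos: np.ndarray,
    pairs: np.ndarray,
    k: np.ndarray,
    r0: np.ndarray,
    out: np.ndarray | None = None,
):
    """Harmonic extension forces for an array of node-index pairs.

    Returns ``(tension, length)`` where ``tension = k (r - r0)`` (positive
    when stretched).  When ``out`` is given, forces are accumulated into it.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    d = pos[pairs[:, 1]] - pos[pairs[:, 0]]
    r = _norm(d)
    tension = np.asarray(k) * (r - np.asarray(r0))
    axis = _safe_div(d, r[:, None])
    if np.any(r <= _TINY):
        warnings.warn(
            "coincident spring endpoints: zero extension force applied",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
        tension = np.where(r <= _TINY, 0.0, tension)
    f = tension[:, None] * axis  # force on node a (toward b when stretched)
    if out is not None:
        scatter_add(out, pairs[:, 0], f)
        scatter_add(out, pairs[:, 1], -f)
    return tension, r


def extensional_forces(
    r: float, r0: float, ks: float, unit_axis: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Force pair (on node a, on node b) for a spring of length ``r``.

    ``unit_axis`` points from a to b.  ``r = 0`` yields zero forces with a
    degeneracy warning.
    """
    if r < 0:
        raise ValueError("length must be non-negative")
    if r <= _TINY:
        warnings.warn(
            "zero-length spring: direction undefined, applying zero force",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
        return np.zeros(3), np.zeros(3)
    axis = np.asarray(unit_axis, dtype=float)
    fa = ks * (r - r0) * axis
    return fa, -fa


# ---------------------------------------------------------------------------
# bending (three-node hinge)
# ---------------------------------------------------------------------------


def angle_forces(
    pos: np.ndarray,
    triples: np.ndarray,
    kb: np.ndarray,
    theta0: np.ndarray,
    out: np.ndarray | None = None,
):
    """Bending forces at hinges (a, b, c).

    The bend angle is between segment directions ``u = b - a`` and
    ``v = c - b``; a straight chain has theta = 0.  Returns the angles.
    """
    triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    a, b, c = triples[:, 0], triples[:, 1], triples[:, 2]
    u = pos[b] - pos[a]
    v = pos[c] - pos[b]
    w = _cross(u, v)
    s = _norm(w)
    theta = np.arctan2(s, _dot(u, v))
    if out is not None:
        lu = _norm(u)
        lv = _norm(v)
        what = _safe_div(w, s[:, None])
        uhat = _safe_div(u, lu[:, None])
        vhat = _safe_div(v, lv[:, None])
        # grad_a theta = (what x uhat)/|u|; grad_c theta = (what x vhat)/|v|
        ga = _safe_div(_cross(what, uhat), lu[:, None])
        gc = _safe_div(_cross(what, vhat), lv[:, None])
        coef = -(np.asarray(kb) * (theta - np.asarray(theta0)))[:, None]
        ok = (s > _TINY)[:, None]
        fa = np.where(ok, coef * ga, 0.0)
        fc = np.where(ok, coef * gc, 0.0)
        scatter_add(out, a, fa)
        scatter_add(out, c, fc)
        scatter_add(out, b, -fa - fc)
    return theta


def bending_forces(
    pa: np.ndarray, pb: np.ndarray, pc: np.ndarray, kb: float, theta0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Force triple for one three-node hinge; see :func:`angle_forces`.

    Degenerate geometry (coincident nodes, or theta at the singular
    anti-parallel point) yields zero forces with a warning.
    """
    pos = np.array([pa, pb, pc], dtype=float)
    if (
        np.linalg.norm(pos[1] - pos[0]) <= _TINY
        or np.linalg.norm(pos[2] - pos[1]) <= _TINY
    ):
        warnings.warn(
            "degenerate hinge geometry: zero bending force applied",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
        return np.zeros(3), np.zeros(3), np.zeros(3)
    out = np.zeros((3, 3))
    angle_forces(pos, np.array([[0, 1, 2]]), np.array([kb]), np.array([theta0]), out)
    return out[0], out[1], out[2]


# ---------------------------------------------------------------------------
# bending (membrane dihedral)
# ---------------------------------------------------------------------------


def dihedral_bend_forces(
    pos: np.ndarray,
    quads: np.ndarray,
    kb: np.ndarray,
    theta0: np.ndarray,
    out: np.ndarray | None = None,
):
    """Dihedral bending forces for quadruples (a, b, c, d).

    The hinge edge is (b, c); a and d are the opposite vertices of the two
    adjacent triangles (a, b, c) and (d, c, b).  theta is the angle between
    the two (consistently oriented) triangle normals, zero when coplanar.
    Returns the dihedral angles.
    """
    quads = np.asarray(quads, dtype=np.int64).reshape(-1, 4)
    a, b, c, d = quads.T
    pa, pb, pc, pd = pos[a], pos[b], pos[c], pos[d]
    n1 = _cross(pb - pa, pc - pa)
    n2 = _cross(pc - pd, pb - pd)
    w = _cross(n1, n2)
    s = _norm(w)
    theta = np.arctan2(s, _dot(n1, n2))
    if out is not None:
        l1 = _norm(n1)
        l2 = _norm(n2)
        what = _safe_div(w, s[:, None])
        # gradients of theta w.r.t. the two normals
        g = -_safe_div(_cross(what, _safe_div(n1, l1[:, None])), l1[:, None])
        h = _safe_div(_cross(what, _safe_div(n2, l2[:, None])), l2[:, None])
        grad_a = _cross(pb - pc, g)
        grad_b = _cross(pc - pa, g) + _cross(h, pc - pd)
        grad_c = _cross(g, pb - pa) + _cross(pb - pd, h)
        grad_d = _cross(pc - pb, h)
        coef = -(np.asarray(kb) * (theta - np.asarray(theta0)))[:, None]
        ok = (s > _TINY)[:, None]
        scatter_add(out, a, np.where(ok, coef * grad_a, 0.0))
        scatter_add(out, b, np.where(ok, coef * grad_b, 0.0))
        scatter_add(out, c, np.where(ok, coef * grad_c, 0.0))
        scatter_add(out, d, np.where(ok, coef * grad_d, 0.0))
    return theta


def dihedral_forces(
    pa, pb, pc, pd, kb: float, theta0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Force quadruple for one dihedral hinge; see :func:`dihedral_bend_forces`."""
    pos = np.array([pa, pb, pc, pd], dtype=float)
    out = np.zeros((4, 3))
    dihedral_bend_forces(
        pos, np.array([[0, 1, 2, 3]]), np.array([kb]), np.array([theta0]), out
    )
    return out[0], out[1], out[2], out[3]


# ---------------------------------------------------------------------------
# closest-point geometry
# ---------------------------------------------------------------------------


def segment_segment_closest(p1, q1, p2, q2):
    """Closest points between segment batches.

    Returns ``(dist, s, t, cp1, cp2)`` with ``cp1 = p1 + s (q1 - p1)`` etc.
    Degenerate (point-like) segments are handled.
    """
    p1, q1, p2, q2 = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (p1, q1, p2, q2))
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = _dot(d1, d1)
    e = _dot(d2, d2)
    f = _dot(d2, r)
    c = _dot(d1, r)
    b = _dot(d1, d2)
    denom = a * e - b * b
    s = np.clip(_safe_div(b * f - c * e, denom), 0.0, 1.0)
    # parallel segments: any s works, pick 0
    s = np.where(denom > _TINY, s, 0.0)
    t = _safe_div(b * s + f, e)
    t_clamped = np.clip(t, 0.0, 1.0)
    s = np.where(
        np.abs(t_clamped - t) > 0,
        np.clip(_safe_div(t_clamped * b - c, a), 0.0, 1.0),
        s,
    )
    s = np.where(a > _TINY, s, 0.0)
    t = np.where(e > _TINY, t_clamped, 0.0)
    cp1 = p1 + s[:, None] * d1
    cp2 = p2 + t[:, None] * d2
    return _norm(cp1 - cp2), s, t, cp1, cp2


def point_triangle_closest(p, a, b, c):
    """Closest point on triangle (a, b, c) to point(s) ``p``.

    Returns ``(dist, cp, bary)`` with barycentric weights (wa, wb, wc).
    """
    p, a, b, c = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (p, a, b, c))
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = _dot(ab, ap)
    d2 = _dot(ac, ap)
    bp = p - b
    d3 = _dot(ab, bp)
    d4 = _dot(ac, bp)
    cp_ = p - c
    d5 = _dot(ab, cp_)
    d6 = _dot(ac, cp_)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    n = p.shape[0] if p.shape[0] >= a.shape[0] else a.shape[0]
    bary = np.empty((n, 3))
    # interior (default)
    denom = va + vb + vc
    v_in = _safe_div(vb, denom)
    w_in = _safe_div(vc, denom)
    bary[:, 0] = 1.0 - v_in - w_in
    bary[:, 1] = v_in
    bary[:, 2] = w_in

    def assign(mask, wa, wb, wc):
        bary[mask, 0] = np.broadcast_to(wa, mask.shape)[mask]
        bary[mask, 1] = np.broadcast_to(wb, mask.shape)[mask]
        bary[mask, 2] = np.broadcast_to(wc, mask.shape)[mask]

    taken = np.zeros(n, dtype=bool)
    # vertex A
    m = (d1 <= 0) & (d2 <= 0) & ~taken
    assign(m, 1.0, 0.0, 0.0)
    taken |= m
    # vertex B
    m = (d3 >= 0) & (d4 <= d3) & ~taken
    assign(m, 0.0, 1.0, 0.0)
    taken |= m
    # edge AB
    v_ab = _safe_div(d1, d1 - d3)
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~taken
    assign(m, 1.0 - v_ab, v_ab, 0.0)
    taken |= m
    # vertex C
    m = (d6 >= 0) & (d5 <= d6) & ~taken
    assign(m, 0.0, 0.0, 1.0)
    taken |= m
    # edge AC
    w_ac = _safe_div(d2, d2 - d6)
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~taken
    assign(m, 1.0 - w_ac, 0.0, w_ac)
    taken |= m
    # edge BC
    w_bc = _safe_div(d4 - d3, (d4 - d3) + (d5 - d6))
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0) & ~taken
    assign(m, 0.0, 1.0 - w_bc, w_bc)

    cp = bary[:, 0:1] * a + bary[:, 1:2] * b + bary[:, 2:3] * c
    return _norm(p - cp), cp, bary


def segment_triangle_closest(p, q, a, b, c):
    """Closest points between segment (p, q) and triangle (a, b, c) batches.

    Returns ``(dist, s, bary, cp_seg, cp_tri)`` where ``s`` parametrises the
    segment and ``bary`` the triangle closest point.
    """
    p, q, a, b, c = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (p, q, a, b, c))
    n = max(x.shape[0] for x in (p, q, a, b, c))
    p, q, a, b, c = (np.broadcast_to(x, (n, 3)) for x in (p, q, a, b, c))

    cands_d = []
    cands_s = []
    cands_bary = []

    # segment endpoints vs triangle face
    for pt, sval in ((p, 0.0), (q, 1.0)):
        d, _, bary = point_triangle_closest(pt, a, b, c)
        cands_d.append(d)
        cands_s.append(np.full(n, sval))
        cands_bary.append(bary)

    # segment vs triangle edges
    for e0, e1, which in ((a, b, "ab"), (b, c, "bc"), (c, a, "ca")):
        d, s, t, _, _ = segment_segment_closest(p, q, e0, e1)
        bary = np.zeros((n, 3))
        if which == "ab":
            bary[:, 0] = 1 - t
            bary[:, 1] = t
        elif which == "bc":
            bary[:, 1] = 1 - t
            bary[:, 2] = t
        else:
            bary[:, 2] = 1 - t
            bary[:, 0] = t
        cands_d.append(d)
        cands_s.append(s)
        cands_bary.append(bary)

    # segment crossing the triangle plane
    nrm = _cross(b - a, c - a)
    dp = _dot(p - a, nrm)
    dq = _dot(q - a, nrm)
    crossing = dp * dq < 0
    s_cross = np.where(crossing, _safe_div(dp, dp - dq), 0.0)
    x = p + s_cross[:, None] * (q - p)
    d, _, bary = point_triangle_closest(x, a, b, c)
    cands_d.append(np.where(crossing, d, np.inf))
    cands_s.append(s_cross)
    cands_bary.append(bary)

    D = np.stack(cands_d)  # (ncand, n)
    S = np.stack(cands_s)
    B = np.stack(cands_bary)  # (ncand, n, 3)
    best = np.argmin(D, axis=0)
    idx = np.arange(n)
    dist = D[best, idx]
    s = S[best, idx]
    bary = B[best, idx]
    cp_seg = p + s[:, None] * (q - p)
    cp_tri = bary[:, 0:1] * a + bary[:, 1:2] * b + bary[:, 2:3] * c
    return dist, s, bary, cp_seg, cp_tri


def min_distance(prim_a, prim_b):
    """Shortest distance between two primitives and the closest point pair.

    Accepts :class:`Segment` and :class:`Triangle` in either order.
    Returns ``(r12, point_on_a, point_on_b)``.
    """
    if isinstance(prim_a, Segment) and isinstance(prim_b, Segment):
        d, _, _, cp1, cp2 = segment_segment_closest(
            prim_a.p, prim_a.q, prim_b.p, prim_b.q
        )
        return float(d[0]), cp1[0], cp2[0]
    if isinstance(prim_a, Segment) and isinstance(prim_b, Triangle):
        d, _, _, cp_seg, cp_tri = segment_triangle_closest(
            prim_a.p, prim_a.q, prim_b.a, prim_b.b, prim_b.c
        )
        return float(d[0]), cp_seg[0], cp_tri[0]
    if isinstance(prim_a, Triangle) and isinstance(prim_b, Segment):
        d, pb, pa = min_distance(prim_b, prim_a)
        return d, pa, pb
    if isinstance(prim_a, Triangle) and isinstance(prim_b, Triangle):
        raise NotImplementedError("triangle-triangle distance is not needed")
    raise TypeError(f"unsupported primitives {type(prim_a)}, {type(prim_b)}")


# ---------------------------------------------------------------------------
# repulsion
# ---------------------------------------------------------------------------

_FALLBACK_AXIS = np.array([0.0, 0.0, 1.0])


def _repulsion_axes(cp1, cp2, dist, mid1, mid2):
    """Unit axes pointing from primitive B toward primitive A.

    Overlapping primitives fall back to the midpoint axis, then to a fixed
    lattice axis, keeping runs deterministic.
    """
    axis = _safe_div(cp1 - cp2, dist[:, None])
    degen = dist <= _TINY
    if np.any(degen):
        alt = mid1 - mid2
        altn = _norm(alt)
        alt = np.where(
            (altn > _TINY)[:, None], _safe_div(alt, altn[:, None]), _FALLBACK_AXIS
        )
        axis = np.where(degen[:, None], alt, axis)
    return axis


def segment_segment_repulsion(
    pos: np.ndarray,
    pairs_a: np.ndarray,
    pairs_b: np.ndarray,
    rule: RepulsionRule,
    out: np.ndarray | None = None,
):
    """Volume-exclusion forces between fiber segment pairs.

    ``pairs_a``/``pairs_b`` are (n, 2) node-index arrays of the two segment
    sets.  The point force at the closest approach is split onto each
    segment's endpoints by the closest-point parameter, preserving net force
    and torque.  Returns the overlap magnitudes ``max(0, rc - r12)``.
    """
    pairs_a = np.asarray(pairs_a, dtype=np.int64).reshape(-1, 2)
    pairs_b = np.asarray(pairs_b, dtype=np.int64).reshape(-1, 2)
    p1, q1 = pos[pairs_a[:, 0]], pos[pairs_a[:, 1]]
    p2, q2 = pos[pairs_b[:, 0]], pos[pairs_b[:, 1]]
    dist, s, t, cp1, cp2 = segment_segment_closest(p1, q1, p2, q2)
    overlap = np.maximum(0.0, rule.threshold - dist)
    if out is not None and np.any(overlap > 0):
        axis = _repulsion_axes(cp1, cp2, dist, 0.5 * (p1 + q1), 0.5 * (p2 + q2))
        f = (rule.strength * overlap)[:, None] * axis  # on segment A
        scatter_add(out, pairs_a[:, 0], (1.0 - s)[:, None] * f)
        scatter_add(out, pairs_a[:, 1], s[:, None] * f)
        scatter_add(out, pairs_b[:, 0], -(1.0 - t)[:, None] * f)
        scatter_add(out, pairs_b[:, 1], -t[:, None] * f)
    return overlap


def segment_triangle_repulsion(
    pos: np.ndarray,
    seg_pairs: np.ndarray,
    tri_triples: np.ndarray,
    rule: RepulsionRule,
    out: np.ndarray | None = None,
):
    """Volume-exclusion forces between fiber segments and membrane triangles.

    The closest-approach point force is split onto the two segment endpoints
    (by the segment parameter) and the three triangle vertices (by
    barycentric weights).  Returns the overlap magnitudes.
    """
    seg_pairs = np.asarray(seg_pairs, dtype=np.int64).reshape(-1, 2)
    tri_triples = np.asarray(tri_triples, dtype=np.int64).reshape(-1, 3)
    p, q = pos[seg_pairs[:, 0]], pos[seg_pairs[:, 1]]
    a, b, c = pos[tri_triples[:, 0]], pos[tri_triples[:, 1]], pos[tri_triples[:, 2]]
    dist, s, bary, cp_seg, cp_tri = segment_triangle_closest(p, q, a, b, c)
    overlap = np.maximum(0.0, rule.threshold - dist)
    if out is not None and np.any(overlap > 0):
        axis = _repulsion_axes(
            cp_seg, cp_tri, dist, 0.5 * (p + q), (a + b + c) / 3.0
        )
        f = (rule.strength * overlap)[:, None] * axis  # on the segment
        scatter_add(out, seg_pairs[:, 0], (1.0 - s)[:, None] * f)
        scatter_add(out, seg_pairs[:, 1], s[:, None] * f)
        for k in range(3):
            scatter_add(out, tri_triples[:, k], -bary[:, k : k + 1] * f)
    return overlap


def repulsive_forces(prim_a, prim_b, rule: RepulsionRule):
    """Distributed repulsion force set for one primitive pair.

    Returns a list of ``(endpoint_label, force)`` entries: for a
    segment-segment pair labels are ``("a0","a1","b0","b1")``; for a
    segment-triangle pair ``("a0","a1","t0","t1","t2")``.  All forces are
    zero when the pair is separated by at least ``rule.threshold``.
    """
    if isinstance(prim_a, Segment) and isinstance(prim_b, Segment):
        pos = np.array([prim_a.p, prim_a.q, prim_b.p, prim_b.q], dtype=float)
        out = np.zeros((4, 3))
        segment_segment_repulsion(pos, [[0, 1]], [[2, 3]], rule, out)
        return list(zip(("a0", "a1", "b0", "b1"), out))
    if isinstance(prim_a, Segment) and isinstance(prim_b, Triangle):
        pos = np.array(
            [prim_a.p, prim_a.q, prim_b.a, prim_b.b, prim_b.c], dtype=float
        )
        out = np.zeros((5, 3))
        segment_triangle_repulsion(pos, [[0, 1]], [[2, 3, 4]], rule, out)
        return list(zip(("a0", "a1", "t0", "t1", "t2"), out))
    raise TypeError("repulsive_forces expects (Segment, Segment) or (Segment, Triangle)")
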