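"""Phantom-cell mechanics.

Cells are volume-less spheres that form transient force-bearing links to
fiber endpoints inside a spherical shell around their centre.  Linked
endpoints are pulled toward the centre with a constant force; the cell
receives the opposite reaction and migrates by the same overdamped Euler
rule as every other node.  Link dissociation follows a catch-bond law:
the off-rate decreases exponentially with the elastic load on the linked
endpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import units

__all__ = [
    "Cell",
    "CellFiberLink",
    "BondKinetics",
    "candidate_fiber_points",
    "bind_links",
    "unbind_links",
    "apply_contractile_forces",
    "update_cell_position",
]


@dataclass(frozen=True)
class CellFiberLink:
    """A transient cell-to-fiber-endpoint attachment."""

    cell: int
    fiber_endpoint: int
    formed_at: float


@dataclass
class BondKinetics:
    """Rate constants of link formation and catch-bond dissociation.

    ``k_off(F) = k_off0 * exp(-|F| * x_bell / kBT)``: the off-rate is
    non-increasing in load (catch bond).  The zero-force off-rate and the
    force sensitivity are not printed in the source model and must be
    supplied; the defaults here are plausible placeholders.
    """

    k_on: float = 0.03
    k_off0: float = 0.1
    x_bell: float = 1.0e-4  # um (0.1 nm)
    kBT: float = units.KBT_300K

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off0 < 0 or self.x_bell < 0:
            raise ValueError("rates and force sensitivity must be non-negative")

    def off_rate(self, force_magnitude) -> np.ndarray:
        """Force-dependent dissociation rate (catch bond)."""
        f = np.asarray(force_magnitude, dtype=float)
        return self.k_off0 * np.exp(-f * self.x_bell / self.kBT)


@dataclass
class Cell:
    """Contractile phantom agent.

    ``node`` is the index of its centre in the global node arrays; ``links``
    maps linked fiber endpoint node index -> formation time.
    """

    node: int
    radius: float = 2.0
    interaction_distance: float = 4.0
    contractile_force: float = 100.0
    drag: float | None = None  # None -> Stokes sphere 6 pi mu R
    links: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.interaction_distance <= 0:
            raise ValueError("radius and interaction distance must be positive")
        if self.contractile_force < 0:
            raise ValueError("contractile force must be non-negative")

    def stokes_drag(self, viscosity: float) -> float:
        return (
            self.drag
            if self.drag is not None
            else 6.0 * np.pi * viscosity * self.radius
        )


def candidate_fiber_points(
    cell: Cell,
    cell_position: np.ndarray,
    endpoint_positions: np.ndarray,
    endpoint_ids: np.ndarray,
) -> np.ndarray:
    """Endpoint ids inside the interaction shell, excluding linked ones.

    The shell is ``radius <= |r_endpoint - r_cell| <= radius + d_I``.
    """
    if len(endpoint_positions) == 0:
        return np.zeros(0, dtype=np.int64)
    d = np.linalg.norm(endpoint_positions - cell_position, axis=1)
    lo, hi = cell.radius, cell.radius + cell.interaction_distance
    mask = (d >= lo) & (d <= hi)
    ids = np.asarray(endpoint_ids, dtype=np.int64)[mask]
    if cell.links:
        ids = ids[~np.isin(ids, np.fromiter(cell.links, dtype=np.int64))]
    return ids


def bind_links(
    cell: Cell,
    candidates: np.ndarray,
    kinetics: BondKinetics,
    dt: float,
    time: float,
    rng: np.random.Generator,
) -> list[CellFiberLink]:
    """Independent Bernoulli binding at probability ``1 - exp(-k_on dt)``."""
    candidates = np.asarray(candidates, dtype=np.int64)
    if len(candidates) == 0 or kinetics.k_on == 0.0:
        return []
    p = -np.expm1(-kinetics.k_on * dt)
    hit = rng.random(len(candidates)) < p
    formed = [
        CellFiberLink(cell=cell.node, fiber_endpoint=int(e), formed_at=time)
        for e in candidates[hit]
    ]
    for link in formed:
        cell.links[link.fiber_endpoint] = time
    return formed


def unbind_links(
    cell: Cell,
    endpoint_forces: dict[int, float],
    kinetics: BondKinetics,
    dt: float,
    rng: np.random.Generator,
) -> list[int]:
    """Catch-bond dissociation; returns the endpoint ids removed.

    ``endpoint_forces`` maps linked endpoint id -> magnitude of the elastic
    (spring) force currently acting on that endpoint.
    """
    if not cell.links:
        return []
    ids = np.fromiter(cell.links, dtype=np.int64)
    f = np.array([endpoint_forces.get(int(e), 0.0) for e in ids])
    k_off = kinetics.off_rate(f)
    p = -np.expm1(-k_off * dt)
    gone = ids[rng.random(len(ids)) < p]
    for e in gone:
        del cell.links[int(e)]
    return [int(e) for e in gone]


def apply_contractile_forces(
    cell: Cell,
    cell_position: np.ndarray,
    positions: np.ndarray,
    out: np.ndarray,
) -> np.ndarray:
    """Constant-magnitude pull on linked endpoints; reaction on the cell.

    Each linked endpoint receives ``F0`` directed toward the cell centre;
    the cell accumulates exactly the opposite of the summed endpoint
    forces, so no net momentum is injected.  Returns the reaction force.
    """
    reaction = np.zeros(3)
    if not cell.links or cell.contractile_force == 0.0:
        return reaction
    ids = np.fromiter(cell.links, dtype=np.int64)
    d = cell_position - positions[ids]
    r = np.linalg.norm(d, axis=1)
    ok = r > 1e-12
    if not np.all(ok):
        warnings.warn(
            "fiber endpoint coincides with cell centre: skipping its pull",
            stacklevel=2,
        )
    f = np.zeros_like(d)
    f[ok] = cell.contractile_force * d[ok] / r[ok, None]
    np.add.at(out, ids, f)
    reaction = -f.sum(axis=0)
    out[cell.node] += reaction
    return reaction


def update_cell_position(
    cell_position: np.ndarray,
    force: np.ndarray,
    drag: float,
    dt: float,
    extents: np.ndarray | None = None,
) -> np.ndarray:
    """One overdamped Euler displacement, optionally clipped to the domain."""
    new = cell_position + force / drag * dt
    if extents is not None:
        new = np.clip(new, 0.0, np.asarray(extents, dtype=float))
    return new
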