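"""Cellular-scale rules: phenotype switching, migration, division placement.

Phenotype decision each hour (glucose first, then the signaling readout):

* glucose below the dead threshold        -> dead (absorbing)
* glucose between dead and active levels  -> reversible quiescence
* glucose at/above the active threshold   -> active; migration potential
  strictly above sigma selects migration, otherwise the proliferative track.

Offspring and migration targets are scored over free neighbour sites by
P_j = psi * G_j / F_j + (1 - psi) * eps_j with eps_j ~ N(0, 1); the argmax
free site wins, and a cell with no free neighbour falls back to quiescence
(division) or stays put (migration).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .signaling import PathwayState

__all__ = [
    "Phenotype",
    "CellAgent",
    "PhenotypeThresholds",
    "phenotype_switch",
    "offspring_site_choice",
    "divide",
    "migrate",
    "neighbor_sites",
]


class Phenotype(str, Enum):
    ACTIVE = "active"
    MIGRATORY = "migratory"
    PROLIFERATIVE = "proliferative"
    QUIESCENT = "quiescent"
    DEAD = "dead"


@dataclass
class CellAgent:
    position: tuple[int, int]
    age: float = 0.0  # hours since birth; reporting only
    phenotype: Phenotype = Phenotype.ACTIVE
    pathway: Optional[PathwayState] = None
    # step-local bookkeeping used by the census
    divided_this_step: bool = field(default=False, repr=False)
    reactivated_this_step: bool = field(default=False, repr=False)

    @property
    def alive(self) -> bool:
        return self.phenotype is not Phenotype.DEAD


@dataclass(frozen=True)
class PhenotypeThresholds:
    glucose_active: float
    glucose_dead: float
    sigma_plc: float
    thr1: float
    thr2: float
    psi: float = 0.7
    fibronectin_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not self.glucose_dead < self.glucose_active:
            raise ValueError("glucose_dead must be < glucose_active")
        if not 0.0 < self.psi < 1.0:
            raise ValueError("psi must lie in (0, 1)")


_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_VON_NEUMANN = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def neighbor_sites(
    pos: tuple[int, int], shape: tuple[int, int], neighborhood: str = "moore"
) -> list[tuple[int, int]]:
    """On-grid neighbour coordinates of ``pos`` (Moore by default)."""
    offsets = _MOORE if neighborhood == "moore" else _VON_NEUMANN
    i, j = pos
    return [
        (i + di, j + dj)
        for di, dj in offsets
        if 0 <= i + di < shape[0] and 0 <= j + dj < shape[1]
    ]


def phenotype_switch(
    cell: CellAgent,
    glucose_local: float,
    thresholds: PhenotypeThresholds,
    mp: float,
) -> Phenotype:
    """Classify a live cell for this step (does not mutate the agent)."""
    if not cell.alive:
        raise ValueError("dead cells do not switch phenotype")
    if glucose_local < thresholds.glucose_dead:
        return Phenotype.DEAD
    if glucose_local < thresholds.glucose_active:
        return Phenotype.QUIESCENT
    if mp > thresholds.sigma_plc:  # strict: equality stays proliferative
        return Phenotype.MIGRATORY
    return Phenotype.PROLIFERATIVE


def offspring_site_choice(
    neighbor_info: Sequence[tuple[float, float, bool]],
    psi: float,
    rng: np.random.Generator,
    fibronectin_floor: float = 1e-6,
) -> Optional[int]:
    """Pick the most attractive free neighbour.

    ``neighbor_info`` is a sequence of (glucose, fibronectin, free) triples.
    Scores P_j = psi * G_j / max(F_j, floor) + (1 - psi) * eps_j are computed
    for free sites only (one standard-normal draw per free site, in listing
    order); returns the index of the winning entry, or None when nothing is
    free.
    """
    free_idx = [k for k, (_, _, free) in enumerate(neighbor_info) if free]
    if not free_idx:
        return None
    scores = []
    for k in free_idx:
        g, f, _ = neighbor_info[k]
        eps = rng.standard_normal()
        scores.append(psi * g / max(f, fibronectin_floor) + (1.0 - psi) * eps)
    return free_idx[int(np.argmax(scores))]


def divide(
    cell: CellAgent,
    site: tuple[int, int],
    newborn_state: PathwayState,
    cycle_reset: PathwayState,
    occupied: set[tuple[int, int]],
) -> CellAgent:
    """Place an offspring at ``site`` and reset the parent's cell cycle.

    ``cycle_reset`` carries the parent's post-division pathway state (cell
    cycle species back at their newborn values).  ``occupied`` is the live+dead
    occupancy set and is updated in place.
    """
    if site in occupied:
        raise ValueError(f"division target {site} is occupied")
    child = CellAgent(
        position=site,
        age=0.0,
        phenotype=Phenotype.ACTIVE,
        pathway=newborn_state,
        divided_this_step=True,
    )
    cell.pathway = cycle_reset
    cell.divided_this_step = True
    occupied.add(site)
    return child


def migrate(
    cell: CellAgent,
    site: Optional[tuple[int, int]],
    occupied: set[tuple[int, int]],
) -> None:
    """Move a migratory cell one site (or stay when no free neighbour)."""
    if site is None:
        return
    if site in occupied:
        raise ValueError(f"migration target {site} is occupied")
    occupied.discard(cell.position)
    occupied.add(site)
    cell.position = site
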