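"""Tissue-scale vessel network: tip-cell migration, branching, anastomosis.

Tip endothelial cells move on the lattice under VEGF chemotaxis and
fibronectin haptotaxis.  Raw directional weights

    P_k = alpha * k_v / (k_v + V(i,j)) * dV_k + lambda * dF_k,   k = 1..4

(up, down, right, left; negative weights clamped to zero) plus a stationary
weight P_5 = mean(P_1..P_4) are normalised into a categorical distribution
whose cumulative intervals I_1..I_5 drive the stochastic branching and
migration rules.  Two rule sets are shipped:

* ``literal``     - branch when r1 in I2 and r2 in I3 (daughters placed below
                    and right); otherwise migrate right when r in I3.
* ``generalized`` - the move direction is sampled from I1..I5 directly, so
                    sprouts can also grow up, down and left.

A tip stepping onto an endothelial site of a different sprout fuses the two
sprouts (anastomosis); the moving tip is absorbed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .microenv import Field

__all__ = [
    "TipCell",
    "VesselNetwork",
    "MigrationDistribution",
    "tip_migration_distribution",
    "branch_or_migrate",
    "anastomosis_merge",
    "step_vessels",
]

# Direction offsets in lattice coordinates (i = x/column, j = y/row):
# P1 up (j+1), P2 down (j-1), P3 right (i+1), P4 left (i-1).
DIRECTIONS = [(0, 1), (0, -1), (1, 0), (-1, 0)]


@dataclass
class TipCell:
    position: tuple[int, int]
    sprout_id: int
    sprout_age: float = 0.0  # hours since this sprout was created
    parent_sprout: int = -1  # sprout this one branched from; never fused with


@dataclass
class MigrationDistribution:
    p_raw: np.ndarray  # un-normalised P1..P5 (>= 0)
    p_norm: np.ndarray  # normalised, sums to 1
    intervals: list[tuple[float, float]]  # half-open (lo, hi] partitioning (0, 1]

    def interval_contains(self, k: int, r: float) -> bool:
        lo, hi = self.intervals[k]
        return lo < r <= hi


@dataclass
class VesselNetwork:
    """Endothelial occupancy plus sprout bookkeeping."""

    shape: tuple[int, int]
    ec_sites: dict[tuple[int, int], int] = field(default_factory=dict)  # site -> sprout id
    tips: list[TipCell] = field(default_factory=list)
    edges: list[tuple[tuple[int, int], tuple[int, int], int, float]] = field(default_factory=list)
    next_sprout_id: int = 0
    merges: list[tuple[int, int]] = field(default_factory=list)  # (absorbed, surviving)

    @classmethod
    def with_parent_vessel(
        cls, shape: tuple[int, int], column: int, n_tips: int, rng: np.random.Generator
    ) -> "VesselNetwork":
        """A vertical parent vessel with evenly spaced sprout tips."""
        net = cls(shape=shape)
        parent_id = net.new_sprout_id()
        for j in range(shape[1]):
            net.ec_sites[(column, j)] = parent_id
        if n_tips > 0:
            rows = np.linspace(0, shape[1] - 1, n_tips + 2)[1:-1]
            for j in np.round(rows).astype(int):
                sid = net.new_sprout_id()
                net.tips.append(
                    TipCell(position=(column, int(j)), sprout_id=sid, parent_sprout=parent_id)
                )
                net.ec_sites[(column, int(j))] = sid
        return net

    def new_sprout_id(self) -> int:
        sid = self.next_sprout_id
        self.next_sprout_id += 1
        return sid

    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape)
        for (i, j) in self.ec_sites:
            m[i, j] = 1.0
        return m

    @property
    def ec_count(self) -> int:
        return len(self.ec_sites)

    def in_bounds(self, site: tuple[int, int]) -> bool:
        return 0 <= site[0] < self.shape[0] and 0 <= site[1] < self.shape[1]

    def free_neighbors(
        self, site: tuple[int, int], tumor_occupied: Iterable[tuple[int, int]] = ()
    ) -> set[tuple[int, int]]:
        blocked = set(tumor_occupied)
        out = set()
        for di, dj in DIRECTIONS:
            s = (site[0] + di, site[1] + dj)
            if self.in_bounds(s) and s not in self.ec_sites and s not in blocked:
                out.add(s)
        return out


def _grad_samples(grid: np.ndarray, i: int, j: int) -> list[float]:
    """Neighbour-minus-centre differences (up, down, right, left) with
    edge-mirrored (zero-flux) boundary values."""
    ni, nj = grid.shape

    def val(a: int, b: int) -> float:
        a = min(max(a, 0), ni - 1)
        b = min(max(b, 0), nj - 1)
        return float(grid[a, b])

    c = val(i, j)
    return [val(i + di, j + dj) - c for di, dj in DIRECTIONS]


def tip_migration_distribution(
    tip: TipCell,
    vegf: Field,
    fibronectin: Field,
    alpha: float,
    k_v: float,
    lam: float,
) -> MigrationDistribution:
    """Directional move distribution of one tip cell."""
    i, j = tip.position
    v_here = float(vegf.grid[i, j])
    chemo = alpha * k_v / (k_v + v_here)
    dv = _grad_samples(vegf.grid, i, j)
    df = _grad_samples(fibronectin.grid, i, j)
    raw = np.array([max(chemo * dv[k] + lam * df[k], 0.0) for k in range(4)])
    p5 = raw.mean()
    p_raw = np.append(raw, p5)
    total = p_raw.sum()
    if total <= 0.0:
        p_norm = np.array([0.0, 0.0, 0.0, 0.0, 1.0])  # degenerate: tip stays
    else:
        p_norm = p_raw / total
    cum = np.concatenate([[0.0], np.cumsum(p_norm)])
    cum[-1] = 1.0
    intervals = [(float(cum[k]), float(cum[k + 1])) for k in range(5)]
    return MigrationDistribution(p_raw=p_raw, p_norm=p_norm, intervals=intervals)


def anastomosis_merge(network: VesselNetwork, absorbed: int, surviving: int) -> None:
    """Fuse two sprouts: relabel sites and tips of ``absorbed``."""
    if absorbed == surviving:
        return
    for site, sid in network.ec_sites.items():
        if sid == absorbed:
            network.ec_sites[site] = surviving
    for t in network.tips:
        if t.sprout_id == absorbed:
            t.sprout_id = surviving
    network.merges.append((absorbed, surviving))


def _move_tip(
    network: VesselNetwork,
    tip: TipCell,
    target: tuple[int, int],
    tumor_occupied: set[tuple[int, int]],
    hour: float,
) -> bool:
    """Move ``tip`` onto ``target``; returns False when the tip was absorbed
    by anastomosis (or the move was skipped)."""
    if not network.in_bounds(target) or target in tumor_occupied:
        return True  # blocked: skip this move, tip persists
    owner = network.ec_sites.get(target)
    if owner is not None:
        if owner not in (tip.sprout_id, tip.parent_sprout):
            # Anastomosis: sprouts fuse, the moving tip is absorbed.
            anastomosis_merge(network, absorbed=tip.sprout_id, surviving=owner)
            network.edges.append((tip.position, target, owner, hour))
            network.tips.remove(tip)
            return False
        return True  # own stalk or origin vessel: skip
    network.edges.append((tip.position, target, tip.sprout_id, hour))
    network.ec_sites[target] = tip.sprout_id
    tip.position = target
    return True


def branch_or_migrate(
    network: VesselNetwork,
    tip: TipCell,
    dist: MigrationDistribution,
    vessel_age_ok: bool,
    free_neighbors: set[tuple[int, int]],
    rng: np.random.Generator,
    tumor_occupied: set[tuple[int, int]],
    hour: float = 0.0,
    mode: str = "literal",
) -> None:
    """Apply the stochastic branching/migration rule to one tip (in place)."""
    i, j = tip.position
    down = (i, j - 1)
    right = (i + 1, j)
    if vessel_age_ok and free_neighbors:
        r1, r2 = rng.uniform(), rng.uniform()
        if dist.interval_contains(1, r1) and dist.interval_contains(2, r2):
            # Branch: daughters one below and one to the right, ages reset.
            network.tips.remove(tip)
            for target in (down, right):
                if not network.in_bounds(target) or target in tumor_occupied:
                    continue
                owner = network.ec_sites.get(target)
                if owner is not None:
                    if owner not in (tip.sprout_id, tip.parent_sprout):
                        anastomosis_merge(network, absorbed=tip.sprout_id, surviving=owner)
                        network.edges.append((tip.position, target, owner, hour))
                    continue
                sid = network.new_sprout_id()
                network.ec_sites[target] = sid
                network.edges.append((tip.position, target, sid, hour))
                network.tips.append(
                    TipCell(position=target, sprout_id=sid, sprout_age=0.0,
                            parent_sprout=tip.sprout_id)
                )
            return
    if mode == "literal":
        r = rng.uniform()
        if dist.interval_contains(2, r):
            _move_tip(network, tip, right, tumor_occupied, hour)
        return
    # generalized mode: sample the direction from the full distribution
    r = rng.uniform()
    for k in range(5):
        if dist.interval_contains(k, r):
            if k == 4:
                return  # stationary
            di, dj = DIRECTIONS[k]
            _move_tip(network, tip, (i + di, j + dj), tumor_occupied, hour)
            return


def step_vessels(
    network: VesselNetwork,
    vegf: Field,
    fibronectin: Field,
    alpha: float,
    k_v: float,
    lam: float,
    branch_age: float,
    rng: np.random.Generator,
    tumor_occupied: set[tuple[int, int]],
    hour: float,
    dt: float = 1.0,
    mode: str = "literal",
) -> None:
    """Advance every sprout tip one agent step (in place)."""
    for tip in list(network.tips):
        if tip not in network.tips:  # absorbed by an earlier move this step
            continue
        dist = tip_migration_distribution(tip, vegf, fibronectin, alpha, k_v, lam)
        free = network.free_neighbors(tip.position, tumor_occupied)
        age_ok = tip.sprout_age > branch_age  # strict: 18 h exactly does not branch
        branch_or_migrate(
            network, tip, dist, age_ok, free, rng, tumor_occupied, hour=hour, mode=mode
        )
    for tip in network.tips:
        tip.sprout_age += dt
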