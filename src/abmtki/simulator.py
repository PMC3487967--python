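"""Hour-stepped orchestration of the four model scales.

Per step (in this order): extracellular fields advance; each active cell's
signaling network integrates one hour with its local ligand level and
drug-reduced receptor pool; cells switch phenotype, migrate and divide;
sprout tips migrate/branch/fuse; occupancy masks are rebuilt and the census
is appended.  All randomness flows from one master seed through named
child streams (init / agents / vessels), so identical configurations give
identical trajectories.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import agents as ag
from . import angiogenesis as angio
from . import microenv as me
from . import signaling as sig
from .config import SimConfig

logger = logging.getLogger(__name__)

__all__ = ["SimulationState", "RunResult", "build_pathway", "initialize", "step", "run"]

FIELD_NAMES = ["glucose", "oxygen", "tgfa", "vegf", "fibronectin", "tki"]

CENSUS_COLUMNS = [
    "hour",
    "n_active",
    "n_migratory",
    "n_proliferative",
    "n_quiescent",
    "n_dead",
    "n_live",
    "n_ec",
    "mean_plc_rate",
    "migration_events",
    "divisions",
]


@dataclass
class SimulationState:
    clock: float
    config: SimConfig
    pathway: sig.PathwaySpec
    binding: sig.TkiBinding
    fields: dict[str, me.Field]
    agents: list[ag.CellAgent]
    vessels: angio.VesselNetwork
    masks: me.OccupancyMasks
    rng_agents: np.random.Generator
    rng_vessels: np.random.Generator
    census: list[dict] = field(default_factory=list)
    cumulative_migration_events: int = 0
    cumulative_divisions: int = 0

    @property
    def live_agents(self) -> list[ag.CellAgent]:
        return [c for c in self.agents if c.alive]

    def occupied_sites(self) -> set[tuple[int, int]]:
        """Sites blocked for cell placement: any tumor cell (live or dead)."""
        return {c.position for c in self.agents}


@dataclass
class RunResult:
    state: SimulationState
    metrics: pd.DataFrame


def build_pathway(config: SimConfig) -> sig.PathwaySpec:
    """Pathway spec from the config: user table if given, else the default."""
    if config.pathway.table_path is not None:
        spec = sig.load_rate_table(config.pathway.table_path)
        if config.pathway.params:
            spec = spec.with_params(**config.pathway.params)
        if config.pathway.initial:
            spec = spec.with_initial(**config.pathway.initial)
        return spec
    return sig.default_pathway(params=config.pathway.params, initial=config.pathway.initial)


def _make_fields(config: SimConfig) -> dict[str, me.Field]:
    L = config.lattice_size
    shape = (L, L)

    def uniform(level: float) -> np.ndarray:
        return np.full(shape, level, dtype=float)

    g = config.glucose
    return {
        "glucose": me.Field(
            "glucose", uniform(g.initial), diffusivity=g.diffusivity, permeability=g.q,
            blood_level=g.blood_level, uptake=g.uptake,
        ),
        "oxygen": me.Field(
            "oxygen", uniform(config.oxygen.initial), diffusivity=config.oxygen.diffusivity,
            permeability=config.oxygen.permeability, blood_level=config.oxygen.blood_level,
            uptake=config.oxygen.uptake,
        ),
        "tgfa": me.Field(
            "tgfa", uniform(config.tgfa.initial), diffusivity=config.tgfa.diffusivity,
            permeability=config.tgfa.permeability, secretion=config.tgfa.secretion,
            decay=config.tgfa.decay,
        ),
        "vegf": me.Field(
            "vegf", uniform(config.vegf.initial), diffusivity=config.vegf.diffusivity,
            permeability=config.vegf.permeability, secretion=config.vegf.secretion,
            decay=config.vegf.decay,
        ),
        "fibronectin": me.Field(
            "fibronectin", uniform(config.fibronectin.initial),
            beta=config.fibronectin.beta, gamma=config.fibronectin.gamma,
        ),
        "tki": me.Field(
            "tki", uniform(0.0), diffusivity=config.tki.diffusivity,
            permeability=config.tki.permeability, blood_level=config.tki.blood_level,
            uptake=config.tki.uptake, decay=config.tki.decay,
        ),
    }


def _build_masks(state: SimulationState) -> me.OccupancyMasks:
    L = state.config.lattice_size
    x_tum = np.zeros((L, L))
    for c in state.agents:
        if c.alive:
            x_tum[c.position] = 1.0
    return me.OccupancyMasks(x_ves=state.vessels.mask(), x_tum=x_tum)


class ConfigurationError(ValueError):
    pass


def initialize(config: SimConfig) -> SimulationState:
    """Build the initial state: parent vessel + tips, tumor cluster, fields."""
    ss = np.random.SeedSequence(config.seed)
    seq_init, seq_agents, seq_vessels = ss.spawn(3)
    rng_init = np.random.default_rng(seq_init)

    pathway = build_pathway(config)
    binding = sig.TkiBinding(egfr0=config.pathway.egfr0, km=config.pathway.km)
    fields = _make_fields(config)
    vessels = angio.VesselNetwork.with_parent_vessel(
        (config.lattice_size, config.lattice_size),
        column=config.vessels.column,
        n_tips=config.vessels.n_tips,
        rng=rng_init,
    )

    L = config.lattice_size
    cx = int(round(config.tumor.center[0] * (L - 1)))
    cy = int(round(config.tumor.center[1] * (L - 1)))
    r = config.tumor.cluster_radius
    disc = [
        (i, j)
        for i in range(max(0, cx - r), min(L, cx + r + 1))
        for j in range(max(0, cy - r), min(L, cy + r + 1))
        if (i - cx) ** 2 + (j - cy) ** 2 <= r * r
    ]
    if any(site in vessels.ec_sites for site in disc):
        raise ConfigurationError("initial tumor cluster overlaps the vasculature")
    if len(disc) < config.tumor.n_cells:
        raise ConfigurationError(
            f"cluster radius {r} holds {len(disc)} sites < n_cells={config.tumor.n_cells}"
        )
    chosen = rng_init.choice(len(disc), size=config.tumor.n_cells, replace=False)
    x0 = pathway.initial_vector()
    cells = []
    for idx in chosen:
        age = float(rng_init.uniform(0.0, 24.0))
        # a cell of age a has already progressed its cycle by a hours, which
        # desynchronises the first division wave
        conc, rate = sig.integrate_population(
            pathway,
            x0[None, :].copy(),
            dt=age,
            tgf_local=np.array([0.0]),
            egfr_eff=np.array([config.pathway.egfr0]),
            n_substeps=max(1, int(np.ceil(age)) * config.pathway.n_substeps),
        )
        state0 = sig.PathwayState(conc=conc[0], plc_gamma_rate=float(rate[0]))
        cells.append(
            ag.CellAgent(
                position=disc[int(idx)],
                age=age,
                phenotype=ag.Phenotype.ACTIVE,
                pathway=state0,
            )
        )

    state = SimulationState(
        clock=0.0,
        config=config,
        pathway=pathway,
        binding=binding,
        fields=fields,
        agents=cells,
        vessels=vessels,
        masks=me.OccupancyMasks.empty((L, L)),
        rng_agents=np.random.default_rng(seq_agents),
        rng_vessels=np.random.default_rng(seq_vessels),
    )
    state.masks = _build_masks(state)
    _append_census(state, migration_events=0, divisions=0)
    return state


def _integrate_pathways(state: SimulationState) -> None:
    """Molecular scale: advance the network of every glucose-active cell."""
    cfg = state.config
    glucose = state.fields["glucose"].grid
    tgfa = state.fields["tgfa"].grid
    tki = state.fields["tki"].grid
    cells = [
        c for c in state.live_agents if glucose[c.position] >= cfg.cells.glucose_active
    ]
    if not cells:
        return
    conc = np.stack([c.pathway.conc for c in cells])
    tgf_local = np.array([tgfa[c.position] for c in cells]) * cfg.pathway.tgf_gain
    if cfg.treatment_on:
        egfr_eff = np.array(
            [sig.effective_egfr(state.binding, float(tki[c.position])) for c in cells]
        )
    else:
        egfr_eff = np.full(len(cells), state.binding.egfr0)
    new_conc, rates = sig.integrate_population(
        state.pathway, conc, cfg.dt, tgf_local, egfr_eff, n_substeps=cfg.pathway.n_substeps
    )
    for k, c in enumerate(cells):
        c.pathway = sig.PathwayState(conc=new_conc[k], plc_gamma_rate=float(rates[k]))


def _newborn_state(state: SimulationState) -> sig.PathwayState:
    return sig.PathwayState(conc=state.pathway.initial_vector(), plc_gamma_rate=0.0)


def _cycle_reset_state(state: SimulationState, parent: sig.PathwayState) -> sig.PathwayState:
    conc = parent.conc.copy()
    for species in ("CDh1", "cycCDK"):
        conc[state.pathway.index(species)] = state.pathway.initial[species]
    return sig.PathwayState(conc=conc, plc_gamma_rate=parent.plc_gamma_rate)


def _sigma(state: SimulationState) -> float:
    cfg = state.config.cells
    if cfg.sigma_mode == "population":
        rates = [c.pathway.plc_gamma_rate for c in state.live_agents]
        return float(np.mean(rates)) if rates else cfg.sigma_plc
    return cfg.sigma_plc


def _update_cells(state: SimulationState) -> tuple[int, int]:
    """Cellular scale; returns (migration events, divisions) this step."""
    cfg = state.config
    thresholds = ag.PhenotypeThresholds(
        glucose_active=cfg.cells.glucose_active,
        glucose_dead=cfg.cells.glucose_dead,
        sigma_plc=_sigma(state),
        thr1=cfg.cells.thr1,
        thr2=cfg.cells.thr2,
        psi=cfg.cells.psi,
        fibronectin_floor=cfg.cells.fibronectin_floor,
    )
    glucose = state.fields["glucose"].grid
    fibro = state.fields["fibronectin"].grid
    rng = state.rng_agents
    occupied = state.occupied_sites()
    migrations = 0
    divisions = 0

    live = state.live_agents
    order = rng.permutation(len(live))
    for idx in order:
        cell = live[int(idx)]
        cell.divided_this_step = False
        cell.reactivated_this_step = False
        was_quiescent = cell.phenotype is ag.Phenotype.QUIESCENT
        g_here = float(glucose[cell.position])
        phen = ag.phenotype_switch(
            cell, g_here, thresholds, mp=sig.migration_potential(cell.pathway)
        )
        if phen is ag.Phenotype.DEAD:
            cell.phenotype = phen
            continue
        cell.age += cfg.dt
        if phen is ag.Phenotype.QUIESCENT:
            cell.phenotype = phen
            continue
        if was_quiescent:
            cell.reactivated_this_step = True
        neighbors = ag.neighbor_sites(
            cell.position, (cfg.lattice_size, cfg.lattice_size), cfg.cells.neighborhood
        )
        # vessel sites do not block cells: capillaries and tumor cells
        # coexist on a site, only cell-cell exclusion applies
        info = [
            (float(glucose[s]), float(fibro[s]), s not in occupied)
            for s in neighbors
        ]
        if phen is ag.Phenotype.MIGRATORY:
            cell.phenotype = phen
            pick = ag.offspring_site_choice(
                info, thresholds.psi, rng, thresholds.fibronectin_floor
            )
            if pick is not None:
                ag.migrate(cell, neighbors[pick], occupied)
                migrations += 1
            continue
        # proliferative track
        cell.phenotype = ag.Phenotype.PROLIFERATIVE
        if sig.division_ready(cell.pathway, state.pathway, thresholds.thr1, thresholds.thr2):
            pick = ag.offspring_site_choice(
                info, thresholds.psi, rng, thresholds.fibronectin_floor
            )
            if pick is None:
                cell.phenotype = ag.Phenotype.QUIESCENT  # no free space: wait
                continue
            child = ag.divide(
                cell,
                neighbors[pick],
                newborn_state=_newborn_state(state),
                cycle_reset=_cycle_reset_state(state, cell.pathway),
                occupied=occupied,
            )
            state.agents.append(child)
            divisions += 1
    return migrations, divisions


def _append_census(state: SimulationState, migration_events: int, divisions: int) -> None:
    cfg = state.config
    live = state.live_agents
    counts = {p: 0 for p in ag.Phenotype}
    for c in state.agents:
        counts[c.phenotype] += 1
    if cfg.cells.active_includes_proliferative:
        n_active = (
            counts[ag.Phenotype.MIGRATORY]
            + counts[ag.Phenotype.PROLIFERATIVE]
            + counts[ag.Phenotype.ACTIVE]
        )
    else:
        n_active = sum(
            1
            for c in live
            if c.phenotype is ag.Phenotype.MIGRATORY
            or c.divided_this_step
            or c.reactivated_this_step
        )
    rates = [c.pathway.plc_gamma_rate for c in live]
    state.census.append(
        {
            "hour": state.clock,
            "n_active": n_active,
            "n_migratory": counts[ag.Phenotype.MIGRATORY],
            "n_proliferative": counts[ag.Phenotype.PROLIFERATIVE],
            "n_quiescent": counts[ag.Phenotype.QUIESCENT],
            "n_dead": counts[ag.Phenotype.DEAD],
            "n_live": len(live),
            "n_ec": state.vessels.ec_count,
            "mean_plc_rate": float(np.mean(rates)) if rates else 0.0,
            "migration_events": migration_events,
            "divisions": divisions,
        }
    )


def step(state: SimulationState, config: Optional[SimConfig] = None) -> SimulationState:
    """Advance the whole system by one agent step (in place)."""
    cfg = config or state.config
    if state.clock >= cfg.horizon and cfg.horizon > 0:
        raise RuntimeError("clock already at horizon")
    try:
        # (1) micro-environmental scale
        state.fields = me.step_all_fields(state.fields, state.masks, cfg.treatment_on, cfg.dt)
        # (2) molecular scale
        _integrate_pathways(state)
        # (3) cellular scale
        migrations, divisions = _update_cells(state)
        # (4) tissue scale
        angio.step_vessels(
            state.vessels,
            state.fields["vegf"],
            state.fields["fibronectin"],
            alpha=cfg.angio.alpha,
            k_v=cfg.angio.k_v,
            lam=cfg.angio.lam,
            branch_age=cfg.angio.branch_age,
            rng=state.rng_vessels,
            tumor_occupied=state.occupied_sites(),
            hour=state.clock,
            dt=cfg.dt,
            mode=cfg.angio.mode,
        )
        # (5) masks, (6) metrics
        state.masks = _build_masks(state)
        state.clock += cfg.dt
        state.cumulative_migration_events += migrations
        state.cumulative_divisions += divisions
        _append_census(state, migrations, divisions)
    except Exception as exc:
        raise RuntimeError(f"simulation step failed at t={state.clock} h: {exc}") from exc
    return state


def run(config: SimConfig) -> RunResult:
    """Execute a full run of ``horizon/dt`` steps from a fresh initial state."""
    state = initialize(config)
    for _ in range(config.n_steps):
        step(state)
    metrics = pd.DataFrame(state.census, columns=CENSUS_COLUMNS)
    logger.info(
        "run complete: %d steps, %d live cells, %d EC",
        config.n_steps,
        len(state.live_agents),
        state.vessels.ec_count,
    )
    return RunResult(state=state, metrics=metrics)
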