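"""Per-cell receptor-signaling / cell-cycle ODE network.

Each tumor cell carries a small reaction network: a growth-factor ligand
(``X1``) binds the receptor (``X2``), the activated receptor (``X4``) turns
over the effector phospholipase pool (``X5`` inactive / ``X6`` active), and a
two-species cell-cycle switch (``CDh1`` antagonised by ``cycCDK``) gates
division.  The network is declarative: a :class:`PathwaySpec` is a table of
signed rate-law terms (mass-action products, optionally saturated by a
Michaelis-Menten factor), so user-supplied kinetic tables can replace the
shipped default without code changes.

The cell's *migration potential* is the instantaneous rate of change of the
active effector concentration, d[X6]/dt.

Receptor blockade by a kinase inhibitor is reduced to a quasi-steady-state
occupancy: the drug-bound receptor fraction follows a Michaelis-Menten curve
in the local drug concentration, leaving ``EGFR_eff = EGFR0 * km/(km + Tki)``
available for signaling.
"""
from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

__all__ = [
    "Reaction",
    "PathwaySpec",
    "PathwayState",
    "TkiBinding",
    "default_pathway",
    "effective_egfr",
    "derivatives",
    "integrate_pathway",
    "integrate_population",
    "migration_potential",
    "division_ready",
    "load_rate_table",
    "save_rate_table",
]

PLC_SPECIES = "X6"
INPUT_SPECIES = "X1"
EGFR_SPECIES = "X2"


class PathwayConfigError(ValueError):
    """Raised when a rate table and a state disagree or a table is malformed."""


@dataclass(frozen=True)
class Reaction:
    """One signed rate-law term.

    rate = params[rate_const] * prod(conc[s]**e for s, e in order)
                              * (conc[mm[0]] / (params[mm[1]] + conc[mm[0]]))   # if mm

    ``stoich`` maps species -> signed stoichiometric coefficient; the term
    contributes ``coefficient * rate`` to each species derivative.
    """

    name: str
    rate_const: str
    order: Mapping[str, float] = field(default_factory=dict)
    stoich: Mapping[str, float] = field(default_factory=dict)
    mm: Optional[tuple[str, str]] = None  # (substrate species, K parameter name)


@dataclass
class PathwaySpec:
    """Declarative reaction network with named parameters and initial state."""

    species: list[str]
    reactions: list[Reaction]
    params: dict[str, float]
    initial: dict[str, float]
    clamped: frozenset[str] = frozenset({INPUT_SPECIES})

    def __post_init__(self) -> None:
        self.validate()
        self._index = {s: i for i, s in enumerate(self.species)}

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        declared = set(self.species)
        touched: set[str] = set()
        for rxn in self.reactions:
            used = set(rxn.order) | set(rxn.stoich)
            if rxn.mm is not None:
                used.add(rxn.mm[0])
                if rxn.mm[1] not in self.params:
                    raise PathwayConfigError(
                        f"reaction {rxn.name!r}: unknown MM constant {rxn.mm[1]!r}"
                    )
            undeclared = used - declared
            if undeclared:
                raise PathwayConfigError(
                    f"reaction {rxn.name!r} references undeclared species {sorted(undeclared)}"
                )
            if rxn.rate_const not in self.params:
                raise PathwayConfigError(
                    f"reaction {rxn.name!r}: unknown rate constant {rxn.rate_const!r}"
                )
            touched |= used
        unused = declared - touched
        if unused:
            raise PathwayConfigError(f"species never referenced by any reaction: {sorted(unused)}")
        for name, value in self.params.items():
            if not math.isfinite(value) or value < 0:
                raise PathwayConfigError(f"rate constant {name}={value!r} must be finite and >= 0")

    # -- helpers ------------------------------------------------------------
    def index(self, species: str) -> int:
        try:
            return self._index[species]
        except KeyError:
            raise PathwayConfigError(f"unknown species {species!r}") from None

    def initial_vector(self) -> np.ndarray:
        return np.array([self.initial.get(s, 0.0) for s in self.species], dtype=float)

    def with_params(self, **overrides: float) -> "PathwaySpec":
        params = dict(self.params)
        params.update(overrides)
        return PathwaySpec(
            species=list(self.species),
            reactions=list(self.reactions),
            params=params,
            initial=dict(self.initial),
            clamped=self.clamped,
        )

    def with_initial(self, **overrides: float) -> "PathwaySpec":
        initial = dict(self.initial)
        initial.update(overrides)
        return PathwaySpec(
            species=list(self.species),
            reactions=list(self.reactions),
            params=dict(self.params),
            initial=initial,
            clamped=self.clamped,
        )

    # -- vectorised right-hand side -----------------------------------------
    def rhs(self, conc: np.ndarray) -> np.ndarray:
        """Derivatives for a (..., n_species) concentration array.

        Clamped (externally driven) species get a zero derivative.
        """
        conc = np.asarray(conc, dtype=float)
        out = np.zeros_like(conc)
        for rxn in self.reactions:
            rate = np.full(conc.shape[:-1], self.params[rxn.rate_const])
            for sp, exp in rxn.order.items():
                x = conc[..., self.index(sp)]
                rate = rate * (x if exp == 1 else x**exp)
            if rxn.mm is not None:
                sub = conc[..., self.index(rxn.mm[0])]
                rate = rate * sub / (self.params[rxn.mm[1]] + sub)
            for sp, coeff in rxn.stoich.items():
                out[..., self.index(sp)] += coeff * rate
        for sp in self.clamped:
            out[..., self.index(sp)] = 0.0
        return out


@dataclass
class PathwayState:
    """Per-cell concentrations plus the cached effector rate (d[X6]/dt)."""

    conc: np.ndarray
    plc_gamma_rate: float = 0.0

    def concentrations(self, spec: PathwaySpec) -> dict[str, float]:
        if self.conc.shape != (len(spec.species),):
            raise PathwayConfigError(
                f"state has {self.conc.shape[0]} species, spec declares {len(spec.species)}"
            )
        return {s: float(self.conc[i]) for i, s in enumerate(spec.species)}


@dataclass(frozen=True)
class TkiBinding:
    """Quasi-steady-state receptor/inhibitor binding parameters."""

    egfr0: float
    km: float  # ~ k_b / k_u

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ValueError("km must be > 0")
        if self.egfr0 < 0:
            raise ValueError("egfr0 must be >= 0")


def effective_egfr(binding: TkiBinding, tki_local: float) -> float:
    """Receptor amount left available for downstream activation.

    EGFR_eff = EGFR0 - EGFR0 * Tki / (km + Tki); monotone decreasing in the
    local drug concentration, bounded in [0, EGFR0].
    """
    if tki_local < 0:
        raise ValueError(f"tki_local must be >= 0, got {tki_local}")
    bound = binding.egfr0 * tki_local / (binding.km + tki_local)
    return binding.egfr0 - bound


def _apply_inputs(spec: PathwaySpec, conc: np.ndarray, tgf_local, egfr_eff) -> np.ndarray:
    """Drive the ligand input species and cap the free receptor pool."""
    conc = np.array(conc, dtype=float, copy=True)
    conc[..., spec.index(INPUT_SPECIES)] = tgf_local
    i2 = spec.index(EGFR_SPECIES)
    conc[..., i2] = np.minimum(conc[..., i2], egfr_eff)
    return conc


def derivatives(
    spec: PathwaySpec,
    state: PathwayState,
    tgf_local: float,
    egfr_eff: float,
) -> np.ndarray:
    """Rate vector dX/dt at the stored concentrations.

    The ligand species is clamped to ``tgf_local`` (its derivative is zero)
    and the free receptor is capped at ``egfr_eff`` before evaluation.
    """
    if tgf_local < 0 or egfr_eff < 0:
        raise ValueError("tgf_local and egfr_eff must be >= 0")
    if np.shape(state.conc) != (len(spec.species),):
        raise PathwayConfigError("state/spec species mismatch")
    conc = _apply_inputs(spec, state.conc, tgf_local, egfr_eff)
    return spec.rhs(conc)


def migration_potential(state: PathwayState) -> float:
    """The cell's migration potential: the stored d[X6]/dt."""
    return state.plc_gamma_rate


def division_ready(state: PathwayState, spec: PathwaySpec, thr1: float, thr2: float) -> bool:
    """True iff [CDh1] < thr1 and [cycCDK] > thr2 (both strict)."""
    if thr1 <= 0 or thr2 <= 0:
        raise ValueError("thresholds must be > 0")
    cdh1 = state.conc[spec.index("CDh1")]
    cyc = state.conc[spec.index("cycCDK")]
    return bool(cdh1 < thr1 and cyc > thr2)


class IntegrationError(RuntimeError):
    pass


def integrate_pathway(
    spec: PathwaySpec,
    state: PathwayState,
    dt: float,
    tgf_local: float = 0.0,
    egfr_eff: float = math.inf,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> PathwayState:
    """Advance one cell's network by ``dt`` hours (adaptive, stiff-capable).

    Uses LSODA with the given tolerances; concentrations are clamped at zero
    (clamping is logged) and the effector rate is re-evaluated at the end
    point.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    conc0 = _apply_inputs(spec, state.conc, tgf_local, egfr_eff)

    def rhs(_t, y):
        return spec.rhs(y)

    sol = solve_ivp(rhs, (0.0, dt), conc0, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"pathway integration failed: {sol.message}")
    conc = sol.y[:, -1]
    if np.any(conc < 0):
        worst = float(conc.min())
        if worst < -10 * atol:
            logger.warning("clamped negative concentration %.3e to 0", worst)
        conc = np.maximum(conc, 0.0)
    rate = spec.rhs(conc)[spec.index(PLC_SPECIES)]
    return PathwayState(conc=conc, plc_gamma_rate=float(rate))


def integrate_population(
    spec: PathwaySpec,
    conc: np.ndarray,
    dt: float,
    tgf_local: np.ndarray,
    egfr_eff: np.ndarray,
    n_substeps: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance many cells at once with fixed-step RK4.

    ``conc`` has shape (n_cells, n_species); ``tgf_local`` and ``egfr_eff``
    are per-cell scalars.  Returns (new concentrations, d[X6]/dt per cell).
    The default network is non-stiff at the shipped rates, so 10 RK4
    substeps per hour agree with the adaptive integrator to ~1e-8.
    """
    y0 = _apply_inputs(spec, conc, np.asarray(tgf_local), np.asarray(egfr_eff))
    # step-doubling guard: fold-changed rate tables can make the fixed step
    # unstable, so retry with finer substeps until the solution is finite
    n = n_substeps
    max_n = max(n_substeps, 1) * 64
    while True:
        y = y0.copy()
        h = dt / n
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(n):
                k1 = spec.rhs(y)
                k2 = spec.rhs(y + 0.5 * h * k1)
                k3 = spec.rhs(y + 0.5 * h * k2)
                k4 = spec.rhs(y + h * k3)
                y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                np.maximum(y, 0.0, out=y)
        if np.all(np.isfinite(y)) and np.all(np.abs(y) < 1e6):
            break
        if n >= max_n:
            raise IntegrationError("population integrator failed to stabilise")
        n *= 4
        logger.debug("unstable pathway step; retrying with %d substeps", n)
    rate = spec.rhs(y)[..., spec.index(PLC_SPECIES)]
    return y, rate


# ---------------------------------------------------------------------------
# Default network
# ---------------------------------------------------------------------------

#: Documented stand-in for the unpublished kinetic tables.  Topology: ligand
#: binding -> receptor autophosphorylation -> effector activation, coupled to
#: a CDh1/cycCDK antagonism cell-cycle switch.  Species:
#:   X1  ligand (TGFa, clamped to the local extracellular level)
#:   X2  free receptor (EGFR)
#:   X3  ligand:receptor complex
#:   X4  autophosphorylated (active) receptor
#:   X5  inactive effector (PLCg)
#:   X6  active effector (PLCg*); d[X6]/dt is the migration potential
#:   CDh1, cycCDK  cell-cycle antagonists
DEFAULT_PARAMS: dict[str, float] = {
    "k1": 0.4,     # ligand-receptor association
    "k1r": 0.05,   # complex dissociation
    "k2": 0.6,     # receptor autophosphorylation
    "k3": 0.08,    # active-receptor dephosphorylation / recycling
    "kf": 0.5,     # effector-mediated receptor desensitisation (neg. feedback)
    "k12": 0.03,   # ligand-stimulated receptor recruitment
    "V4": 3.0,     # effector activation Vmax (cooperative in active receptor)
    "K4": 0.1,     # effector activation Michaelis constant
    "k5": 0.06,    # effector deactivation
    "k6": 0.008,   # signal-driven cycCDK synthesis Vmax
    "K6": 0.02,    # saturation of the cycCDK drive in X4
    "k60": 0.04,   # basal cycCDK synthesis
    "k7": 0.6,     # cycCDK degradation promoted by CDh1
    "k7d": 0.02,   # basal cycCDK decay
    "k8": 0.01,    # CDh1 synthesis
    "k9": 1.0,     # CDh1 inactivation promoted by cycCDK
    "k9d": 0.005,  # basal CDh1 decay
}

DEFAULT_INITIAL: dict[str, float] = {
    "X1": 0.2,
    "X2": 1.0,
    "X3": 0.0,
    "X4": 0.0,
    "X5": 0.95,
    "X6": 0.05,
    "CDh1": 0.9,
    "cycCDK": 0.05,
}


def _default_reactions() -> list[Reaction]:
    return [
        Reaction("bind", "k1", {"X1": 1, "X2": 1}, {"X1": -1, "X2": -1, "X3": 1}),
        Reaction("unbind", "k1r", {"X3": 1}, {"X3": -1, "X1": 1, "X2": 1}),
        Reaction("phosphorylate", "k2", {"X3": 1}, {"X3": -1, "X4": 1}),
        Reaction("recycle", "k3", {"X4": 1}, {"X4": -1, "X2": 1}),
        Reaction("desensitize", "kf", {"X6": 1, "X4": 1}, {"X4": -1, "X2": 1}),
        Reaction("recruit", "k12", {"X1": 1}, {"X2": 1}),
        # cooperative activation by the phosphorylated receptor (second order
        # in X4), saturating in the inactive effector pool
        Reaction("activate_plc", "V4", {"X4": 2}, {"X5": -1, "X6": 1}, mm=("X5", "K4")),
        Reaction("deactivate_plc", "k5", {"X6": 1}, {"X6": -1, "X5": 1}),
        Reaction("cyc_drive", "k6", {}, {"cycCDK": 1}, mm=("X4", "K6")),
        Reaction("cyc_basal", "k60", {}, {"cycCDK": 1}),
        Reaction("cyc_deg", "k7", {"CDh1": 1, "cycCDK": 1}, {"cycCDK": -1}),
        Reaction("cyc_decay", "k7d", {"cycCDK": 1}, {"cycCDK": -1}),
        Reaction("cdh1_synth", "k8", {}, {"CDh1": 1}),
        Reaction("cdh1_inact", "k9", {"cycCDK": 1, "CDh1": 1}, {"CDh1": -1}),
        Reaction("cdh1_decay", "k9d", {"CDh1": 1}, {"CDh1": -1}),
    ]


def default_pathway(
    params: Optional[Mapping[str, float]] = None,
    initial: Optional[Mapping[str, float]] = None,
) -> PathwaySpec:
    """The shipped default network, optionally with parameter overrides."""
    p = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise PathwayConfigError(f"unknown rate-constant overrides: {sorted(unknown)}")
        p.update(params)
    x0 = dict(DEFAULT_INITIAL)
    if initial:
        unknown = set(initial) - set(x0)
        if unknown:
            raise PathwayConfigError(f"unknown initial-concentration overrides: {sorted(unknown)}")
        x0.update(initial)
    return PathwaySpec(
        species=list(DEFAULT_INITIAL),
        reactions=_default_reactions(),
        params=p,
        initial=x0,
    )


# ---------------------------------------------------------------------------
# Tabular rate-law interchange format
# ---------------------------------------------------------------------------

_TABLE_FIELDS = ["name", "rate_const", "order", "mm", "stoich"]


def _fmt_pairs(d: Mapping[str, float]) -> str:
    return ",".join(f"{k}:{v:g}" for k, v in d.items())


def _parse_pairs(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    text = text.strip()
    if not text:
        return out
    for item in text.split(","):
        key, _, val = item.partition(":")
        out[key.strip()] = float(val)
    return out


def save_rate_table(spec: PathwaySpec, path: str | Path) -> None:
    """Write the network as a TSV: reaction rows, then #param/#initial lines."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_TABLE_FIELDS, delimiter="\t")
        writer.writeheader()
        for rxn in spec.reactions:
            writer.writerow(
                {
                    "name": rxn.name,
                    "rate_const": rxn.rate_const,
                    "order": _fmt_pairs(rxn.order),
                    "mm": f"{rxn.mm[0]}/{rxn.mm[1]}" if rxn.mm else "",
                    "stoich": _fmt_pairs(rxn.stoich),
                }
            )
        for name, value in spec.params.items():
            fh.write(f"#param\t{name}\t{value!r}\n")
        for name, value in spec.initial.items():
            fh.write(f"#initial\t{name}\t{value!r}\n")
        fh.write(f"#clamped\t{','.join(sorted(spec.clamped))}\n")


def load_rate_table(path: str | Path) -> PathwaySpec:
    """Load a network written by :func:`save_rate_table` (or hand-authored)."""
    path = Path(path)
    reactions: list[Reaction] = []
    params: dict[str, float] = {}
    initial: dict[str, float] = {}
    clamped: set[str] = {INPUT_SPECIES}
    header: Optional[list[str]] = None
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#param\t"):
                _, name, value = line.split("\t")
                params[name] = float(value)
                continue
            if line.startswith("#initial\t"):
                _, name, value = line.split("\t")
                initial[name] = float(value)
                continue
            if line.startswith("#clamped\t"):
                clamped = set(line.split("\t")[1].split(","))
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                if header != _TABLE_FIELDS:
                    raise PathwayConfigError(
                        f"bad rate-table header {header!r}, expected {_TABLE_FIELDS!r}"
                    )
                continue
            row = dict(zip(header, cells))
            mm = None
            if row.get("mm", "").strip():
                sub, _, kname = row["mm"].partition("/")
                mm = (sub.strip(), kname.strip())
            reactions.append(
                Reaction(
                    name=row["name"],
                    rate_const=row["rate_const"],
                    order=_parse_pairs(row.get("order", "")),
                    stoich=_parse_pairs(row["stoich"]),
                    mm=mm,
                )
            )
    species = list(initial)
    return PathwaySpec(
        species=species,
        reactions=reactions,
        params=params,
        initial=initial,
        clamped=frozenset(clamped),
    )
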