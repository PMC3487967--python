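"""Derived metrics and the sensitivity / robustness statistics.

Sensitivity: each pathway parameter (kinetic rates and initial
concentrations) is perturbed one at a time by +/-10%, a single reference
cell is re-integrated, and the relative response of the migration potential
is expressed as the local sensitivity coefficient

    S = (dMP / MP) / (dP / P).

The migration-potential readout is the mean rate of change of the active
effector over the readout window, (X6(T) - X6(0)) / T, which is the windowed
version of the instantaneous d[X6]/dt.

Robustness: one parameter at a time is scaled by a fold factor, the full
lattice model is run to a readout hour, and the active-cell number (ACN) is
compared against a stochastic reference baseline through

    R = (ACN_p - ACN_0) / ACN_0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import signaling as sig
from .config import SimConfig
from .simulator import run

logger = logging.getLogger(__name__)

__all__ = [
    "sensitivity_coefficient",
    "reference_migration_potential",
    "sensitivity_scan",
    "robustness_index",
    "RobustnessResult",
    "robustness_protocol",
    "cv_of_outcomes",
    "survival_percentage",
    "proliferation_rate",
    "acn_at",
]

#: Parameters highlighted by the robustness protocol: three initial
#: concentrations and six kinetic rates.
ROBUSTNESS_PARAMS = ["X1", "X2", "X6", "k1", "k2", "k3", "k5", "K4", "V4"]
ROBUSTNESS_FOLDS = [0.1, 2.0, 5.0, 10.0, 50.0, 100.0]


def sensitivity_coefficient(mp_base: float, mp_pert: float, rel_delta: float) -> float:
    """Local sensitivity S = ((MP_p - MP_0)/MP_0) / rel_delta."""
    if mp_base == 0:
        raise ZeroDivisionError("sensitivity undefined for zero baseline migration potential")
    if rel_delta == 0:
        raise ValueError("rel_delta must be non-zero")
    return ((mp_pert - mp_base) / mp_base) / rel_delta


def _windowed_mp(
    spec: sig.PathwaySpec,
    tgf: float,
    egfr_eff: float,
    hours: float,
    substeps_per_hour: int = 10,
) -> float:
    """Mean d[X6]/dt of one cell over [0, hours] at fixed inputs."""
    conc = spec.initial_vector()[None, :]
    x6 = spec.index(sig.PLC_SPECIES)
    start = float(conc[0, x6])
    conc, _ = sig.integrate_population(
        spec,
        conc,
        dt=hours,
        tgf_local=np.array([tgf]),
        egfr_eff=np.array([egfr_eff]),
        n_substeps=int(substeps_per_hour * hours),
    )
    return (float(conc[0, x6]) - start) / hours


def reference_migration_potential(
    spec: sig.PathwaySpec,
    tgf: float,
    egfr_eff: float,
    hours: float = 24.0,
) -> float:
    """Baseline MP readout for the sensitivity scan."""
    return _windowed_mp(spec, tgf, egfr_eff, hours)


def sensitivity_scan(
    spec: Optional[sig.PathwaySpec] = None,
    tgf: float = 0.2,
    egfr_eff: float = 1.0,
    hours: float = 24.0,
    rel_deltas: Sequence[float] = (0.10, -0.10),
    parameters: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One-at-a-time +/-10% scan over kinetic rates and initial levels.

    Returns a frame with one row per (parameter, delta):
    ``parameter, kind, delta, mp, S, pct_change`` where ``pct_change`` is the
    percentage change of MP (100 * dMP/MP), the scale on which the scan's
    headline bound is quoted.
    """
    spec = spec or sig.default_pathway()
    mp0 = _windowed_mp(spec, tgf, egfr_eff, hours)
    rows = []
    rate_names = sorted(spec.params)
    init_names = [s for s in spec.species]
    wanted = set(parameters) if parameters is not None else None
    for name in rate_names + init_names:
        if wanted is not None and name not in wanted:
            continue
        kind = "rate" if name in spec.params else "initial"
        for delta in rel_deltas:
            if kind == "rate":
                pert = spec.with_params(**{name: spec.params[name] * (1.0 + delta)})
                mp = _windowed_mp(pert, tgf, egfr_eff, hours)
            elif name == sig.INPUT_SPECIES:
                # the ligand input is clamped: its "initial concentration"
                # is the sustained input level
                mp = _windowed_mp(spec, tgf * (1.0 + delta), egfr_eff, hours)
            else:
                base = spec.initial.get(name, 0.0)
                pert = spec.with_initial(**{name: base * (1.0 + delta)})
                eff = egfr_eff
                if name == sig.EGFR_SPECIES:
                    eff = egfr_eff * (1.0 + delta)
                mp = _windowed_mp(pert, tgf, eff, hours)
            s = sensitivity_coefficient(mp0, mp, delta)
            rows.append(
                {
                    "parameter": name,
                    "kind": kind,
                    "delta": delta,
                    "mp": mp,
                    "S": s,
                    "pct_change": 100.0 * (mp - mp0) / mp0,
                }
            )
    return pd.DataFrame(rows)


def robustness_index(acn_p: float, acn_0: float) -> float:
    """R = (ACN_p - ACN_0) / ACN_0."""
    if acn_0 <= 0:
        raise ZeroDivisionError("robustness undefined for non-positive baseline ACN")
    return (acn_p - acn_0) / acn_0


def cv_of_outcomes(acn_values: Sequence[float]) -> float:
    """Sample standard deviation over mean of the pooled outcomes."""
    values = np.asarray(list(acn_values), dtype=float)
    if values.size < 2:
        raise ValueError("need at least two outcomes for a coefficient of variation")
    mean = values.mean()
    if mean == 0:
        raise ZeroDivisionError("coefficient of variation undefined for zero mean")
    return float(values.std(ddof=1) / mean)


def acn_at(metrics: pd.DataFrame, hour: float) -> float:
    """Active-cell number at (or at the last record before) ``hour``."""
    sel = metrics[metrics["hour"] <= hour + 1e-9]
    if sel.empty:
        raise ValueError(f"no census rows at or before hour {hour}")
    return float(sel.iloc[-1]["n_active"])


def _fold_config(config: SimConfig, param: str, fold: float) -> SimConfig:
    """Config with one pathway parameter scaled by ``fold``."""
    data = config.model_dump()
    pw = data["pathway"]
    if param == "X1":
        pw["tgf_gain"] = config.pathway.tgf_gain * fold
    elif param == "X2":
        base = sig.DEFAULT_INITIAL["X2"]
        base = config.pathway.initial.get("X2", base)
        pw["initial"] = {**pw["initial"], "X2": base * fold}
        pw["egfr0"] = config.pathway.egfr0 * fold
    elif param == "X6":
        base = config.pathway.initial.get("X6", sig.DEFAULT_INITIAL["X6"])
        pw["initial"] = {**pw["initial"], "X6": base * fold}
    else:
        base = config.pathway.params.get(param, sig.DEFAULT_PARAMS[param])
        pw["params"] = {**pw["params"], param: base * fold}
    return SimConfig(**data)


@dataclass
class RobustnessResult:
    acn_0: float  # baseline mean active-cell number
    baseline_values: list[float]
    table: pd.DataFrame  # parameter, fold, mean ACN, R
    runs: pd.DataFrame  # one row per simulation: parameter, fold, acn
    cv: float  # CV of the pooled fold-change outcomes

    def max_abs_r(
        self,
        exclude: Iterable[str] = (),
        max_fold: Optional[float] = None,
    ) -> float:
        t = self.table
        mask = ~t["parameter"].isin(set(exclude))
        if max_fold is not None:
            mask &= t["fold"] <= max_fold
        return float(t.loc[mask, "R"].abs().max())


def robustness_protocol(
    config: SimConfig,
    params: Sequence[str] = tuple(ROBUSTNESS_PARAMS),
    folds: Sequence[float] = (0.1, 2.0, 5.0, 10.0),
    n_baseline: int = 100,
    replicates_per_fold: int = 1,
    readout_hour: float = 100.0,
    base_seed: int = 0,
) -> RobustnessResult:
    """One-at-a-time fold-change experiment on the full lattice model.

    ``n_baseline`` reference runs (different seeds) define ACN_0; each
    (parameter, fold) condition is run ``replicates_per_fold`` times and its
    mean ACN gives R.  The CV pools the per-run fold-change outcomes.
    """
    horizon = max(config.horizon, readout_hour)
    base = config.model_copy(update={"horizon": horizon})
    baseline_values = []
    for k in range(n_baseline):
        cfg = base.model_copy(update={"seed": base_seed + k})
        baseline_values.append(acn_at(run(cfg).metrics, readout_hour))
    acn_0 = float(np.mean(baseline_values))
    logger.info("baseline ACN_0 = %.2f over %d runs", acn_0, n_baseline)

    rows = []
    run_rows = []
    seed = base_seed + n_baseline
    for param in params:
        for fold in folds:
            cfg_f = _fold_config(base, param, fold)
            acns = []
            for _ in range(replicates_per_fold):
                cfg = cfg_f.model_copy(update={"seed": seed})
                seed += 1
                acns.append(acn_at(run(cfg).metrics, readout_hour))
            acn_p = float(np.mean(acns))
            run_rows.extend(
                {"parameter": param, "fold": fold, "acn": a} for a in acns
            )
            rows.append(
                {
                    "parameter": param,
                    "fold": fold,
                    "acn": acn_p,
                    "R": robustness_index(acn_p, acn_0),
                }
            )
    table = pd.DataFrame(rows)
    runs_df = pd.DataFrame(run_rows, columns=["parameter", "fold", "acn"])
    pooled = runs_df["acn"].tolist()
    return RobustnessResult(
        acn_0=acn_0,
        baseline_values=baseline_values,
        table=table,
        runs=runs_df,
        cv=cv_of_outcomes(pooled) if len(pooled) >= 2 else float("nan"),
    )


def survival_percentage(
    viable_treated: Sequence[float], viable_reference: Sequence[float]
) -> np.ndarray:
    """100 * treated / reference, element-wise; NaN where the reference is 0."""
    t = np.asarray(viable_treated, dtype=float)
    r = np.asarray(viable_reference, dtype=float)
    if t.shape != r.shape:
        raise ValueError("series must be aligned in time")
    out = np.full(t.shape, np.nan)
    ok = r != 0
    out[ok] = 100.0 * t[ok] / r[ok]
    return out


def proliferation_rate(viable: pd.Series, window: float = 24.0) -> pd.Series:
    """Fold growth of the viable count per trailing window.

    rate(t) = (N(t) - N(t - window)) / N(t - window); NaN before one full
    window has elapsed or where the earlier count is zero.
    """
    if window < 1:
        raise ValueError("window must be >= 1 h")
    hours = viable.index.to_numpy(dtype=float)
    values = viable.to_numpy(dtype=float)
    out = np.full(values.shape, np.nan)
    for k, t in enumerate(hours):
        prev = np.nonzero(np.isclose(hours, t - window))[0]
        if prev.size and values[prev[0]] != 0:
            out[k] = (values[k] - values[prev[0]]) / values[prev[0]]
    return pd.Series(out, index=viable.index, name="proliferation_rate")
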