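"""Finite-difference reaction-diffusion solvers for the extracellular fields.

All diffusible fields share one PDE form on the square lattice:

    du/dt = D * Lap(u) + X_ves * q * (u_blood - u) + X_tum * (S - U) - delta * u

with homogeneous Neumann (zero-flux) boundaries, discretised with the 5-point
Laplacian and explicit forward-Euler substeps bounded by the stability limit
dt_sub <= h^2 / (4 D).  Fibronectin has no diffusion term and uses the local
update  dF/dt = X_ves * beta - X_tum * gamma * F.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["Field", "OccupancyMasks", "rd_step", "fibronectin_step", "step_all_fields"]

#: Safety factor under the explicit stability bound h^2/(4D).
_STABILITY_SAFETY = 0.9


class FieldNumericsError(RuntimeError):
    pass


@dataclass
class Field:
    """One lattice-registered concentration grid with its PDE coefficients."""

    name: str
    grid: np.ndarray
    diffusivity: float = 0.0
    permeability: float = 0.0  # q, transvascular exchange rate
    blood_level: float = 0.0
    uptake: float = 0.0  # U, per tumor-occupied site
    secretion: float = 0.0  # S, per tumor-occupied site
    decay: float = 0.0  # delta
    beta: float = 0.0  # fibronectin secretion per vessel site
    gamma: float = 0.0  # fibronectin uptake rate at tumor sites
    spacing: float = 1.0  # lattice spacing h in the units of diffusivity

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("field grid must be 2-D")

    def copy(self) -> "Field":
        out = Field(**{k: v for k, v in self.__dict__.items()})
        out.grid = self.grid.copy()
        return out


@dataclass
class OccupancyMasks:
    """Indicator grids: x_ves marks endothelial sites, x_tum live tumor sites."""

    x_ves: np.ndarray
    x_tum: np.ndarray

    def __post_init__(self) -> None:
        self.x_ves = np.asarray(self.x_ves, dtype=float)
        self.x_tum = np.asarray(self.x_tum, dtype=float)
        for m in (self.x_ves, self.x_tum):
            vals = np.unique(m)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("occupancy masks must be 0/1 valued")
        if self.x_ves.shape != self.x_tum.shape:
            raise ValueError("mask shapes differ")

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "OccupancyMasks":
        return cls(np.zeros(shape), np.zeros(shape))


def neumann_laplacian(u: np.ndarray, h: float = 1.0) -> np.ndarray:
    """5-point Laplacian with zero-flux boundaries via ghost-cell mirroring."""
    p = np.pad(u, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * u) / (h * h)


def _n_substeps(field: Field, dt: float, max_substep: float | None) -> int:
    limit = dt
    if field.diffusivity > 0:
        limit = min(limit, _STABILITY_SAFETY * field.spacing**2 / (4.0 * field.diffusivity))
    if max_substep is not None:
        limit = min(limit, max_substep)
    n = max(1, math.ceil(dt / limit - 1e-12))
    if n > 1:
        logger.debug("field %s: %d explicit substeps for dt=%g", field.name, n, dt)
    return n


def rd_step(
    field: Field,
    masks: OccupancyMasks,
    dt: float,
    max_substep: float | None = None,
) -> Field:
    """Advance one diffusible field by ``dt`` hours (returns a new Field).

    ``max_substep`` optionally forces finer explicit substeps than the
    stability bound requires (used by high-accuracy oracle comparisons).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if masks.x_ves.shape != field.grid.shape:
        raise ValueError("mask/grid shape mismatch")
    out = field.copy()
    u = out.grid
    n = _n_substeps(field, dt, max_substep)
    h = dt / n
    src_tum = masks.x_tum * (field.secretion - field.uptake)
    clamped = 0
    for _ in range(n):
        du = src_tum - field.decay * u
        if field.diffusivity > 0:
            du = du + field.diffusivity * neumann_laplacian(u, field.spacing)
        if field.permeability > 0:
            du = du + masks.x_ves * field.permeability * (field.blood_level - u)
        u = u + h * du
        neg = u < 0
        if neg.any():
            clamped += int(neg.sum())
            u[neg] = 0.0
    if not np.all(np.isfinite(u)):
        raise FieldNumericsError(f"non-finite values in field {field.name!r} after rd_step")
    if clamped:
        logger.warning("field %s: clamped %d negative values to 0", field.name, clamped)
    out.grid = u
    return out


def fibronectin_step(field: Field, masks: OccupancyMasks, dt: float) -> Field:
    """Per-site fibronectin update: dF/dt = X_ves*beta - X_tum*gamma*F."""
    out = field.copy()
    f = out.grid + dt * (masks.x_ves * field.beta - masks.x_tum * field.gamma * out.grid)
    np.maximum(f, 0.0, out=f)
    out.grid = f
    return out


def step_all_fields(
    fields: dict[str, Field],
    masks: OccupancyMasks,
    treatment_on: bool,
    dt: float,
) -> dict[str, Field]:
    """Advance every field one agent step; the drug field only under treatment."""
    out: dict[str, Field] = {}
    for name, fld in fields.items():
        if name == "fibronectin":
            out[name] = fibronectin_step(fld, masks, dt)
        elif name == "tki" and not treatment_on:
            out[name] = fld.copy()
        else:
            out[name] = rd_step(fld, masks, dt)
    return out
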