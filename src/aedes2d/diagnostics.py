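"""Domain-integrated population totals, insecticide-effect reductions and
solver-health checks.

The headline observables of an insecticide comparison are the domain
integrals of the *total* populations, ``int psi*M dOmega`` and
``int psi*A dOmega`` (midpoint quadrature on the cell-centered mesh), and
the percent reduction of a treated run against an untreated baseline at a
chosen evaluation day (default: the end of the six-week run).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .geometry import Grid, RegionMap

__all__ = [
    "SimulationResult",
    "total_population",
    "reduction_percentage",
    "health_report",
]


@dataclass
class SimulationResult:
    """Output of one scenario run.

    ``snapshots`` holds ``(t, psi*M, psi*A)`` gridded fields; ``totals`` is
    a tidy frame with columns ``t_days``, ``winged``, ``aquatic`` holding
    the domain integrals over time.
    """

    snapshots: list[tuple[float, np.ndarray, np.ndarray]]
    totals: pd.DataFrame
    config: Any
    grid: Grid
    regions: RegionMap
    psi: np.ndarray
    reports: list[Any] = field(default_factory=list)
    final_state: Any = None
    boundary_flux: float | None = None

    def validate(self) -> None:
        t = self.totals["t_days"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError("total-population times must be strictly increasing")
        if (self.totals[["winged", "aquatic"]].to_numpy() < 0).any():
            raise ValueError("total populations must be non-negative")

    def total_at(self, t: float, phase: str = "winged") -> float:
        """Domain total of a phase at recorded time ``t`` (days)."""
        return _series_at(self.totals, t, phase)

    def snapshot_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        for ts, psiM, psiA in self.snapshots:
            if abs(ts - t) < 1e-9:
                return psiM, psiA
        raise KeyError(f"no snapshot recorded at t = {t} d")

    def totals_to_csv(self, path) -> None:
        self.totals.to_csv(path, index=False)

    def max_cfl(self) -> float:
        return max((r.max_cfl for r in self.reports), default=0.0)


def total_population(field: np.ndarray, psi: np.ndarray, grid: Grid) -> float:
    """Midpoint-quadrature domain integral ``sum psi * U * dx * dy``."""
    field = np.asarray(field, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if field.shape != grid.shape or psi.shape != grid.shape:
        raise ValueError(
            f"shapes {field.shape}/{psi.shape} do not match grid {grid.shape}"
        )
    return float((psi * field).sum()) * grid.cell_area


def _series_at(totals: pd.DataFrame, t: float, phase: str,
               atol: float = 1e-8) -> float:
    if phase not in ("winged", "aquatic"):
        raise KeyError(f"unknown phase {phase!r}")
    tt = totals["t_days"].to_numpy()
    hits = np.flatnonzero(np.abs(tt - t) <= atol)
    if hits.size == 0:
        raise KeyError(f"time {t} d not present in the totals series")
    return float(totals[phase].iloc[hits[0]])


def reduction_percentage(
    baseline: pd.DataFrame,
    treated: pd.DataFrame,
    t: float,
    phase: str = "winged",
) -> float:
    """Percent reduction ``100 (1 - treated(t)/baseline(t))`` of a domain
    total at evaluation time ``t`` (days).

    Returns NaN (reduction undefined) when the baseline total vanishes; a
    treated total above the baseline yields a negative percentage.
    Invariant under a common rescaling of both series, so the result does
    not depend on the seed amplitude once both runs share it.
    """
    b = _series_at(baseline, t, phase)
    x = _series_at(treated, t, phase)
    if b == 0.0:
        return float("nan")
    return 100.0 * (1.0 - x / b)


def health_report(result: SimulationResult, twin_days: float = 2.0,
                  mass_tol: float = 1e-10) -> Mapping[str, Any]:
    """Post-run sanity summary.

    Checks that every accepted step respected the CFL bound, that densities
    stayed non-negative, that recorded times increase, and that a
    transport-only twin of the first ``twin_days`` days balances the change
    of ``int psi*M`` against the accumulated boundary flux to ``mass_tol``
    (discrete conservation: interior fluxes telescope).
    """
    from dataclasses import replace as _replace

    from .solver import simulate

    max_cfl = result.max_cfl()
    m_min = min((r.m_min for r in result.reports), default=0.0)
    a_min = min((r.a_min for r in result.reports), default=0.0)
    t = result.totals["t_days"].to_numpy()

    twin_cfg = _replace(
        result.config,
        duration=min(twin_days, result.config.duration),
        snapshots=(),
        disable_reactions=True,
    )
    twin = simulate(twin_cfg, track_mass_balance=True)
    start = twin.totals["winged"].iloc[0]
    end = twin.totals["winged"].iloc[-1]
    residual = abs((end - start) - twin.boundary_flux) / max(abs(start), 1e-300)

    report = {
        "max_cfl": max_cfl,
        "cfl_ok": bool(max_cfl <= 1.0 + 1e-12),
        "min_density": float(min(m_min, a_min)),
        "positivity_ok": bool(min(m_min, a_min) >= 0.0),
        "times_monotone": bool(np.all(np.diff(t) > 0)),
        "mass_balance_residual": float(residual),
        "mass_balance_ok": bool(residual <= mass_tol),
    }
    report["all_ok"] = all(
        report[k] for k in
        ("cfl_ok", "positivity_ok", "times_monotone", "mass_balance_ok")
    )
    return report
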