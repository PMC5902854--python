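"""Finite-volume discretization and explicit time stepping.

The winged-phase density M obeys a scalar conservation law with advective
flux ``-v M`` (first-order upwind at cell faces) and diffusive flux
``D dM/dx`` (two-point central difference); the aquatic phase A is static
and evolves by reaction only.  Because the time derivative carries the area
support ``psi`` and ``psi`` is time-independent, the forward-Euler update
divides the right-hand side by ``psi``:

    M^{n+1} = M^n + (dt/psi) * (div F(M^n) + R_M(M^n, A^n))
    A^{n+1} = A^n + (dt/psi) * R_A(M^n, A^n)

For piecewise-constant coefficients the discrete transport operator is
linear; it is assembled once per wind window as a sparse matrix plus an
affine offset carrying Dirichlet boundary data, which keeps the per-step
cost at one sparse mat-vec plus a handful of vector operations.

Boundary handling:

* zero-gradient (Neumann) sides contribute no diffusive flux; advective
  outflow uses the boundary-cell value, inflow is zero (zero-net-influx
  reading of an isolated neighborhood);
* fixed-value (Dirichlet) sides place a ghost value at one cell spacing
  outside the face and use it in both the upwind and the diffusive flux
  (sea-facing side with zero mosquito population).

Internal units: meters and days.  Table values given in m/s are converted
when the parameter fields are built (see :mod:`aedes2d.geometry`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .geometry import Grid, ParameterFields, SECONDS_PER_DAY

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import ScenarioConfig
    from .diagnostics import SimulationResult

__all__ = [
    "BoundaryCondition",
    "BoundarySpec",
    "State",
    "StepReport",
    "InstabilityError",
    "upwind_face_value",
    "harmonic_mean",
    "TransportOperator",
    "flux_divergence",
    "stable_dt",
    "step",
    "simulate",
    "NEGATIVITY_TOL",
]

#: Densities below this (negative) threshold abort the run; smaller
#: round-off undershoots are clipped to zero.
NEGATIVITY_TOL = -1e-10


class InstabilityError(RuntimeError):
    """Raised when a step produces NaNs or a genuine negative density."""

    def __init__(self, message: str, t_days: float | None = None) -> None:
        super().__init__(message)
        self.t_days = t_days


@dataclass(frozen=True)
class BoundaryCondition:
    """Condition on one side of the domain: ``neumann`` (zero normal
    gradient) or ``dirichlet`` (fixed boundary density, default 0)."""

    kind: str = "neumann"
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("neumann", "dirichlet"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")


SIDES = ("left", "right", "bottom", "top")


@dataclass(frozen=True)
class BoundarySpec:
    """One :class:`BoundaryCondition` per domain side (for the winged
    phase; the aquatic phase is not transported)."""

    left: BoundaryCondition = BoundaryCondition()
    right: BoundaryCondition = BoundaryCondition()
    bottom: BoundaryCondition = BoundaryCondition()
    top: BoundaryCondition = BoundaryCondition()

    @classmethod
    def all_neumann(cls) -> "BoundarySpec":
        return cls()

    @classmethod
    def with_dirichlet(cls, side: str, value: float = 0.0) -> "BoundarySpec":
        if side not in SIDES:
            raise ValueError(f"unknown side {side!r}")
        kwargs = {side: BoundaryCondition("dirichlet", value)}
        return cls(**kwargs)

    def dirichlet_sides(self) -> tuple[str, ...]:
        return tuple(s for s in SIDES if getattr(self, s).kind == "dirichlet")


@dataclass
class State:
    """Winged (M) and aquatic (A) density fields at time ``t`` (days)."""

    M: np.ndarray
    A: np.ndarray
    t: float = 0.0


@dataclass(frozen=True)
class StepReport:
    """Stability/positivity bookkeeping for one accepted step (or a
    segment of equal steps)."""

    t_days: float
    dt_days: float
    max_cfl: float
    m_min: float
    m_max: float
    a_min: float
    a_max: float
    positivity_ok: bool = True

    @property
    def dt_seconds(self) -> float:
        return self.dt_days * SECONDS_PER_DAY


def upwind_face_value(
    left_cell: np.ndarray | float,
    right_cell: np.ndarray | float,
    face_velocity: np.ndarray | float,
):
    """First-order upwind reconstruction at a face.

    Returns the upstream cell value: the left cell for positive face
    velocity, the right cell for negative.  At exactly zero velocity the
    arithmetic mean is returned (the advective flux vanishes there, so the
    choice is a tie-break only).
    """
    left_cell = np.asarray(left_cell, dtype=float)
    right_cell = np.asarray(right_cell, dtype=float)
    v = np.asarray(face_velocity, dtype=float)
    out = np.where(v > 0, left_cell, np.where(v < 0, right_cell,
                                              0.5 * (left_cell + right_cell)))
    return out if out.ndim else float(out)


def harmonic_mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Harmonic mean with 0 wherever either argument is 0 (blocked face)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    s = a + b
    out = np.zeros(np.broadcast(a, b).shape)
    nz = s > 0
    out[nz] = 2.0 * (a * b)[nz] / s[nz]
    return out


class TransportOperator:
    """Affine discrete transport operator ``M -> L M + b`` for the winged
    phase: upwind advection plus central diffusion with the configured
    boundary conditions.

    ``matrix`` is an ``(N, N)`` CSR matrix acting on ``M.ravel()`` (row-major,
    shape ``(ny, nx)``); ``offset`` carries Dirichlet boundary data.  Face
    velocities are arithmetic means of the adjacent cell values; face
    diffusivities default to the harmonic mean (``d_face="arithmetic"``
    selects the arithmetic mean instead).
    """

    def __init__(
        self,
        p: ParameterFields,
        grid: Grid,
        bc: BoundarySpec,
        d_face: str = "harmonic",
    ) -> None:
        if p.shape != grid.shape:
            raise ValueError(
                f"parameter shape {p.shape} does not match grid {grid.shape}"
            )
        if d_face not in ("harmonic", "arithmetic"):
            raise ValueError(f"unknown face-diffusivity rule {d_face!r}")
        self.grid = grid
        self.bc = bc
        self.d_face = d_face
        self.matrix, self.offset = self._assemble(p, grid, bc)

    def _face_D(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if self.d_face == "harmonic":
            return harmonic_mean(a, b)
        return 0.5 * (a + b)

    def _assemble(
        self, p: ParameterFields, grid: Grid, bc: BoundarySpec
    ) -> tuple[sp.csr_matrix, np.ndarray]:
        ny, nx = grid.shape
        dx, dy = grid.dx, grid.dy
        N = nx * ny
        idx = np.arange(N).reshape(ny, nx)
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        b = np.zeros(N)

        def add(r, c, v):
            rows.append(np.asarray(r).ravel())
            cols.append(np.asarray(c).ravel())
            vals.append(np.asarray(v).ravel())

        # ---- interior faces, x direction -------------------------------
        if nx > 1:
            L = idx[:, :-1]
            R = idx[:, 1:]
            vf = 0.5 * (p.vx[:, :-1] + p.vx[:, 1:])
            Df = self._face_D(p.Dx[:, :-1], p.Dx[:, 1:])
            ap = np.maximum(vf, 0.0)
            am = np.minimum(vf, 0.0)
            # face flux F = -(ap M_L + am M_R) + Df (M_R - M_L)/dx
            dF_dL = -ap - Df / dx
            dF_dR = -am + Df / dx
            # divergence: cell L gains +F/dx (right face), cell R gains -F/dx
            add(L, L, dF_dL / dx)
            add(L, R, dF_dR / dx)
            add(R, L, -dF_dL / dx)
            add(R, R, -dF_dR / dx)

        # ---- interior faces, y direction -------------------------------
        if ny > 1:
            B = idx[:-1, :]
            T = idx[1:, :]
            vf = 0.5 * (p.vy[:-1, :] + p.vy[1:, :])
            Df = self._face_D(p.Dy[:-1, :], p.Dy[1:, :])
            ap = np.maximum(vf, 0.0)
            am = np.minimum(vf, 0.0)
            dF_dB = -ap - Df / dy
            dF_dT = -am + Df / dy
            add(B, B, dF_dB / dy)
            add(B, T, dF_dT / dy)
            add(T, B, -dF_dB / dy)
            add(T, T, -dF_dT / dy)

        # ---- boundary faces --------------------------------------------
        # Divergence of cell c gets -F/dh for its low face (left/bottom)
        # and +F/dh for its high face (right/top).
        def boundary(side: str, cells: np.ndarray, v: np.ndarray,
                     D: np.ndarray, dh: float, low: bool) -> None:
            cond = getattr(bc, side)
            vp = np.maximum(v, 0.0)
            vm = np.minimum(v, 0.0)
            sgn = -1.0 if low else +1.0
            if cond.kind == "neumann":
                # no diffusive flux; advective outflow only
                # low face: outflow when v < 0, F = -vm * M_c
                # high face: outflow when v > 0, F = -vp * M_c
                dF_dc = -vm if low else -vp
                add(cells, cells, sgn * dF_dc / dh)
            else:  # dirichlet ghost value g one spacing outside
                g = cond.value
                if low:
                    # F_low = -(vp g + vm M_c) + D (M_c - g)/dh
                    dF_dc = -vm + D / dh
                    const = -vp * g - D * g / dh
                else:
                    # F_high = -(vp M_c + vm g) + D (g - M_c)/dh
                    dF_dc = -vp - D / dh
                    const = -vm * g + D * g / dh
                add(cells, cells, sgn * dF_dc / dh)
                np.add.at(b, np.asarray(cells).ravel(),
                          sgn * np.asarray(const).ravel() / dh)

        boundary("left", idx[:, 0], p.vx[:, 0], p.Dx[:, 0], dx, low=True)
        boundary("right", idx[:, -1], p.vx[:, -1], p.Dx[:, -1], dx, low=False)
        boundary("bottom", idx[0, :], p.vy[0, :], p.Dy[0, :], dy, low=True)
        boundary("top", idx[-1, :], p.vy[-1, :], p.Dy[-1, :], dy, low=False)

        mat = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(N, N),
        ).tocsr()
        return mat, b

    def apply(self, M: np.ndarray) -> np.ndarray:
        """Net flux divergence per cell (density per day), shape (ny, nx)."""
        M = np.asarray(M, dtype=float)
        if M.shape != self.grid.shape:
            raise ValueError(
                f"field shape {M.shape} does not match grid {self.grid.shape}"
            )
        return (self.matrix @ M.ravel() + self.offset).reshape(self.grid.shape)


def flux_divergence(
    M: np.ndarray, p: ParameterFields, grid: Grid, bc: BoundarySpec
) -> np.ndarray:
    """One-shot evaluation of the transport divergence (see
    :class:`TransportOperator` for the discretization)."""
    return TransportOperator(p, grid, bc).apply(M)


def _cfl_denominator(p: ParameterFields, grid: Grid) -> np.ndarray:
    return (np.abs(p.vx) / grid.dx + np.abs(p.vy) / grid.dy
            + 2.0 * p.Dx / grid.dx ** 2 + 2.0 * p.Dy / grid.dy ** 2)


def stable_dt(
    p: ParameterFields,
    grid: Grid,
    safety: float = 0.9,
    cap_seconds: float = 600.0,
) -> float:
    """Largest stable explicit step in **days**.

    Combined advective-diffusive forward-Euler bound, per cell::

        dt <= psi / (|vx|/dx + |vy|/dy + 2 Dx/dx^2 + 2 Dy/dy^2)

    scaled by ``safety``; ``psi`` enters because the update divides by it.
    With no transport anywhere the bound is infinite and the configured cap
    (``cap_seconds``, default 600 s) is returned instead.
    """
    if not 0.0 < safety <= 1.0:
        raise ValueError("safety must lie in (0, 1]")
    denom = _cfl_denominator(p, grid)
    cap = cap_seconds / SECONDS_PER_DAY
    active = denom > 0
    if not active.any():
        return cap
    bound = float(np.min(p.psi[active] / denom[active]))
    return min(safety * bound, cap)


def _max_cfl(p: ParameterFields, grid: Grid, dt: float) -> float:
    return float(dt * np.max(_cfl_denominator(p, grid) / p.psi))


def _check_positive(m: np.ndarray, a: np.ndarray, t: float) -> None:
    m_min = m.min()
    a_min = a.min()
    # NaN fails every comparison and is caught here as well
    if not (m_min >= NEGATIVITY_TOL and a_min >= NEGATIVITY_TOL):
        raise InstabilityError(
            f"density became negative or NaN at t = {t:.4f} d "
            f"(min M = {m_min}, min A = {a_min}); "
            "the time step likely violates the stability bound",
            t_days=t,
        )
    if m_min < 0:
        np.maximum(m, 0.0, out=m)
    if a_min < 0:
        np.maximum(a, 0.0, out=a)


def step(
    state: State,
    p: ParameterFields,
    grid: Grid,
    bc: BoundarySpec,
    dt: float,
    operator: TransportOperator | None = None,
) -> tuple[State, StepReport]:
    """One forward-Euler step of length ``dt`` (days).

    The winged phase advances by transport plus reaction, the aquatic phase
    by reaction only; both right-hand sides are divided by ``psi``.  Returns
    the new state and a :class:`StepReport`; raises
    :class:`InstabilityError` on NaNs or a negative overshoot beyond
    ``NEGATIVITY_TOL``.
    """
    from .kinetics import aquatic_reaction, winged_reaction

    if operator is None:
        operator = TransportOperator(p, grid, bc)
    M, A = np.asarray(state.M, dtype=float), np.asarray(state.A, dtype=float)
    if M.shape != grid.shape or A.shape != grid.shape:
        raise ValueError("state fields do not match the grid shape")
    w = dt / p.psi
    M_new = M + w * (operator.apply(M) + winged_reaction(M, A, p))
    A_new = A + w * aquatic_reaction(M, A, p)
    t_new = state.t + dt
    _check_positive(M_new, A_new, t_new)
    report = StepReport(
        t_days=t_new,
        dt_days=dt,
        max_cfl=_max_cfl(p, grid, dt),
        m_min=float(M_new.min()), m_max=float(M_new.max()),
        a_min=float(A_new.min()), a_max=float(A_new.max()),
    )
    return State(M=M_new, A=A_new, t=t_new), report


def _run_segment(
    m: np.ndarray,
    a: np.ndarray,
    t0: float,
    n_steps: int,
    dt: float,
    op: TransportOperator,
    p: ParameterFields,
    reactions: bool,
    mass_ledger: list | None,
    cell_area: float,
) -> float:
    """Advance flattened fields in place by ``n_steps`` equal steps."""
    w = (dt / p.psi).ravel()
    Pm = sp.diags(w) @ op.matrix
    pb = w * op.offset
    if reactions:
        h1 = p.h1.ravel()
        h2 = p.h2.ravel()
        c_ga = w * p.gamma
        c_gk = w * (p.gamma / p.k1)
        c_m = w * (p.mu1 + h1)
        c_r = w * p.r
        c_rk = w * (p.r / p.k2)
        c_a = w * (p.mu2 + h2 + p.gamma)
    t = t0
    for k in range(n_steps):
        if mass_ledger is not None:
            # net boundary in/outflux of psi*M this step (interior fluxes
            # telescope, so the domain sum of the divergence is boundary-only)
            mass_ledger.append(float((p.psi.ravel() * (Pm @ m + pb)).sum()) * cell_area)
        if reactions:
            ma = m * a
            dm = Pm @ m + pb + (c_ga * a - c_gk * ma - c_m * m)
            da = c_r * m - c_rk * ma - c_a * a
            m += dm
            a += da
        else:
            m += Pm @ m + pb
        t = t0 + (k + 1) * dt
        m_min = m.min()
        a_min = a.min()
        if not (m_min >= NEGATIVITY_TOL and a_min >= NEGATIVITY_TOL):
            raise InstabilityError(
                f"density became negative or NaN at t = {t:.4f} d "
                f"(min M = {m_min}, min A = {a_min})",
                t_days=t,
            )
        if m_min < 0:
            np.maximum(m, 0.0, out=m)
        if a_min < 0:
            np.maximum(a, 0.0, out=a)
    return t


def simulate(
    config: "ScenarioConfig",
    progress: Callable[[StepReport], None] | None = None,
    reactions: bool = True,
    track_mass_balance: bool = False,
) -> "SimulationResult":
    """Run a scenario from ``t = 0`` to ``config.duration`` days.

    The step size is re-evaluated from the stability bound whenever the
    wind schedule switches; snapshot fields ``psi*M`` and ``psi*A`` are
    recorded at ``config.snapshots`` and domain totals every
    ``config.record_interval`` days.  Fully deterministic given the
    configuration.

    ``reactions=False`` runs the transport-only twin used by the
    mass-balance health check; with ``track_mass_balance=True`` the result
    carries the accumulated boundary flux of ``psi*M``.
    """
    from .diagnostics import SimulationResult, total_population

    config.validate()
    grid = config.grid()
    regions = config.regions(grid)
    M0, A0 = config.initial_state(grid, regions)
    duration = float(config.duration)

    # piecewise-constant wind: params + operator cached per window key
    p_cache: dict[str, ParameterFields] = {}
    op_cache: dict[str, TransportOperator] = {}

    def fields_for(key: str) -> tuple[ParameterFields, TransportOperator]:
        if key not in p_cache:
            p_cache[key] = config.parameter_fields(regions, window=key)
            op_cache[key] = TransportOperator(
                p_cache[key], grid, config.boundary_spec(), d_face=config.d_face
            )
        return p_cache[key], op_cache[key]

    snapshot_times = sorted({float(s) for s in config.snapshots
                             if 0.0 <= s <= duration})
    record_times = set(np.arange(0.0, duration + 1e-9, config.record_interval))
    events = sorted(
        {0.0, duration} | set(snapshot_times) | record_times
        | set(config.wind_switch_times(duration))
    )

    m = np.asarray(M0, dtype=float).ravel().copy()
    a = np.asarray(A0, dtype=float).ravel().copy()
    _check_positive(m, a, 0.0)

    snapshots: list[tuple[float, np.ndarray, np.ndarray]] = []
    totals_rows: list[tuple[float, float, float]] = []
    reports: list[StepReport] = []
    mass_ledger: list[float] | None = [] if track_mass_balance else None

    psi0 = config.parameter_fields(
        regions, window=config.window_key_at(0.0)).psi

    def record(t: float, psi: np.ndarray) -> None:
        psiM = (psi.ravel() * m).reshape(grid.shape)
        psiA = (psi.ravel() * a).reshape(grid.shape)
        totals_rows.append((
            t,
            float(psiM.sum()) * grid.cell_area,
            float(psiA.sum()) * grid.cell_area,
        ))
        if any(abs(t - s) < 1e-9 for s in snapshot_times):
            snapshots.append((t, psiM.copy(), psiA.copy()))

    record(0.0, psi0)
    t = 0.0
    for ta, tb in zip(events[:-1], events[1:]):
        seg = tb - ta
        if seg <= 1e-12:
            continue
        key = config.window_key_at(0.5 * (ta + tb))
        p, op = fields_for(key)
        dt_max = stable_dt(p, grid, safety=config.safety,
                           cap_seconds=getattr(config, 'dt_cap_seconds', 600.0))
        n = max(1, math.ceil(seg / dt_max))
        dt = seg / n
        t = _run_segment(m, a, ta, n, dt, op, p,
                         reactions and not config.disable_reactions,
                         mass_ledger, grid.cell_area)
        rep = StepReport(
            t_days=tb, dt_days=dt, max_cfl=_max_cfl(p, grid, dt),
            m_min=float(m.min()), m_max=float(m.max()),
            a_min=float(a.min()), a_max=float(a.max()),
        )
        reports.append(rep)
        if progress is not None:
            progress(rep)
        record(tb, p.psi)

    totals = pd.DataFrame(totals_rows, columns=["t_days", "winged", "aquatic"])
    totals = totals.drop_duplicates(subset="t_days").reset_index(drop=True)
    final = State(M=m.reshape(grid.shape), A=a.reshape(grid.shape), t=duration)
    result = SimulationResult(
        snapshots=snapshots,
        totals=totals,
        config=config,
        grid=grid,
        regions=regions,
        psi=psi0,
        reports=reports,
        final_state=final,
        boundary_flux=(None if mass_ledger is None else float(np.sum(mass_ledger))),
    )
    result.validate()
    return result
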