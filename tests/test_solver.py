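"""Discrete transport operator, stability bound, stepping and conservation.

The reference implementations in this module (scalar loop-based flux sums,
ghost-cell bookkeeping) are written independently of the solver's sparse
assembly and share only its stated conventions: arithmetic-mean face
velocities, harmonic-mean face diffusivities, outflow-only advection at
zero-gradient sides, ghost value at one spacing outside Dirichlet sides.
"""

import numpy as np
import pytest

import aedes2d as a
from aedes2d.geometry import (
    Grid,
    RegionParams,
    SECONDS_PER_DAY,
    build_parameter_fields,
    rasterize_blocks,
)
from aedes2d.solver import (
    BoundaryCondition,
    BoundarySpec,
    InstabilityError,
    State,
    TransportOperator,
    flux_divergence,
    stable_dt,
    step,
    upwind_face_value,
)


def uniform_field_params(grid, psi=1.0, vx=0.0, vy=0.0, Dx=0.0, Dy=0.0,
                         h1=0.0, unit="m/day"):
    rm = rasterize_blocks(grid, [])
    table = {"street": RegionParams(psi=psi, vx=vx, vy=vy, Dx=Dx, Dy=Dy, h1=h1)}
    return build_parameter_fields(rm, table, transport_unit=unit)


# ---------------------------------------------------------------------------
# independent loop-based 1-D oracle
# ---------------------------------------------------------------------------

def oracle_divergence_1d(M, v, D, dx, left=("neumann",), right=("neumann",)):
    """Scalar-loop flux divergence for a single row of cells."""
    n = len(M)
    F = np.zeros(n + 1)  # F[f] = flux through face f (between f-1 and f)
    for f in range(1, n):
        vf = 0.5 * (v[f - 1] + v[f])
        Df = (2 * D[f - 1] * D[f] / (D[f - 1] + D[f])
              if D[f - 1] + D[f] > 0 else 0.0)
        if vf > 0:
            up = M[f - 1]
        elif vf < 0:
            up = M[f]
        else:
            up = 0.5 * (M[f - 1] + M[f])
        F[f] = -vf * up + Df * (M[f] - M[f - 1]) / dx
    # left boundary face (face 0)
    if left[0] == "neumann":
        F[0] = -min(v[0], 0.0) * M[0]
    else:
        g = left[1]
        up = g if v[0] > 0 else (M[0] if v[0] < 0 else 0.5 * (g + M[0]))
        F[0] = -v[0] * up + D[0] * (M[0] - g) / dx
    # right boundary face (face n)
    if right[0] == "neumann":
        F[n] = -max(v[-1], 0.0) * M[-1]
    else:
        g = right[1]
        up = M[-1] if v[-1] > 0 else (g if v[-1] < 0 else 0.5 * (M[-1] + g))
        F[n] = -v[-1] * up + D[-1] * (g - M[-1]) / dx
    return (F[1:] - F[:-1]) / dx


# ---------------------------------------------------------------------------
# upwind rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "left,right,v,expected",
    [(2.0, 4.0, 0.1, 2.0), (2.0, 4.0, -0.1, 4.0), (3.0, 3.0, 0.0, 3.0),
     (3.0, 3.0, 5.0, 3.0), (1.0, 9.0, 0.0, 5.0)],
)
def test_upwind_face_value(left, right, v, expected):
    assert upwind_face_value(left, right, v) == expected


def test_upwind_face_value_vectorized():
    out = upwind_face_value(np.array([2.0, 2.0, 3.0]),
                            np.array([4.0, 4.0, 3.0]),
                            np.array([0.1, -0.1, 0.0]))
    np.testing.assert_array_equal(out, [2.0, 4.0, 3.0])


# ---------------------------------------------------------------------------
# flux divergence
# ---------------------------------------------------------------------------

def test_divergence_zero_for_uniform_field():
    grid = Grid.from_spacing(80.0, 80.0, 10.0)
    p = uniform_field_params(grid, psi=0.5, Dx=7.0, Dy=3.0)
    div = flux_divergence(np.full(grid.shape, 4.2), p, grid,
                          BoundarySpec.all_neumann())
    assert np.abs(div).max() < 1e-13


def test_divergence_matches_1d_oracle_translation():
    # top-hat, uniform v > 0, D = 0
    grid = Grid(nx=64, ny=1, Lx=64.0, Ly=1.0)
    p = uniform_field_params(grid, vx=20.0)
    M = np.zeros(grid.shape)
    M[0, 16:32] = 1.0
    div = flux_divergence(M, p, grid, BoundarySpec.all_neumann())
    ref = oracle_divergence_1d(M[0], p.vx[0], p.Dx[0], grid.dx)
    np.testing.assert_allclose(div[0], ref, atol=1e-12)


def test_divergence_matches_1d_oracle_random_fields():
    rng = np.random.default_rng(7)
    grid = Grid(nx=48, ny=1, Lx=48.0, Ly=1.0)
    for bc, left, right in [
        (BoundarySpec.all_neumann(), ("neumann",), ("neumann",)),
        (BoundarySpec(left=BoundaryCondition("dirichlet", 2.0)),
         ("dirichlet", 2.0), ("neumann",)),
        (BoundarySpec.with_dirichlet("right", 0.0),
         ("neumann",), ("dirichlet", 0.0)),
    ]:
        p = uniform_field_params(grid)
        p.vx = rng.uniform(-30.0, 30.0, grid.shape)
        p.Dx = rng.uniform(0.0, 10.0, grid.shape)
        M = rng.uniform(0.0, 5.0, grid.shape)
        div = flux_divergence(M, p, grid, bc)
        ref = oracle_divergence_1d(M[0], p.vx[0], p.Dx[0], grid.dx,
                                   left=left, right=right)
        np.testing.assert_allclose(div[0], ref, atol=1e-12)


def test_diffusion_divergence_telescopes_to_zero():
    # discrete delta on a 5-cell line: zero-flux diffusion conserves mass
    grid = Grid(nx=5, ny=1, Lx=5.0, Ly=1.0)
    p = uniform_field_params(grid, Dx=3.0)
    M = np.zeros(grid.shape)
    M[0, 2] = 1.0
    div = flux_divergence(M, p, grid, BoundarySpec.all_neumann())
    assert div.sum() == pytest.approx(0.0, abs=1e-14)


def test_dirichlet_side_bounded_by_interior():
    # zero-Dirichlet side drains the boundary cells; the prescribed value
    # enters the flux and boundary-adjacent densities stay below interior
    grid = Grid.from_spacing(40.0, 40.0, 4.0)
    p = uniform_field_params(grid, psi=1.0, Dx=20.0, Dy=20.0)
    bc = BoundarySpec.with_dirichlet("right", 0.0)
    state = State(M=np.full(grid.shape, 8.0), A=np.zeros(grid.shape))
    op = TransportOperator(p, grid, bc)
    dt = stable_dt(p, grid, cap_seconds=1e9)
    for _ in range(50):
        m = state.M + (dt / p.psi) * op.apply(state.M)
        state = State(M=m, A=state.A, t=state.t + dt)
    assert state.M[:, -1].max() < state.M[:, :-1].max()
    assert state.M[:, -1].min() >= 0.0
    # interior column stays near the far (Neumann) side maximum
    assert state.M[:, 0].max() <= 8.0 + 1e-12


# ---------------------------------------------------------------------------
# stability bound
# ---------------------------------------------------------------------------

def test_stable_dt_hand_value_street_cell():
    # street coefficients read as m/s on a 2 m grid, safety = 1:
    # 0.3 / (0.05/2 + 0.15/2 + 2*0.0125/4 + 2*0.0125/4) = 2.667 s
    grid = Grid.from_spacing(20.0, 20.0, 2.0)
    p = uniform_field_params(grid, psi=0.3, vx=5.0e-2, vy=1.5e-1,
                             Dx=1.25e-2, Dy=1.25e-2, unit="m/s")
    dt_days = stable_dt(p, grid, safety=1.0)
    assert dt_days * SECONDS_PER_DAY == pytest.approx(2.6667, rel=1e-3)


def test_stable_dt_cap_without_transport():
    grid = Grid.from_spacing(20.0, 20.0, 2.0)
    p = uniform_field_params(grid)
    assert stable_dt(p, grid) == pytest.approx(600.0 / SECONDS_PER_DAY)
    assert stable_dt(p, grid, cap_seconds=60.0) == pytest.approx(
        60.0 / SECONDS_PER_DAY)


def test_stable_dt_decreases_with_refinement():
    p_dt = []
    for dx in (4.0, 2.0, 1.0):
        grid = Grid.from_spacing(40.0, 40.0, dx)
        p = uniform_field_params(grid, psi=0.3, vx=50.0, Dx=100.0, Dy=100.0)
        p_dt.append(stable_dt(p, grid))
    assert p_dt[0] > p_dt[1] > p_dt[2]


def test_stable_dt_rejects_bad_safety():
    grid = Grid.from_spacing(20.0, 20.0, 2.0)
    p = uniform_field_params(grid)
    with pytest.raises(ValueError):
        stable_dt(p, grid, safety=0.0)


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def test_step_keeps_extinction_fixed_point():
    grid = Grid.from_spacing(40.0, 40.0, 10.0)
    p = uniform_field_params(grid, vx=10.0, Dx=5.0, Dy=5.0)
    state = State(M=np.zeros(grid.shape), A=np.zeros(grid.shape))
    new, report = step(state, p, grid, BoundarySpec.all_neumann(),
                       stable_dt(p, grid))
    assert np.all(new.M == 0.0) and np.all(new.A == 0.0)
    assert report.max_cfl <= 1.0


def test_step_equilibrium_drift_below_1e8():
    grid = Grid.from_spacing(40.0, 40.0, 10.0)
    p = uniform_field_params(grid, psi=0.8, Dx=10.0, Dy=10.0)
    eq = a.homogeneous_equilibrium(p)
    M_star, A_star = eq.coexistence
    state = State(M=np.full(grid.shape, M_star), A=np.full(grid.shape, A_star))
    new, _ = step(state, p, grid, BoundarySpec.all_neumann(),
                  stable_dt(p, grid))
    assert np.abs(new.M / M_star - 1.0).max() < 1e-8
    assert np.abs(new.A / A_star - 1.0).max() < 1e-8


def test_step_total_changes_by_reaction_only():
    # delta spike, v = 0: transport conserves the psi-weighted total, so
    # the change equals the reaction contribution exactly
    grid = Grid.from_spacing(50.0, 50.0, 10.0)
    p = uniform_field_params(grid, psi=0.5, Dx=8.0, Dy=8.0)
    M = np.zeros(grid.shape)
    M[2, 2] = 30.0
    A = np.full(grid.shape, 5.0)
    state = State(M=M, A=A)
    dt = stable_dt(p, grid)
    new, _ = step(state, p, grid, BoundarySpec.all_neumann(), dt)
    total_before = a.total_population(M, p.psi, grid)
    total_after = a.total_population(new.M, p.psi, grid)
    reaction = dt * a.winged_reaction(M, A, p).sum() * grid.cell_area
    assert total_after - total_before == pytest.approx(
        reaction, rel=1e-12, abs=1e-12 * abs(total_before))


def test_step_shape_mismatch():
    grid = Grid.from_spacing(40.0, 40.0, 10.0)
    p = uniform_field_params(grid)
    state = State(M=np.zeros((2, 2)), A=np.zeros((2, 2)))
    with pytest.raises(ValueError):
        step(state, p, grid, BoundarySpec.all_neumann(), 1e-3)


def test_mass_conservation_1000_steps():
    # zero reactions, zero-flux boundaries, velocities vanishing in the
    # boundary cells: int psi M dOmega is conserved to 1e-10 relative
    rng = np.random.default_rng(11)
    grid = Grid.from_spacing(32.0, 32.0, 2.0)
    p = uniform_field_params(grid, psi=0.7)
    p.vx = rng.uniform(-40.0, 40.0, grid.shape)
    p.vy = rng.uniform(-40.0, 40.0, grid.shape)
    for f in (p.vx, p.vy):
        f[0, :] = f[-1, :] = 0.0
        f[:, 0] = f[:, -1] = 0.0
    p.Dx = rng.uniform(0.0, 30.0, grid.shape)
    p.Dy = rng.uniform(0.0, 30.0, grid.shape)
    bc = BoundarySpec.all_neumann()
    op = TransportOperator(p, grid, bc)
    dt = stable_dt(p, grid)
    m = rng.uniform(0.0, 10.0, grid.shape)
    total0 = a.total_population(m, p.psi, grid)
    for _ in range(1000):
        m = m + (dt / p.psi) * op.apply(m)
    assert a.total_population(m, p.psi, grid) == pytest.approx(
        total0, rel=1e-10)
    assert m.min() >= 0.0


def test_positivity_under_stable_dt_randomized():
    # 100 randomized parameter/field draws, 20 steps each
    rng = np.random.default_rng(2024)
    grid = Grid.from_spacing(32.0, 32.0, 4.0)
    bc = BoundarySpec.all_neumann()
    for _ in range(100):
        p = uniform_field_params(grid)
        p.psi = rng.uniform(0.3, 1.0, grid.shape)
        p.vx = rng.uniform(-150.0, 150.0, grid.shape)
        p.vy = rng.uniform(-150.0, 150.0, grid.shape)
        p.Dx = rng.uniform(0.0, 4000.0, grid.shape)
        p.Dy = rng.uniform(0.0, 4000.0, grid.shape)
        p.h1 = rng.uniform(0.0, 7.6, grid.shape)
        state = State(M=rng.uniform(0.0, 50.0, grid.shape),
                      A=rng.uniform(0.0, 150.0, grid.shape))
        op = TransportOperator(p, grid, bc)
        dt = stable_dt(p, grid)
        for _ in range(20):
            state, report = step(state, p, grid, bc, dt, operator=op)
            assert report.max_cfl <= 1.0 + 1e-12
        assert state.M.min() >= 0.0
        assert state.A.min() >= 0.0


def test_unstable_dt_aborts_with_diagnostic():
    grid = Grid.from_spacing(32.0, 32.0, 2.0)
    p = uniform_field_params(grid, psi=0.3, Dx=500.0, Dy=500.0)
    bc = BoundarySpec.all_neumann()
    M = np.zeros(grid.shape)
    M[8, 8] = 10.0
    state = State(M=M, A=np.zeros(grid.shape))
    dt = 5.0 * stable_dt(p, grid, safety=1.0, cap_seconds=1e9)
    with pytest.raises(InstabilityError) as err:
        for _ in range(200):
            state, _ = step(state, p, grid, bc, dt)
    assert err.value.t_days is not None
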