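"""Small deterministic verification scenarios with known references.

Each fixture pairs a runnable :class:`ScenarioConfig` with an independent
reference: the exact translated profile for pure upwind advection, the
analytic heat kernel for pure diffusion, the homogeneous coexistence
equilibrium for the reaction system, or (for the two-region fixture) just
the expected label layout.  They back the solver verification suite:
conservation, convergence order and fixed-point checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .geometry import RegionParams
from .kinetics import Equilibrium, equilibrium_from_rates
from .scenarios import InitialSpec, ScenarioConfig

__all__ = ["Fixture", "make_fixture"]


@dataclass(frozen=True)
class Fixture:
    """A scenario plus its independent reference solution."""

    config: ScenarioConfig
    #: callable ``(x, t_days) -> density`` for the 1-D fixtures,
    #: an :class:`Equilibrium` for ``equilibrium``, ``None`` otherwise.
    reference: Callable[[np.ndarray, float], np.ndarray] | Equilibrium | None


def _advection_1d(size: int) -> Fixture:
    L = 64.0
    v = 20.0  # m/day
    x0, x1 = L / 4, L / 2

    cfg = ScenarioConfig(
        name="fixture:1d_advection",
        Lx=L, Ly=L / size, dx=L / size,
        rectangles=(),
        background="street",
        region_params={"street": RegionParams(psi=1.0, vx=v)},
        transport_unit="m/day",
        initial=InitialSpec(kind="rect", rect=(x0, 0.0, x1, L),
                            m_amplitude=1.0, a_amplitude=0.0),
        duration=1.0, snapshots=(), record_interval=1.0,
        dt_cap_seconds=1e9,  # let the advective stability bound set dt
        disable_reactions=True,
    )

    def reference(x: np.ndarray, t_days: float) -> np.ndarray:
        xs = x - v * t_days
        return ((xs >= x0) & (xs < x1)).astype(float)

    return Fixture(cfg, reference)


def _diffusion_1d(size: int) -> Fixture:
    L = 64.0
    D = 20.0       # m^2/day
    sigma = 4.0    # m
    xc = L / 2

    cfg = ScenarioConfig(
        name="fixture:1d_diffusion",
        Lx=L, Ly=L / size, dx=L / size,
        rectangles=(),
        background="street",
        region_params={"street": RegionParams(psi=1.0, Dx=D, Dy=D)},
        transport_unit="m/day",
        initial=InitialSpec(kind="gaussian", center=(xc, L / (2 * size)),
                            sigma=sigma, m_amplitude=1.0, a_amplitude=0.0),
        duration=0.2, snapshots=(), record_interval=0.2,
        dt_cap_seconds=1e9,  # let the diffusive stability bound set dt
        disable_reactions=True,
    )

    def reference(x: np.ndarray, t_days: float) -> np.ndarray:
        # heat-kernel evolution of a Gaussian: variance grows by 2 D t
        s2 = sigma**2 + 2.0 * D * t_days
        return sigma / np.sqrt(s2) * np.exp(-((x - xc) ** 2) / (2.0 * s2))

    return Fixture(cfg, reference)


def _two_region(size: int) -> Fixture:
    L = 40.0
    cfg = ScenarioConfig(
        name="fixture:two_region",
        Lx=L, Ly=L, dx=L / size,
        rectangles=(("block", 0.0, 0.0, L / 2, L),),
        background="street",
        region_params={
            "block": RegionParams(psi=1.0, Dx=5.0, Dy=5.0),
            "street": RegionParams(psi=0.3, vx=20.0, vy=0.0,
                                   Dx=15.0, Dy=15.0),
        },
        transport_unit="m/day",
        initial=InitialSpec(kind="region", label="block",
                            m_amplitude=5.0, a_amplitude=20.0),
        duration=2.0, snapshots=(), record_interval=1.0,
    )
    return Fixture(cfg, None)


def _equilibrium(size: int) -> Fixture:
    eq = equilibrium_from_rates(0.2, 30.0, 25.0, 100.0, 0.04, 0.01)
    M_star, A_star = eq.coexistence
    L = 40.0
    cfg = ScenarioConfig(
        name="fixture:equilibrium",
        Lx=L, Ly=L, dx=L / size,
        rectangles=(),
        background="park",
        region_params={"park": RegionParams(psi=0.8, Dx=10.0, Dy=10.0)},
        transport_unit="m/day",
        initial=InitialSpec(kind="uniform",
                            m_amplitude=M_star, a_amplitude=A_star),
        duration=1.0, snapshots=(), record_interval=1.0,
    )
    return Fixture(cfg, eq)


_KINDS = {
    "1d_advection": _advection_1d,
    "1d_diffusion": _diffusion_1d,
    "two_region": _two_region,
    "equilibrium": _equilibrium,
}


def make_fixture(kind: str, size: int = 64) -> Fixture:
    """Build a verification fixture.

    ``kind`` is one of ``1d_advection`` (translating top-hat),
    ``1d_diffusion`` (Gaussian against the heat kernel), ``two_region``
    (block/street contrast) or ``equilibrium`` (uniform coexistence state);
    ``size`` is the cell count along x.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {sorted(_KINDS)}")
    return _KINDS[kind](size)
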