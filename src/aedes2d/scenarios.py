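"""Ready-to-run scenario presets: geometries, coefficient tables, wind
schedules, insecticide masks and initial conditions for the four study
areas.

* ``example1`` -- a generic 200 x 200 m quarter: nine square building
  blocks on a regular street lattice.
* ``example2`` -- a 500 x 500 m reconstruction of the Juiz de Fora city
  center: 17 building blocks, one central park and a street lattice.
* ``example3`` -- the Juiz de Fora domain with an adulticide killing term
  on the winged phase, either concentrated along one street corridor
  (``one_street``, h1 = 7.6/day) or spread over every street
  (``all_streets``, h1 = 0.928/day); the larvicide term h2 is zero in both.
* ``example4`` -- a 400 x 400 m reconstruction of the Copacabana beach
  front: 12 blocks, streets, a beach strip along the sea-facing side with a
  day/night periodic wind and a zero-Dirichlet (sea) boundary.

The block layouts are approximate reconstructions: the published maps show
the arrangements only graphically, so the rectangle lists below reproduce
counts, proportions and adjacency rather than surveyed coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .geometry import (
    Grid,
    ParameterFields,
    RegionMap,
    RegionParams,
    Rectangle,
    build_parameter_fields,
    rasterize_blocks,
)
from .solver import BoundarySpec

__all__ = [
    "WindSchedule",
    "InitialSpec",
    "ScenarioConfig",
    "example1",
    "example2",
    "example3",
    "example4",
    "wind_at",
    "PRESETS",
    "get_preset",
]

#: Transport-coefficient unit used by all presets.  The coefficient tables
#: descend from the classic traveling-wave literature on Ae. aegypti
#: dispersal, where D ~ 1.25e-2 km^2/day and v ~ 5e-2 km/day; read in
#: km/day the presets reproduce the published invasion time scale of weeks
#: over a few hundred meters, which m/s values (86400x larger) cannot.
PRESET_TRANSPORT_UNIT = "km/day"


@dataclass(frozen=True)
class WindSchedule:
    """Piecewise-constant-in-time, per-region wind field.

    ``constant`` mode uses the ``vx, vy`` columns of the region table.
    ``periodic`` mode alternates between a day window
    ``[day_start, day_end)`` (fractions of a 24 h day) and the
    complementary night window, with separate per-region ``(vx, vy)``
    tables for each; the two windows tile 24 h exactly by construction.
    """

    mode: str = "constant"
    day: Mapping[str, tuple[float, float]] | None = None
    night: Mapping[str, tuple[float, float]] | None = None
    day_start: float = 0.25   # 06:00
    day_end: float = 0.75     # 18:00

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "periodic"):
            raise ValueError(f"unknown wind mode {self.mode!r}")
        if self.mode == "periodic":
            if self.day is None or self.night is None:
                raise ValueError("periodic wind needs day and night tables")
            if not 0.0 <= self.day_start < self.day_end <= 1.0:
                raise ValueError(
                    "day window must satisfy 0 <= day_start < day_end <= 1 "
                    "so that day and night tile 24 h"
                )

    def window_at(self, t_days: float) -> str:
        if self.mode == "constant":
            return "constant"
        frac = t_days - math.floor(t_days)
        return "day" if self.day_start <= frac < self.day_end else "night"

    def values(self, window: str) -> Mapping[str, tuple[float, float]] | None:
        if self.mode == "constant":
            return None
        if window == "day":
            return self.day
        if window == "night":
            return self.night
        raise KeyError(f"unknown wind window {window!r}")

    def switch_times(self, duration: float) -> list[float]:
        if self.mode == "constant":
            return []
        times = []
        for k in range(int(math.floor(duration)) + 1):
            for f in (self.day_start, self.day_end):
                t = k + f
                if 0.0 < t < duration:
                    times.append(t)
        return times


def wind_at(
    schedule: WindSchedule,
    t: float,
    regions: RegionMap,
    region_params: Mapping[str, RegionParams] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell wind fields at time ``t`` (days), in raw table units.

    ``constant`` mode reads the static ``vx, vy`` from ``region_params``;
    ``periodic`` mode selects the day or night table.
    """
    window = schedule.window_at(t)
    shape = regions.grid.shape
    vx = np.zeros(shape)
    vy = np.zeros(shape)
    for label in regions.labels_present():
        m = regions.mask(label)
        if window == "constant":
            if region_params is None:
                raise ValueError("constant wind needs the region table")
            row = region_params[label]
            vx[m], vy[m] = row.vx, row.vy
        else:
            vals = schedule.values(window)
            vx[m], vy[m] = vals.get(label, (0.0, 0.0))
    return vx, vy


@dataclass(frozen=True)
class InitialSpec:
    """Initial densities: an amplitude pair painted on a seed region.

    ``kind`` selects the seed support: a labelled region (``region``), an
    explicit rectangle (``rect``, meters), a Gaussian bump (``gaussian``)
    or the whole domain (``uniform``).
    """

    kind: str = "region"
    label: str | None = None
    rect: tuple[float, float, float, float] | None = None  # x0, y0, x1, y1
    center: tuple[float, float] | None = None
    sigma: float | None = None
    m_amplitude: float = 25.0
    a_amplitude: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("region", "rect", "gaussian", "uniform"):
            raise ValueError(f"unknown initial-condition kind {self.kind!r}")
        if self.kind == "region" and self.label is None:
            raise ValueError("region initial condition needs a label")
        if self.kind == "rect" and self.rect is None:
            raise ValueError("rect initial condition needs a rectangle")
        if self.kind == "gaussian" and (self.center is None or self.sigma is None):
            raise ValueError("gaussian initial condition needs center and sigma")

    def fields(self, grid: Grid, regions: RegionMap) -> tuple[np.ndarray, np.ndarray]:
        if self.kind == "uniform":
            shape_fn = np.ones(grid.shape)
        elif self.kind == "region":
            shape_fn = regions.mask(self.label).astype(float)
        elif self.kind == "rect":
            x0, y0, x1, y1 = self.rect
            X, Y = grid.center_mesh()
            shape_fn = ((X >= x0) & (X < x1) & (Y >= y0) & (Y < y1)).astype(float)
        else:
            X, Y = grid.center_mesh()
            cx, cy = self.center
            shape_fn = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2)
                              / (2.0 * self.sigma ** 2))
        return self.m_amplitude * shape_fn, self.a_amplitude * shape_fn


_BCKinds = Mapping[str, object]


@dataclass
class ScenarioConfig:
    """Complete, validated description of one simulation run."""

    name: str
    Lx: float
    Ly: float
    dx: float
    rectangles: tuple[Rectangle, ...]
    region_params: Mapping[str, RegionParams]
    initial: InitialSpec
    background: str = "street"
    biology: Mapping[str, float] = field(default_factory=dict)
    transport_unit: str = PRESET_TRANSPORT_UNIT
    bc: BoundarySpec = field(default_factory=BoundarySpec.all_neumann)
    wind: WindSchedule = field(default_factory=WindSchedule)
    duration: float = 42.0
    snapshots: tuple[float, ...] = (0.0, 21.0, 42.0)
    safety: float = 0.9
    record_interval: float = 1.0
    dt_cap_seconds: float = 600.0
    d_face: str = "harmonic"
    disable_reactions: bool = False
    provenance: str = ""

    # -- construction helpers -------------------------------------------

    def grid(self) -> Grid:
        return Grid.from_spacing(self.Lx, self.Ly, self.dx)

    def regions(self, grid: Grid | None = None) -> RegionMap:
        grid = grid or self.grid()
        return rasterize_blocks(grid, self.rectangles,
                                background=self.background,
                                provenance=self.provenance)

    def parameter_fields(
        self, regions: RegionMap | None = None, window: str = "constant"
    ) -> ParameterFields:
        regions = regions if regions is not None else self.regions()
        table = dict(self.region_params)
        if self.wind.mode == "periodic":
            vals = self.wind.values(window)
            for label, row in table.items():
                vx, vy = vals.get(label, (0.0, 0.0))
                table[label] = replace(row, vx=vx, vy=vy)
        return build_parameter_fields(
            regions, table, biology=self.biology,
            transport_unit=self.transport_unit,
        )

    def boundary_spec(self) -> BoundarySpec:
        return self.bc

    def initial_state(self, grid: Grid, regions: RegionMap):
        return self.initial.fields(grid, regions)

    def window_key_at(self, t: float) -> str:
        return self.wind.window_at(t)

    def wind_switch_times(self, duration: float) -> list[float]:
        return self.wind.switch_times(duration)

    def validate(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not 0 < self.safety <= 1:
            raise ValueError("safety must lie in (0, 1]")
        if self.initial.kind == "region":
            labels = {lab for lab, *_ in self.rectangles} | {self.background}
            if self.initial.label not in labels:
                raise ValueError(
                    f"initial-condition label {self.initial.label!r} does not "
                    "occur in the scenario geometry"
                )
        grid = self.grid()
        regions = self.regions(grid)
        # builds all windows once; raises on any field invariant breach
        for window in (("day", "night") if self.wind.mode == "periodic"
                       else ("constant",)):
            self.parameter_fields(regions, window=window)


# ---------------------------------------------------------------------------
# Preset geometries
# ---------------------------------------------------------------------------

def _lattice(cols: Sequence[tuple[float, float]],
             rows: Sequence[tuple[float, float]],
             label: str = "block",
             skip: Sequence[tuple[int, int]] = ()) -> list[Rectangle]:
    """Rectangles for a lattice of blocks; ``skip`` holds (col, row) slots
    left out (they keep the street background)."""
    rects = []
    for ci, (x0, x1) in enumerate(cols):
        for ri, (y0, y1) in enumerate(rows):
            if (ci, ri) in skip:
                continue
            rects.append((label, x0, y0, x1, y1))
    return rects


def example1(dx: float = 2.0) -> ScenarioConfig:
    """Generic 200 x 200 m quarter: nine 40 m blocks on a 20 m street
    lattice; constant wind along the streets, stronger in y than in x."""
    cols = [(20.0, 60.0), (80.0, 120.0), (140.0, 180.0)]
    rects = _lattice(cols, cols)
    params = {
        "block": RegionParams(psi=1.0, vx=0.0, vy=0.0,
                              Dx=3.75e-3, Dy=3.75e-3),
        "street": RegionParams(psi=0.3, vx=5.0e-2, vy=1.5e-1,
                               Dx=1.25e-2, Dy=1.25e-2),
    }
    return ScenarioConfig(
        name="example1",
        Lx=200.0, Ly=200.0, dx=dx,
        rectangles=tuple(rects),
        region_params=params,
        initial=InitialSpec(kind="rect", rect=(80.0, 80.0, 120.0, 120.0)),
        provenance="generic quarter, 3x3 blocks of 40 m on 20 m streets; "
                   "seed in the central block",
    )


# Juiz de Fora lattice: 4 block columns x 5 block rows = 20 slots on a 20 m
# street lattice; one central slot is the park, two slots stay open
# (street-level squares), leaving exactly 17 building blocks.
_JF_COLS = [(20.0, 120.0), (140.0, 240.0), (260.0, 360.0), (380.0, 480.0)]
_JF_ROWS = [(20.0, 96.0), (116.0, 192.0), (212.0, 288.0), (308.0, 384.0),
            (404.0, 480.0)]
_JF_PARK = (1, 2)            # central-west slot
_JF_OPEN = ((2, 2), (3, 0))  # square facing the park + one corner slot
#: Corridor (x range) of the one-street insecticide application: the
#: central vertical street plus its immediate surroundings.
_JF_CORRIDOR = (225.0, 275.0)


def _jf_rectangles(treated_corridor: bool = False) -> list[Rectangle]:
    rects: list[Rectangle] = []
    if treated_corridor:
        x0, x1 = _JF_CORRIDOR
        rects.append(("treated-street", x0, 0.0, x1, 500.0))
    rects += _lattice(_JF_COLS, _JF_ROWS, skip=(_JF_PARK, *_JF_OPEN))
    c, r = _JF_PARK
    rects.append(("park", _JF_COLS[c][0], _JF_ROWS[r][0],
                  _JF_COLS[c][1], _JF_ROWS[r][1]))
    return rects


_JF_PARAMS = {
    "block": RegionParams(psi=1.0, vx=0.0, vy=0.0, Dx=3.75e-3, Dy=3.75e-3),
    "street": RegionParams(psi=0.3, vx=-1.0e-1, vy=5.0e-2,
                           Dx=1.25e-2, Dy=1.25e-2),
    "park": RegionParams(psi=0.8, vx=-5.0e-2, vy=2.5e-2,
                         Dx=1.25e-2, Dy=1.25e-2),
}


def example2(dx: float = 2.0) -> ScenarioConfig:
    """Juiz de Fora city center (500 x 500 m, 17 blocks + park), no
    insecticides; both phases seeded in the park."""
    return ScenarioConfig(
        name="example2",
        Lx=500.0, Ly=500.0, dx=dx,
        rectangles=tuple(_jf_rectangles()),
        region_params=dict(_JF_PARAMS),
        initial=InitialSpec(kind="region", label="park"),
        provenance="Juiz de Fora center reconstruction: 4x5 lattice of "
                   "100x76 m slots on 20 m streets; park in a central slot, "
                   "two slots open, 17 building blocks",
    )


def example3(variant: str = "all_streets", dx: float = 2.0) -> ScenarioConfig:
    """Juiz de Fora with adulticide: ``one_street`` applies h1 = 7.6/day on
    the central street corridor, ``all_streets`` h1 = 0.928/day on every
    street; h2 = 0 everywhere (adulticides do not reach the aquatic phase).
    The corridor width is chosen so that both variants deploy roughly the
    same total amount of insecticide (h1 x treated area)."""
    base = example2(dx=dx)
    params = dict(_JF_PARAMS)
    if variant == "one_street":
        params["treated-street"] = replace(params["street"], h1=7.6)
        rects = tuple(_jf_rectangles(treated_corridor=True))
    elif variant == "all_streets":
        params["street"] = replace(params["street"], h1=0.928)
        rects = base.rectangles
    else:
        raise ValueError(
            f"unknown variant {variant!r}; use 'one_street' or 'all_streets'"
        )
    return replace(
        base,
        name=f"example3:{variant}",
        rectangles=rects,
        region_params=params,
    )


# Copacabana lattice: 3 block columns x 4 rows west of a 50 m beach strip
# along the sea-facing (right) side.
_RIO_COLS = [(20.0, 110.0), (130.0, 220.0), (240.0, 330.0)]
_RIO_ROWS = [(20.0, 95.0), (115.0, 190.0), (210.0, 285.0), (305.0, 380.0)]
_RIO_BEACH = (350.0, 0.0, 400.0, 400.0)


def example4(dx: float = 2.0) -> ScenarioConfig:
    """Copacabana beach front (400 x 400 m, 12 blocks + beach strip).

    Day wind blows from the sea into the city, night wind reverses along
    shore; the beach wind is twice the street wind componentwise.  The
    sea-facing (right) side carries a zero-Dirichlet condition for the
    winged phase; the other three sides are zero-gradient.  Both phases are
    seeded in a small park-like square in the interior."""
    rects = _lattice(_RIO_COLS, _RIO_ROWS)
    rects.append(("beach", *_RIO_BEACH))
    params = {
        "block": RegionParams(psi=1.0, Dx=3.75e-3, Dy=3.75e-3),
        "street": RegionParams(psi=0.3, Dx=1.25e-2, Dy=1.25e-2),
        "beach": RegionParams(psi=0.8, Dx=1.25e-2, Dy=1.25e-2),
    }
    wind = WindSchedule(
        mode="periodic",
        day={"block": (0.0, 0.0), "street": (-0.2, 0.15),
             "beach": (-0.4, 0.3)},
        night={"block": (0.0, 0.0), "street": (0.0, -0.25),
               "beach": (0.0, -0.5)},
    )
    return ScenarioConfig(
        name="example4",
        Lx=400.0, Ly=400.0, dx=dx,
        rectangles=tuple(rects),
        region_params=params,
        initial=InitialSpec(kind="rect", rect=(160.0, 160.0, 200.0, 200.0)),
        bc=BoundarySpec.with_dirichlet("right", 0.0),
        wind=wind,
        provenance="Copacabana reconstruction: 3x4 lattice of 90x75 m "
                   "blocks on 20 m streets, 50 m beach strip on the "
                   "sea-facing side; seed in a small interior square",
    )


PRESETS = {
    "example1": example1,
    "example2": example2,
    "example3:one_street": lambda dx=2.0: example3("one_street", dx=dx),
    "example3:all_streets": lambda dx=2.0: example3("all_streets", dx=dx),
    "example4": example4,
}


def get_preset(name: str, dx: float | None = None) -> ScenarioConfig:
    """Look up a preset by name (``example3`` accepts ``example3:variant``)."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return PRESETS[name]() if dx is None else PRESETS[name](dx=dx)
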