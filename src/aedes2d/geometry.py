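"""Rectangular urban rasters and the per-cell coefficient fields of the model.

The computational domain is a rectangle ``[0, Lx] x [0, Ly]`` covered by a
uniform cell-centered mesh.  A :class:`RegionMap` assigns every cell one
categorical land-use label (building block, street, park, beach, or a street
segment treated with insecticide); :func:`build_parameter_fields` then turns
a per-region table of coefficients into piecewise-constant per-cell fields:

* ``psi`` -- dimensionless area-support coefficient in ``(0, 1]``: the
  fraction of mosquitoes the location can support.  The plotted/integrated
  population is always ``psi * density``.
* ``vx, vy`` -- wind velocity advecting the winged phase.
* ``Dx, Dy`` -- diffusion coefficients for the random flight of winged
  females.
* ``h1, h2`` -- additional per-day mortality from insecticides (adulticide
  acting on the winged phase; larvicide on the aquatic phase).

Internally all rates are kept per day and all transport coefficients in
m/day and m^2/day; ``transport_unit`` selects how the table values are
interpreted at construction time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Grid",
    "RegionMap",
    "RegionParams",
    "ParameterFields",
    "rasterize_blocks",
    "build_parameter_fields",
    "KNOWN_LABELS",
    "DEFAULT_BIOLOGY",
    "PSI_MIN",
    "SECONDS_PER_DAY",
    "TRANSPORT_UNITS",
]

#: Closed set of admissible region labels.
KNOWN_LABELS = ("street", "block", "park", "beach", "treated-street")

#: Smallest admissible area-support coefficient.  psi divides the discrete
#: update, so psi = 0 is rejected even though the continuous model allows it.
PSI_MIN = 1e-6

SECONDS_PER_DAY = 86400.0

#: Base biology constants (maturation, oviposition, capacities, mortality).
#: k1 and k2 act as dimensionless density scales of the logistic terms.
DEFAULT_BIOLOGY: Mapping[str, float] = {
    "gamma": 0.2,   # aquatic -> winged maturation rate, day^-1
    "r": 30.0,      # oviposition rate, day^-1
    "k1": 25.0,     # winged-phase carrying capacity (density scale)
    "k2": 100.0,    # aquatic-phase carrying capacity (density scale)
    "mu1": 0.04,    # winged mortality, day^-1
    "mu2": 0.01,    # aquatic mortality, day^-1
}

#: (velocity scale -> m/day, diffusivity scale -> m^2/day)
TRANSPORT_UNITS: Mapping[str, tuple[float, float]] = {
    "m/s": (SECONDS_PER_DAY, SECONDS_PER_DAY),
    "m/day": (1.0, 1.0),
    "km/day": (1.0e3, 1.0e6),
}


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centered rectangular mesh.

    Cell ``(i, j)`` (0-based, i along x, j along y) has its center at
    ``((i + 1/2) dx, (j + 1/2) dy)``; faces sit at integer multiples of the
    spacings (half-open cell convention).  Fields are stored as arrays of
    shape ``(ny, nx)`` with row ``j = 0`` at ``y = 0``.
    """

    nx: int
    ny: int
    Lx: float
    Ly: float

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid needs at least one cell per direction")
        if not (self.Lx > 0 and self.Ly > 0):
            raise ValueError("domain extents must be positive")

    @classmethod
    def from_spacing(cls, Lx: float, Ly: float, dx: float) -> "Grid":
        """Build a grid with (approximately) square cells of size ``dx``."""
        nx = int(round(Lx / dx))
        ny = int(round(Ly / dx))
        return cls(nx=nx, ny=ny, Lx=Lx, Ly=Ly)

    @property
    def dx(self) -> float:
        return self.Lx / self.nx

    @property
    def dy(self) -> float:
        return self.Ly / self.ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` arrays of cell-center coordinates, shape (ny, nx)."""
        return np.meshgrid(self.x_centers, self.y_centers)


class RegionMap:
    """Per-cell categorical land-use labels on a :class:`Grid`.

    Labels are stored as small integer codes with a legend; the label set is
    closed (:data:`KNOWN_LABELS`), unknown labels are rejected.
    """

    def __init__(
        self,
        grid: Grid,
        codes: np.ndarray,
        legend: Sequence[str],
        provenance: str = "",
    ) -> None:
        legend = tuple(legend)
        for label in legend:
            if label not in KNOWN_LABELS:
                raise ValueError(
                    f"unknown region label {label!r}; admissible labels are "
                    f"{KNOWN_LABELS}"
                )
        codes = np.asarray(codes, dtype=np.int16)
        if codes.shape != grid.shape:
            raise ValueError(
                f"codes shape {codes.shape} does not match grid {grid.shape}"
            )
        if codes.size and (codes.min() < 0 or codes.max() >= len(legend)):
            raise ValueError("region codes outside the legend range")
        self.grid = grid
        self.codes = codes
        self.legend = legend
        self.provenance = provenance

    def labels_present(self) -> tuple[str, ...]:
        """Labels that actually occur, in legend order."""
        present = np.unique(self.codes)
        return tuple(self.legend[c] for c in present)

    def mask(self, label: str) -> np.ndarray:
        if label not in self.legend:
            raise KeyError(f"label {label!r} not in legend {self.legend}")
        return self.codes == self.legend.index(label)

    def area(self, label: str) -> float:
        """Total cell area carrying ``label`` (m^2)."""
        return float(self.mask(label).sum()) * self.grid.cell_area

    def relabel(self, mask: np.ndarray, label: str) -> "RegionMap":
        """Return a copy with cells under ``mask`` assigned ``label``."""
        if label in self.legend:
            legend = self.legend
            code = legend.index(label)
        else:
            legend = self.legend + (label,)
            code = len(legend) - 1
        codes = self.codes.copy()
        codes[np.asarray(mask, dtype=bool)] = code
        return RegionMap(self.grid, codes, legend, provenance=self.provenance)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionMap):
            return NotImplemented
        if self.grid != other.grid:
            return False
        mine = np.array([self.legend[c] for c in self.codes.ravel()])
        theirs = np.array([other.legend[c] for c in other.codes.ravel()])
        return bool((mine == theirs).all())

    # -- plain-text persistence -------------------------------------------

    def to_csv(self, path) -> None:
        """Write the integer label grid as CSV (row 0 = y = 0) with a
        legend and grid geometry in ``#`` header lines."""
        header = (
            f"Lx={self.grid.Lx} Ly={self.grid.Ly} "
            f"nx={self.grid.nx} ny={self.grid.ny}\n"
            "legend: " + " ".join(f"{i}={lab}" for i, lab in enumerate(self.legend))
        )
        np.savetxt(path, self.codes, fmt="%d", delimiter=",", header=header)

    @classmethod
    def from_csv(cls, path) -> "RegionMap":
        with open(path) as fh:
            lines = fh.readlines()
        head = [ln[1:].strip() for ln in lines if ln.startswith("#")]
        geom = dict(re.findall(r"(\w+)=([0-9.eE+-]+)", head[0]))
        legend_line = next(ln for ln in head if ln.startswith("legend:"))
        pairs = re.findall(r"(\d+)=([\w-]+)", legend_line)
        legend = [lab for _, lab in sorted(pairs, key=lambda p: int(p[0]))]
        grid = Grid(
            nx=int(geom["nx"]), ny=int(geom["ny"]),
            Lx=float(geom["Lx"]), Ly=float(geom["Ly"]),
        )
        codes = np.loadtxt(
            [ln for ln in lines if not ln.startswith("#")],
            delimiter=",", dtype=np.int16,
        ).reshape(grid.shape)
        return cls(grid, codes, legend)


Rectangle = tuple[str, float, float, float, float]


def rasterize_blocks(
    grid: Grid,
    rectangles: Iterable[Rectangle],
    background: str = "street",
    provenance: str = "",
) -> RegionMap:
    """Paint axis-aligned rectangles ``(label, x0, y0, x1, y1)`` onto the grid.

    Each cell receives the label of the *last* rectangle covering its center;
    uncovered cells keep the ``background`` label.  Rectangles must be
    non-empty and lie inside the domain.
    """
    rectangles = list(rectangles)
    if background not in KNOWN_LABELS:
        raise ValueError(f"unknown background label {background!r}")
    legend = [background]
    codes = np.zeros(grid.shape, dtype=np.int16)
    X, Y = grid.center_mesh()
    tol = 1e-9 * max(grid.Lx, grid.Ly)
    for label, x0, y0, x1, y1 in rectangles:
        if label not in KNOWN_LABELS:
            raise ValueError(f"unknown region label {label!r}")
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"empty rectangle {(label, x0, y0, x1, y1)}")
        if x0 < -tol or y0 < -tol or x1 > grid.Lx + tol or y1 > grid.Ly + tol:
            raise ValueError(
                f"rectangle {(label, x0, y0, x1, y1)} lies outside the domain "
                f"[0,{grid.Lx}]x[0,{grid.Ly}]"
            )
        if label not in legend:
            legend.append(label)
        inside = (X >= x0) & (X < x1) & (Y >= y0) & (Y < y1)
        codes[inside] = legend.index(label)
    return RegionMap(grid, codes, legend, provenance=provenance)


@dataclass(frozen=True)
class RegionParams:
    """One row of a per-region coefficient table (raw table units)."""

    psi: float
    vx: float = 0.0
    vy: float = 0.0
    Dx: float = 0.0
    Dy: float = 0.0
    h1: float = 0.0
    h2: float = 0.0


@dataclass
class ParameterFields:
    """Per-cell coefficient fields plus scalar biology constants.

    Transport fields are stored internally in m/day and m^2/day; all rate
    constants are per day.
    """

    psi: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    Dx: np.ndarray
    Dy: np.ndarray
    h1: np.ndarray
    h2: np.ndarray
    gamma: float = DEFAULT_BIOLOGY["gamma"]
    r: float = DEFAULT_BIOLOGY["r"]
    k1: float = DEFAULT_BIOLOGY["k1"]
    k2: float = DEFAULT_BIOLOGY["k2"]
    mu1: float = DEFAULT_BIOLOGY["mu1"]
    mu2: float = DEFAULT_BIOLOGY["mu2"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.psi.shape

    def validate(self) -> None:
        shapes = {f.shape for f in (self.psi, self.vx, self.vy,
                                    self.Dx, self.Dy, self.h1, self.h2)}
        if len(shapes) != 1:
            raise ValueError(f"coefficient fields disagree in shape: {shapes}")
        if np.any(self.psi < PSI_MIN) or np.any(self.psi > 1.0):
            raise ValueError(
                f"psi must lie in [{PSI_MIN}, 1]; got range "
                f"[{self.psi.min()}, {self.psi.max()}]"
            )
        for name in ("Dx", "Dy", "h1", "h2"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        for name in ("gamma", "r", "k1", "k2", "mu1", "mu2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def build_parameter_fields(
    regions: RegionMap,
    per_region_values: Mapping[str, RegionParams | Mapping[str, float]],
    biology: Mapping[str, float] | None = None,
    transport_unit: str = "m/s",
) -> ParameterFields:
    """Expand a per-region coefficient table into per-cell fields.

    ``per_region_values`` must cover every label present in ``regions``;
    fields come out piecewise constant by region.  ``transport_unit``
    states the unit in which the table's velocities/diffusivities are given
    and controls conversion to the internal m/day scale.
    """
    if transport_unit not in TRANSPORT_UNITS:
        raise ValueError(
            f"unknown transport unit {transport_unit!r}; "
            f"choose from {sorted(TRANSPORT_UNITS)}"
        )
    v_scale, d_scale = TRANSPORT_UNITS[transport_unit]

    table: dict[str, RegionParams] = {}
    for label, row in per_region_values.items():
        if isinstance(row, Mapping):
            row = RegionParams(**row)
        table[label] = row

    missing = [lab for lab in regions.labels_present() if lab not in table]
    if missing:
        raise KeyError(
            f"no parameter values supplied for region label(s) {missing}"
        )

    shape = regions.grid.shape
    fields = {name: np.zeros(shape) for name in
              ("psi", "vx", "vy", "Dx", "Dy", "h1", "h2")}
    for label in regions.labels_present():
        row = table[label]
        if not (PSI_MIN <= row.psi <= 1.0):
            raise ValueError(
                f"psi for region {label!r} must lie in [{PSI_MIN}, 1], "
                f"got {row.psi}"
            )
        m = regions.mask(label)
        fields["psi"][m] = row.psi
        fields["vx"][m] = row.vx * v_scale
        fields["vy"][m] = row.vy * v_scale
        fields["Dx"][m] = row.Dx * d_scale
        fields["Dy"][m] = row.Dy * d_scale
        fields["h1"][m] = row.h1
        fields["h2"][m] = row.h2

    bio = dict(DEFAULT_BIOLOGY)
    if biology:
        unknown = set(biology) - set(bio)
        if unknown:
            raise KeyError(f"unknown biology constant(s) {sorted(unknown)}")
        bio.update(biology)

    p = ParameterFields(**fields, **bio)
    p.validate()
    return p
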