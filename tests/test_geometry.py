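"""Raster construction, label bookkeeping and coefficient-field assembly."""

import numpy as np
import pytest

from aedes2d.geometry import (
    Grid,
    RegionMap,
    RegionParams,
    SECONDS_PER_DAY,
    build_parameter_fields,
    rasterize_blocks,
)
from aedes2d.scenarios import example2


def test_grid_geometry_and_validation():
    g = Grid.from_spacing(200.0, 100.0, 2.0)
    assert (g.nx, g.ny) == (100, 50)
    assert g.dx == pytest.approx(2.0) and g.dy == pytest.approx(2.0)
    assert g.x_centers[0] == pytest.approx(1.0)      # (i + 1/2) dx
    assert g.y_centers[-1] == pytest.approx(99.0)
    assert g.cell_area == pytest.approx(4.0)
    with pytest.raises(ValueError):
        Grid(nx=0, ny=10, Lx=10.0, Ly=10.0)
    with pytest.raises(ValueError):
        Grid(nx=10, ny=10, Lx=-1.0, Ly=10.0)


def test_rasterize_background_fill():
    g = Grid.from_spacing(200.0, 200.0, 10.0)
    rm = rasterize_blocks(g, [], background="street")
    assert rm.labels_present() == ("street",)
    assert rm.area("street") == pytest.approx(200.0 * 200.0)


def test_rasterize_single_rectangle_cell_centers():
    # dx = 100 m: only the lower-left cell center (50, 50) falls inside
    g = Grid(nx=2, ny=2, Lx=200.0, Ly=200.0)
    rm = rasterize_blocks(g, [("block", 0.0, 0.0, 100.0, 100.0)])
    assert rm.mask("block").sum() == 1
    assert bool(rm.mask("block")[0, 0])


def test_rasterize_last_rectangle_wins():
    g = Grid.from_spacing(100.0, 100.0, 10.0)
    rm = rasterize_blocks(
        g,
        [("block", 0.0, 0.0, 100.0, 100.0), ("park", 0.0, 0.0, 50.0, 50.0)],
    )
    assert bool(rm.mask("park")[0, 0])
    assert not rm.mask("block")[0, 0]


@pytest.mark.parametrize(
    "rect",
    [
        ("block", -10.0, 0.0, 50.0, 50.0),   # outside the domain
        ("block", 0.0, 0.0, 120.0, 50.0),    # beyond Lx
        ("block", 50.0, 50.0, 50.0, 80.0),   # empty (x1 <= x0)
        ("lagoon", 0.0, 0.0, 50.0, 50.0),    # unknown label
    ],
)
def test_rasterize_rejects_bad_rectangles(rect):
    g = Grid.from_spacing(100.0, 100.0, 10.0)
    with pytest.raises(ValueError):
        rasterize_blocks(g, [rect])


def test_rasterize_area_conservation():
    # painted label areas match rectangle areas to one cell layer per edge
    g = Grid.from_spacing(100.0, 100.0, 2.0)
    rects = [("block", 13.0, 7.0, 61.0, 43.0), ("park", 70.0, 50.0, 95.0, 99.0)]
    rm = rasterize_blocks(g, rects)
    for label, x0, y0, x1, y1 in rects:
        exact = (x1 - x0) * (y1 - y0)
        margin = 2 * g.dx * ((x1 - x0) + (y1 - y0))  # one layer per edge
        assert abs(rm.area(label) - exact) <= margin


def test_juiz_de_fora_preset_layout():
    cfg = example2(dx=2.0)
    rm = cfg.regions()
    assert set(rm.labels_present()) == {"block", "street", "park"}
    # 17 building blocks in the rectangle list
    assert sum(1 for lab, *_ in cfg.rectangles if lab == "block") == 17
    # the park is one contiguous axis-aligned rectangle: its mask fills
    # its own bounding box exactly
    park = rm.mask("park")
    ys, xs = np.nonzero(park)
    bbox = park[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    assert bbox.all()


def test_region_map_csv_roundtrip(tmp_path):
    cfg = example2(dx=10.0)
    rm = cfg.regions()
    path = tmp_path / "regions.csv"
    rm.to_csv(path)
    back = RegionMap.from_csv(path)
    assert back == rm
    assert back.grid == rm.grid


def test_build_fields_piecewise_constant_values():
    g = Grid.from_spacing(100.0, 100.0, 10.0)
    rm = rasterize_blocks(g, [("block", 0.0, 0.0, 50.0, 100.0)])
    table = {
        "street": RegionParams(psi=0.3, vx=5.0e-2, vy=1.5e-1,
                               Dx=1.25e-2, Dy=1.25e-2),
        "block": RegionParams(psi=1.0, Dx=3.75e-3, Dy=3.75e-3),
    }
    p = build_parameter_fields(rm, table, transport_unit="m/day")
    street = rm.mask("street")
    assert np.all(p.psi[street] == 0.3)
    assert np.all(p.vx[street] == 5.0e-2)
    assert np.all(p.vy[street] == 1.5e-1)
    assert np.all(p.Dx[rm.mask("block")] == 3.75e-3)
    assert np.all(p.h1 == 0.0) and np.all(p.h2 == 0.0)


@pytest.mark.parametrize(
    "unit,v_scale,d_scale",
    [("m/s", SECONDS_PER_DAY, SECONDS_PER_DAY),
     ("m/day", 1.0, 1.0),
     ("km/day", 1.0e3, 1.0e6)],
)
def test_transport_unit_conversion(unit, v_scale, d_scale):
    g = Grid.from_spacing(40.0, 40.0, 10.0)
    rm = rasterize_blocks(g, [])
    table = {"street": RegionParams(psi=0.5, vx=2.0, Dy=3.0)}
    p = build_parameter_fields(rm, table, transport_unit=unit)
    assert np.all(p.vx == 2.0 * v_scale)
    assert np.all(p.Dy == 3.0 * d_scale)


def test_build_fields_errors():
    g = Grid.from_spacing(40.0, 40.0, 10.0)
    rm = rasterize_blocks(g, [("block", 0.0, 0.0, 20.0, 20.0)])
    with pytest.raises(KeyError, match="block"):
        build_parameter_fields(rm, {"street": RegionParams(psi=0.3)})
    with pytest.raises(ValueError, match="psi"):
        build_parameter_fields(
            rm,
            {"street": RegionParams(psi=1.5), "block": RegionParams(psi=1.0)},
        )
    with pytest.raises(KeyError):
        build_parameter_fields(
            rm,
            {"street": RegionParams(psi=0.3), "block": RegionParams(psi=1.0)},
            biology={"sigma": 1.0},
        )


def test_build_fields_idempotent_and_order_independent():
    g = Grid.from_spacing(60.0, 60.0, 10.0)
    rm = rasterize_blocks(g, [("block", 0.0, 0.0, 30.0, 60.0),
                              ("park", 30.0, 30.0, 60.0, 60.0)])
    table = {
        "street": RegionParams(psi=0.3, vx=1.0),
        "block": RegionParams(psi=1.0, Dx=2.0),
        "park": RegionParams(psi=0.8, vy=3.0),
    }
    reordered = dict(reversed(list(table.items())))
    p1 = build_parameter_fields(rm, table, transport_unit="m/day")
    p2 = build_parameter_fields(rm, table, transport_unit="m/day")
    p3 = build_parameter_fields(rm, reordered, transport_unit="m/day")
    for name in ("psi", "vx", "vy", "Dx", "Dy", "h1", "h2"):
        np.testing.assert_array_equal(getattr(p1, name), getattr(p2, name))
        np.testing.assert_array_equal(getattr(p1, name), getattr(p3, name))
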