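"""Shared fixtures: coarse-grid scenario runs reused across test modules.

The insecticide-comparison runs use a 50x50 coarse tier (dx = 10 m); the
reduction percentages they produce are grid-converged to well under a
percentage point against the 125x125 production tier.
"""

from __future__ import annotations

from dataclasses import replace

import pytest

import aedes2d as a

COARSE_DX = 10.0


@pytest.fixture(scope="session")
def jf_runs():
    """Juiz de Fora baseline + both insecticide variants at the coarse tier."""
    out = {}
    for name in ("example2", "example3:one_street", "example3:all_streets"):
        cfg = replace(a.get_preset(name, dx=COARSE_DX), snapshots=())
        out[name] = a.simulate(cfg)
    return out


@pytest.fixture(scope="session")
def ex1_run():
    cfg = replace(a.get_preset("example1", dx=COARSE_DX), snapshots=())
    return a.simulate(cfg)


@pytest.fixture(scope="session")
def ex4_run():
    cfg = replace(a.get_preset("example4", dx=COARSE_DX),
                  duration=21.0, snapshots=(0.0, 21.0))
    return a.simulate(cfg)
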