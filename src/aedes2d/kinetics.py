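"""Local (non-spatial) reaction terms of the two-phase mosquito model.

The winged phase M (mature females) is fed by maturation of the aquatic
phase and drained by natural plus insecticide-induced mortality:

    R_M = gamma * A * (1 - M / k1) - (mu1 + h1) * M

The aquatic phase A (eggs + larvae + pupae) is fed by oviposition,
saturating as breeding sites fill, and drained by mortality, larvicide and
maturation:

    R_A = r * M * (1 - A / k2) - (mu2 + h2 + gamma) * A

All rates are per day.  The logistic factors are kept exactly as written --
transient overshoot above k1/k2 flips the corresponding source negative and
is not floored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .geometry import ParameterFields

__all__ = [
    "winged_reaction",
    "aquatic_reaction",
    "homogeneous_equilibrium",
    "equilibrium_from_rates",
    "Equilibrium",
]


def _check_shapes(M: np.ndarray, A: np.ndarray, p: ParameterFields) -> None:
    M = np.asarray(M)
    A = np.asarray(A)
    if M.shape != A.shape or M.shape != p.shape:
        raise ValueError(
            f"field shapes disagree: M {M.shape}, A {A.shape}, "
            f"parameters {p.shape}"
        )


def winged_reaction(M: np.ndarray, A: np.ndarray, p: ParameterFields) -> np.ndarray:
    """Per-day reaction rate of the winged-phase density (elementwise)."""
    _check_shapes(M, A, p)
    return p.gamma * A * (1.0 - M / p.k1) - (p.mu1 + p.h1) * M


def aquatic_reaction(M: np.ndarray, A: np.ndarray, p: ParameterFields) -> np.ndarray:
    """Per-day reaction rate of the aquatic-phase density (elementwise)."""
    _check_shapes(M, A, p)
    return p.r * M * (1.0 - A / p.k2) - (p.mu2 + p.h2 + p.gamma) * A


@dataclass(frozen=True)
class Equilibrium:
    """Homogeneous steady states of the reaction system.

    ``coexistence`` is ``None`` when the parameters admit only extinction
    (i.e. when ``gamma * r <= (mu1 + h1) * (mu2 + h2 + gamma)``).
    """

    trivial: tuple[float, float]
    coexistence: tuple[float, float] | None

    @property
    def extinction_only(self) -> bool:
        return self.coexistence is None


def equilibrium_from_rates(
    gamma: float,
    r: float,
    k1: float,
    k2: float,
    mu1: float,
    mu2: float,
    h1: float = 0.0,
    h2: float = 0.0,
    rtol: float = 1e-12,
) -> Equilibrium:
    """Solve the spatially homogeneous steady state of the reaction system.

    Setting both reaction rates to zero and eliminating A through the
    aquatic balance ``A(M) = r M k2 / ((mu2+h2+gamma) k2 + r M)`` reduces the
    problem to one scalar root in ``(0, k1)``, bracketed and solved with
    Brent's method.  A positive root exists iff the net reproduction at
    vanishing density exceeds losses: ``gamma r > (mu1+h1)(mu2+h2+gamma)``.
    """
    sa = mu2 + h2 + gamma  # total aquatic loss rate
    sm = mu1 + h1          # total winged loss rate

    def A_of_M(M: float) -> float:
        return r * M * k2 / (sa * k2 + r * M)

    def g(M: float) -> float:
        # winged balance divided by M (removes the trivial root at M = 0)
        return gamma * (A_of_M(M) / M) * (1.0 - M / k1) - sm

    if not gamma * r > sm * sa:
        return Equilibrium(trivial=(0.0, 0.0), coexistence=None)

    lo, hi = 1e-12 * k1, (1.0 - 1e-12) * k1
    M_star = brentq(g, lo, hi, xtol=1e-14, rtol=rtol)
    A_star = A_of_M(M_star)
    return Equilibrium(trivial=(0.0, 0.0), coexistence=(M_star, A_star))


def homogeneous_equilibrium(p: ParameterFields, rtol: float = 1e-12) -> Equilibrium:
    """Equilibrium of :func:`winged_reaction`/:func:`aquatic_reaction` for a
    spatially uniform parameter field (killing terms must be uniform too)."""
    for name in ("h1", "h2"):
        f = getattr(p, name)
        if np.ptp(f) > 0:
            raise ValueError(f"{name} must be uniform for a homogeneous equilibrium")
    return equilibrium_from_rates(
        p.gamma, p.r, p.k1, p.k2, p.mu1, p.mu2,
        h1=float(np.asarray(p.h1).flat[0]),
        h2=float(np.asarray(p.h2).flat[0]),
        rtol=rtol,
    )
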