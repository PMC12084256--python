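"""Reduced models of the planar mass-action system.

Five reductions are implemented:

* ``sqssa`` -- the standard QSS approximation, a scalar substrate ODE.
* ``slow_product`` -- the reduction valid when product formation (k2) is the
  slow process; a scalar substrate ODE with a coupled complex slope.
* ``kumar_josic`` -- a corrected scalar reduction derived by differentiating
  the standard QSS curve along the flow.
* ``calder_siegel`` -- the near-origin reduction built from the slow
  eigenvector slope m.
* ``rqssa`` -- the reverse QSS reduction for high enzyme, exposed as two
  pieces (outer: constant-rate substrate depletion along c = e0; inner:
  exponential complex decay on the c-axis).

Each scalar reduction carries a ``complex_map`` giving the c-coordinate of
its associated QSS curve so that full (s, c) trajectories can be
reconstructed from the 1-D solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .kinetics import PhaseState, RateConstants, origin_spectrum

__all__ = [
    "ReductionModel",
    "sqssa_rhs",
    "slow_product_reduction",
    "slow_product_rhs",
    "kumar_josic_rhs",
    "calder_siegel_rhs",
    "phi",
    "rqssa_reduction",
    "shifted_initial_condition",
    "get_model",
    "MODEL_NAMES",
]


@dataclass(frozen=True)
class ReductionModel:
    """A named scalar substrate reduction with optional complex reconstruction."""

    name: str
    rhs: Callable[[float, RateConstants], float]
    complex_map: Optional[Callable[[float, RateConstants], float]] = None


def sqssa_rhs(s: float, p: RateConstants) -> float:
    """Standard QSSA substrate rate: ds/dt = -k2 e0 s / (K_M + s)."""
    if s < 0:
        raise ValueError(f"s must be nonnegative, got {s}")
    return -p.k2 * p.e0 * s / (p.K_M + s)


def slow_product_rhs(s: float, p: RateConstants) -> float:
    """Substrate rate of the slow-product reduction.

    ds/dt = -k2 e0 s (K_S + s) / (K_S e0 + (K_S + s)^2)
    """
    if s < 0:
        raise ValueError(f"s must be nonnegative, got {s}")
    ks = p.K_S
    return -p.k2 * p.e0 * s * (ks + s) / (ks * p.e0 + (ks + s) ** 2)


def slow_product_reduction(s: float, p: RateConstants) -> tuple[float, float]:
    """Slow-product reduction as a coupled (ds/dt, dc/dt) pair.

    dc/dt = ds/dt * (K_S e0 - K (K_S + s)) / (K_S + s)^2
    """
    sdot = slow_product_rhs(s, p)
    ks = p.K_S
    cdot = sdot * (ks * p.e0 - p.K * (ks + s)) / (ks + s) ** 2
    return sdot, cdot


def phi(s: float, p: RateConstants) -> float:
    """Envelope-width function K_M e0 / (K_M + s)^2.

    Its maximum over [0, s0] is eps_RS = e0/K_M, and the corrected scalar
    reduction equals the standard one divided by (1 + phi(s)).
    """
    return p.K_M * p.e0 / (p.K_M + s) ** 2


def kumar_josic_rhs(s: float, p: RateConstants) -> float:
    """Corrected substrate rate: ds/dt = -k2 e0 s (K_M+s) / (K_M e0 + (K_M+s)^2).

    Algebraically identical to ``sqssa_rhs(s, p) / (1 + phi(s, p))``.
    """
    if s < 0:
        raise ValueError(f"s must be nonnegative, got {s}")
    km = p.K_M
    return -p.k2 * p.e0 * s * (km + s) / (km * p.e0 + (km + s) ** 2)


def calder_siegel_rhs(s: float, p: RateConstants) -> float:
    """Near-origin reduction: ds/dt = -(e0 s / (e0 + m s)) (k1 e0 - k_neg1 m)."""
    if s < 0:
        raise ValueError(f"s must be nonnegative, got {s}")
    if p.e0 == 0:
        return 0.0
    m = origin_spectrum(p).m
    return -(p.e0 * s / (p.e0 + m * s)) * (p.k1 * p.e0 - p.k_neg1 * m)


def rqssa_reduction(piece: str, state: PhaseState | tuple[float, float],
                    p: RateConstants) -> tuple[float, float]:
    """Reverse-QSSA vector field on one of the two critical-manifold pieces.

    ``piece="outer"`` (valid along c = e0, right of the bifurcation point at
    (0, e0)): (ds/dt, dc/dt) = (-k2 e0, 0).

    ``piece="inner"`` (valid on the c-axis): (ds/dt, dc/dt) = (0, -k2 c).
    """
    if isinstance(state, PhaseState):
        c = state.c
    else:
        c = float(state[1])
    if piece == "outer":
        return -p.k2 * p.e0, 0.0
    if piece == "inner":
        return 0.0, -p.k2 * c
    raise ValueError(f"unknown rQSSA piece {piece!r}; expected 'outer' or 'inner'")


def shifted_initial_condition(p: RateConstants, s0: float) -> PhaseState:
    """Initial condition (s0 - e0, e0) for the outer reverse-QSSA piece.

    Only meaningful when the trajectory starts at (s0, 0) with s0 > e0 so
    the fast transient carries it to the line c = e0.
    """
    if s0 <= p.e0:
        raise ValueError(
            f"outside rQSSA outer regime: requires s0 > e0, got s0={s0}, e0={p.e0}"
        )
    return PhaseState(s=s0 - p.e0, c=p.e0)


def _gamma_c_map(s: float, p: RateConstants) -> float:
    return p.e0 * s / (p.K_M + s)


def _gamma_sp_map(s: float, p: RateConstants) -> float:
    ks = p.K_S
    return p.e0 * s / (ks + s) - p.k2 * p.e0 * s / (p.k1 * (ks * p.e0 + (ks + s) ** 2))


def _alpha_cs_map(s: float, p: RateConstants) -> float:
    m = origin_spectrum(p).m
    return m * p.e0 * s / (p.e0 + m * s)


MODEL_NAMES = ("sqssa", "slow_product", "kumar_josic", "calder_siegel", "rqssa")

_MODELS: dict[str, ReductionModel] = {
    "sqssa": ReductionModel("sqssa", sqssa_rhs, _gamma_c_map),
    "slow_product": ReductionModel("slow_product", slow_product_rhs, _gamma_sp_map),
    "kumar_josic": ReductionModel("kumar_josic", kumar_josic_rhs, _gamma_c_map),
    "calder_siegel": ReductionModel("calder_siegel", calder_siegel_rhs, _alpha_cs_map),
}


def get_model(name: str) -> ReductionModel:
    """Look up a scalar reduction by name (rQSSA is piecewise; see
    :func:`rqssa_reduction` and ``simulate.integrate_rqssa_outer``)."""
    try:
        return _MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown reduction {name!r}; expected one of {sorted(_MODELS)}"
        ) from None
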