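"""Nullclines, fence curves, and anti-funnel regions in the (s, c) plane.

A *fence* is a curve whose vector-field residual

    r(s) = dc/dt(s, curve(s)) - curve'(s) * ds/dt(s, curve(s))

has a fixed sign, so that trajectories can only cross it in one direction.
An *anti-funnel* is the region between an upper and a lower fence; when the
fence separation tends to zero the region traps a unique distinguished
solution (the slow manifold).

Curves provided (all vanish at s = 0, all have analytic derivatives):

* ``gamma_c``  -- c-nullcline c = e0 s / (K_M + s); upper fence of every funnel
  built on it.
* ``gamma_s``  -- s-nullcline c = e0 s / (K_S + s).
* ``alpha_cs`` -- m e0 s / (e0 + m s), slope m at the origin; classical lower
  fence.
* ``gamma``    -- the corrected QSS curve, lower fence of the narrowing
  anti-funnel that pins the slow manifold against ``gamma_c``.
* ``gamma_SP`` -- the slow-product QSS curve, an upper fence when e0 < 8 K_S.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from .kinetics import RateConstants, mass_action_rhs, origin_spectrum

__all__ = [
    "CurveSpec",
    "FunnelRegion",
    "CURVE_NAMES",
    "FUNNEL_NAMES",
    "curve",
    "s_star",
    "fence_sign",
    "funnel",
    "curve_ordering_report",
    "default_s_grid",
    "curve_table",
]

CURVE_NAMES = ("gamma_c", "gamma_s", "alpha_cs", "gamma", "gamma_SP")
FUNNEL_NAMES = ("Gamma", "Gamma_cs", "Gamma_0", "Gamma_SP")


@dataclass(frozen=True)
class CurveSpec:
    """A named scalar curve c = value(s) with its analytic derivative."""

    name: str
    value: Callable[[np.ndarray], np.ndarray]
    derivative: Callable[[np.ndarray], np.ndarray]
    validity: Optional[str] = None

    def __call__(self, s):
        return self.value(s)


@dataclass(frozen=True)
class FunnelRegion:
    """Region lower(s) <= c <= upper(s) over a half-open s-interval."""

    name: str
    lower: CurveSpec
    upper: CurveSpec
    s_interval: tuple[float, float]
    narrowing: bool = False

    def contains(self, s: float, c: float, rtol: float = 1e-12) -> bool:
        lo = float(self.lower.value(np.asarray(s, dtype=float)))
        hi = float(self.upper.value(np.asarray(s, dtype=float)))
        slack = rtol * max(abs(lo), abs(hi), 1.0)
        return (self.s_interval[0] <= s < self.s_interval[1]
                and lo - slack <= c <= hi + slack)

    def width(self, s):
        s = np.asarray(s, dtype=float)
        return self.upper.value(s) - self.lower.value(s)


def curve(name: str, p: RateConstants) -> CurveSpec:
    """Build the named curve for parameters ``p``."""
    e0, km, ks, k = p.e0, p.K_M, p.K_S, p.K

    if name == "gamma_c":
        return CurveSpec(
            name,
            lambda s: e0 * np.asarray(s, dtype=float) / (km + s),
            lambda s: e0 * km / (km + np.asarray(s, dtype=float)) ** 2,
        )
    if name == "gamma_s":
        return CurveSpec(
            name,
            lambda s: e0 * np.asarray(s, dtype=float) / (ks + s),
            lambda s: e0 * ks / (ks + np.asarray(s, dtype=float)) ** 2,
        )
    if name == "alpha_cs":
        if p.e0 <= 0:
            raise ValueError("alpha_cs requires e0 > 0")
        m = origin_spectrum(p).m

        def _acs(s):
            s = np.asarray(s, dtype=float)
            return m * e0 * s / (e0 + m * s)

        def _acs_d(s):
            s = np.asarray(s, dtype=float)
            return m * e0**2 / (e0 + m * s) ** 2

        return CurveSpec(name, _acs, _acs_d)
    if name == "gamma":
        # gamma(s) = gamma_s(s) - (k2/k1) * e0 s (K_M+s) /
        #            ((K_S+s)(K_M e0 + (K_M+s)^2))
        def _g(s):
            s = np.asarray(s, dtype=float)
            corr = (p.k2 / p.k1) * e0 * s * (km + s) / (
                (ks + s) * (km * e0 + (km + s) ** 2)
            )
            return e0 * s / (ks + s) - corr

        def _g_d(s):
            s = np.asarray(s, dtype=float)
            num = e0 * s * (km + s)
            num_d = e0 * (km + 2.0 * s)
            den = (ks + s) * (km * e0 + (km + s) ** 2)
            den_d = (km * e0 + (km + s) ** 2) + (ks + s) * 2.0 * (km + s)
            corr_d = (p.k2 / p.k1) * (num_d * den - num * den_d) / den**2
            return e0 * ks / (ks + s) ** 2 - corr_d

        return CurveSpec(name, _g, _g_d)
    if name == "gamma_SP":
        # gamma_SP(s) = gamma_s(s) - (k2/k1) * e0 s / (K_S e0 + (K_S+s)^2)
        def _gsp(s):
            s = np.asarray(s, dtype=float)
            return e0 * s / (ks + s) - (p.k2 / p.k1) * e0 * s / (
                ks * e0 + (ks + s) ** 2
            )

        def _gsp_d(s):
            s = np.asarray(s, dtype=float)
            den = ks * e0 + (ks + s) ** 2
            corr_d = (p.k2 / p.k1) * e0 * (den - s * 2.0 * (ks + s)) / den**2
            return e0 * ks / (ks + s) ** 2 - corr_d

        validity = None if e0 < 8 * ks else "upper-fence role unproven: e0 >= 8 K_S"
        return CurveSpec(name, _gsp, _gsp_d, validity=validity)
    raise ValueError(f"unknown curve {name!r}; expected one of {CURVE_NAMES}")


def s_star(p: RateConstants) -> float:
    """Substrate coordinate of the gamma_SP / gamma_c intersection.

    s* = (k_neg1 / k2)(e0 - K).  Negative when e0 < K, in which case the
    intersection lies outside the first quadrant and is inconsequential.
    """
    if p.k2 <= 0:
        raise ValueError("s_star undefined for k2 = 0")
    return (p.k_neg1 / p.k2) * (p.e0 - p.K)


def fence_sign(curve_spec: CurveSpec, p: RateConstants,
               s_grid: np.ndarray) -> np.ndarray:
    """Signed fence residual r(s) = cdot - curve'(s) * sdot along the curve.

    The caller asserts the sign required by the curve's fence role
    (r < 0 for a lower fence of the slow-manifold anti-funnels here,
    r > 0 for an upper fence).  The grid must be strictly positive: every
    residual vanishes identically at s = 0.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(s_grid <= 0):
        raise ValueError("s_grid must be strictly positive")
    c = curve_spec.value(s_grid)
    dcurve = curve_spec.derivative(s_grid)
    bind = p.k1 * (p.e0 - c) * s_grid
    sdot = -bind + p.k_neg1 * c
    cdot = bind - (p.k_neg1 + p.k2) * c
    return cdot - dcurve * sdot


def funnel(name: str, p: RateConstants,
           s_interval: tuple[float, float] = (0.0, np.inf)) -> FunnelRegion:
    """Build one of the four anti-funnel regions.

    * ``Gamma``    : gamma_c <= c <= gamma_s (positively invariant trapping
      region between the nullclines).
    * ``Gamma_cs`` : gamma_c <= c <= alpha_cs (classical narrowing anti-funnel).
    * ``Gamma_0``  : gamma_c <= c <= gamma (narrowing anti-funnel).
    * ``Gamma_SP`` : gamma_SP <= c <= gamma; requires e0 < 8 K_S.
    """
    if name == "Gamma":
        return FunnelRegion(name, curve("gamma_c", p), curve("gamma_s", p),
                            s_interval, narrowing=False)
    if name == "Gamma_cs":
        return FunnelRegion(name, curve("gamma_c", p), curve("alpha_cs", p),
                            s_interval, narrowing=True)
    if name == "Gamma_0":
        return FunnelRegion(name, curve("gamma_c", p), curve("gamma", p),
                            s_interval, narrowing=True)
    if name == "Gamma_SP":
        if not p.e0 < 8 * p.K_S:
            raise ValueError(
                f"Gamma_SP requires e0 < 8 K_S; got e0={p.e0}, 8 K_S={8 * p.K_S}"
            )
        return FunnelRegion(name, curve("gamma_SP", p), curve("gamma", p),
                            s_interval, narrowing=True)
    raise ValueError(f"unknown funnel {name!r}; expected one of {FUNNEL_NAMES}")


def default_s_grid(p: RateConstants, s0: float = 0.0, n: int = 200) -> np.ndarray:
    """Log-spaced positive grid for fence and ordering checks.

    Spans (1e-6 * max(K_M, e0, 1), 10 * max(s0, K_M, e0)]; s = 0 is excluded
    because every fence residual vanishes there.
    """
    s_min = 1e-6 * max(p.K_M, p.e0, 1.0)
    s_max = 10.0 * max(s0, p.K_M, p.e0)
    return np.geomspace(s_min, s_max, n)


def curve_ordering_report(p: RateConstants, s_grid: np.ndarray) -> dict:
    """Pairwise ordering of gamma_SP vs gamma_c (and gamma) on a grid.

    Returns the per-point boolean comparisons, the theoretical crossover
    ``s_star`` and, when it is positive, a bisection-refined numerical root
    of gamma_SP - gamma_c.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(s_grid <= 0):
        raise ValueError("s_grid must be strictly positive")
    gsp = curve("gamma_SP", p)
    gc = curve("gamma_c", p)
    g = curve("gamma", p)
    diff = gsp.value(s_grid) - gc.value(s_grid)
    sstar = s_star(p) if p.k2 > 0 else np.nan
    crossover = None
    if np.isfinite(sstar) and sstar > 0:
        # gamma_SP - gamma_c = (k2/k1) e0 s [1/((K_S+s)(K_M+s))
        #                                   - 1/(K_S e0 + (K_S+s)^2)];
        # bisect on the bracketed factor, which shares the positive root but
        # does not suffer the catastrophic cancellation of the raw difference
        # when both curves are saturated near c = e0.
        ks, km, e0 = p.K_S, p.K_M, p.e0

        def f(s):
            return 1.0 / ((ks + s) * (km + s)) - 1.0 / (ks * e0 + (ks + s) ** 2)

        lo, hi = 0.5 * sstar, 2.0 * sstar
        # widen until the root is bracketed (it exists exactly at s_star)
        for _ in range(80):
            if f(lo) * f(hi) <= 0:
                break
            lo *= 0.5
            hi *= 2.0
        crossover = brentq(f, lo, hi, xtol=1e-10, rtol=1e-15)
    return {
        "s_grid": s_grid,
        "gsp_above_gc": diff > 0,
        "gsp_below_gamma": gsp.value(s_grid) < g.value(s_grid),
        "s_star": sstar,
        "crossover": crossover,
    }


def curve_table(curve_spec: CurveSpec, s_grid: np.ndarray) -> "np.ndarray":
    """Two-column (s, c) array for CSV export/plotting."""
    s_grid = np.asarray(s_grid, dtype=float)
    return np.column_stack([s_grid, curve_spec.value(s_grid)])
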