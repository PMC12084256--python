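"""Numerical integration of the full mass-action system and its reductions,
crossing-time detection against QSS curves, trajectory error metrics, and
pointwise rate-bound verification.

The full planar system is stiff whenever the fast/slow eigenvalue ratio is
large, so integration defaults to a stiffness-capable method (LSODA) with
tight tolerances and dense output.  Crossing times are refined on the dense
interpolant with bracketed root-finding, never on raw solver steps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import reductions
from .kinetics import PhaseState, RateConstants
from .phase_geometry import CurveSpec, curve, s_star

__all__ = [
    "Trajectory",
    "integrate_full",
    "integrate_reduction",
    "integrate_rqssa_outer",
    "find_crossing",
    "error_metrics",
    "rate_bound_check",
    "sqssa_time_of_substrate",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass
class Trajectory:
    """Time-indexed solution of the full or a reduced model.

    ``sample(t)`` evaluates the dense interpolant, returning (s, c) arrays;
    for scalar reductions c is reconstructed through the model's QSS curve
    (``complex_map``) and may be None if the model has no such curve.
    """

    times: np.ndarray
    s: np.ndarray
    c: Optional[np.ndarray]
    model: str
    params: RateConstants
    events: dict = field(default_factory=dict)
    _interp: Optional[Callable[[np.ndarray], np.ndarray]] = None
    _complex_map: Optional[Callable] = None

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def sample(self, t) -> tuple[np.ndarray, Optional[np.ndarray]]:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self._interp is None:
            raise ValueError("trajectory has no dense interpolant")
        y = self._interp(t)
        if y.ndim == 2 and y.shape[0] == 2:
            return y[0], y[1]
        s = np.atleast_1d(np.asarray(y, dtype=float).squeeze())
        if self._complex_map is not None:
            return s, self._complex_map(s, self.params)
        return s, None

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.times, "s": self.s}
        data["c"] = self.c if self.c is not None else np.full_like(self.s, np.nan)
        frame = pd.DataFrame(data)
        frame["model"] = self.model
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model,
            "params": {
                "k1": self.params.k1,
                "k_neg1": self.params.k_neg1,
                "k2": self.params.k2,
                "e0": self.params.e0,
            },
            "events": {k: (None if v is None else float(v))
                       for k, v in self.events.items()},
            "t": [float(v) for v in self.times],
            "s": [float(v) for v in self.s],
            "c": None if self.c is None else [float(v) for v in self.c],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _default_horizon(p: RateConstants, s0: float, s_stop: float) -> float:
    """Heuristic integration horizon covering the slow depletion regime."""
    if p.k2 * p.e0 > 0 and s0 > 0 and s_stop > 0:
        # closed-form standard-QSSA depletion time to s_stop, with margin;
        # the initial transient is fast and adds little
        t_qssa = (p.K_M * math.log(s0 / s_stop) + s0 - s_stop) / (p.k2 * p.e0)
        return 20.0 * t_qssa
    rate = p.k1 * max(p.e0, s0, 1.0) + p.k_neg1 + p.k2
    return 100.0 / rate if rate > 0 else 1.0


def integrate_full(p: RateConstants, ic: PhaseState,
                   horizon: Optional[float] = None,
                   rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                   s_stop: Optional[float] = None,
                   method: str = "LSODA") -> Trajectory:
    """Integrate the planar mass-action system from ``ic``.

    Stops at ``t = horizon`` or when s drops to ``s_stop`` (default
    1e-3 * s0), whichever comes first.  Dense output is attached for
    crossing detection and resampling.
    """
    s0 = ic.s
    if s_stop is None:
        s_stop = 1e-3 * s0
    if horizon is None:
        horizon = _default_horizon(p, s0, max(s_stop, 1e-6 * max(s0, 1.0)))
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")

    def rhs(t, y):
        s, c = y
        bind = p.k1 * (p.e0 - c) * s
        return (-bind + p.k_neg1 * c, bind - (p.k_neg1 + p.k2) * c)

    def jac(t, y):
        s, c = y
        return [
            [-p.k1 * (p.e0 - c), p.k1 * s + p.k_neg1],
            [p.k1 * (p.e0 - c), -p.k1 * s - (p.k_neg1 + p.k2)],
        ]

    events = []
    if s_stop > 0 and s0 > s_stop:
        def stop(t, y):
            return y[0] - s_stop
        stop.terminal = True
        stop.direction = -1
        events.append(stop)

    sol = solve_ivp(rhs, (0.0, horizon), [ic.s, ic.c], method=method,
                    rtol=rtol, atol=atol, dense_output=True,
                    jac=jac if method in ("LSODA", "Radau", "BDF") else None,
                    events=events or None)
    if not sol.success:
        raise RuntimeError(
            f"full-model integration failed for {p} from ({ic.s}, {ic.c}): "
            f"{sol.message}"
        )
    return Trajectory(times=sol.t, s=sol.y[0], c=sol.y[1], model="full",
                      params=p, _interp=sol.sol)


def integrate_reduction(model: reductions.ReductionModel | str,
                        p: RateConstants, ic: float,
                        horizon: Optional[float] = None,
                        rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                        s_stop: Optional[float] = None) -> Trajectory:
    """Integrate a scalar substrate reduction from s(0) = ic.

    The complex coordinate is reconstructed post hoc through the model's
    QSS curve.  Use :func:`integrate_rqssa_outer` for the piecewise
    reverse-QSSA outer solution.
    """
    if isinstance(model, str):
        model = reductions.get_model(model)
    s0 = float(ic)
    if s0 < 0:
        raise ValueError(f"initial substrate must be nonnegative, got {s0}")
    if s_stop is None:
        s_stop = 1e-3 * s0
    if horizon is None:
        horizon = _default_horizon(p, s0, max(s_stop, 1e-6 * max(s0, 1.0)))

    def rhs(t, y):
        return (model.rhs(max(y[0], 0.0), p),)

    events = []
    if s_stop > 0 and s0 > s_stop:
        def stop(t, y):
            return y[0] - s_stop
        stop.terminal = True
        stop.direction = -1
        events.append(stop)

    sol = solve_ivp(rhs, (0.0, horizon), [s0], method="LSODA",
                    rtol=rtol, atol=atol, dense_output=True,
                    events=events or None)
    if not sol.success:
        raise RuntimeError(
            f"{model.name} integration failed for {p} from s0={s0}: {sol.message}"
        )
    s = sol.y[0]
    c = model.complex_map(s, p) if model.complex_map is not None else None
    if c is not None:
        c = np.asarray(c, dtype=float)
    return Trajectory(times=sol.t, s=s, c=c, model=model.name, params=p,
                      _interp=sol.sol, _complex_map=model.complex_map)


def integrate_rqssa_outer(p: RateConstants, s0: float,
                          n_points: int = 200) -> Trajectory:
    """Closed-form outer reverse-QSSA solution from the shifted initial
    condition (s0 - e0, e0): s(t) = s0 - e0 - k2 e0 t, clipped at zero."""
    ic = reductions.shifted_initial_condition(p, s0)
    rate = p.k2 * p.e0
    if rate <= 0:
        raise ValueError("rQSSA outer piece requires k2 e0 > 0")
    t_hit = ic.s / rate
    times = np.linspace(0.0, t_hit, n_points)
    s = np.clip(ic.s - rate * times, 0.0, None)
    c = np.full_like(s, p.e0)

    def interp(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        sv = np.clip(ic.s - rate * t, 0.0, None)
        return np.vstack([sv, np.full_like(sv, p.e0)])

    return Trajectory(times=times, s=s, c=c, model="rqssa_outer", params=p,
                      _interp=interp)


def find_crossing(traj: Trajectory, curve_spec: CurveSpec,
                  n_scan: int = 4000) -> Optional[float]:
    """First time the trajectory crosses c = curve(s).

    Scans g(t) = c(t) - curve(s(t)) on a fine grid over the dense output and
    refines the first sign change by bracketed root-finding to an absolute
    time tolerance of 1e-9 * (t_end - t0).  Returns None when g never
    changes sign; returns t0 when the trajectory starts on the curve.
    """
    if traj._interp is None:
        raise ValueError("find_crossing requires a dense-output trajectory")

    def g(t):
        s, c = traj.sample(t)
        if c is None:
            raise ValueError("trajectory has no complex coordinate")
        return float((np.asarray(c) - curve_spec.value(np.asarray(s)))[0])

    t0, t1 = traj.t0, traj.t_end
    g0 = g(t0)
    if g0 == 0.0:
        return t0
    ts = np.linspace(t0, t1, n_scan)
    gs = np.array([g(t) for t in ts])
    sign_change = np.nonzero(np.sign(gs[:-1]) * np.sign(gs[1:]) <= 0)[0]
    # discard pseudo-changes caused by exact zeros at the scan start
    for idx in sign_change:
        a, b = ts[idx], ts[idx + 1]
        ga, gb = gs[idx], gs[idx + 1]
        if ga == 0.0:
            return float(a)
        if ga * gb < 0:
            return float(brentq(g, a, b, xtol=max(1e-9 * (t1 - t0), 5e-16)))
        if gb == 0.0:
            return float(b)
    return None


def error_metrics(full: Trajectory, reduced: Trajectory,
                  window: Optional[tuple[float, float]] = None,
                  n_grid: int = 800,
                  rel_floor_factor: float = 1e-6) -> dict[str, float]:
    """Substrate-error metrics between two trajectories on a common grid.

    Both trajectories are resampled (dense output) on ``n_grid`` uniform
    points inside ``window`` (default: the overlap of their time ranges).
    ``max_rel`` divides by max(|s_full|, floor) with
    floor = rel_floor_factor * s_full(t0) to keep late-time ratios finite.
    """
    lo = max(full.t0, reduced.t0)
    hi = min(full.t_end, reduced.t_end)
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    if not hi > lo:
        raise ValueError(f"empty comparison window [{lo}, {hi}]")
    ts = np.linspace(lo, hi, n_grid)
    s_full, _ = full.sample(ts)
    s_red, _ = reduced.sample(ts)
    diff = np.abs(s_full - s_red)
    floor = rel_floor_factor * max(float(full.s[0]), 1e-300)
    rel = diff / np.maximum(np.abs(s_full), floor)
    dt = ts[1] - ts[0]
    return {
        "max_abs": float(diff.max()),
        "max_rel": float(rel.max()),
        "L2": float(np.sqrt(np.trapezoid(diff**2, dx=dt))),
    }


def sqssa_time_of_substrate(s: float, s0: float, p: RateConstants) -> float:
    """Closed-form time at which the standard-QSSA solution reaches s:
    t(s) = (K_M ln(s0/s) + s0 - s) / (k2 e0)."""
    if not 0 < s <= s0:
        raise ValueError("requires 0 < s <= s0")
    return (p.K_M * math.log(s0 / s) + s0 - s) / (p.k2 * p.e0)


_BOUND_KINDS = ("prop1", "prop2", "eq67")


def rate_bound_check(full: Trajectory, p: RateConstants, which: str,
                     slack_factor: float = 1e-8,
                     n_grid: int = 1000) -> dict:
    """Verify a substrate-rate envelope pointwise along a full trajectory.

    * ``prop1``: sQSSA rate <= ds/dt <= near-origin (eigenvector) rate,
      for t >= t_cross (first crossing of gamma_c).
    * ``prop2``: sQSSA rate <= ds/dt <= corrected rate, for t >= t_cross.
    * ``eq67``: sQSSA <= slow-product <= ds/dt <= corrected rate, for
      t >= t_cross_sp (first crossing of gamma_SP) while s <= s*;
      requires e0 > K and e0 < 8 K_S.

    ds/dt is evaluated from the mass-action field at the trajectory point.
    A slack of ``slack_factor * |envelope width|`` absorbs floating-point
    and solver-tolerance noise.  Crossing times are computed and cached in
    ``full.events`` if absent.
    """
    if which not in _BOUND_KINDS:
        raise ValueError(f"unknown bound check {which!r}; expected {_BOUND_KINDS}")
    if p.e0 == 0:
        return {"which": which, "n_checked": 0, "n_violations": 0,
                "max_excess": 0.0, "window": (0.0, 0.0)}

    if which == "eq67":
        if not (p.e0 > p.K and p.e0 < 8 * p.K_S):
            raise ValueError(
                "eq67 envelope requires K < e0 < 8 K_S; "
                f"got e0={p.e0}, K={p.K}, K_S={p.K_S}"
            )
        key = "t_cross_sp"
        if key not in full.events:
            full.events[key] = find_crossing(full, curve("gamma_SP", p))
    else:
        key = "t_cross"
        if key not in full.events:
            full.events[key] = find_crossing(full, curve("gamma_c", p))
    t_start = full.events[key]
    if t_start is None:
        raise ValueError(f"trajectory never crosses the {key} curve")

    ts = np.linspace(t_start, full.t_end, n_grid)
    s, c = full.sample(ts)
    if which == "eq67":
        sstar = s_star(p)
        mask = s <= sstar
        ts, s, c = ts[mask], s[mask], c[mask]
    sdot = -p.k1 * (p.e0 - c) * s + p.k_neg1 * c

    lower = np.array([reductions.sqssa_rhs(v, p) for v in s])
    if which == "prop1":
        upper = np.array([reductions.calder_siegel_rhs(v, p) for v in s])
    else:
        upper = np.array([reductions.kumar_josic_rhs(v, p) for v in s])
    if which == "eq67":
        sp = np.array([reductions.slow_product_rhs(v, p) for v in s])
        # the chain additionally requires sqssa <= slow_product; fold the
        # tighter lower bound in and record the chain's own consistency
        chain_ok = bool(np.all(lower <= sp + slack_factor * np.abs(upper - lower)))
        lower = sp
    else:
        chain_ok = True

    width = np.abs(upper - lower)
    slack = slack_factor * width
    viol = (sdot < lower - slack) | (sdot > upper + slack)
    excess = np.maximum(lower - sdot, sdot - upper)
    return {
        "which": which,
        "window": (float(t_start), float(full.t_end)),
        "n_checked": int(len(ts)),
        "n_violations": int(viol.sum()),
        "max_excess": float(excess.max()) if len(ts) else 0.0,
        "chain_ok": chain_ok,
        "times": ts,
        "violations": viol,
    }
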