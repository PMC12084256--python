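"""Accuracy verdicts and the empirical predominance ranking.

This module turns the dimensionless indicators, the fence geometry, and
trajectory error measurements into the package's headline outputs: which
validity conditions hold, whether the proven rate bounds are respected
numerically, and which reduction is empirically the most accurate in the
slow regime.

"Much smaller than" verdicts use a configurable threshold ``theta``
(default 0.1) and always carry the raw ratio so users can apply their own
cut-offs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import reductions, simulate
from .kinetics import PhaseState, RateConstants, indicators, origin_spectrum
from .phase_geometry import curve, s_star

__all__ = [
    "ValidityReport",
    "series_bound_factor",
    "slope_error_comparison",
    "predominance_experiment",
    "validity_report",
    "DEFAULT_THETA",
]

DEFAULT_THETA = 0.1


@dataclass
class ValidityReport:
    """Aggregated indicator values, condition verdicts, and model ranking."""

    params: RateConstants
    s0: float
    theta: float
    indicators: dict
    conditions: dict
    s_star: Optional[float]
    slope_comparison: dict
    bound_results: dict = field(default_factory=dict)
    ranking: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)
    verdict: str = ""
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": {"k1": self.params.k1, "k_neg1": self.params.k_neg1,
                       "k2": self.params.k2, "e0": self.params.e0},
            "s0": self.s0,
            "theta": self.theta,
            "indicators": self.indicators,
            "conditions": self.conditions,
            "s_star": self.s_star,
            "slope_comparison": self.slope_comparison,
            "bound_results": {
                k: {kk: vv for kk, vv in v.items()
                    if kk not in ("times", "violations")}
                for k, v in self.bound_results.items()
            },
            "ranking": self.ranking,
            "errors": self.errors,
            "verdict": self.verdict,
            "flags": self.flags,
        }

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.bool_):
                return bool(o)
            raise TypeError(f"not JSON serializable: {type(o)}")
        return json.dumps(self.to_dict(), indent=2, default=_default,
                          allow_nan=True)

    def render_text(self) -> str:
        lines = [f"validity report (theta={self.theta})",
                 f"  k1={self.params.k1} k_neg1={self.params.k_neg1} "
                 f"k2={self.params.k2} e0={self.params.e0} s0={self.s0}",
                 "  indicators:"]
        for k, v in self.indicators.items():
            lines.append(f"    {k:10s} = {v:.6g}")
        lines.append("  conditions:")
        for k, v in self.conditions.items():
            lines.append(f"    {k:14s} holds={v['holds']} ratio={v['ratio']:.6g}")
        if self.s_star is not None:
            lines.append(f"  s_star = {self.s_star:.6g}")
        if self.ranking:
            lines.append("  ranking (best first): " + ", ".join(self.ranking))
            for name in self.ranking:
                lines.append(f"    {name:14s} max_rel={self.errors[name]['max_rel']:.4g}")
        lines.append(f"  verdict: {self.verdict}")
        for f in self.flags:
            lines.append(f"  flag: {f}")
        return "\n".join(lines)


def series_bound_factor(p: RateConstants, regime: str) -> dict[str, float]:
    """Closed form of the alternating geometric bound series.

    ``low_enzyme`` (eps_RS < 1): sum_j (-eps_RS)^j = 1/(1 + eps_RS).
    ``high_enzyme`` (eps_RS > 1): sum_j (-1/eps_RS)^j = 1/(1 + 1/eps_RS),
    returned together with mu = eps_RS/(1+eps_RS)^2 which bounds the
    envelope-width maximum on [e0, s0].

    Both series diverge at eps_RS = 1, which is rejected.
    """
    eps = p.e0 / p.K_M
    if eps == 1.0:
        raise ValueError("series diverges at eps_RS = 1")
    if regime == "low_enzyme":
        if not eps < 1.0:
            raise ValueError(f"low_enzyme requires eps_RS < 1, got {eps}")
        return {"factor": 1.0 / (1.0 + eps), "eps_RS": eps}
    if regime == "high_enzyme":
        if not eps > 1.0:
            raise ValueError(f"high_enzyme requires eps_RS > 1, got {eps}")
        return {"factor": 1.0 / (1.0 + 1.0 / eps), "eps_RS": eps,
                "mu": eps / (1.0 + eps) ** 2}
    raise ValueError(f"unknown regime {regime!r}")


def slope_error_comparison(p: RateConstants) -> dict[str, float]:
    """Origin slopes of the two QSS curves against the slow eigenvector.

    The gap between a QSS curve's slope at the origin and the slow
    eigenvector slope m measures the near-origin approximation error of
    the corresponding reduction: the slow-product gap is smaller than the
    standard gap exactly when e0 > K (they tie at e0 = K).
    """
    if p.e0 <= 0:
        raise ValueError("requires e0 > 0")
    m = origin_spectrum(p).m
    gc_slope = p.e0 / p.K_M
    gsp_slope = (p.k1 * p.e0 / p.k_neg1
                 - p.k2 * p.e0 / (p.k_neg1 * (p.K_S + p.e0))) \
        if p.k_neg1 > 0 else math.inf
    return {
        "m": m,
        "gc_slope": gc_slope,
        "gsp_slope": gsp_slope,
        "sqssa_gap": m - gc_slope,
        "sp_gap": m - gsp_slope,
    }


def predominance_experiment(p: RateConstants, s0: float,
                            models: Sequence[str] = ("sqssa", "slow_product"),
                            window_mode: str = "initial",
                            rtol: float = simulate.DEFAULT_RTOL,
                            atol: float = simulate.DEFAULT_ATOL,
                            metric: str = "max_rel") -> dict:
    """Rank reductions by slow-regime substrate error against the full model.

    The full model is integrated from (s0, 0); each reduction is launched
    either from s(0) = s0 at t = 0 (``window_mode="initial"``, the figure
    convention) or from the full model's substrate at t_cross
    (``window_mode="crossing"``).  Errors are measured on [t_cross, end]
    and models are ranked ascending (best first).
    """
    if len(models) < 1:
        raise ValueError("at least one model required")
    full = simulate.integrate_full(p, PhaseState(s=s0, c=0.0),
                                   rtol=rtol, atol=atol)
    t_cross = simulate.find_crossing(full, curve("gamma_c", p))
    if t_cross is None:
        raise RuntimeError("full trajectory never crosses the c-nullcline")
    full.events["t_cross"] = t_cross

    errors: dict[str, dict] = {}
    for name in models:
        if window_mode == "initial":
            red = simulate.integrate_reduction(name, p, s0,
                                               rtol=rtol, atol=atol,
                                               horizon=full.t_end * 1.05,
                                               s_stop=0.0)
            err = simulate.error_metrics(full, red,
                                         window=(t_cross, full.t_end))
        elif window_mode == "crossing":
            s_at_cross = float(full.sample(t_cross)[0][0])
            red = simulate.integrate_reduction(
                name, p, s_at_cross, rtol=rtol, atol=atol,
                horizon=(full.t_end - t_cross) * 1.05, s_stop=0.0)
            red.times = red.times + t_cross
            base = red._interp
            red._interp = (lambda b: (lambda t: b(np.asarray(t) - t_cross)))(base)
            err = simulate.error_metrics(full, red,
                                         window=(t_cross, full.t_end))
        else:
            raise ValueError(f"unknown window_mode {window_mode!r}")
        errors[name] = err
    ranking = sorted(models, key=lambda nm: errors[nm][metric])
    return {
        "ranking": list(ranking),
        "errors": errors,
        "t_cross": t_cross,
        "window_mode": window_mode,
        "metric": metric,
    }


def validity_report(p: RateConstants, s0: float,
                    theta: float = DEFAULT_THETA,
                    run_ranking: bool = True,
                    run_bounds: bool = False,
                    models: Sequence[str] = ("sqssa", "slow_product"),
                    window_mode: str = "initial") -> ValidityReport:
    """Full validity assessment for one parameter set.

    Conditions are threshold verdicts on the raw dimensionless ratios; the
    final verdict follows the e0-versus-K rule (standard reduction
    predominant when e0/K is small), cross-checked by the empirical ranking
    when ``run_ranking`` is set.
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    ind = indicators(p)
    flags: list[str] = []
    km_over_e0 = p.K_M / p.e0 if p.e0 > 0 else math.inf
    conditions = {
        "reich_selkov": {"ratio": ind["eps_RS"],
                         "holds": ind["eps_RS"] <= theta},
        "predominance": {"ratio": ind["eps_K"],
                         "holds": ind["eps_K"] <= theta},
        "predominance_strict": {"ratio": ind["eps_K"],
                                "holds": ind["eps_K"] < 1.0},
        "gamma_sp_fence": {"ratio": (p.e0 / (8.0 * p.K_S)
                                     if p.K_S > 0 else math.inf),
                           "holds": p.e0 < 8.0 * p.K_S},
        "timescale": {"ratio": ind["node_disc"],
                      "holds": ind["node_disc"] <= theta},
        "high_enzyme": {"ratio": km_over_e0, "holds": km_over_e0 <= theta},
    }
    if not conditions["gamma_sp_fence"]["holds"]:
        flags.append("slow-product upper-fence claim unproven: e0 >= 8 K_S "
                     "(the sufficient condition fails; not necessarily false)")

    sstar = s_star(p) if p.k2 > 0 else None
    slope_cmp = slope_error_comparison(p) if p.e0 > 0 else {}

    report = ValidityReport(params=p, s0=s0, theta=theta, indicators=ind,
                            conditions=conditions, s_star=sstar,
                            slope_comparison=slope_cmp, flags=flags)

    if p.k2 == 0:
        # the standard reduction degenerates to ds/dt = 0; the slow-product
        # reduction is the exact QSS in this singular limit
        report.verdict = "slow_product"
        flags.append("k2 = 0: predominance ratio infinite; standard "
                     "reduction degenerate")
        return report

    if run_ranking and p.e0 > 0 and s0 > 0:
        exp = predominance_experiment(p, s0, models=models,
                                      window_mode=window_mode)
        report.ranking = exp["ranking"]
        report.errors = exp["errors"]

    if run_bounds and p.e0 > 0 and s0 > 0:
        full = simulate.integrate_full(p, PhaseState(s=s0, c=0.0))
        for which in ("prop1", "prop2"):
            try:
                report.bound_results[which] = simulate.rate_bound_check(
                    full, p, which)
            except (ValueError, RuntimeError) as exc:
                report.bound_results[which] = {"which": which,
                                               "skipped": str(exc)}

    if conditions["predominance"]["holds"]:
        report.verdict = "sqssa"
    elif report.ranking:
        report.verdict = report.ranking[0]
    else:
        report.verdict = "sqssa" if (sstar is not None and sstar < 0) \
            else "slow_product"
    return report
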