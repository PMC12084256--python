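"""Parameter scenarios: verbatim figure fixtures and seeded regime samplers.

Every other module is testable offline through this one.  Fixtures carry the
exact rate constants and initial conditions printed in the source figure
captions; samplers draw log-uniform rate constants and then choose e0 and s0
by rejection so every returned scenario satisfies its regime's defining
inequalities by construction (a margin factor of 10 operationalizes "much
smaller than"; plain strict inequalities are kept strict).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Optional

import numpy as np

from .kinetics import PhaseState, RateConstants
from .simulate import Trajectory

__all__ = [
    "Scenario",
    "figure_fixtures",
    "get_fixture",
    "fixture_labels",
    "sample_regime",
    "noisy_progress_curve",
    "REGIMES",
    "MUCH_LESS_MARGIN",
]

MUCH_LESS_MARGIN = 10.0


@dataclass(frozen=True)
class Scenario:
    """A labelled parameter set with initial condition and regime tag."""

    label: str
    params: RateConstants
    ic: PhaseState
    regime: str
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "k1": self.params.k1,
            "k_neg1": self.params.k_neg1,
            "k2": self.params.k2,
            "e0": self.params.e0,
            "s0": self.ic.s,
            "c0": self.ic.c,
            "regime": self.regime,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            label=d.get("label", "inline"),
            params=RateConstants(k1=float(d["k1"]), k_neg1=float(d["k_neg1"]),
                                 k2=float(d["k2"]), e0=float(d["e0"])),
            ic=PhaseState(s=float(d.get("s0", 0.0)), c=float(d.get("c0", 0.0))),
            regime=d.get("regime", "inline"),
            seed=d.get("seed"),
        )


def _sc(label, k1, k_neg1, k2, e0, s0, c0=0.0, regime="fixture") -> Scenario:
    return Scenario(label=label,
                    params=RateConstants(k1=k1, k_neg1=k_neg1, k2=k2, e0=e0),
                    ic=PhaseState(s=s0, c=c0), regime=regime)


def figure_fixtures() -> list[Scenario]:
    """Caption-exact fixture scenarios for all six source figures.

    Phase-plane panels that print several initial substrate values yield one
    scenario per value; the panels that print no s0 (curve-geometry only)
    default to s0 = 10.
    """
    fixtures = [
        # large unbinding rate: the standard and slow-product reductions blur
        _sc("fig1_left", 1.0, 100.0, 1.0, 10.0, 10.0, regime="large_k_neg1"),
        _sc("fig1_right", 1.0, 500.0, 1.0, 10.0, 10.0, regime="large_k_neg1"),
        # nullcline trapping region, six starts on the s-axis
        *[_sc(f"fig2_s{s0}", 1.0, 1.0, 1.0, 6.0, float(s0))
          for s0 in (1, 2, 3, 4, 5, 6)],
        # corrected-curve anti-funnel; same parameter set as fig2
        _sc("fig3", 1.0, 1.0, 1.0, 6.0, 6.0),
        # four slow-product/c-nullcline intersection panels
        _sc("fig4_top_left", 0.1, 1.0, 1.0, 6.0, 10.0),       # e0 < K, s* = -4
        _sc("fig4_top_right", 0.1, 1.0, 0.6, 6.0, 10.0),      # e0 = K, s* = 0
        _sc("fig4_bottom_left", 1.0, 1.0, 1.0, 6.0, 10.0),    # e0 > K, s* = 5
        _sc("fig4_bottom_right", 1.0, 1.0, 0.4, 6.0, 10.0),   # e0 > K, s* = 14
        # slow-product trapping region (e0 < 8 K_S), three starts
        *[_sc(f"fig5_s{s0}", 1.0, 1.0, 1.0, 6.0, float(s0))
          for s0 in (2, 6, 12)],
        # predominance comparison under the accuracy condition
        _sc("fig6_left", 1.0, 100.0, 10.0, 6.0, 9.0),         # e0 < K
        _sc("fig6_right", 1.0, 100.0, 4.0, 6.0, 9.0),         # e0 > K
    ]
    return fixtures


_REGISTRY = {f.label: f for f in figure_fixtures()}


def fixture_labels() -> list[str]:
    return sorted(_REGISTRY)


def get_fixture(label: str) -> Scenario:
    try:
        return _REGISTRY[label]
    except KeyError:
        raise KeyError(
            f"unknown fixture {label!r}; available: {fixture_labels()}"
        ) from None


def _regime_predicates() -> dict[str, Callable[[RateConstants, float], bool]]:
    m = MUCH_LESS_MARGIN
    return {
        # e0 << K_M: accuracy of the standard reduction
        "reich_selkov": lambda p, s0: p.e0 * m <= p.K_M,
        # e0 << K and e0 << K_M: the standard reduction is also predominant
        "predominant_sqssa": lambda p, s0: (p.K > 0
                                            and p.e0 * m <= p.K
                                            and p.e0 * m <= p.K_M),
        # K < e0 < 8 K_S: slow-product curve enters the trapping region
        "slow_product": lambda p, s0: p.K < p.e0 < 8.0 * p.K_S,
        # K_M << e0 <~ s0: high-enzyme (reverse-QSSA) territory
        "high_enzyme": lambda p, s0: p.K_M * m <= p.e0 <= s0,
        # large unbinding: both k1 e0 and k2 dwarfed by k_neg1
        "large_k_neg1": lambda p, s0: (p.k_neg1 >= m * p.k1 * p.e0
                                       and p.k_neg1 >= m * p.k2),
    }


REGIMES = tuple(_regime_predicates())


def sample_regime(regime: str, n: int, seed: int,
                  max_tries: int = 10000) -> list[Scenario]:
    """Draw ``n`` scenarios satisfying the regime's inequalities.

    Rate constants are log-uniform on [1e-2, 1e2]; e0 and s0 are drawn
    log-uniformly on ranges adapted to the regime and accepted by rejection
    against the regime predicate.  Deterministic under ``seed``.
    """
    predicates = _regime_predicates()
    if regime not in predicates:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if n < 1:
        raise ValueError("n must be >= 1")
    pred = predicates[regime]
    rng = np.random.default_rng(seed)
    out: list[Scenario] = []
    tries = 0
    widen = 1.0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            # widen the concentration ranges rather than fail outright
            widen *= 10.0
            tries = 0
            if widen > 1e6:
                raise RuntimeError(
                    f"rejection sampling failed for regime {regime!r}"
                )
        k1, k_neg1, k2 = np.exp(rng.uniform(np.log(1e-2), np.log(1e2), size=3))
        km = (k_neg1 + k2) / k1
        if regime == "high_enzyme":
            lo, hi = km * MUCH_LESS_MARGIN, km * MUCH_LESS_MARGIN * 100.0 * widen
        elif regime == "slow_product":
            k, ks = k2 / k1, k_neg1 / k1
            if not k < 8.0 * ks:
                continue
            lo, hi = k, min(8.0 * ks, k * 1e4)
        else:
            lo, hi = 1e-3 / widen, 1e2 * widen
        e0 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if regime == "high_enzyme":
            s0 = float(e0 * np.exp(rng.uniform(0.0, np.log(10.0))))
        else:
            s0 = float(np.exp(rng.uniform(np.log(1e-1), np.log(1e2))))
        try:
            p = RateConstants(k1=k1, k_neg1=k_neg1, k2=k2, e0=e0)
        except ValueError:
            continue
        if not pred(p, s0):
            continue
        out.append(Scenario(label=f"{regime}_{len(out)}", params=p,
                            ic=PhaseState(s=s0, c=0.0), regime=regime,
                            seed=seed))
    return out


def noisy_progress_curve(traj: Trajectory, sigma: float, seed: int,
                         n_points: int = 100) -> np.ndarray:
    """Sample (t, s) from a trajectory with multiplicative log-normal noise.

    Returns an (n_points, 2) array on a uniform time grid.  The noise model
    is a synthetic-data convention of this package, not a measured one:
    s_obs = s * exp(sigma * z), z ~ N(0, 1), seeded.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    ts = np.linspace(traj.t0, traj.t_end, n_points)
    s, _ = traj.sample(ts)
    s_obs = s * np.exp(sigma * rng.standard_normal(n_points))
    return np.column_stack([ts, s_obs])
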