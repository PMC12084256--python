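"""Core domain types and pure kinetics functions.

The irreversible one-enzyme, one-substrate mechanism

    S + E <-> C -> E + P

reduces (after eliminating the conserved enzyme total ``e0``) to a planar
mass-action system in the substrate ``s`` and complex ``c``.  This module
houses the parameter record, the planar vector field, the linearization at
the origin, and the dimensionless indicators used everywhere else in the
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateConstants",
    "PhaseState",
    "SpectralData",
    "derived_constants",
    "mass_action_rhs",
    "origin_jacobian",
    "origin_spectrum",
    "indicators",
]


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of the mechanism plus the total enzyme ``e0``.

    Units are arbitrary but must be mutually consistent: ``k1`` carries
    1/(concentration * time), ``k_neg1`` and ``k2`` carry 1/time, and
    ``e0`` is a concentration.

    Derived constants:

    * ``K_S = k_neg1 / k1`` -- equilibrium (dissociation) constant,
    * ``K = k2 / k1`` -- Van Slyke-Cullen constant,
    * ``K_M = (k_neg1 + k2) / k1`` -- Michaelis constant, ``K_M = K_S + K``.
    """

    k1: float
    k_neg1: float
    k2: float
    e0: float

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError(f"k1 must be strictly positive, got {self.k1}")
        if self.k_neg1 < 0:
            raise ValueError(f"k_neg1 must be nonnegative, got {self.k_neg1}")
        if self.k2 < 0:
            raise ValueError(f"k2 must be nonnegative, got {self.k2}")
        if self.e0 < 0:
            raise ValueError(f"e0 must be nonnegative, got {self.e0}")

    @property
    def K_S(self) -> float:
        return self.k_neg1 / self.k1

    @property
    def K(self) -> float:
        return self.k2 / self.k1

    @property
    def K_M(self) -> float:
        return (self.k_neg1 + self.k2) / self.k1


@dataclass(frozen=True)
class PhaseState:
    """A point (s, c) in the substrate-complex phase plane."""

    s: float
    c: float

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"s must be nonnegative, got {self.s}")
        if self.c < 0:
            raise ValueError(f"c must be nonnegative, got {self.c}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s, self.c], dtype=float)


@dataclass(frozen=True)
class SpectralData:
    """Eigenstructure of the origin: eigenvalues and slow-eigenvector slope.

    For ``e0 > 0`` and ``k2 > 0`` the origin is a stable node with real
    eigenvalues ``lambda_minus <= lambda_plus < 0``; ``m`` is the slope
    (c per s) of the slow eigenvector spanning the tangent space of the
    slow manifold at the origin.
    """

    lambda_minus: float
    lambda_plus: float
    m: float


def derived_constants(p: RateConstants) -> dict[str, float]:
    """Return ``{"K_M": ..., "K_S": ..., "K": ...}`` for parameters ``p``."""
    return {"K_M": p.K_M, "K_S": p.K_S, "K": p.K}


def mass_action_rhs(x: PhaseState | tuple[float, float] | np.ndarray,
                    p: RateConstants) -> tuple[float, float]:
    """Planar mass-action vector field (ds/dt, dc/dt).

    ds/dt = -k1 (e0 - c) s + k_neg1 c
    dc/dt =  k1 (e0 - c) s - (k_neg1 + k2) c
    """
    if isinstance(x, PhaseState):
        s, c = x.s, x.c
    else:
        s, c = float(x[0]), float(x[1])
    bind = p.k1 * (p.e0 - c) * s
    sdot = -bind + p.k_neg1 * c
    cdot = bind - (p.k_neg1 + p.k2) * c
    return sdot, cdot


def origin_jacobian(p: RateConstants) -> np.ndarray:
    """Jacobian of the mass-action field at the stationary point (0, 0)."""
    return np.array(
        [
            [-p.k1 * p.e0, p.k_neg1],
            [p.k1 * p.e0, -(p.k_neg1 + p.k2)],
        ]
    )


def _slow_slope(p: RateConstants, sqrt_disc: float) -> float:
    """Slope m of the slow eigenvector, evaluated cancellation-safely.

    The textbook closed form

        m = (k1 e0 - k_neg1 - k2 + sqrt(D)) / (2 k_neg1),
        D = (k_neg1 + k2 + k1 e0)^2 - 4 k1 k2 e0,

    subtracts nearly equal quantities when ``k1 e0 << k_neg1 + k2``.
    Rationalizing the numerator gives the equivalent conjugate form

        m = 2 k1 e0 / (k_neg1 + k2 - k1 e0 + sqrt(D)),

    which is accurate for small ``e0``; the original form is kept for the
    opposite regime where its subtraction is benign.
    """
    a = p.k_neg1 + p.k2
    h = p.k1 * p.e0
    if h <= a:
        denom = a - h + sqrt_disc
        if denom == 0.0:  # only when e0 == 0 and a == 0
            return 0.0
        return 2.0 * h / denom
    if p.k_neg1 > 0:
        return (h - a + sqrt_disc) / (2.0 * p.k_neg1)
    return math.inf  # slow eigenvector vertical when k_neg1 = 0, k1 e0 > k2


def origin_spectrum(p: RateConstants) -> SpectralData:
    """Eigenvalues of the origin node and the slow-eigenvector slope.

    lambda_pm = (k1/2)(K_M + e0) * (-1 +- sqrt(1 - 4 K e0 / (K_M + e0)^2))

    Raises if the discriminant is negative, which cannot occur for
    nonnegative parameters (the origin is always a node, never a focus).
    """
    if p.e0 <= 0:
        raise ValueError("origin_spectrum requires e0 > 0")
    total = p.K_M + p.e0
    disc = 1.0 - 4.0 * p.K * p.e0 / total**2
    if disc < 0:
        raise ArithmeticError(
            f"negative node discriminant {disc} for {p}; "
            "this contradicts the AM-GM bound and indicates corrupt input"
        )
    root = math.sqrt(disc)
    half_trace = 0.5 * p.k1 * total
    lam_plus = half_trace * (-1.0 + root)
    lam_minus = half_trace * (-1.0 - root)
    # sqrt of the unscaled discriminant (k_neg1+k2+k1 e0)^2 - 4 k1 k2 e0
    sqrt_disc = p.k1 * total * root
    m = _slow_slope(p, sqrt_disc)
    return SpectralData(lambda_minus=lam_minus, lambda_plus=lam_plus, m=m)


def indicators(p: RateConstants) -> dict[str, float]:
    """Dimensionless validity indicators.

    Returns a mapping with keys:

    * ``eps_RS`` -- e0 / K_M, the Reich-Sel'kov ratio (accuracy indicator),
    * ``eps_K`` -- e0 / K, the predominance ratio (``inf`` when k2 = 0),
    * ``delta`` -- leading-order slow/fast eigenvalue ratio near the origin,
      ``(e0/K_M) * k2/(k_neg1+k2)``; the exact ratio is available as
      ``lambda_plus/lambda_minus`` from :func:`origin_spectrum`,
    * ``node_disc`` -- 4 K e0 / (K_M + e0)^2, which must stay below 1 (node
      condition) and well below which signals timescale separation,
    * ``mu`` -- eps_RS / (1 + eps_RS)^2, the high-enzyme bound factor.
    """
    eps_rs = p.e0 / p.K_M if p.K_M > 0 else math.inf
    eps_k = p.e0 / p.K if p.K > 0 else (0.0 if p.e0 == 0 else math.inf)
    rate_sum = p.k_neg1 + p.k2
    delta = eps_rs * (p.k2 / rate_sum) if rate_sum > 0 else 0.0
    node_disc = 4.0 * p.K * p.e0 / (p.K_M + p.e0) ** 2 if (p.K_M + p.e0) > 0 else 0.0
    mu = eps_rs / (1.0 + eps_rs) ** 2 if math.isfinite(eps_rs) else 0.0
    return {
        "eps_RS": eps_rs,
        "eps_K": eps_k,
        "delta": delta,
        "node_disc": node_disc,
        "mu": mu,
    }
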