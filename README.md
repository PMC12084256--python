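# qssa

Accuracy and predominance diagnostics for quasi-steady-state (QSS)
reductions of the irreversible Michaelis–Menten mechanism.

The planar mass-action system in substrate `s` and complex `c`,

    ds/dt = -k1 (e0 - c) s + k_neg1 c
    dc/dt =  k1 (e0 - c) s - (k_neg1 + k2) c,

admits several reduced one-dimensional models whose validity regions
overlap. This package implements the machinery needed to tell them apart:

- **kinetics**: parameter record with derived constants
  (`K_M`, `K_S`, `K`), the mass-action vector field, the origin
  eigenstructure (cancellation-safe slow-eigenvector slope), and the
  dimensionless indicators `e0/K_M`, `e0/K`, the slow/fast eigenvalue
  ratio, and the node discriminant.
- **reductions**: the standard QSSA, the slow-product QSSA, the corrected
  (flow-differentiated) reduction, the near-origin eigenvector reduction,
  and the piecewise reverse QSSA with its shifted initial condition
  `(s0 - e0, e0)`.
- **phase_geometry**: nullclines and fence curves with analytic
  derivatives, signed fence residuals, anti-funnel regions that trap the
  slow manifold, and the closed-form intersection point
  `s* = (k_neg1/k2)(e0 - K)` of the slow-product QSS curve with the
  c-nullcline.
- **simulate**: stiff-capable integration (LSODA, dense output) of the
  full system and every reduction, curve-crossing detection by bracketed
  root-finding on the interpolant, substrate error metrics, and pointwise
  verification of the proven rate-bound envelopes.
- **validity**: condition verdicts at a configurable threshold
  (default 0.1, raw ratios always reported), origin slope-gap comparison,
  and an empirical predominance experiment that ranks reductions by
  slow-regime substrate error. The headline rule: the standard QSSA is
  accurate when `e0 << K_M` but predominant only when `e0` is also small
  against the Van Slyke–Cullen constant `K`.
- **scenarios**: caption-exact figure fixtures and seeded regime samplers
  so everything is testable offline.

## CLI

```sh
qssa fixtures                          # list built-in scenarios
qssa report   --fixture fig6_left      # indicators, conditions, ranking
qssa simulate --fixture fig2_s6        # full + reduced trajectories (CSV)
qssa compare  --fixture fig6_right     # error metrics vs the full model
qssa fences   --fixture fig3           # fence residual signs + curve CSVs
qssa sweep    --config sweep.yaml      # error grid over (e0/K_M, e0/K)
```

Scenarios can also be given inline (`--k1 1 --k-neg1 1 --k2 1 --e0 6
--s0 6`) or via a YAML/JSON config; every run persists its resolved
configuration (`run_config.json`) next to its outputs.

Example sweep config:

```yaml
grid:
  eps_RS: {min: 0.01, max: 0.3, n: 10}   # e0 / K_M axis
  eps_K:  {min: 0.1,  max: 10, n: 10}    # e0 / K axis
e0: 1.0
models: [sqssa, slow_product]
```

## Python API

```python
from qssa import (RateConstants, PhaseState, integrate_full,
                  predominance_experiment, validity_report)

p = RateConstants(k1=1.0, k_neg1=100.0, k2=10.0, e0=6.0)
report = validity_report(p, s0=9.0)
print(report.render_text())          # verdict: sqssa (e0 < K)
```
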