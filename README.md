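# ivim-bopt

Tools for choosing **b values and averaging schemes for intravoxel incoherent
motion (IVIM) perfusion MRI of the brain**, where the pseudo-diffusion maps
are notoriously noisy.  The package is aimed at MR physicists and image
analysts who want to (i) fit the IVIM model the way clinical brain studies do,
(ii) understand how thermal and physiological noise propagate from repeated
trace acquisitions into the parameter maps, and (iii) design an acquisition —
which b values, how many averages of each — under a scan-time budget.

## The model

The diffusion-weighted trace signal is biexponential,

```
S(b) = S0 · [ f · exp(−b·D*) + (1 − f) · exp(−b·D) ]
```

with perfusion fraction `f`, tissue diffusion coefficient `D` (mm²/s) and
pseudo-diffusion coefficient `D* ≥ D` (mm²/s).  Fitting is *segmented*: `D` is
fitted on the tail of the decay curve (b ≥ 300 s/mm², where the perfusion
compartment has decayed), then fixed while `(S0, f, D*)` are fitted on the
full curve; both stages are bounded quasi-Newton fits seeded by an analytic
log-linear initialization, and the stage pair is cycled to convergence.  With
only three b values the fit reduces exactly to the analytic initialization.

Around the fitter the package provides:

- **`ivim_bopt.phantom`** — a synthetic brain phantom (GM ring, WM core) with
  three-direction trace synthesis, Rician thermal noise and a multiplicative
  physiological component that peaks at low b, is stronger in GM than WM, and
  is AR(1)-correlated across consecutive repetitions.
- **`ivim_bopt.repetition`** — partitioning of R repetitions into ⌊R/k⌋
  consecutive k-averages (20/10/6/5/4 images for k = 1..5 at R = 20, 45 in
  total), CoV(b, k) tables and parameter-map standard deviations.
- **`ivim_bopt.schemes`** — the 16-b-value palette (0–900 s/mm²), the three
  deterministic subset-selection strategies (low / high / alternating around
  the fixed base {0, 200, 900}), ensemble construction and scan-time
  accounting (b = 0 costs 1 TR, weighted b values one TR per direction).
- **`ivim_bopt.crlb`** — Fisher information `FIM = Σ_b N_b/σ_b² g(b)g(b)ᵀ`
  with analytic derivatives, Cramér–Rao lower bounds, and a greedy integer
  search for the measurement allocation minimizing the weighted sum of
  relative root-CRLBs under a count or scan-time budget.
- **`ivim_bopt.trend`** — Mann-Kendall trend test (tie-corrected, continuity-
  corrected), OLS of map SD on design factors with partial R², Bonferroni.
- **`ivim_bopt.pipeline`** — the end-to-end workflow: simulate once, evaluate
  every (scheme, averages) cell, select schemes by argmin-SD and by CRLB.

## Worked example

```python
import numpy as np
from ivim_bopt import *
from ivim_bopt.phantom import default_gm_params

truth = default_gm_params()                # f=0.06, D=0.85e-3, D*=10e-3
b = np.array(PALETTE, float)               # 16 b values, 0-900 s/mm^2
rng = np.random.default_rng(0)
noisy = np.abs(ivim_signal(truth, b) + rng.normal(0, 0.01, b.size))
res = fit_ivim(SignalCurve(b, noisy))
print(res.params)
```

prints (SNR 100 at b = 0):

```
f     = 0.0887   (truth 0.0600)
D     = 0.8380e-3 mm^2/s (truth 0.8500e-3)
Dstar = 5.314e-3 mm^2/s (truth 10.000e-3)
```

`D` is precise while `f` and `D*` scatter — the core problem the design layer
addresses.  Designing a 12-minute acquisition from noise measured on the
synthetic phantom:

```python
ph = build_phantom((10, 10, 1), seed=17)
stack = simulate_stack(ph, PALETTE, NoiseProfile.default_brain(), n_reps=20, seed=17)
sigma = estimate_sigma_b(stack, ph.mask("GM"))
scheme, path = optimize_for_scan_time(PALETTE, 12.0, ph.truth("GM"), sigma)
print(scheme.to_string())
```

```
0 (15), 110 (14), 140 (9), 400 (3), 500 (18), 900 (11)
```

— heavy averaging at low b (against physiological noise) plus support at
mid/high b, the qualitative signature of CRLB-optimal brain IVIM schemes.

A command-line interface mirrors the workflow
(`ivim-bopt simulate|fit|cov|ensemble|optimize|stats|run-all`).

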