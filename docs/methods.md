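# Methods

This note documents the models, numerical choices and defaults behind
`ivim_bopt`, and what the synthetic experiments do and do not demonstrate.

## IVIM signal model and segmented fitting

The trace DWI signal is modelled as
`S(b) = S0·[f·exp(−b·D*) + (1−f)·exp(−b·D)]` with bounds `f ∈ [0, 1]`,
`D ∈ (1e-5, 4e-3]` mm²/s, `D* ∈ [D, 0.5]` mm²/s.  The bounds are
physiological brain ranges and prevent the two compartments from exchanging
roles during optimization.

**Analytic initialization.**  `D` and the diffusion-only intercept come from
the least-squares line through `(b, log S)` on the tail (`b ≥ 300` s/mm²);
`f = max(0, 1 − exp(intercept)/S(0))`; `D*` from the log-linear slope of the
positive perfusion residual `S(b) − (1−f)·S0·exp(−b·D)` over `b < 200` s/mm²,
falling back to `10·D` when fewer than two usable points exist.  When a
subset has fewer than two b values at or above 300, the tail extends down to
200 so that the minimal scheme {0, 200, 900} remains fittable.

**Two-stage fit, cycled.**  Stage 1 fits `(amplitude, D)` on the tail by
bounded nonlinear least squares (L-BFGS-B with analytic gradients, variables
scaled so diffusivities are O(1)); stage 2 fits `(S0, f, D*)` on all points
with `D` fixed.  The first cycle is the classical segmented procedure.  A
single pass, however, leaves a systematic `D` bias because the perfusion term
has not fully decayed at b = 300 (about 1 % for f = 0.1, D* = 10e-3 mm²/s),
so the pair of stages is cycled, subtracting the current perfusion-component
estimate from the tail before re-fitting `D`, until the full-curve SSE
changes by less than `tol` (default 1e-10, max 30 cycles).  On noiseless data
the generating parameters are the cycle's zero-residual fixed point, which is
what makes exact-recovery testing possible.  Stage-1 residuals are linear-
space (the log-space line is only the seed).  A 3-b-value curve is returned
directly from the analytic initialization — with three unknowns per stage and
three points there is no residual freedom.  Non-convergent fits keep the
initialization values and are flagged rather than dropped, so parameter maps
stay complete for SD analysis.  For large map-evaluation grids the pipeline
uses a faster setting (`tol 1e-8`, 6 cycles), which changes map SDs
negligibly relative to the noise being measured.

## Synthetic phantom and noise model

The phantom is a background border, a grey-matter ring and a white-matter
core (shape configurable, default 12×12×1).  Tissue defaults are
literature-typical healthy-brain values: GM `f=0.06, D=0.85e-3, D*=10e-3`;
WM `f=0.03, D=0.75e-3, D*=10e-3` (mm²/s), `S0=1`.  All are overridable and
recorded in run metadata.

Each repetition is synthesized in three orthogonal diffusion directions and
collapsed to the trace by geometric mean.  Noise has two components:

- **Thermal**: b-independent Gaussian channel noise; magnitudes are Rician,
  `sqrt((S+n₁)² + n₂²)` (single-coil model).  The trace carries roughly
  `σ_thermal/√3`.
- **Physiological**: a multiplicative factor `1 + a(b)·ε`, with
  `a(b) = amplitude·exp(−b/decay)` and `ε` standard normal, shared across
  the three directions of a repetition and AR(1)-correlated across
  consecutive repetitions (default ρ = 0.5).  The correlation reflects that
  cardiac/respiratory fluctuations outlast one TR; it is what makes
  consecutive-block averaging less effective at low b than the 1/√k thermal
  law, the behaviour reported for repeated brain acquisitions.  ρ = 0 gives
  independent draws.

Default noise levels (per tissue: `σ_thermal`, `amplitude`, `decay`) are
GM (0.118, 0.37, 400 s/mm²) and WM (0.081, 0.093, 1100 s/mm²).  They were set
from the closed-form single-repetition CoV model
(`TissueNoise.predicted_cov`) so that CoV(b) spans ≈15–40 % in GM with a low-b
peak and ≈9–10.5 % in WM with peaks at both ends — the measured structure of
repeated brain trace data.  The per-tissue thermal σ is an *effective* value:
on a flat two-tissue phantom a single spatially uniform σ cannot reproduce
both tissues' CoV levels simultaneously (real tissue heterogeneity and
partial-volume effects are absent), so the thermal component is scaled per
tissue.  What passing tests show is that the *structure* (two noise regimes,
GM ≫ WM at low b, averaging flattening at low b) propagates correctly through
the pipeline — not that the phantom is anatomically realistic.  Motion, CSF
partial volume and gated acquisition are not simulated.

## Repetition analysis

R repetitions are partitioned into ⌊R/k⌋ *consecutive, disjoint* k-blocks
(leftovers dropped), matching the counts 20/10/6/5/4 for R = 20, k = 1..5
(45 averaged images in total; b = 0 images are averaged identically).  CoV
cells pool masked voxel intensities across all averaged images of a cell.
SD is population (divide-by-n) throughout — a convention choice, applied
consistently.

## Scheme ensemble and scan time

Subsets grow from the fixed base {0, 200, 900} s/mm² by three deterministic
strategies (additions in ascending b; "alternating" starts low).  The union
plus optional manual YAML sets, de-duplicated and ordered by (size, b list),
forms the candidate ensemble (26 schemes without manual sets).  Scan time is
`Σ_b N_b·TR·(1 if b=0 else 3)` with TR = 4 s; budget checks allow one
measurement of slack.  A fixture of 24 published suggested schemes for
3/6/12-minute budgets ships in `ivim_bopt/data/suggested_schemes.yaml`.

## Fisher information and CRLB search

The FIM uses the heteroscedastic-Gaussian approximation
`Σ_b N_b/σ_b²·g(b)g(b)ᵀ` with analytic `g`; Rician corrections are ignored at
the design stage, appropriate at moderate-to-high trace SNR.  Per-b σ is
measured from data as the root-mean-square across voxels of the per-voxel SD
over repetitions.  Singularity is declared when the diagonally *scaled* FIM
(correlation form) has condition number above 1e12 — the raw FIM mixes units
(mm²/s vs unitless) and its condition number is meaningless.  Singular
designs yield flagged infinite bounds, not exceptions.

The design objective is `J = Σ w_i·sqrt(CRLB_i)/|θ_i|` with default weights
(0, 1, 1, 1) over (S0, f, D, D*): relative bounds make the parameters
commensurate; weights are configurable.  The search is greedy integer
allocation — start with one measurement at each of `len(free)` spread palette
values, then repeatedly add the measurement that most decreases `J` (ties to
lower b) until the count or time budget is exhausted.  `J` is provably
non-increasing along the path (the FIM grows in Loewner order) and the
greedy solution matches exhaustive enumeration on small problems; global
optimality in general is not guaranteed, which is the standard trade-off for
integer designs.

A `free` parameter subset supports restricted designs.  Notably, the palette
{0, 200, 900} cannot identify the full model (rank 3 < 4), and with S0 known
the b = 0 row is identically zero (rank 2); the only identifiable
3-parameter restriction there is the stage-2 set (S0, f, D*) with D known,
which is what the degenerate-palette validation uses.

## Statistics

Mann-Kendall: `S = Σ_{i<j} sign(x_j − x_i)`, tie-corrected null variance,
±1 continuity correction, two-sided normal p.  The exact permutation
distribution (used as a test oracle at n = 5) and the nominal-level
calibration under the i.i.d. null are both exercised in the test suite; the
normal approximation's true size at n = 20 is ≈4.7 %.

The SD model is OLS `sd ~ C(scheme) + n_bvalues + n_reps` with treatment
coding.  Because the scheme factor determines `n_bvalues` exactly, that
design is rank-deficient by construction; aliased columns are reported, and
factor comparisons use nested-model partial R² (scheme identity is dropped
*while keeping* `n_bvalues`, so its partial R² measures composition beyond
size).  Bonferroni adjustment is `min(1, m·p)`.  All tests are two-sided;
directionality is read from signs.

## Problem sizes and determinism

The shipped experiments use a 10×10×1 phantom (64 fitted voxels), 20
repetitions, a 9-scheme sub-ensemble spanning all strategies and sizes for
the GLM grid, and 2000 Monte-Carlo curves for the CRLB bound check — sizes
chosen so the full suite and the acceptance script each run in minutes on one
core while keeping Monte-Carlo errors well below the asserted margins.  Every
stochastic step takes an explicit seed; identical seeds give bit-identical
stacks, tables and scheme selections, and run artifacts are stamped with the
configuration hash and seed.

## Known limitations

- Single-coil Rician magnitude model; no multi-channel or parallel-imaging
  noise statistics.
- The physiological component is a two-parameter empirical model
  (exponential-in-b amplitude, AR(1) memory), not a cardiac/respiratory
  simulation.
- Greedy CRLB allocation is exact only on small enumerable problems.
- The exact published 95-set candidate ensemble is not reconstructible from
  the generation rules alone; users holding the full list can supply it as
  manual YAML sets.
- Alternative fitters (Bayesian, simultaneous 4-parameter NLLS) are out of
  scope; the fitting procedure affects absolute parameter values and their
  SDs.
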