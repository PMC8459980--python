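"""Fisher information, Cramér-Rao lower bounds and budgeted scheme search.

Under heteroscedastic Gaussian noise with per-b-value SD sigma_b, the Fisher
information of an acquisition scheme for the IVIM parameters
theta = (S0, f, D, Dstar) is

    FIM = sum_b  N_b / sigma_b^2 * g(b) g(b)^T,      g(b) = dS(b; theta)/dtheta

with N_b averages at b.  The variance of any unbiased estimator of theta_i is
bounded below by (FIM^-1)_ii.  The design search allocates an integer
measurement budget over a b-value palette by greedy descent on the weighted
sum of relative root-CRLBs, which is guaranteed non-increasing because adding
a measurement grows the FIM in the Loewner order.

A near-singular FIM (reciprocal condition number below 1e-12, e.g. fewer
distinct b values than free parameters) yields an explicitly flagged infinite
bound, never an exception.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .ivim import IVIMParams, PARAM_NAMES, ivim_jacobian
from .phantom import TraceStack
from .schemes import BValueScheme

__all__ = [
    "CRLBResult",
    "fisher_information",
    "crlb",
    "optimize_scheme",
    "optimize_for_scan_time",
    "exhaustive_scheme_search",
    "estimate_sigma_b",
]

RCOND_SINGULAR = 1e-12
DEFAULT_WEIGHTS = {"f": 1.0, "D": 1.0, "Dstar": 1.0}


def _sigma_array(scheme: BValueScheme, noise) -> np.ndarray:
    """Per-b noise SD aligned with scheme.bvalues (scalar, mapping or array)."""
    b = np.asarray(scheme.bvalues, dtype=float)
    if np.isscalar(noise):
        sig = np.full(b.size, float(noise))
    elif isinstance(noise, dict):
        try:
            sig = np.array([float(noise[key]) for key in scheme.bvalues])
        except KeyError as exc:
            raise KeyError(f"noise mapping lacks sigma for b={exc.args[0]}") from None
    else:
        sig = np.asarray(noise, dtype=float)
        if sig.size != b.size:
            raise ValueError("noise array must have one sigma per b value")
    if np.any(sig <= 0):
        raise ValueError("sigma_b must be positive for every b (zero noise has "
                         "infinite information)")
    return sig


def fisher_information(scheme: BValueScheme, truth: IVIMParams, noise) -> np.ndarray:
    """4x4 Fisher information matrix of the scheme at truth, order (S0, f, D, Dstar)."""
    b = np.asarray(scheme.bvalues, dtype=float)
    sig = _sigma_array(scheme, noise)
    n = np.asarray(scheme.averages, dtype=float)
    g = ivim_jacobian(truth, b)  # (nb, 4)
    w = n / sig**2
    return (g * w[:, None]).T @ g


@dataclass(frozen=True)
class CRLBResult:
    """Per-parameter variance lower bounds for one scheme."""

    scheme: BValueScheme
    free: tuple  # free parameter names, order as in PARAM_NAMES
    variances: dict  # name -> variance bound (inf when singular)
    relative: dict  # name -> sqrt(bound)/|truth|
    singular: bool
    fim: np.ndarray

    def objective(self, weights=None) -> float:
        """Weighted sum of relative root-CRLBs (default: f, D, Dstar equally)."""
        weights = weights or DEFAULT_WEIGHTS
        return float(sum(w * self.relative[name] for name, w in weights.items()
                         if w != 0))


def crlb(scheme: BValueScheme, truth: IVIMParams, noise,
         free=PARAM_NAMES) -> CRLBResult:
    """CRLB per free parameter; parameters not in ``free`` are treated as known."""
    free = tuple(free)
    unknown = set(free) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names {sorted(unknown)}")
    idx = [i for i, name in enumerate(PARAM_NAMES) if name in free]
    free = tuple(PARAM_NAMES[i] for i in idx)
    fim_full = fisher_information(scheme, truth, noise)
    fim = fim_full[np.ix_(idx, idx)]

    # condition test on the diagonally scaled FIM so that parameter units
    # (mm^2/s vs unitless) do not masquerade as rank deficiency
    diag_f = np.diag(fim).copy()
    if fim.size == 0 or np.any(diag_f <= 0):
        singular = True
    else:
        scale = 1.0 / np.sqrt(diag_f)
        corr = fim * scale[:, None] * scale[None, :]
        singular = np.linalg.cond(corr) > 1.0 / RCOND_SINGULAR
    theta = truth.as_array()[idx]
    if singular:
        var = {name: np.inf for name in free}
        rel = {name: np.inf for name in free}
    else:
        diag = np.diag(np.linalg.inv(fim))
        var = {name: float(v) for name, v in zip(free, diag)}
        rel = {
            name: float(np.sqrt(max(v, 0.0)) / abs(t)) if t != 0 else np.inf
            for (name, v), t in zip(var.items(), theta)
        }
    return CRLBResult(scheme=scheme, free=free, variances=var, relative=rel,
                      singular=singular, fim=fim)


def _scheme_from_counts(palette, counts, label="") -> BValueScheme:
    bvals = [b for b in palette if counts[b] > 0]
    return BValueScheme(
        bvalues=tuple(bvals),
        averages=tuple(counts[b] for b in bvals),
        label=label,
        strategy="crlb",
    )


def _objective(palette, counts, truth, noise, weights, free) -> float:
    return crlb(_scheme_from_counts(palette, counts), truth, noise,
                free=free).objective(weights)


def _spread_start(palette, n_start):
    """One measurement at each of n_start palette values spread across its range."""
    idx = np.unique(np.round(np.linspace(0, len(palette) - 1, n_start)).astype(int))
    return [palette[i] for i in idx]


def optimize_scheme(
    palette,
    budget: int,
    truth: IVIMParams,
    noise,
    weights=None,
    free=PARAM_NAMES,
    label="crlb-optimized",
):
    """Greedy integer allocation of ``budget`` measurements over the palette.

    Starts from one measurement at each of len(free) spread palette values
    (identifiability seed), then repeatedly adds the single measurement that
    most decreases the weighted relative-CRLB objective, breaking ties toward
    lower b.  Returns (scheme, objective_path); the path is non-increasing.
    """
    palette = tuple(sorted(set(float(b) for b in palette)))
    free = tuple(free)
    weights = weights or DEFAULT_WEIGHTS
    n_start = min(len(palette), len(free))
    if budget < n_start:
        raise ValueError(
            f"budget {budget} below the {n_start} measurements needed for "
            f"identifiability of {free}"
        )
    counts = {b: 0 for b in palette}
    for b in _spread_start(palette, n_start):
        counts[b] += 1
    path = [_objective(palette, counts, truth, noise, weights, free)]
    for _ in range(budget - sum(counts.values())):
        best_b, best_j = None, np.inf
        for b in palette:  # ascending order => ties resolve toward lower b
            counts[b] += 1
            j = _objective(palette, counts, truth, noise, weights, free)
            counts[b] -= 1
            if j < best_j:
                best_b, best_j = b, j
        counts[best_b] += 1
        path.append(best_j)
    path = np.asarray(path)
    if np.any(np.diff(path[np.isfinite(path)]) > 1e-9 * np.abs(path[np.isfinite(path)][:-1])):
        raise AssertionError("greedy objective increased along the path")
    return _scheme_from_counts(palette, counts, label=label), path


def exhaustive_scheme_search(palette, budget, truth, noise, weights=None,
                             free=PARAM_NAMES):
    """Brute-force optimum over all allocations of ``budget`` measurements.

    Reference for small problems only (the allocation count grows
    combinatorially).  Ties resolve toward the lexicographically first
    allocation in ascending-b order, matching the greedy tie-break.
    """
    palette = tuple(sorted(set(float(b) for b in palette)))
    weights = weights or DEFAULT_WEIGHTS
    best = None
    best_j = np.inf
    for comp in _compositions(budget, len(palette)):
        counts = dict(zip(palette, comp))
        j = _objective(palette, counts, truth, noise, weights, free)
        if j < best_j - 1e-12 * max(abs(j), 1.0):
            best, best_j = counts, j
    if best is None:
        raise ValueError("every allocation is singular for the requested model")
    return _scheme_from_counts(palette, best, label="exhaustive"), best_j


def _compositions(total, parts):
    """All tuples of `parts` non-negative ints summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for rest in _compositions(total - head, parts - 1):
            yield (head,) + rest


def optimize_for_scan_time(
    palette,
    minutes: float,
    truth: IVIMParams,
    noise,
    tr: float = 4.0,
    directions: int = 3,
    weights=None,
    free=PARAM_NAMES,
    label=None,
):
    """Greedy allocation under a scan-time budget (b=0: 1 TR, else `directions` TRs)."""
    palette = tuple(sorted(set(float(b) for b in palette)))
    free = tuple(free)
    weights = weights or DEFAULT_WEIGHTS
    seconds = minutes * 60.0
    cost = {b: tr * (1 if b == 0 else directions) for b in palette}
    counts = {b: 0 for b in palette}
    start = _spread_start(palette, min(len(palette), len(free)))
    spent = sum(cost[b] for b in start)
    if spent > seconds:
        raise ValueError(f"{minutes} min cannot accommodate the {len(start)} "
                         "identifiability measurements")
    for b in start:
        counts[b] += 1
    path = [_objective(palette, counts, truth, noise, weights, free)]
    while True:
        affordable = [b for b in palette if spent + cost[b] <= seconds]
        if not affordable:
            break
        best_b, best_j = None, np.inf
        for b in affordable:
            counts[b] += 1
            j = _objective(palette, counts, truth, noise, weights, free)
            counts[b] -= 1
            if j < best_j:
                best_b, best_j = b, j
        counts[best_b] += 1
        spent += cost[best_b]
        path.append(best_j)
    scheme = _scheme_from_counts(
        palette, counts, label=label or f"crlb-{minutes:g}min"
    )
    return scheme, np.asarray(path)


def estimate_sigma_b(stack: TraceStack, mask: np.ndarray) -> dict:
    """Measured per-b noise SD: pooled voxel SD across repetitions.

    For each b value, per-voxel SDs across the repetition axis are computed
    inside the mask and pooled (root mean square), giving the absolute signal
    SD that feeds the CRLB.  Population SD convention.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vox = stack.data[mask]  # (nvox, nb, nreps)
    per_voxel_var = vox.var(axis=2)  # population
    sig = np.sqrt(per_voxel_var.mean(axis=0))
    return {float(b): float(s) for b, s in zip(stack.bvalues, sig)}
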