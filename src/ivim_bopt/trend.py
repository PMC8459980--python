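"""Mann-Kendall trend testing, OLS/GLM of map-SD versus design factors, Bonferroni.

The Mann-Kendall statistic S = sum_{i<j} sign(x_j - x_i) tests for a monotone
trend without distributional assumptions; its null variance carries the usual
tie correction and the z score a +/-1 continuity correction.  The general
linear model layer regresses the standard deviation of an IVIM parameter map
on the acquisition design factors (b-value-set identity as a treatment-coded
factor, number of b values, number of averaged repetitions), with nested-model
partial R^2 to compare how much variability each factor explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "TrendResult",
    "GLMResult",
    "mann_kendall",
    "fit_glm",
    "partial_r2",
    "bonferroni",
    "sd_glm_formula",
]


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall test outcome."""

    S: int
    var_S: float
    z: float
    p: float
    n: int


def mann_kendall(sequence) -> TrendResult:
    """Two-sided Mann-Kendall trend test with tie correction."""
    x = np.asarray(sequence, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Mann-Kendall requires at least 3 observations")
    diff = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff, k=1).sum())

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_S = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0

    if var_S <= 0:  # fully tied sequence
        return TrendResult(S=S, var_S=0.0, z=0.0, p=1.0, n=n)
    if S > 0:
        z = (S - 1) / np.sqrt(var_S)
    elif S < 0:
        z = (S + 1) / np.sqrt(var_S)
    else:
        z = 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return TrendResult(S=S, var_S=float(var_S), z=float(z), p=float(min(p, 1.0)), n=n)


def mann_kendall_exact_p(sequence) -> float:
    """Exact two-sided permutation p value of |S| (feasible for small n only)."""
    import itertools

    x = np.asarray(sequence, dtype=float)
    s_obs = abs(mann_kendall(x).S)
    count = total = 0
    for perm in itertools.permutations(x):
        p = np.asarray(perm)
        s = abs(int(np.triu(np.sign(p[None, :] - p[:, None]), k=1).sum()))
        count += s >= s_obs
        total += 1
    return count / total


@dataclass
class GLMResult:
    """OLS fit summary with term-level coefficients and aliasing report."""

    table: pd.DataFrame  # term, estimate, se, t, p
    rsquared: float
    resid_var: float
    df_resid: int
    aliased: list
    model: object  # fitted statsmodels results, for downstream inspection

    def to_csv(self, path, alpha: float = 0.05) -> None:
        out = self.table.copy()
        p_adj, reject = bonferroni(out["p"].to_numpy(), alpha)
        out["p_bonferroni"] = p_adj
        out["significant"] = reject
        out.to_csv(path, index=False)


def sd_glm_formula(scheme_factor: str = "scheme") -> str:
    """Default model: SD ~ b-value-set identity + number of b values + repetitions."""
    return f"sd ~ C({scheme_factor}) + n_bvalues + n_reps"


def fit_glm(table: pd.DataFrame, formula: str | None = None) -> GLMResult:
    """Ordinary least squares with treatment-coded factors via a model formula."""
    formula = formula or sd_glm_formula()
    model = smf.ols(formula, data=table).fit()
    exog = model.model.exog
    rank = np.linalg.matrix_rank(exog)
    aliased = []
    if rank < exog.shape[1]:
        # report columns whose removal does not drop the rank (aliased terms)
        names = model.model.exog_names
        for j, name in enumerate(names):
            reduced = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                aliased.append(name)
    out = pd.DataFrame(
        {
            "term": model.params.index,
            "estimate": model.params.to_numpy(),
            "se": model.bse.to_numpy(),
            "t": model.tvalues.to_numpy(),
            "p": model.pvalues.to_numpy(),
        }
    )
    return GLMResult(
        table=out,
        rsquared=float(model.rsquared),
        resid_var=float(model.scale),
        df_resid=int(model.df_resid),
        aliased=aliased,
        model=model,
    )


def partial_r2(table: pd.DataFrame, formula_full: str, term: str) -> float:
    """Nested-model partial R^2 of one term: (SSE_reduced - SSE_full)/SSE_reduced."""
    full = smf.ols(formula_full, data=table).fit()
    parts = [t.strip() for t in formula_full.split("~")[1].split("+")]
    reduced_terms = [t for t in parts if t != term]
    if len(reduced_terms) == len(parts):
        raise ValueError(f"term {term!r} not found in formula {formula_full!r}")
    lhs = formula_full.split("~")[0].strip()
    reduced_formula = f"{lhs} ~ {' + '.join(reduced_terms) if reduced_terms else '1'}"
    reduced = smf.ols(reduced_formula, data=table).fit()
    sse_full = float(np.sum(full.resid**2))
    sse_red = float(np.sum(reduced.resid**2))
    if sse_red <= 0:
        return 0.0
    return max(0.0, (sse_red - sse_full) / sse_red)


def bonferroni(p_values, alpha: float = 0.05):
    """Bonferroni adjustment: p_adj = min(1, m*p); significant iff p_adj < alpha."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    p_adj = np.minimum(1.0, m * p)
    return p_adj, p_adj < alpha
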