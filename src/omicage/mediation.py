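"""Lifestyle -> aging-rate -> disease mediation with Sobel testing.

The mediation model is the classic recursive two-equation linear path
system. With exposure X, mediator M and outcome Y (all min-max scaled to
[0, 1] for comparability), maximum-likelihood estimation of the
linear-Gaussian paths reduces to three ordinary least-squares fits:

    M = i1 + a X            (a-path)
    Y = i2 + c' X + b M     (b-path and direct effect)
    Y = i3 + c X            (total effect)

The indirect effect is a*b, tested with the Sobel z statistic

    z = a b / sqrt(b^2 SE_a^2 + a^2 SE_b^2)

and the proportion mediated is (a*b)/c. The exact OLS decomposition
c = c' + a*b holds for every fit and is asserted downstream. Disease
outcomes are 0/1, so the Y-equations are linear probability models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "MediationResult",
    "minmax_scale",
    "fit_paths",
    "sobel_test",
    "mediation_matrix",
    "protein_mediator_variant",
]

TOTAL_EFFECT_TOL = 1e-10


def minmax_scale(values, name: str = "values") -> np.ndarray:
    """Scale to [0, 1] by (v - min) / (max - min); constant input is an
    error naming the column."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError(f"non-finite values in {name}")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError(f"constant column: {name}")
    return (v - lo) / (hi - lo)


@dataclass
class MediationResult:
    factor: str
    mediator: str
    disease: str
    a: float
    se_a: float
    b: float
    se_b: float
    c_prime: float
    se_c_prime: float
    total: float
    se_total: float
    indirect: float
    sobel_z: float
    sobel_p: float
    proportion_mediated: float | None
    inconsistent: bool
    significant_p10: bool
    significant_p01: bool


def _ols(y: np.ndarray, X: np.ndarray):
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return model.params[1:], model.bse[1:]


def fit_paths(X, M, Y, factor: str = "X", mediator: str = "M",
              disease: str = "Y") -> MediationResult:
    """Estimate the two-equation mediation path model by OLS (the ML
    estimate for linear-Gaussian paths) and run the Sobel test."""
    x = np.asarray(X, dtype=float)
    m = np.asarray(M, dtype=float)
    y = np.asarray(Y, dtype=float)
    n = len(x)
    if n < 30:
        raise ValueError("need at least 30 observations")
    if abs(np.corrcoef(x, m)[0, 1]) > 1 - 1e-10:
        raise ValueError("exposure and mediator are collinear")

    (a,), (se_a,) = _ols(m, x[:, None])
    coef, se = _ols(y, np.column_stack([x, m]))
    c_prime, b = coef
    se_cp, se_b = se
    (total,), (se_total,) = _ols(y, x[:, None])
    indirect = a * b
    z, p = sobel_test(a, se_a, b, se_b)

    if abs(total) < TOTAL_EFFECT_TOL:
        prop = None
        inconsistent = True
    else:
        prop = indirect / total
        inconsistent = not (0.0 <= prop <= 1.0)
    return MediationResult(
        factor=factor, mediator=mediator, disease=disease,
        a=float(a), se_a=float(se_a), b=float(b), se_b=float(se_b),
        c_prime=float(c_prime), se_c_prime=float(se_cp),
        total=float(total), se_total=float(se_total),
        indirect=float(indirect), sobel_z=z, sobel_p=p,
        proportion_mediated=prop, inconsistent=inconsistent,
        significant_p10=p < 0.1, significant_p01=p < 0.01,
    )


def sobel_test(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Sobel z and two-sided normal p for the indirect effect a*b.

    The degenerate a=b=0 case returns (0, 1) (limit convention).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    denom2 = b**2 * se_a**2 + a**2 * se_b**2
    if denom2 == 0.0:
        return 0.0, 1.0
    z = (a * b) / np.sqrt(denom2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def mediation_matrix(data: pd.DataFrame, factors: list[str], mediator: str,
                     diseases: list[str], scale: bool = True) -> pd.DataFrame:
    """Run the full factor x disease mediation grid with a shared mediator.

    Each variable is min-max scaled before fitting (0/1 outcomes are
    unchanged by the scaling). Returns one row per (factor, disease) pair
    with path coefficients, Sobel z/p, proportion mediated and significance
    flags at the 0.1 and 0.01 thresholds.
    """
    cols = {}
    for name in set(factors) | {mediator} | set(diseases):
        v = data[name].to_numpy(float)
        cols[name] = minmax_scale(v, name=name) if scale else v
    rows = []
    for factor in factors:
        for disease in diseases:
            res = fit_paths(cols[factor], cols[mediator], cols[disease],
                            factor=factor, mediator=mediator, disease=disease)
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def protein_mediator_variant(data: pd.DataFrame, factors: list[str],
                             protein_column: str, diseases: list[str],
                             scale: bool = True) -> pd.DataFrame:
    """Mediation grid with a single protein abundance as the mediator in
    place of the aging rate — same contract as :func:`mediation_matrix`."""
    return mediation_matrix(data, factors, protein_column, diseases, scale=scale)
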