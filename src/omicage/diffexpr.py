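"""Disease-vs-healthy differential protein abundance with a composite
effect-size / significance ranking.

For each protein the fold change is the ratio of mean abundances
(disease / healthy) on the raw, pre-standardization scale, significance is
a two-sided Welch t-test, and proteins are ranked by the composite score

    |log2 FC| x (-log10 p)

which balances magnitude and significance (the volcano-plot geometry).
Because ratio-based fold changes are undefined for non-positive values, a
strictly-positive floor (half the smallest positive value of the protein)
is applied before taking means for the ratio; the t-test runs on the
unfloored values. The top up- and down-regulated proteins (defaults 10 and
5) are reported as candidate disease markers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["welch_t_test", "composite_score", "differential_table", "rank_markers"]


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Two-sample Welch t-test (unequal variances).

    Returns ``(t, df, p_two_sided)`` with the Welch-Satterthwaite degrees
    of freedom. Two zero-variance samples with equal means give
    ``(0, nx+ny-2, 1)``; zero pooled variance with unequal means is an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite sample values")
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    sem2 = vx / nx + vy / ny
    if sem2 == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(nx + ny - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    t = (x.mean() - y.mean()) / np.sqrt(sem2)
    df = sem2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def composite_score(fc: float, p: float) -> float:
    """Composite ranking score |log2 FC| x (-log10 p); requires fc > 0 and
    0 < p <= 1."""
    if fc <= 0:
        raise ValueError(f"fold change must be positive, got {fc}")
    if not (0 < p <= 1):
        raise ValueError(f"p-value outside (0, 1]: {p}")
    return float(abs(np.log2(fc)) * (-np.log10(p)))


def differential_table(disease: pd.DataFrame, healthy: pd.DataFrame,
                       proteins: list[str] | None = None) -> pd.DataFrame:
    """Per-protein differential abundance between two groups.

    ``disease`` and ``healthy`` are participants x proteins frames of raw
    abundances. Columns: group means (after the positivity floor used for
    the ratio), fold change, log2 fold change, Welch t/df/p, a
    Benjamini-Hochberg adjusted p (informational; the ranking uses raw p),
    the composite score, direction, and the composite rank. Proteins whose
    floored means are still non-positive are flagged ``excluded``.
    """
    proteins = proteins if proteins is not None else [
        c for c in disease.columns if c in set(healthy.columns)]
    rows = []
    for protein in proteins:
        xd = disease[protein].to_numpy(float)
        xh = healthy[protein].to_numpy(float)
        combined = np.concatenate([xd, xh])
        positive = combined[combined > 0]
        excluded = len(positive) == 0
        if excluded:
            mean_d = mean_h = fc = log2fc = comp = np.nan
            t = df = p = np.nan
        else:
            floor = 0.5 * positive.min()
            mean_d = float(np.maximum(xd, floor).mean())
            mean_h = float(np.maximum(xh, floor).mean())
            fc = mean_d / mean_h
            log2fc = float(np.log2(fc))
            t, df, p = welch_t_test(xd, xh)
            comp = composite_score(fc, max(p, np.finfo(float).tiny))
        rows.append({
            "protein": protein, "mean_disease": mean_d, "mean_healthy": mean_h,
            "fc": fc, "log2fc": log2fc, "welch_t": t, "welch_df": df, "p": p,
            "composite": comp,
            "direction": ("excluded" if excluded else
                          "up" if fc > 1 else "down" if fc < 1 else "flat"),
        })
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["p_bh"] = np.nan
    if ok.any():
        table.loc[ok, "p_bh"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    table = table.sort_values(["composite", "protein"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def rank_markers(table: pd.DataFrame, n_up: int = 10, n_down: int = 5
                 ) -> tuple[list[str], list[str]]:
    """Top up- and down-regulated candidate markers by composite score.

    Direction is by fold change (up: fc > 1; down: fc < 1); ties break by
    protein name. Warns and returns what is available when a direction has
    fewer markers than requested.
    """
    up = table[table["direction"] == "up"]
    down = table[table["direction"] == "down"]
    if len(up) < n_up or len(down) < n_down:
        warnings.warn(
            f"requested top {n_up}/{n_down} markers but only "
            f"{len(up)}/{len(down)} available")
    return list(up["protein"].iloc[:n_up]), list(down["protein"].iloc[:n_down])
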