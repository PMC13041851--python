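"""Pseudotime regression tests for gene-set dynamics.

Two nested-model F-tests on cells carrying externally computed pseudotime,
branch and species labels:

* **Branch dependence** — a natural cubic spline fit of expression on
  pseudotime (default 6 degrees of freedom) shared across branches (null)
  versus branch-specific intercepts and spline coefficients (alternative).
* **Species dependence** — within a branch, an additive linear model
  (species + pseudotime) versus the interaction model
  (species * pseudotime).

Both compare residual sums of squares with
``F = ((RSS0 - RSS1)/ddf) / (RSS1/(n - p1))``, take the p-value from the F
distribution, Bonferroni-adjust across the gene sets tested in a run, and
call significance at adjusted p < 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SPLINE_DF = 6
DEFAULT_ALPHA = 1e-4

#: metadata columns of a trajectory cell table; remaining columns are gene sets
TRAJECTORY_META_COLUMNS = ("cell_id", "pseudotime", "branch", "species")


@dataclass
class SplineTestResult:
    set_id: str
    f_stat: float
    rss_null: float
    rss_alt: float
    df_num: int
    df_den: int
    pvalue: float
    padj: float
    significant: bool


def natural_spline_basis(t: Sequence[float], df: int = DEFAULT_SPLINE_DF) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Knots: ``df - 1`` internal knots at evenly spaced quantiles of ``t``,
    boundary knots at min/max.  The basis is piecewise cubic between the
    boundary knots and linear beyond them, built from the truncated-power
    construction N_1 = x, N_{k+1} = d_k - d_{K-1}, where
    d_k(x) = ((x - xi_k)_+^3 - (x - xi_K)_+^3) / (xi_K - xi_k)
    and xi_1 < ... < xi_K are all knots.
    """
    t = np.asarray(t, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    n_distinct = len(np.unique(t))
    if n_distinct < df + 2:
        raise ValueError(
            f"need at least {df + 2} distinct pseudotime values, got {n_distinct}"
        )
    n_internal = df - 1
    probs = np.linspace(0, 1, n_internal + 2)[1:-1]
    internal = np.quantile(np.unique(t), probs) if n_internal else np.array([])
    knots = np.concatenate(([t.min()], internal, [t.max()]))
    knots = np.unique(knots)
    K = len(knots)
    if K < 2:
        raise ValueError("degenerate knot sequence")

    def dk(k: int) -> np.ndarray:
        num = np.clip(t - knots[k], 0, None) ** 3 - np.clip(t - knots[K - 1], 0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = [t]
    for k in range(K - 2):
        cols.append(dk(k) - dk(K - 2))
    basis = np.column_stack(cols)
    if basis.shape[1] != df:
        # coincident knots reduced K; pad is not meaningful — report clearly
        raise ValueError("could not construct a basis with the requested df")
    return basis


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and design rank for a least-squares fit."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _f_test(
    rss0: float, rss1: float, rank0: int, rank1: int, n: int
) -> tuple[float, int, int, float]:
    df_num = rank1 - rank0
    df_den = n - rank1
    if df_num <= 0 or df_den <= 0:
        raise ValueError("invalid degrees of freedom for the F-test")
    f = max(rss0 - rss1, 0.0) / df_num / (rss1 / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return f, df_num, df_den, p


def branch_dependence_test(
    table: pd.DataFrame,
    set_id: str,
    df: int = DEFAULT_SPLINE_DF,
    alpha: float = DEFAULT_ALPHA,
    share_intercept: bool = False,
) -> SplineTestResult:
    """Spline F-test for branch-dependent pseudotime dynamics of one set.

    Null: a shared spline trajectory over pooled cells.  Alternative:
    branch-specific spline coefficients (and intercepts, unless
    ``share_intercept``).  The spline basis uses knots from the pooled
    pseudotime so the models are nested.
    """
    t = table["pseudotime"].values.astype(float)
    y = table[set_id].values.astype(float)
    branches = table["branch"].astype(str).values
    uniq = sorted(np.unique(branches))
    if len(uniq) < 2:
        raise ValueError("need at least 2 branches")
    for b in uniq:
        if (branches == b).sum() < df + 2:
            raise ValueError(f"branch {b!r} has fewer than df + 2 = {df + 2} cells")
    N = natural_spline_basis(t, df=df)
    n = len(y)
    X0 = np.column_stack([np.ones(n), N])
    blocks = []
    if share_intercept:
        blocks.append(np.ones((n, 1)))
    for b in uniq:
        ind = (branches == b).astype(float)[:, None]
        if not share_intercept:
            blocks.append(ind)
        blocks.append(ind * N)
    X1 = np.column_stack(blocks)
    rss0, rank0 = _ols_rss(X0, y)
    rss1, rank1 = _ols_rss(X1, y)
    expected_rank = X1.shape[1]
    if rank1 < expected_rank:
        raise ValueError(f"rank-deficient branch design for set {set_id!r}")
    f, df_num, df_den, p = _f_test(rss0, rss1, rank0, rank1, n)
    return SplineTestResult(
        set_id=set_id,
        f_stat=f,
        rss_null=rss0,
        rss_alt=min(rss1, rss0),
        df_num=df_num,
        df_den=df_den,
        pvalue=p,
        padj=p,
        significant=p < alpha,
    )


def species_interaction_test(
    table: pd.DataFrame, set_id: str, alpha: float = DEFAULT_ALPHA
) -> SplineTestResult:
    """F-test of species-by-pseudotime interaction for one gene set.

    Additive model (species + pseudotime) versus the full interaction
    model (species * pseudotime), linear in pseudotime.
    """
    t = table["pseudotime"].values.astype(float)
    y = table[set_id].values.astype(float)
    species = table["species"].astype(str).values
    uniq = sorted(np.unique(species))
    if len(uniq) < 2:
        raise ValueError("need at least 2 species")
    for s in uniq:
        if (species == s).sum() < 3:
            raise ValueError(f"species {s!r} has fewer than 3 cells")
    n = len(y)
    dummies = np.column_stack([(species == s).astype(float) for s in uniq[1:]])
    X0 = np.column_stack([np.ones(n), dummies, t])
    X1 = np.column_stack([np.ones(n), dummies, t, dummies * t[:, None]])
    rss0, rank0 = _ols_rss(X0, y)
    rss1, rank1 = _ols_rss(X1, y)
    if rank1 < X1.shape[1]:
        raise ValueError(f"rank-deficient species design for set {set_id!r}")
    f, df_num, df_den, p = _f_test(rss0, rss1, rank0, rank1, n)
    return SplineTestResult(
        set_id=set_id,
        f_stat=f,
        rss_null=rss0,
        rss_alt=min(rss1, rss0),
        df_num=df_num,
        df_den=df_den,
        pvalue=p,
        padj=p,
        significant=p < alpha,
    )


def _scan(results: list[SplineTestResult], alpha: float) -> pd.DataFrame:
    m = len(results)
    rows = []
    for r in results:
        padj = min(r.pvalue * m, 1.0)
        rows.append(
            {
                "set_id": r.set_id,
                "F": r.f_stat,
                "rss_null": r.rss_null,
                "rss_alt": r.rss_alt,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "pvalue": r.pvalue,
                "padj": padj,
                "significant": padj < alpha,
            }
        )
    return pd.DataFrame(rows)


def branch_dependence_scan(
    table: pd.DataFrame,
    set_ids: Sequence[str] | None = None,
    df: int = DEFAULT_SPLINE_DF,
    alpha: float = DEFAULT_ALPHA,
    share_intercept: bool = False,
) -> pd.DataFrame:
    """Branch-dependence test over many sets with Bonferroni correction."""
    if set_ids is None:
        set_ids = [c for c in table.columns if c not in TRAJECTORY_META_COLUMNS]
    results = [
        branch_dependence_test(table, sid, df=df, alpha=alpha, share_intercept=share_intercept)
        for sid in set_ids
    ]
    return _scan(results, alpha)


def species_interaction_scan(
    table: pd.DataFrame,
    set_ids: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Species-interaction test over many sets with Bonferroni correction."""
    if set_ids is None:
        set_ids = [c for c in table.columns if c not in TRAJECTORY_META_COLUMNS]
    results = [species_interaction_test(table, sid, alpha=alpha) for sid in set_ids]
    return _scan(results, alpha)
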