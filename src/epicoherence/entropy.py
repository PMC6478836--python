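"""Single-cell expression heterogeneity via binary Shannon entropy.

For each gene the fraction of positive cells (fpc: cells with > 0 reads) is
converted to the binary entropy ent = -[fpc log2 fpc + (1-fpc) log2 (1-fpc)],
a 0-1 bit measure of cell-to-cell detection heterogeneity.  Its association
with chromatin-state membership is assessed either by a rank test inside a
population-mean-expression window (with an expression-matched control set) or
by a backfitted additive model: a local-regression smooth in log10 population
mean expression plus a linear chromatin-state term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_expression",
    "compute_fpc",
    "shannon_entropy",
    "entropy_records",
    "stratified_entropy_compare",
    "entropy_state_association",
    "intermediate_entropy_fraction",
]


def normalize_expression(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """TPM-style normalization: counts over transcript length, rescaled to
    one million per cell.  ``counts`` is cells x genes."""
    lengths = gene_lengths.reindex(counts.columns)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("all gene lengths must be positive")
    rate = counts.div(lengths, axis=1)
    totals = rate.sum(axis=1)
    zero_cells = totals == 0
    if zero_cells.any():
        logger.warning("normalize_expression: %d zero-count cells", int(zero_cells.sum()))
        totals = totals.replace(0, 1)
    return rate.div(totals, axis=0) * 1e6


def compute_fpc(matrix: pd.DataFrame) -> pd.Series:
    """Fraction of positive cells per gene (a cell is positive at > 0 reads)."""
    return (matrix > 0).mean(axis=0).rename("fpc")


def shannon_entropy(fpc) -> np.ndarray | float:
    """Binary Shannon entropy (bits) of the detection fraction, with
    0 * log2(0) := 0; symmetric about fpc = 0.5 where it peaks at 1 bit."""
    arr = np.asarray(fpc, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("fpc must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -(arr * np.log2(arr) + (1 - arr) * np.log2(1 - arr))
    ent = np.where((arr == 0) | (arr == 1), 0.0, ent)
    return float(ent) if np.isscalar(fpc) else ent


def entropy_records(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-gene records: fpc, entropy (bits) and log10 population mean
    normalized expression."""
    fpc = compute_fpc(normalized)
    pop_mean = normalized.mean(axis=0)
    with np.errstate(divide="ignore"):
        log_mean = np.log10(pop_mean.to_numpy())
    return pd.DataFrame(
        {
            "fpc": fpc,
            "ent": shannon_entropy(fpc.to_numpy()),
            "pop_mean_expr": log_mean,
        },
        index=normalized.columns,
    )


@dataclass
class StateAssociationResult:
    coefficient: float
    se: float
    z: float
    p: float
    n_marked: int
    n_control: int
    extra: dict


def stratified_entropy_compare(
    records: pd.DataFrame,
    marked_genes,
    window: tuple[float, float] = (-1.25, -0.75),
    match_expression: bool = True,
    seed: int = 0,
    alternative: str = "two-sided",
) -> StateAssociationResult:
    """Compare entropy of marked vs control genes within a population-mean
    expression window (log10 scale), with an expression-matched control set
    drawn by nearest-quantile matching."""
    lo, hi = window
    inside = records[(records["pop_mean_expr"] >= lo) & (records["pop_mean_expr"] <= hi)]
    if inside.empty:
        raise ValueError(f"no genes inside expression window [{lo}, {hi}]")
    marked_set = set(marked_genes)
    marked = inside[inside.index.isin(marked_set)]
    pool = inside[~inside.index.isin(marked_set)]
    if marked.empty or pool.empty:
        raise ValueError(f"empty stratum inside window [{lo}, {hi}]")
    if match_expression:
        # nearest-expression matching without replacement
        rng = np.random.default_rng(seed)
        pool_expr = pool["pop_mean_expr"].to_numpy()
        order = rng.permutation(len(marked))
        available = np.ones(len(pool), dtype=bool)
        chosen = []
        for i in order:
            target = marked["pop_mean_expr"].iloc[i]
            dist = np.abs(pool_expr - target)
            dist[~available] = np.inf
            j = int(np.argmin(dist))
            if not np.isfinite(dist[j]):
                break
            available[j] = False
            chosen.append(j)
        control = pool.iloc[chosen]
    else:
        control = pool
    res = stats.mannwhitneyu(marked["ent"], control["ent"], alternative=alternative)
    diff = float(marked["ent"].median() - control["ent"].median())
    return StateAssociationResult(
        coefficient=diff,
        se=np.nan,
        z=np.nan,
        p=float(res.pvalue),
        n_marked=len(marked),
        n_control=len(control),
        extra={
            "marked_median": float(marked["ent"].median()),
            "control_median": float(control["ent"].median()),
            "window": window,
        },
    )


def entropy_state_association(
    records: pd.DataFrame,
    state_indicator: pd.Series,
    span: float = 0.5,
    n_backfit: int = 2,
) -> StateAssociationResult:
    """Additive-model association of entropy with chromatin-state membership.

    Fits ent ~ s(pop_mean_expr) + state by backfitting: the smooth term is a
    locally weighted regression (lowess, ``span`` fraction), the state term is
    linear; the two are alternated ``n_backfit`` times and the state
    coefficient, its standard error and a Wald p-value are returned.
    """
    df = records.join(state_indicator.rename("state")).dropna(
        subset=["ent", "pop_mean_expr", "state"]
    )
    if len(df) < 50:
        raise ValueError("need at least 50 genes for the association model")
    x = df["pop_mean_expr"].to_numpy(dtype=float)
    s = df["state"].to_numpy(dtype=float)
    y = df["ent"].to_numpy(dtype=float)
    if len(np.unique(s)) < 2:
        return StateAssociationResult(0.0, np.nan, np.nan, 1.0, int(s.sum()), int((1 - s).sum()), {})
    # identifiability: the state must not perfectly predict the expression stratum
    if np.min(x[s == 1]) > np.max(x[s == 0]) or np.max(x[s == 1]) < np.min(x[s == 0]):
        raise ValueError(
            "state indicator perfectly separates expression strata; "
            "the smooth and state terms are not identifiable"
        )
    beta = 0.0
    smooth = np.zeros_like(y)
    for _ in range(n_backfit):
        partial = y - beta * s
        fit = lowess(partial, x, frac=span, return_sorted=True)
        smooth = np.interp(x, fit[:, 0], fit[:, 1])
        resid = y - smooth
        # centred linear term keeps the smooth as the intercept carrier
        sc = s - s.mean()
        denom = float(sc @ sc)
        beta = float(sc @ resid) / denom
    resid_full = y - smooth - beta * (s - s.mean())
    dof = max(len(y) - 2, 1)
    sigma2 = float(resid_full @ resid_full) / dof
    sc = s - s.mean()
    se = float(np.sqrt(sigma2 / (sc @ sc)))
    z = beta / se if se > 0 else np.nan
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return StateAssociationResult(
        coefficient=beta,
        se=se,
        z=z,
        p=p,
        n_marked=int(s.sum()),
        n_control=int(len(s) - s.sum()),
        extra={"span": span, "n_backfit": n_backfit},
    )


def intermediate_entropy_fraction(
    records: pd.DataFrame,
    genes,
    band: tuple[float, float] = (0.25, 0.75),
) -> float:
    """Fraction of the given genes with entropy inside the (open) central band
    — a summary of how many genes sit between uniform silence/expression and
    maximal heterogeneity."""
    ent = records.loc[records.index.isin(set(genes)), "ent"]
    if ent.empty:
        raise ValueError("no entropy records for the requested genes")
    lo, hi = band
    return float(((ent > lo) & (ent < hi)).mean())
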