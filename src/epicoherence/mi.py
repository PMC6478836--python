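"""Mutual-information coordination between DNA methylation and expression.

Bulk mode: per-sample MI between coverage-weighted region methylation and
H3K27ac (or expression) signal after equal-frequency discretization.

Single-cell mode: per-cell MI between binarized promoter methylation and
binarized expression across genes, compared with a scrambled baseline in
which each gene's methylation values are permuted across cells (expression
held fixed), repeated as many times as there are cells; the scrambled value
is the per-cell median across rounds.  The headline statistic is the
percentage MI uplift of matched over scrambled data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SingleCellJoint

logger = logging.getLogger(__name__)

__all__ = [
    "mutual_information",
    "mutual_information_pairs",
    "quantile_discretize",
    "bulk_coordination_mi",
    "sc_qc",
    "downsample_cells",
    "promoter_meth_rate",
    "sc_gene_filter",
    "sc_matched_mi",
    "sc_scrambled_mi",
    "mi_uplift_report",
]


def mutual_information(hist: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a joint count table.

    MI = sum_xy p(x,y) log2[p(x,y) / (p(x) p(y))] with 0*log(0) := 0.
    """
    hist = np.asarray(hist, dtype=float)
    n = hist.sum()
    if n <= 0:
        raise ValueError("empty joint histogram")
    p = hist / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms[p > 0]))


def _binary_mi_from_counts(n11, n10, n01, n00) -> np.ndarray:
    """Vectorized plug-in MI (bits) for 2x2 tables given as parallel arrays."""
    n11, n10, n01, n00 = (np.asarray(x, dtype=float) for x in (n11, n10, n01, n00))
    n = n11 + n10 + n01 + n00
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.zeros_like(n)
        for nxy, rx, cy in (
            (n11, n11 + n10, n11 + n01),
            (n10, n11 + n10, n10 + n00),
            (n01, n01 + n00, n11 + n01),
            (n00, n01 + n00, n10 + n00),
        ):
            p = nxy / n
            term = p * np.log2(nxy * n / (rx * cy))
            mi += np.where(nxy > 0, term, 0.0)
    return mi


def mutual_information_pairs(x: np.ndarray, y: np.ndarray) -> float:
    """MI (bits) of two aligned label vectors via their joint contingency table."""
    x = np.asarray(x)
    y = np.asarray(y)
    xi, x_lab = pd.factorize(x)
    yi, y_lab = pd.factorize(y)
    hist = np.zeros((len(x_lab), len(y_lab)))
    np.add.at(hist, (xi, yi), 1)
    return mutual_information(hist)


def quantile_discretize(values: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Equal-frequency discretization; values tied at a bin edge go to the
    lower bin.  Collapses (with a warning) when there are fewer distinct
    values than bins."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    distinct = np.unique(values)
    if len(distinct) < n_bins:
        warnings.warn(
            f"only {len(distinct)} distinct values for {n_bins} bins; bins collapse",
            stacklevel=2,
        )
    edges = np.quantile(values, np.arange(1, n_bins) / n_bins)
    edges = np.unique(edges)
    return np.searchsorted(edges, values, side="left")


def bulk_coordination_mi(
    meth_by_region: pd.DataFrame,
    signal_by_region: pd.DataFrame,
    n_bins: int = 4,
    min_regions: int = 10,
) -> pd.DataFrame:
    """Per-sample MI between region methylation and region signal.

    Inputs are region x sample DataFrames sharing row and column order; rows
    with a missing value in either variable are dropped pairwise per sample.
    Samples with fewer than ``min_regions`` complete pairs are skipped.
    """
    rows = []
    for sample in meth_by_region.columns:
        m = meth_by_region[sample].to_numpy(dtype=float)
        s = signal_by_region[sample].to_numpy(dtype=float)
        ok = ~(np.isnan(m) | np.isnan(s))
        if ok.sum() < min_regions:
            logger.warning("bulk_coordination_mi: sample %s has < %d paired regions; skipped", sample, min_regions)
            continue
        xm = quantile_discretize(m[ok], n_bins)
        xs = quantile_discretize(s[ok], n_bins)
        rows.append({"sample": sample, "mi": mutual_information_pairs(xm, xs), "n_regions": int(ok.sum())})
    return pd.DataFrame(rows, columns=["sample", "mi", "n_regions"])


# ---------------------------------------------------------------------------
# single-cell pipeline
# ---------------------------------------------------------------------------


def sc_qc(
    joint: SingleCellJoint,
    min_genes: int = 500,
    max_mito_ribo: float = 0.2,
    drop_bottom_decile: bool = True,
) -> SingleCellJoint:
    """Quality-control cells and strip constitutive mito/ribo genes.

    Cells with fewer than ``min_genes`` detected genes or a combined
    mitochondrial+ribosomal read fraction above ``max_mito_ribo`` are removed,
    then cells in the bottom decile of total reads (per sample group, ties
    broken by cell id) are removed.
    """
    meta = joint.cell_meta
    keep = (meta["genes_detected"] >= min_genes) & (
        (meta["mito_frac"] + meta["ribo_frac"]) <= max_mito_ribo
    )
    attrition = {"min_genes_or_mito_ribo": int((~keep).sum())}
    cells = meta.index[keep]
    if drop_bottom_decile and len(cells):
        sub = meta.loc[cells]
        kept_cells = []
        for _, grp in sub.groupby("group", sort=False):
            ordered = grp.assign(_cell=grp.index).sort_values(
                ["total_reads", "_cell"], kind="stable"
            )
            n_drop = int(np.ceil(len(grp) * 0.10))
            kept_cells.extend(ordered.index[n_drop:])
        attrition["bottom_decile"] = len(cells) - len(kept_cells)
        cells = pd.Index([c for c in meta.index if c in set(kept_cells)])
    if len(cells) == 0:
        raise ValueError(f"sc_qc removed all cells; attrition: {attrition}")
    gene_keep = ~(joint.gene_meta["is_mito"] | joint.gene_meta["is_ribo"])
    genes = joint.gene_meta.index[gene_keep]
    logger.info("sc_qc attrition: %s; %d cells, %d genes retained", attrition, len(cells), len(genes))
    return SingleCellJoint(
        expression=joint.expression.loc[cells, genes],
        meth_cpg=joint.meth_cpg.loc[cells, genes],
        total_cpg=joint.total_cpg.loc[cells, genes],
        cell_meta=joint.cell_meta.loc[cells],
        gene_meta=joint.gene_meta.loc[genes],
    )


def downsample_cells(expression: pd.DataFrame, seed: int, cutoff: int | None = None) -> pd.DataFrame:
    """Binomially thin each cell's counts to the 10th-percentile total.

    Every read of a cell above the cutoff survives independently with
    probability cutoff/total; cells at or below the cutoff are untouched.
    """
    rng = np.random.default_rng(seed)
    totals = expression.sum(axis=1).to_numpy()
    if cutoff is None:
        cutoff = int(np.percentile(totals, 10))
    out = expression.to_numpy().copy()
    for i, total in enumerate(totals):
        if total > cutoff > 0:
            out[i] = rng.binomial(out[i], cutoff / total)
    return pd.DataFrame(out, index=expression.index, columns=expression.columns)


def promoter_meth_rate(joint: SingleCellJoint, min_cpg: int = 10) -> pd.DataFrame:
    """Cell x gene promoter methylation rate; NaN where a cell has fewer than
    ``min_cpg`` CpG observations for the gene."""
    total = joint.total_cpg.to_numpy(dtype=float)
    meth = joint.meth_cpg.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(total >= min_cpg, meth / total, np.nan)
    return pd.DataFrame(rate, index=joint.total_cpg.index, columns=joint.total_cpg.columns)


def sc_gene_filter(
    expression: pd.DataFrame,
    meth_rate: pd.DataFrame,
    min_cells_detected: int = 5,
    min_cells_meth: int = 10,
    min_nonzero_frac: float = 0.10,
) -> pd.Index:
    """Genes usable for single-cell MI: detected in >= ``min_cells_detected``
    cells, with a valid methylation call in >= ``min_cells_meth`` cells, and
    non-zero expression in strictly more than ``min_nonzero_frac`` of cells."""
    n_cells = len(expression)
    if n_cells == 0:
        return expression.columns[:0]
    detected = (expression > 0).sum(axis=0)
    meth_calls = meth_rate.notna().sum(axis=0)
    nonzero_frac = detected / n_cells
    keep = (
        (detected >= min_cells_detected)
        & (meth_calls >= min_cells_meth)
        & (nonzero_frac > min_nonzero_frac)
    )
    if not keep.any():
        warnings.warn("sc_gene_filter: no genes pass filters; empty result", stacklevel=2)
    return expression.columns[keep]


def _per_cell_binary_mi(meth_bin: np.ndarray, expr_bin: np.ndarray, valid: np.ndarray,
                        min_genes: int = 20) -> np.ndarray:
    """Per-cell MI across genes of two binary matrices under a validity mask.

    Cells with fewer than ``min_genes`` usable genes get NaN.
    """
    v = valid.astype(float)
    n11 = (v * meth_bin * expr_bin).sum(axis=1)
    n10 = (v * meth_bin * (1 - expr_bin)).sum(axis=1)
    n01 = (v * (1 - meth_bin) * expr_bin).sum(axis=1)
    n00 = (v * (1 - meth_bin) * (1 - expr_bin)).sum(axis=1)
    mi = _binary_mi_from_counts(n11, n10, n01, n00)
    usable = n11 + n10 + n01 + n00
    mi[usable < min_genes] = np.nan
    return mi


def sc_matched_mi(
    expression: pd.DataFrame,
    meth_rate: pd.DataFrame,
    genes: pd.Index | None = None,
    min_genes_per_cell: int = 20,
) -> pd.Series:
    """Per-cell MI between binarized promoter methylation and expression.

    Both variables are thresholded at zero (any detected methylation or
    expression counts as 1).  Cells with fewer than ``min_genes_per_cell``
    genes carrying both observations are excluded (NaN).
    """
    if genes is not None:
        expression = expression[genes]
        meth_rate = meth_rate[genes]
    m = meth_rate.to_numpy(dtype=float)
    e = (expression.to_numpy(dtype=float) > 0).astype(float)
    valid = ~np.isnan(m)
    mb = np.where(valid, (m > 0).astype(float), 0.0)
    mi = _per_cell_binary_mi(mb, e, valid, min_genes_per_cell)
    return pd.Series(mi, index=expression.index, name="mi_matched")


def sc_scrambled_mi(
    expression: pd.DataFrame,
    meth_rate: pd.DataFrame,
    seed: int,
    genes: pd.Index | None = None,
    min_genes_per_cell: int = 20,
    n_rounds: int | None = None,
) -> pd.Series:
    """Scrambled baseline: per gene, methylation values (with their missing
    pattern) are permuted across cells while expression stays fixed; the
    per-cell MI is recomputed each round and the per-cell median over
    ``n_rounds`` rounds (default: number of cells) is returned."""
    if genes is not None:
        expression = expression[genes]
        meth_rate = meth_rate[genes]
    rng = np.random.default_rng(seed)
    m = meth_rate.to_numpy(dtype=float)
    e = (expression.to_numpy(dtype=float) > 0).astype(float)
    valid = ~np.isnan(m)
    mb = np.where(valid, (m > 0).astype(float), 0.0)
    n_cells = m.shape[0]
    rounds = n_rounds if n_rounds is not None else n_cells
    mis = np.empty((rounds, n_cells))
    vf = valid.astype(float)
    for r in range(rounds):
        # independent permutation per gene, shared between values and mask
        keys = rng.random(m.shape)
        idx = np.argsort(keys, axis=0)
        mb_p = np.take_along_axis(mb, idx, axis=0)
        v_p = np.take_along_axis(vf, idx, axis=0)
        mis[r] = _per_cell_binary_mi(mb_p, e, v_p.astype(bool), min_genes_per_cell)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        med = np.nanmedian(mis, axis=0)
    return pd.Series(med, index=expression.index, name="mi_scrambled_median")


@dataclass
class UpliftReport:
    per_group: pd.DataFrame  # group, uplift_percent, ci_low, ci_high, n_cells
    per_cell: pd.DataFrame  # cell, group, mi_matched, mi_scrambled, uplift_percent
    between_group_p: float | None


def mi_uplift_report(
    matched: pd.Series,
    scrambled: pd.Series,
    groups: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> UpliftReport:
    """Percentage MI increase of matched over scrambled data, per group.

    Group uplift = 100 * (mean matched - mean scrambled) / mean scrambled
    over the group's usable cells, with a bootstrap CI over cells.  Groups
    are compared by a two-sided Mann-Whitney rank test on per-cell uplifts.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"mi_matched": matched, "mi_scrambled": scrambled, "group": groups})
    df = df.dropna(subset=["mi_matched", "mi_scrambled"])
    with np.errstate(divide="ignore", invalid="ignore"):
        df["uplift_percent"] = 100.0 * (df["mi_matched"] - df["mi_scrambled"]) / df["mi_scrambled"]
    df.loc[df["mi_scrambled"] == 0, "uplift_percent"] = np.nan

    group_rows = []
    per_cell_uplifts = {}
    for g, sub in df.groupby("group", sort=False):
        if len(sub) < 2:
            logger.warning("mi_uplift_report: group %s has < 2 cells; skipped", g)
            continue
        mm, ms = sub["mi_matched"].to_numpy(), sub["mi_scrambled"].to_numpy()
        mean_s = ms.mean()
        uplift = 100.0 * (mm.mean() - mean_s) / mean_s if mean_s > 0 else np.nan
        boots = np.empty(n_boot)
        n = len(sub)
        for b in range(n_boot):
            take = rng.integers(0, n, size=n)
            bs = ms[take].mean()
            boots[b] = 100.0 * (mm[take].mean() - bs) / bs if bs > 0 else np.nan
        ci_low, ci_high = np.nanpercentile(boots, [2.5, 97.5])
        group_rows.append(
            {"group": g, "uplift_percent": uplift, "ci_low": ci_low, "ci_high": ci_high, "n_cells": n}
        )
        per_cell_uplifts[g] = sub["uplift_percent"].dropna().to_numpy()

    p = None
    if len(per_cell_uplifts) == 2:
        a, b = per_cell_uplifts.values()
        if len(a) and len(b):
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return UpliftReport(
        per_group=pd.DataFrame(group_rows, columns=["group", "uplift_percent", "ci_low", "ci_high", "n_cells"]),
        per_cell=df.reset_index(names="cell"),
        between_group_p=p,
    )
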