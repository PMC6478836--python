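"""Super-enhancer calling from H3K27ac peaks and signal (ROSE-style).

Peaks away from promoters are stitched when they lie within a fixed gap of
each other, stitched regions are ranked by total normalized H3K27ac signal,
and the super-enhancer cut-point is the tangent of slope 1 on the rank/signal
curve with both axes scaled to [0, 1] — regions to the right of the tangent
point are super-enhancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import BinnedTrack, GenomicInterval, cpm_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "StitchedEnhancerSet",
    "tangent_cutpoint",
    "exclude_promoter_peaks",
    "stitch_peaks",
    "region_signal",
    "call_super_enhancers",
    "differential_signal",
    "methylation_at_regions",
    "MethylationLevelSummary",
]


@dataclass
class StitchedEnhancerSet:
    """Ranked stitched regions with the super-enhancer cut-point.

    ``rank`` is 1..n ascending in signal; ``is_super`` is true exactly for
    ranks above ``cutpoint_rank``.
    """

    regions: list[GenomicInterval]
    total_signal: np.ndarray
    rank: np.ndarray
    cutpoint_rank: int
    is_super: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "signal": self.total_signal,
                "rank": self.rank,
                "is_super": self.is_super,
            }
        )


def exclude_promoter_peaks(
    peaks: list[GenomicInterval],
    tss_table: pd.DataFrame,
    flank: int = 2500,
) -> list[GenomicInterval]:
    """Remove peaks overlapping any promoter window (TSS +/- flank) by >= 1 bp.

    ``tss_table`` needs columns ``chrom`` and ``tss`` (one row per transcript).
    """
    if tss_table is None or len(tss_table) == 0:
        logger.warning("exclude_promoter_peaks: empty TSS table; returning peaks unchanged")
        return list(peaks)
    windows: dict[str, np.ndarray] = {}
    for chrom, sub in tss_table.groupby("chrom"):
        tss = sub["tss"].to_numpy()
        windows[chrom] = np.stack(
            [np.maximum(tss - flank, 0), tss + flank], axis=1
        )
    kept = []
    for pk in peaks:
        w = windows.get(pk.chrom)
        if w is None or not ((pk.start < w[:, 1]) & (w[:, 0] < pk.end)).any():
            kept.append(pk)
    return kept


def stitch_peaks(peaks: list[GenomicInterval], gap: int = 12_500) -> list[GenomicInterval]:
    """Concatenate peaks whose inter-peak gap is strictly below ``gap`` bp.

    Idempotent: stitching an already-stitched set returns it unchanged.
    """
    if not peaks:
        return []
    out: list[GenomicInterval] = []
    for chrom in sorted({p.chrom for p in peaks}):
        chrom_peaks = sorted((p for p in peaks if p.chrom == chrom), key=lambda p: p.start)
        cur_start, cur_end = chrom_peaks[0].start, chrom_peaks[0].end
        for pk in chrom_peaks[1:]:
            if pk.start - cur_end < gap:
                cur_end = max(cur_end, pk.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = pk.start, pk.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def region_signal(regions: list[GenomicInterval], track: BinnedTrack) -> np.ndarray:
    """Total CPM-normalized signal of a binned track inside each region."""
    cpm = cpm_normalize(track)
    offsets = {}
    total = 0
    for chrom, length in track.chrom_sizes.items():
        offsets[chrom] = total
        total += -(-length // track.bin_size)
    sig = np.zeros(len(regions))
    for i, r in enumerate(regions):
        if r.chrom not in offsets:
            continue
        b0 = offsets[r.chrom] + r.start // track.bin_size
        b1 = offsets[r.chrom] + (r.end - 1) // track.bin_size + 1
        sig[i] = cpm[b0:b1].sum()
    return sig


def tangent_cutpoint(signal_sorted: np.ndarray) -> int:
    """Index (0-based, into the ascending-sorted signal) of the slope-1
    tangent point on the [0, 1]-scaled rank/signal curve.

    With both axes scaled to [0, 1] the tangent of slope 1 touches the curve
    where x - y is maximal; for a convex hockey-stick curve this is exactly
    the rank at which the discrete slope crosses 1, and unlike a local
    finite-difference scan it is insensitive to flat runs in the tail.  Ties
    (including a perfectly flat or linear curve) resolve to the highest rank,
    so a signal-free landscape yields zero supers.
    """
    n = len(signal_sorted)
    if n < 3:
        raise ValueError("need at least 3 regions to locate a cut-point")
    span = signal_sorted[-1] - signal_sorted[0]
    if span <= 0:
        return n - 1  # flat: nothing to the right of the cut-point
    x = np.arange(n) / (n - 1)
    y = (signal_sorted - signal_sorted[0]) / span
    gap = x - y
    return int(np.flatnonzero(gap >= gap.max() - 1e-12)[-1])


def call_super_enhancers(
    stitched: list[GenomicInterval],
    signal: np.ndarray,
) -> StitchedEnhancerSet:
    """Rank stitched regions by total signal and call super-enhancers above
    the slope-1 tangent cut-point.

    The call is invariant under uniform rescaling of the signal because both
    axes are normalized to [0, 1] before the tangent is located.
    """
    signal = np.asarray(signal, dtype=float)
    if len(stitched) != len(signal):
        raise ValueError("one signal value per stitched region required")
    if len(stitched) < 3:
        raise ValueError("need at least 3 stitched regions")
    order = np.argsort(signal, kind="stable")
    sorted_signal = signal[order]
    cut_idx = tangent_cutpoint(sorted_signal)
    rank = np.empty(len(signal), dtype=int)
    rank[order] = np.arange(1, len(signal) + 1)
    cutpoint_rank = cut_idx + 1
    is_super = rank > cutpoint_rank
    return StitchedEnhancerSet(
        regions=list(stitched),
        total_signal=signal,
        rank=rank,
        cutpoint_rank=cutpoint_rank,
        is_super=is_super,
    )


def differential_signal(
    signal_a: np.ndarray,
    signal_b: np.ndarray,
    lfc_threshold: float = 2.0,
    pseudocount: float = 1.0,
    q: np.ndarray | None = None,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-region log2 fold-change of group-mean CPM signal (A over B) with a
    differential flag at |log2FC| strictly above ``lfc_threshold``.

    ``signal_a``/``signal_b`` are (n_samples, n_regions) arrays of CPM signal.
    If a q-value vector is supplied the flag additionally requires
    q < ``q_threshold``.  Regions with zero signal in both groups are marked
    uninformative with log2FC 0.
    """
    signal_a = np.atleast_2d(np.asarray(signal_a, dtype=float))
    signal_b = np.atleast_2d(np.asarray(signal_b, dtype=float))
    mean_a = signal_a.mean(axis=0)
    mean_b = signal_b.mean(axis=0)
    uninformative = (mean_a == 0) & (mean_b == 0)
    lfc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    lfc[uninformative] = 0.0
    # strict > with a float guard so an exact-threshold ratio is not flagged
    flag = np.abs(lfc) > lfc_threshold + 1e-12
    if q is not None:
        flag &= np.asarray(q) < q_threshold
    flag &= ~uninformative
    return pd.DataFrame({"log2fc": lfc, "differential": flag, "uninformative": uninformative})


@dataclass
class MethylationLevelSummary:
    """Pooled per-CpG level histogram and per-region weighted means.

    Category bins follow the convention [0, 0.2], (0.2, 0.8), (0.8, 1]:
    a CpG at exactly the lower boundary falls in the lower category.
    """

    per_region_mean: pd.DataFrame  # chrom, start, end, mean_level, n_cpgs
    cpg_levels: np.ndarray
    category_counts: dict[str, int]
    n_regions_uncovered: int


def methylation_at_regions(
    meth_table: pd.DataFrame,
    regions: list[GenomicInterval],
    min_coverage: int = 5,
    boundaries: tuple[float, float] = (0.2, 0.8),
) -> MethylationLevelSummary:
    """Pool CpG methylation levels over regions and bin them into
    low/intermediate/high categories.

    CpGs covered by fewer than ``min_coverage`` reads are excluded.  Region
    means are coverage-weighted; regions without covered CpGs are excluded
    from the per-region table (their count is reported).
    """
    cov = meth_table["meth_reads"] + meth_table["unmeth_reads"]
    ok = cov >= min_coverage
    mt = meth_table.loc[ok].copy()
    mt["cov"] = cov[ok]
    mt["level"] = mt["meth_reads"] / mt["cov"]

    rows = []
    levels = []
    weights = []
    uncovered = 0
    by_chrom = {c: sub.sort_values("start") for c, sub in mt.groupby("chrom")}
    for r in regions:
        sub = by_chrom.get(r.chrom)
        if sub is None:
            uncovered += 1
            continue
        starts = sub["start"].to_numpy()
        i0, i1 = np.searchsorted(starts, [r.start, r.end])
        if i1 <= i0:
            uncovered += 1
            continue
        lv = sub["level"].to_numpy()[i0:i1]
        w = sub["cov"].to_numpy()[i0:i1]
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "mean_level": float(np.average(lv, weights=w)),
                "n_cpgs": int(i1 - i0),
            }
        )
        levels.append(lv)
        weights.append(w)
    if uncovered:
        logger.warning("methylation_at_regions: %d regions without covered CpGs", uncovered)
    all_levels = np.concatenate(levels) if levels else np.array([])
    lo, hi = boundaries
    counts = {
        "low": int((all_levels <= lo).sum()),
        "intermediate": int(((all_levels > lo) & (all_levels <= hi)).sum()),
        "high": int((all_levels > hi).sum()),
    }
    return MethylationLevelSummary(
        per_region_mean=pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_level", "n_cpgs"]),
        cpg_levels=all_levels,
        category_counts=counts,
        n_regions_uncovered=uncovered,
    )
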