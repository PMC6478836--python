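"""Tile-based differential methylation calling.

CpG-level bisulfite calls are aggregated into fixed 500-bp tiles with
coverage-weighted mean levels, tiles are coverage-filtered, group differences
are tested by Fisher's exact test on read counts pooled within each group,
q-values come from Benjamini-Hochberg over all tested tiles, and significant
tiles (q <= 0.05, |delta| >= 0.3) are merged into DMRs when they lie less
than 400 bp apart and share a direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, bh_adjust, fisher_exact_many

logger = logging.getLogger(__name__)

__all__ = ["tile_methylation", "filter_tiles", "test_tiles", "test_tile", "call_dmrs", "DMR"]


@dataclass
class DMR:
    interval: GenomicInterval
    delta: float
    p: float
    q: float
    direction: str
    n_tiles: int


def tile_methylation(
    meth_tables: dict[str, pd.DataFrame],
    tile_size: int = 500,
    target_regions: list[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Aggregate per-sample CpG counts into genome-anchored tiles.

    Tiles are anchored at multiples of ``tile_size``.  When ``target_regions``
    is given, only tiles overlapping a target are kept (emulating tiling of a
    capture design).  Returns a long DataFrame indexed by
    (chrom, tile_start, sample) with pooled meth/total read counts and the
    coverage-weighted mean level.
    """
    frames = []
    for sample, df in meth_tables.items():
        d = df.copy()
        d["tile_start"] = (d["start"] // tile_size) * tile_size
        cov = d["meth_reads"] + d["unmeth_reads"]
        d["cov"] = cov
        g = d.groupby(["chrom", "tile_start"], sort=True).agg(
            meth_reads=("meth_reads", "sum"), total_reads=("cov", "sum")
        )
        g["sample"] = sample
        frames.append(g.reset_index())
    tiles = pd.concat(frames, ignore_index=True)
    with np.errstate(invalid="ignore"):
        tiles["weighted_mean_level"] = tiles["meth_reads"] / tiles["total_reads"]
    if target_regions is not None:
        keep = pd.Series(False, index=tiles.index)
        for r in target_regions:
            keep |= (
                (tiles["chrom"] == r.chrom)
                & (tiles["tile_start"] < r.end)
                & (tiles["tile_start"] + tile_size > r.start)
            )
        tiles = tiles.loc[keep].reset_index(drop=True)
    tiles.attrs["tile_size"] = tile_size
    return tiles


def filter_tiles(
    tiles: pd.DataFrame, min_reads: int = 10, min_sample_frac: float = 0.7
) -> pd.DataFrame:
    """Retain tiles covered with strictly more than ``min_reads`` reads in at
    least ``min_sample_frac`` of all samples."""
    n_samples = tiles["sample"].nunique()
    ok = (
        tiles.assign(deep=tiles["total_reads"] > min_reads)
        .groupby(["chrom", "tile_start"])["deep"]
        .sum()
    )
    keep = ok[ok >= min_sample_frac * n_samples].index
    out = tiles.set_index(["chrom", "tile_start"]).loc[tiles.set_index(["chrom", "tile_start"]).index.isin(keep)].reset_index()
    out.attrs["tile_size"] = tiles.attrs.get("tile_size", 500)
    return out


def test_tiles(
    tiles: pd.DataFrame, case_ids: list[str], control_ids: list[str]
) -> pd.DataFrame:
    """Per-tile pooled Fisher test: read counts are summed within each group
    and the 2x2 table (meth/unmeth x case/control) is tested two-sided.

    Returns one row per tile with pooled levels, delta (case - control) and p.
    Tiles with zero pooled coverage in either group are skipped (logged).
    """
    is_case = tiles["sample"].isin(case_ids)
    is_control = tiles["sample"].isin(control_ids)

    def _pool(sub):
        return sub.groupby(["chrom", "tile_start"], sort=True).agg(
            meth=("meth_reads", "sum"), total=("total_reads", "sum")
        )

    pooled_case = _pool(tiles[is_case])
    pooled_control = _pool(tiles[is_control])
    merged = pooled_case.join(pooled_control, lsuffix="_case", rsuffix="_control", how="inner")
    usable = (merged["total_case"] > 0) & (merged["total_control"] > 0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.warning("test_tiles: skipped %d tiles with zero pooled group coverage", n_skipped)
    merged = merged[usable]
    a = merged["meth_case"].to_numpy()
    b = (merged["total_case"] - merged["meth_case"]).to_numpy()
    c = merged["meth_control"].to_numpy()
    d = (merged["total_control"] - merged["meth_control"]).to_numpy()
    out = merged.reset_index()
    out["level_case"] = a / (a + b)
    out["level_control"] = c / (c + d)
    out["delta"] = out["level_case"] - out["level_control"]
    out["p"] = fisher_exact_many(a, b, c, d)
    out.attrs["tile_size"] = tiles.attrs.get("tile_size", 500)
    return out


def test_tile(
    tiles: pd.DataFrame,
    chrom: str,
    tile_start: int,
    case_ids: list[str],
    control_ids: list[str],
) -> tuple[float, float]:
    """(delta, p) for a single tile; convenience wrapper over test_tiles."""
    sub = tiles[(tiles["chrom"] == chrom) & (tiles["tile_start"] == tile_start)]
    res = test_tiles(sub, case_ids, control_ids)
    if res.empty:
        raise ValueError(f"tile {chrom}:{tile_start} has zero pooled coverage in a group")
    return float(res["delta"].iloc[0]), float(res["p"].iloc[0])


def call_dmrs(
    tested: pd.DataFrame,
    q_threshold: float = 0.05,
    delta_threshold: float = 0.3,
    merge_gap: int = 400,
    tile_size: int | None = None,
) -> list[DMR]:
    """BH-correct tile p-values, select significant tiles and merge them into
    DMRs.

    Tiles are significant at q <= ``q_threshold`` and |delta| >=
    ``delta_threshold``.  Adjacent significant tiles are merged when the gap
    between them is strictly below ``merge_gap`` bp and their direction
    (hyper = case above control) agrees; the merged delta is the
    coverage-weighted mean of member deltas and the merged p/q the member
    minimum.
    """
    tested = tested.copy()
    tile_size = tile_size or tested.attrs.get("tile_size", 500)
    tested["q"] = bh_adjust(tested["p"].to_numpy())
    sig = tested[
        (tested["q"] <= q_threshold) & (tested["delta"].abs() >= delta_threshold)
    ].sort_values(["chrom", "tile_start"])

    dmrs: list[DMR] = []
    cur: dict | None = None
    for row in sig.itertuples():
        direction = "hyper" if row.delta > 0 else "hypo"
        start, end = row.tile_start, row.tile_start + tile_size
        weight = row.total_case + row.total_control
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and direction == cur["direction"]
            and start - cur["end"] < merge_gap
        ):
            cur["end"] = end
            cur["deltas"].append(row.delta)
            cur["weights"].append(weight)
            cur["p"] = min(cur["p"], row.p)
            cur["q"] = min(cur["q"], row.q)
            cur["n"] += 1
        else:
            if cur is not None:
                dmrs.append(_finalize(cur))
            cur = {
                "chrom": row.chrom,
                "start": start,
                "end": end,
                "direction": direction,
                "deltas": [row.delta],
                "weights": [weight],
                "p": row.p,
                "q": row.q,
                "n": 1,
            }
    if cur is not None:
        dmrs.append(_finalize(cur))
    return dmrs


def _finalize(cur: dict) -> DMR:
    return DMR(
        interval=GenomicInterval(cur["chrom"], int(cur["start"]), int(cur["end"])),
        delta=float(np.average(cur["deltas"], weights=cur["weights"])),
        p=float(cur["p"]),
        q=float(cur["q"]),
        direction=cur["direction"],
        n_tiles=cur["n"],
    )


def dmrs_to_frame(dmrs: list[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.interval.chrom for d in dmrs],
            "start": [d.interval.start for d in dmrs],
            "end": [d.interval.end for d in dmrs],
            "delta": [d.delta for d in dmrs],
            "p": [d.p for d in dmrs],
            "q": [d.q for d in dmrs],
            "direction": [d.direction for d in dmrs],
            "n_tiles": [d.n_tiles for d in dmrs],
        }
    )
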