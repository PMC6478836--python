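"""Genomic interval plumbing, text-format readers/writers and shared statistics.

All coordinates in the package are 0-based half-open (BED convention).
``chrom.sizes`` files carry chromosome *lengths*, not coordinates, and are
converted at the parser boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "BinnedTrack",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_methylation_table",
    "write_methylation_table",
    "bin_genome",
    "count_in_bins",
    "cpm_normalize",
    "overlap_select",
    "bh_adjust",
    "fisher_exact_2x2",
    "fisher_exact_many",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"start >= end in interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class BinnedTrack:
    """Per-sample, per-mark read counts over fixed-width genome bins.

    ``counts`` holds one entry per bin of the concatenated genome tiling
    produced by :func:`bin_genome` with the same ``chrom_sizes`` and
    ``bin_size``.  ``library_size`` may exceed the binned total (reads
    falling outside the binned genome still count toward the library).
    """

    sample_id: str
    mark: str
    bin_size: int
    counts: np.ndarray
    library_size: int
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative bin counts")
        if self.chrom_sizes:
            expected = sum(
                -(-length // self.bin_size) for length in self.chrom_sizes.values()
            )
            if len(self.counts) != expected:
                raise ValueError(
                    f"counts length {len(self.counts)} != expected {expected} bins"
                )

    @property
    def n_bins(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# readers / writers (LF line endings, tab separators)
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file into a list of intervals, preserving file order."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path, extra_columns=None) -> None:
    """Write intervals as BED; ``extra_columns`` is an optional list of
    per-interval sequences appended after the first three fields."""
    intervals = list(intervals)
    extras = list(zip(*extra_columns)) if extra_columns else [()] * len(intervals)
    with open(path, "w", newline="\n") as fh:
        for iv, extra in zip(intervals, extras):
            cols = [iv.chrom, str(iv.start), str(iv.end)] + [str(x) for x in extra]
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length (in bp)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            name, length = line.split("\t")[:2]
            length = int(length)
            if length <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive length")
            sizes[name] = length
    return sizes


_METH_COLUMNS = ["chrom", "start", "end", "meth_reads", "unmeth_reads"]


def read_methylation_table(path) -> pd.DataFrame:
    """Read a CpG coverage table: chrom, start, end, meth_reads, unmeth_reads.

    The Bismark-coverage dialect with an extra percent-methylation column
    (chrom, start, end, percent, meth, unmeth) is auto-detected and the
    percent column dropped.  Zero-coverage rows are retained; a boolean
    ``covered`` column flags rows with any reads.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 6 and _looks_like_percent(df.iloc[:, 3]):
        df = df.iloc[:, [0, 1, 2, 4, 5]]
    else:
        df = df.iloc[:, :5]
    df.columns = _METH_COLUMNS
    if (df["meth_reads"] < 0).any() or (df["unmeth_reads"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    df["covered"] = (df["meth_reads"] + df["unmeth_reads"]) > 0
    return df


def _looks_like_percent(col: pd.Series) -> bool:
    vals = pd.to_numeric(col, errors="coerce")
    if vals.isna().any():
        return False
    # percent column: floats in [0, 100], not all integral counts
    in_range = ((vals >= 0) & (vals <= 100)).all()
    fractional = (vals % 1 != 0).any()
    return bool(in_range and (fractional or (vals <= 100).all()))


def write_methylation_table(df: pd.DataFrame, path) -> None:
    df[_METH_COLUMNS].to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# genome binning
# ---------------------------------------------------------------------------


def bin_genome(chrom_sizes: dict[str, int], bin_size: int) -> list[GenomicInterval]:
    """Non-overlapping tiling of each chromosome; the last bin is truncated
    at the chromosome end."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: list[GenomicInterval] = []
    for chrom, length in chrom_sizes.items():
        for start in range(0, length, bin_size):
            bins.append(GenomicInterval(chrom, start, min(start + bin_size, length)))
    return bins


def _chrom_offsets(chrom_sizes: dict[str, int], bin_size: int) -> dict[str, int]:
    offsets = {}
    total = 0
    for chrom, length in chrom_sizes.items():
        offsets[chrom] = total
        total += -(-length // bin_size)
    return offsets


def count_in_bins(
    read_positions: Sequence[tuple[str, int, str]],
    chrom_sizes: dict[str, int],
    bin_size: int,
    shift_bp: int = 0,
    sample_id: str = "sample",
    mark: str = "track",
) -> BinnedTrack:
    """Assign reads to genome bins after shifting each 5' position ``shift_bp``
    along its strand (+ reads move right, - reads move left).

    Strandless reads are treated as ``+``.  Reads on unknown chromosomes or
    shifted outside the chromosome are skipped with a logged count.
    """
    offsets = _chrom_offsets(chrom_sizes, bin_size)
    n_bins = sum(-(-length // bin_size) for length in chrom_sizes.values())
    counts = np.zeros(n_bins, dtype=np.int64)
    skipped = 0
    for chrom, pos, strand in read_positions:
        if chrom not in chrom_sizes:
            skipped += 1
            continue
        shifted = pos + shift_bp if strand != "-" else pos - shift_bp
        if shifted < 0 or shifted >= chrom_sizes[chrom]:
            skipped += 1
            continue
        counts[offsets[chrom] + shifted // bin_size] += 1
    if skipped:
        logger.warning("count_in_bins: skipped %d reads (unknown chrom or out of range)", skipped)
    return BinnedTrack(
        sample_id=sample_id,
        mark=mark,
        bin_size=bin_size,
        counts=counts,
        library_size=len(read_positions),
        chrom_sizes=dict(chrom_sizes),
    )


def cpm_normalize(track: BinnedTrack) -> np.ndarray:
    """Counts per million mapped reads."""
    if track.library_size <= 0:
        raise ValueError("library_size must be positive for CPM normalization")
    return track.counts * 1e6 / track.library_size


# ---------------------------------------------------------------------------
# interval overlap
# ---------------------------------------------------------------------------


def _merge_intervals(ivs: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merge overlapping intervals per chromosome; returns per-chrom (n, 2) arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        out = [list(pairs[0])]
        for s, e in pairs[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out)
    return merged


def overlap_select(
    query: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    min_frac: float,
) -> np.ndarray:
    """True for each query interval whose total overlap with the (merged)
    reference set is at least ``min_frac`` of the query length."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    merged = _merge_intervals(reference) if reference else {}
    result = np.zeros(len(query), dtype=bool)
    for i, iv in enumerate(query):
        arr = merged.get(iv.chrom)
        if arr is None:
            continue
        ov = np.minimum(arr[:, 1], iv.end) - np.maximum(arr[:, 0], iv.start)
        total = int(ov[ov > 0].sum())
        result[i] = total >= min_frac * len(iv)
    return result


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log_hypergeom_pmf(a: np.ndarray, r1: int, r2: int, k: int) -> np.ndarray:
    """log P(A = a) for the 2x2 table hypergeometric with row margins r1, r2
    and first-column margin k."""
    return (
        gammaln(r1 + 1)
        - gammaln(a + 1)
        - gammaln(r1 - a + 1)
        + gammaln(r2 + 1)
        - gammaln(k - a + 1)
        - gammaln(r2 - (k - a) + 1)
        - (gammaln(r1 + r2 + 1) - gammaln(k + 1) - gammaln(r1 + r2 - k + 1))
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p-value for the table [[a, b], [c, d]].

    Uses the probability-mass criterion: p is the total hypergeometric
    probability of tables (with the observed margins) whose point probability
    does not exceed that of the observed table.  A table with an all-zero
    margin carries no information; p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    r1, r2, k = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or k == 0 or (b + d) == 0:
        logger.debug("fisher_exact_2x2: degenerate margin, p = 1")
        return 1.0
    lo, hi = max(0, k - r2), min(k, r1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, r1, r2, k)
    logp_obs = logp[a - lo]
    # relative tolerance guards against ties lost to floating-point noise
    mask = logp <= logp_obs + 1e-7
    pmf = np.exp(logp)
    return float(min(1.0, pmf[mask].sum()))


def fisher_exact_many(a, b, c, d) -> np.ndarray:
    """Vectorized :func:`fisher_exact_2x2` over parallel cell arrays."""
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    out = np.empty(a.shape, dtype=float)
    for i in range(a.size):
        out.flat[i] = fisher_exact_2x2(
            int(a.flat[i]), int(b.flat[i]), int(c.flat[i]), int(d.flat[i])
        )
    return out
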