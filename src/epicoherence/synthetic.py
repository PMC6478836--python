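"""Synthetic multi-omic cohort generators with known ground truth.

Every generator is a pure function of its spec (including the seed): the
same spec yields bit-identical output.  The simulated conditions emulate a
two-group study design — a leukemia-like case group with degraded
epigenetic-transcriptional coordination and increased cell-to-cell
heterogeneity, against a normal-like control group.

Ground truth is returned alongside the data (and written as TSV by the CLI)
so downstream callers can score recall/precision without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import BinnedTrack, GenomicInterval

__all__ = [
    "CohortSpec",
    "DmrSpec",
    "EnhancerLandscapeSpec",
    "ScJointSpec",
    "StateSimSpec",
    "simulate_enhancer_landscape",
    "simulate_methylome",
    "simulate_sc_joint",
    "simulate_state_tracks",
    "simulate_bulk_coupled_methylation",
    "simulate_state_signal_matrix",
    "SingleCellJoint",
]


@dataclass
class CohortSpec:
    """Two-group bulk cohort layout."""

    n_case: int = 3
    n_control: int = 3
    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 5_000_000})

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both groups need at least one sample")
        if any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be positive")

    @property
    def case_ids(self) -> list[str]:
        return [f"case{i}" for i in range(self.n_case)]

    @property
    def control_ids(self) -> list[str]:
        return [f"control{i}" for i in range(self.n_control)]


@dataclass
class EnhancerLandscapeSpec:
    """Hockey-stick H3K27ac landscape: a log-normal body of typical enhancers
    plus a heavy upper tail of multi-constituent super-enhancers whose
    constituents sit closer than the stitching gap."""

    n_enhancers: int = 500
    fraction_super: float = 0.1
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 50_000_000})
    seed: int = 0
    bin_size: int = 200
    stitch_gap: int = 12_500
    # log-normal body (natural-log scale); supers are boosted multiplicatively,
    # giving them roughly 1.5 orders of magnitude more total signal than the
    # median typical enhancer, as in observed H3K27ac landscapes
    body_mu: float = 3.0
    body_sigma: float = 0.3
    super_boost: float = 25.0
    peak_width: int = 1_000
    constituents_range: tuple[int, int] = (3, 6)


@dataclass
class DmrSpec:
    """Implanted hypo/hyper DMRs in a Beta-background methylome."""

    n_tiles: int = 10_000
    tile_size: int = 500
    cpgs_per_tile: float = 5.0
    coverage_mean: float = 30.0
    n_dmrs: int = 50
    delta: float = 0.5
    dmr_tiles: int = 2  # tiles per implanted DMR
    background_alpha: float = 0.7
    background_beta: float = 0.7
    n_intermediate: int = 0  # case-group tiles pulled toward 0.5


@dataclass
class ScJointSpec:
    """Joint single-cell expression + promoter methylation simulation.

    ``coupling`` is an odds-ratio-like strength theta >= 1 linking promoter
    methylation to transcriptional silencing; theta = 1 means independence.
    In ``admixture`` mode each cell belongs to one of two epistates with
    opposite methylation/expression configurations at heterogeneous genes,
    while marginal per-gene rates match the homogeneous mode.
    """

    n_cells: int = 100
    n_genes: int = 500
    coupling: float = 1.0
    heterogeneity_mode: str = "homogeneous"  # or "admixture"
    admixture_fraction: float = 0.5
    dropout_rate: float = 0.3
    cpg_per_promoter: float = 15.0
    depth: float = 20_000.0
    het_gene_fraction: float = 0.3
    epimutation_rate: float = 0.1  # per cell-gene flip of the methylation config
    n_mito: int = 10
    n_ribo: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling < 1:
            raise ValueError("coupling theta must be >= 1")
        if not 0 <= self.admixture_fraction <= 1:
            raise ValueError("admixture_fraction must be in [0, 1]")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.heterogeneity_mode not in ("homogeneous", "admixture"):
            raise ValueError(f"unknown heterogeneity_mode {self.heterogeneity_mode!r}")


@dataclass
class StateSimSpec:
    """Hidden-Markov ground truth for multi-track binned signal."""

    K: int = 3
    A: Optional[np.ndarray] = None  # K x K transition matrix, rows sum to 1
    nb_means: Optional[np.ndarray] = None  # K x n_tracks
    nb_dispersions: Optional[np.ndarray] = None  # K x n_tracks (size parameter r)
    meth_rates: Optional[np.ndarray] = None  # K, or None for no methylation track
    meth_coverage: float = 30.0
    n_bins: int = 20_000
    bin_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A is None:
            # sticky chain: mean segment length 20 bins
            self.A = np.full((self.K, self.K), 0.05 / max(self.K - 1, 1))
            np.fill_diagonal(self.A, 0.95 if self.K > 1 else 1.0)
        self.A = np.asarray(self.A, dtype=float)
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if self.nb_means is None:
            # well-separated means, shared across 3 tracks with a rotation so
            # tracks are informative jointly
            base = np.array([2.0, 20.0, 80.0])[: self.K]
            if self.K > 3:
                base = np.geomspace(2.0, 80.0, self.K)
            self.nb_means = np.stack([base, np.roll(base, 1), base[::-1]], axis=1)
        self.nb_means = np.asarray(self.nb_means, dtype=float)
        if self.nb_dispersions is None:
            self.nb_dispersions = np.full_like(self.nb_means, 10.0)
        self.nb_dispersions = np.asarray(self.nb_dispersions, dtype=float)
        if (self.nb_means <= 0).any() or (self.nb_dispersions <= 0).any():
            raise ValueError("NB means and dispersions must be positive")


@dataclass
class SingleCellJoint:
    """Cell x gene expression counts paired with promoter CpG observations."""

    expression: pd.DataFrame  # cells x genes, integer counts
    meth_cpg: pd.DataFrame  # cells x genes, methylated CpG observations
    total_cpg: pd.DataFrame  # cells x genes, total CpG observations
    cell_meta: pd.DataFrame  # total_reads, genes_detected, mito_frac, ribo_frac, group
    gene_meta: pd.DataFrame  # is_mito, is_ribo, gene_length, tss

    def __post_init__(self) -> None:
        if (self.meth_cpg.values > self.total_cpg.values).any():
            raise ValueError("meth_cpg exceeds total_cpg")
        if not (
            self.expression.index.equals(self.meth_cpg.index)
            and self.expression.columns.equals(self.meth_cpg.columns)
        ):
            raise ValueError("expression and methylation matrices must share indices")


# ---------------------------------------------------------------------------
# enhancer landscape
# ---------------------------------------------------------------------------


def simulate_enhancer_landscape(spec: EnhancerLandscapeSpec):
    """Place enhancer units along the genome and emit binned H3K27ac signal.

    Returns ``(peaks, track, truth)`` where ``peaks`` is the constituent peak
    list, ``track`` a :class:`BinnedTrack` of simulated H3K27ac read counts,
    and ``truth`` a DataFrame of enhancer units (one row per stitched unit)
    with their ``is_super`` flag.
    """
    rng = np.random.default_rng(spec.seed)
    n_super = int(round(spec.n_enhancers * spec.fraction_super))
    is_super = np.zeros(spec.n_enhancers, dtype=bool)
    if n_super:
        is_super[rng.choice(spec.n_enhancers, size=n_super, replace=False)] = True

    chroms = list(spec.chrom_sizes)
    lengths = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    genome = lengths.sum()

    # sequential placement with > stitch_gap spacing between units so that
    # stitching recovers exactly the simulated units
    peaks: list[GenomicInterval] = []
    unit_rows = []
    peak_signal: list[float] = []
    cursor = {c: spec.stitch_gap for c in chroms}
    chrom_weights = lengths / genome
    order = rng.permutation(spec.n_enhancers)
    for unit_id in order:
        super_flag = bool(is_super[unit_id])
        n_const = (
            int(rng.integers(spec.constituents_range[0], spec.constituents_range[1] + 1))
            if super_flag
            else 1
        )
        gaps = rng.integers(500, spec.stitch_gap - spec.peak_width, size=max(n_const - 1, 0))
        unit_len = n_const * spec.peak_width + int(gaps.sum())
        chrom = rng.choice(chroms, p=chrom_weights)
        start = cursor[chrom]
        if start + unit_len + spec.stitch_gap > spec.chrom_sizes[chrom]:
            candidates = [
                c
                for c in chroms
                if cursor[c] + unit_len + spec.stitch_gap <= spec.chrom_sizes[c]
            ]
            if not candidates:
                raise ValueError("genome too small to place all enhancer units")
            chrom = candidates[0]
            start = cursor[chrom]
        base = float(rng.lognormal(spec.body_mu, spec.body_sigma))
        total = base * spec.super_boost if super_flag else base
        pos = start
        const_signal = rng.dirichlet(np.ones(n_const)) * total
        for j in range(n_const):
            peaks.append(GenomicInterval(chrom, pos, pos + spec.peak_width))
            peak_signal.append(float(const_signal[j]))
            pos += spec.peak_width
            if j < n_const - 1:
                pos += int(gaps[j])
        unit_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": pos,
                "is_super": super_flag,
                "true_signal": total,
            }
        )
        cursor[chrom] = pos + spec.stitch_gap + 1

    truth = pd.DataFrame(unit_rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    # binned read counts: Poisson around each peak's signal spread over its bins
    offsets = {}
    total_bins = 0
    for c in chroms:
        offsets[c] = total_bins
        total_bins += -(-spec.chrom_sizes[c] // spec.bin_size)
    counts = np.zeros(total_bins, dtype=np.int64)
    for iv, sig in zip(peaks, peak_signal):
        b0 = offsets[iv.chrom] + iv.start // spec.bin_size
        b1 = offsets[iv.chrom] + (iv.end - 1) // spec.bin_size + 1
        counts[b0:b1] += rng.poisson(max(sig, 0.01) / (b1 - b0), size=b1 - b0)
    # light uniform background
    counts += rng.poisson(0.05, size=total_bins)
    track = BinnedTrack(
        sample_id="sim",
        mark="H3K27ac",
        bin_size=spec.bin_size,
        counts=counts,
        library_size=int(max(counts.sum(), 1)),
        chrom_sizes=dict(spec.chrom_sizes),
    )
    peaks_sorted = sorted(peaks)
    return peaks_sorted, track, truth


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def simulate_methylome(cohort: CohortSpec, dmr_spec: DmrSpec):
    """Simulate per-sample CpG coverage tables with implanted DMRs.

    Returns ``(tables, truth)``: ``tables`` maps sample id to a coverage-table
    DataFrame (chrom, start, end, meth_reads, unmeth_reads); ``truth`` lists
    the implanted DMR intervals with direction (``hyper`` = higher in case).
    """
    rng = np.random.default_rng(cohort.seed)
    ts = dmr_spec.tile_size
    chrom = next(iter(cohort.chrom_sizes))
    if dmr_spec.n_tiles * ts > cohort.chrom_sizes[chrom]:
        raise ValueError("chromosome too short for requested tile count")

    n_tiles = dmr_spec.n_tiles
    base_level = rng.beta(dmr_spec.background_alpha, dmr_spec.background_beta, size=n_tiles)

    case_level = base_level.copy()
    control_level = base_level.copy()

    # implant DMRs on non-adjacent tile blocks
    truth_rows = []
    taken = np.zeros(n_tiles, dtype=bool)
    n_placed = 0
    guard = 0
    block = dmr_spec.dmr_tiles
    while n_placed < dmr_spec.n_dmrs and guard < 100 * dmr_spec.n_dmrs:
        guard += 1
        t0 = int(rng.integers(0, n_tiles - block))
        # keep one clear tile on each side so merged calls stay separable
        lo, hi = max(t0 - 1, 0), min(t0 + block + 1, n_tiles)
        if taken[lo:hi].any():
            continue
        taken[lo:hi] = True
        direction = rng.choice(["hyper", "hypo"])
        sign = 1.0 if direction == "hyper" else -1.0
        # anchor the base level so the full |delta| fits inside [0, 1]
        anchor = rng.uniform(0.05, 1.0 - dmr_spec.delta - 0.05) if dmr_spec.delta < 0.9 else 0.05
        for t in range(t0, t0 + block):
            if sign > 0:
                control_level[t] = anchor
                case_level[t] = anchor + dmr_spec.delta
            else:
                control_level[t] = anchor + dmr_spec.delta
                case_level[t] = anchor
        truth_rows.append(
            {
                "chrom": chrom,
                "start": t0 * ts,
                "end": (t0 + block) * ts,
                "direction": direction,
                "delta": sign * dmr_spec.delta,
            }
        )
        n_placed += 1
    if n_placed < dmr_spec.n_dmrs:
        raise ValueError("could not place all DMRs without adjacency; reduce n_dmrs")

    # intermediate-methylation regions: case level pulled toward 0.5
    if dmr_spec.n_intermediate:
        free = np.flatnonzero(~taken)
        pick = rng.choice(free, size=min(dmr_spec.n_intermediate, len(free)), replace=False)
        case_level[pick] = rng.uniform(0.4, 0.6, size=len(pick))

    case_level = np.clip(case_level, 0.0, 1.0)
    control_level = np.clip(control_level, 0.0, 1.0)

    # per-tile CpG layout shared across samples
    n_cpg = rng.poisson(dmr_spec.cpgs_per_tile, size=n_tiles)
    cpg_tile = np.repeat(np.arange(n_tiles), n_cpg)
    within = np.concatenate([np.sort(rng.integers(0, ts, size=k)) for k in n_cpg]) if n_cpg.sum() else np.array([], dtype=int)
    cpg_pos = cpg_tile * ts + within

    tables: dict[str, pd.DataFrame] = {}
    sample_noise_sd = 0.03
    for group, ids, level in (
        ("case", cohort.case_ids, case_level),
        ("control", cohort.control_ids, control_level),
    ):
        for sid in ids:
            samp_level = np.clip(level + rng.normal(0, sample_noise_sd, size=n_tiles), 0, 1)
            cov = rng.poisson(dmr_spec.coverage_mean, size=len(cpg_pos))
            meth = rng.binomial(cov, samp_level[cpg_tile])
            tables[sid] = pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": cpg_pos,
                    "end": cpg_pos + 1,
                    "meth_reads": meth,
                    "unmeth_reads": cov - meth,
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "direction", "delta"]
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    return tables, truth


def simulate_bulk_coupled_methylation(
    region_signal: np.ndarray,
    n_case: int = 3,
    n_control: int = 3,
    coupling_case: float = 0.4,
    coupling_control: float = 0.9,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample region methylation levels anticorrelated with an activity
    signal (high H3K27ac regions are hypomethylated), with tunable coupling.

    ``coupling`` in [0, 1] mixes the signal-driven target (1 minus the signal
    rank, so coupling pulls methylation down where signal is high) with an
    independent Beta draw; the case group uses a weaker coupling, emulating
    degraded bulk coordination.  Returns (levels, group labels).
    """
    rng = np.random.default_rng(seed)
    s = np.asarray(region_signal, dtype=float)
    ranks = np.argsort(np.argsort(s)) / max(len(s) - 1, 1)
    target = 1.0 - ranks
    cols = {}
    groups = {}
    for group, n, w in (("case", n_case, coupling_case), ("control", n_control, coupling_control)):
        for i in range(n):
            noise = rng.beta(2, 2, size=len(s))
            level = w * target + (1 - w) * noise + rng.normal(0, noise_sd, size=len(s))
            sid = f"{group}{i}"
            cols[sid] = np.clip(level, 0, 1)
            groups[sid] = group
    levels = pd.DataFrame(cols)
    return levels, pd.Series(groups, name="group")


# ---------------------------------------------------------------------------
# single-cell joint methylome + transcriptome
# ---------------------------------------------------------------------------


def simulate_sc_joint(spec: ScJointSpec):
    """Simulate a joint single-cell promoter-methylation / expression matrix.

    Heterogeneous genes carry the coupling signal.  In ``admixture`` mode a
    cell-level epistate determines both the promoter methylation and the
    silencing of heterogeneous genes (coherent across genes within a cell);
    in ``homogeneous`` mode each cell-gene draws independently from the same
    marginal, with methylation-silencing coupling of strength ``coupling``
    (theta) through a logistic link with slope log(theta).

    Returns ``(joint, truth)`` where truth records the per-cell epistate and
    per-gene class.
    """
    rng = np.random.default_rng(spec.seed)
    n_c, n_g = spec.n_cells, spec.n_genes
    genes = [f"gene{i}" for i in range(n_g)]
    cells = [f"cell{i}" for i in range(n_c)]

    n_het = int(round(n_g * spec.het_gene_fraction))
    gene_class = np.array(["background"] * n_g, dtype=object)
    het_idx = rng.choice(n_g, size=n_het, replace=False)
    gene_class[het_idx] = "heterogeneous"
    is_het = gene_class == "heterogeneous"

    # Methylation architecture.  Each heterogeneous gene has a binary
    # promoter configuration; in the homogeneous mode the configuration is a
    # property of the gene (every cell shares it, up to an epimutation flip),
    # whereas in admixture mode it is a property of the cell's epistate (the
    # two epistates carry opposite configurations).  Aggregate marginals
    # match between modes; what differs is whether the methylation-expression
    # coupling lives at the gene level (survives per-gene scrambling across
    # cells) or at the cell level (destroyed by it).
    if spec.heterogeneity_mode == "admixture":
        epistate = (rng.random(n_c) < spec.admixture_fraction).astype(int)
    else:
        epistate = np.full(n_c, -1)
    het_set = rng.random(n_g) < 0.5  # gene's configuration in epistate 1
    if spec.heterogeneity_mode == "admixture":
        config = epistate[:, None] == het_set[None, :].astype(int)
    else:
        config = np.broadcast_to(het_set[None, :], (n_c, n_g))
    flips = rng.random((n_c, n_g)) < spec.epimutation_rate
    het_state = config ^ flips
    q_gene = rng.beta(1.0, 5.0, size=n_g)  # background promoters: mostly low
    meth_state = np.where(
        is_het[None, :], het_state, rng.random((n_c, n_g)) < q_gene[None, :]
    )
    # observed methylation rate is bimodal given the state: methylated
    # promoters read high, unmethylated near zero (so zero methylated CpG
    # observations are common, making the zero-threshold binarization real)
    rate = np.where(
        meth_state,
        rng.beta(8, 2, size=(n_c, n_g)),
        rng.beta(0.25, 8, size=(n_c, n_g)),
    )

    # expression "on" probability: logistic in the methylation rate with
    # slope log(theta); theta = 1 gives exact independence
    log_theta = np.log(spec.coupling)
    base_logit = rng.normal(0.5, 0.5, size=n_g)  # per-gene baseline detectability
    logit_on = base_logit[None, :] - log_theta * 1.0 * (rate - 0.5)
    p_on = 1.0 / (1.0 + np.exp(-logit_on))
    on = rng.random((n_c, n_g)) < p_on

    # counts: per-gene abundance, per-cell depth factor
    gene_abund = rng.lognormal(0.0, 1.0, size=n_g)
    gene_abund /= gene_abund.sum()
    depth_factor = rng.lognormal(0.0, 0.3, size=n_c)
    lam = np.outer(depth_factor * spec.depth, gene_abund)
    counts = rng.poisson(lam) * on
    counts[counts == 0] += on[counts == 0]  # an "on" gene yields at least 1 read
    dropout = rng.random((n_c, n_g)) < spec.dropout_rate
    counts = np.where(dropout, 0, counts)

    # mito / ribo housekeeping genes: constitutive high expression
    mito_names = [f"MT-gene{i}" for i in range(spec.n_mito)]
    ribo_names = [f"RP-gene{i}" for i in range(spec.n_ribo)]
    hk = rng.poisson(
        np.outer(depth_factor * spec.depth * 0.005, np.ones(spec.n_mito + spec.n_ribo))
    )
    all_genes = genes + mito_names + ribo_names
    expr = np.concatenate([counts, hk], axis=1)

    # promoter CpG observations (sparse coverage emulating single-cell RRBS)
    total_cpg = rng.poisson(spec.cpg_per_promoter, size=(n_c, n_g))
    meth_cpg = rng.binomial(total_cpg, rate)
    zero_pad = np.zeros((n_c, spec.n_mito + spec.n_ribo), dtype=int)
    total_cpg_full = np.concatenate([total_cpg, zero_pad], axis=1)
    meth_cpg_full = np.concatenate([meth_cpg, zero_pad], axis=1)

    gene_meta = pd.DataFrame(
        {
            "gene": all_genes,
            "is_mito": [g.startswith("MT-") for g in all_genes],
            "is_ribo": [g.startswith("RP-") for g in all_genes],
            "gene_length": rng.integers(500, 5000, size=len(all_genes)),
            "tss": np.arange(len(all_genes)) * 100_000 + 50_000,
            "chrom": "chr1",
        }
    ).set_index("gene")

    expr_df = pd.DataFrame(expr, index=cells, columns=all_genes)
    total_reads = expr_df.sum(axis=1)
    mito_frac = expr_df.loc[:, gene_meta["is_mito"]].sum(axis=1) / total_reads.replace(0, 1)
    ribo_frac = expr_df.loc[:, gene_meta["is_ribo"]].sum(axis=1) / total_reads.replace(0, 1)
    cell_meta = pd.DataFrame(
        {
            "total_reads": total_reads,
            "genes_detected": (expr_df > 0).sum(axis=1),
            "mito_frac": mito_frac,
            "ribo_frac": ribo_frac,
            "group": "sim",
        }
    )

    joint = SingleCellJoint(
        expression=expr_df,
        meth_cpg=pd.DataFrame(meth_cpg_full, index=cells, columns=all_genes),
        total_cpg=pd.DataFrame(total_cpg_full, index=cells, columns=all_genes),
        cell_meta=cell_meta,
        gene_meta=gene_meta,
    )
    truth = {
        "cell_epistate": pd.Series(epistate, index=cells, name="epistate"),
        "gene_class": pd.Series(
            list(gene_class) + ["housekeeping"] * (spec.n_mito + spec.n_ribo),
            index=all_genes,
            name="gene_class",
        ),
    }
    return joint, truth


def simulate_state_signal_matrix(
    n_bins: int = 3000,
    K: int = 3,
    n_tracks: int = 3,
    separation: float = 10.0,
    rna_mode: str | None = None,
    split_state: int = 0,
    seed: int = 0,
):
    """Continuous normalized-signal matrix with ``K`` latent chromatin states
    separated by ``separation`` within-state standard deviations — the
    substrate of the Dirichlet-process mixture stage.

    ``rna_mode``: ``None`` (no RNA column), ``"uniform"`` (RNA a deterministic
    function of the state — transcriptional output uniform given chromatin),
    or ``"variable"`` (``split_state`` carries two RNA levels — the
    incomplete-silencing regime in which transcription varies within one
    epigenetic state).  Returns ``(epi_matrix, rna_column, labels)``.
    """
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, K, size=n_bins)
    # state centers on a simplex-like layout scaled to the requested separation
    centers = rng.normal(0, 1, size=(K, n_tracks))
    centers /= np.maximum(np.linalg.norm(centers, axis=1, keepdims=True), 1e-9)
    centers *= separation / np.sqrt(2)  # pairwise distance ~ separation
    epi = centers[labels] + rng.normal(0, 1, size=(n_bins, n_tracks))
    rna = None
    if rna_mode is not None:
        rna_centers = np.linspace(0, separation * (K - 1) / 2, K)
        rna = rna_centers[labels] + rng.normal(0, 1, size=n_bins)
        if rna_mode == "variable":
            half = rng.random(n_bins) < 0.5
            shift = np.where(half, -separation / 2, separation / 2)
            rna = np.where(labels == split_state, rna + shift, rna)
        elif rna_mode != "uniform":
            raise ValueError(f"unknown rna_mode {rna_mode!r}")
    return epi, rna, labels


# ---------------------------------------------------------------------------
# hidden-state multi-track signal
# ---------------------------------------------------------------------------


def simulate_state_tracks(spec: StateSimSpec):
    """Draw a hidden Markov path and emit per-track NB counts (plus an
    optional binomial methylation track).

    Returns ``(tracks, meth, labels)``: ``tracks`` is a list of
    :class:`BinnedTrack` (one per count track), ``meth`` is an (n_bins, 2)
    array of (methylated, total) read counts or ``None``, and ``labels`` the
    true per-bin state vector.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.K
    # stationary start distribution (power iteration)
    pi = np.full(K, 1.0 / K)
    for _ in range(200):
        pi = pi @ spec.A
    labels = np.empty(spec.n_bins, dtype=np.int64)
    labels[0] = rng.choice(K, p=pi / pi.sum())
    cum = spec.A.cumsum(axis=1)
    u = rng.random(spec.n_bins)
    for t in range(1, spec.n_bins):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t])

    n_tracks = spec.nb_means.shape[1]
    marks = ["H3K4me3", "H3K27ac", "H3K27me3", "RNA", "WCE"]
    tracks = []
    chrom_sizes = {"chr1": spec.n_bins * spec.bin_size}
    for j in range(n_tracks):
        mu = spec.nb_means[labels, j]
        r = spec.nb_dispersions[labels, j]
        counts = rng.negative_binomial(r, r / (r + mu))
        tracks.append(
            BinnedTrack(
                sample_id="sim",
                mark=marks[j] if j < len(marks) else f"track{j}",
                bin_size=spec.bin_size,
                counts=counts,
                library_size=int(max(counts.sum(), 1)),
                chrom_sizes=chrom_sizes,
            )
        )
    meth = None
    if spec.meth_rates is not None:
        rates = np.asarray(spec.meth_rates, dtype=float)
        cov = rng.poisson(spec.meth_coverage, size=spec.n_bins)
        m = rng.binomial(cov, rates[labels])
        meth = np.stack([m, cov], axis=1)
    return tracks, meth, labels
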