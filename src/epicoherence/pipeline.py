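"""End-to-end orchestration of the synthetic-cohort demonstration.

``run_pipeline`` generates a synthetic multi-omic cohort (with ground truth),
runs every analysis stage in dependency order, writes all outputs as
deterministic text files (TSV/BED/JSON) under the output directory, and
records a provenance manifest (parameters, seeds, package version, output
checksums).  Reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import GenomicInterval, write_bed
from .dmr import call_dmrs, dmrs_to_frame, filter_tiles, test_tiles, tile_methylation
from .dpm import rna_state_gain
from .enhancers import call_super_enhancers, exclude_promoter_peaks, region_signal, stitch_peaks
from .entropy import entropy_records, entropy_state_association, normalize_expression, stratified_entropy_compare
from .hmm import hmm_fit, posterior_decode
from .mi import (
    bulk_coordination_mi,
    downsample_cells,
    mi_uplift_report,
    promoter_meth_rate,
    sc_gene_filter,
    sc_matched_mi,
    sc_qc,
    sc_scrambled_mi,
)
from .synthetic import (
    simulate_state_signal_matrix,
    CohortSpec,
    DmrSpec,
    EnhancerLandscapeSpec,
    ScJointSpec,
    StateSimSpec,
    simulate_bulk_coupled_methylation,
    simulate_enhancer_landscape,
    simulate_methylome,
    simulate_sc_joint,
    simulate_state_tracks,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Demonstration-cohort configuration.  Thresholds default to the values
    used throughout the package: 500-bp tiles, |delta| >= 0.3, q <= 0.05,
    400-bp DMR merge, 12.5-kb stitching, 2.5-kb promoter flank, 500-gene/20%
    cell QC, TSS +/- 2.5 kb promoters, 10-CpG minimum, 5-cell detection,
    200-bp bins, 100-bp read shift."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 10_000_000})
    # enhancer landscape
    n_enhancers: int = 200
    fraction_super: float = 0.1
    stitch_gap: int = 12_500
    tss_flank: int = 2_500
    # methylome / DMR
    n_case: int = 3
    n_control: int = 3
    n_tiles: int = 3_000
    n_dmrs: int = 30
    dmr_delta: float = 0.5
    coverage_mean: float = 30.0
    tile_size: int = 500
    q_threshold: float = 0.05
    delta_threshold: float = 0.3
    merge_gap: int = 400
    # bulk MI
    coupling_case: float = 0.4
    coupling_control: float = 0.9
    mi_bins: int = 4
    # single-cell
    n_cells: int = 100
    n_genes: int = 300
    sc_theta: float = 8.0
    dropout_rate: float = 0.3
    # detected-gene QC cut scaled to the synthetic panel (the 500-gene default
    # of sc_qc applies to transcriptome-wide data)
    sc_min_genes: int = 50
    # state models
    hmm_K: int = 3
    hmm_bins: int = 4_000
    dpm_truncation: int = 15
    dpm_restarts: int = 2
    log_level: str = "INFO"


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a freshly simulated cohort; returns a result summary
    (also written to ``summary.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {name: config.seed * 1000 + i for i, name in enumerate(
        ["enhancers", "methylome", "bulk", "sc_case", "sc_control", "downsample",
         "scramble", "uplift", "hmm", "dpm", "entropy"]
    )}
    summary: dict = {}

    # --- super-enhancers ----------------------------------------------------
    land_spec = EnhancerLandscapeSpec(
        n_enhancers=config.n_enhancers,
        fraction_super=config.fraction_super,
        chrom_sizes=dict(config.chrom_sizes),
        stitch_gap=config.stitch_gap,
        seed=seeds["enhancers"],
    )
    peaks, track, enh_truth = simulate_enhancer_landscape(land_spec)
    tss = pd.DataFrame(
        {"gene": [f"g{i}" for i in range(20)], "chrom": "chr1",
         "tss": np.linspace(0, config.chrom_sizes["chr1"] - 1, 20, dtype=int)}
    )
    distal = exclude_promoter_peaks(peaks, tss, flank=config.tss_flank)
    stitched = stitch_peaks(distal, gap=config.stitch_gap)
    signal = region_signal(stitched, track)
    se = call_super_enhancers(stitched, signal)
    se_frame = se.to_frame()
    _write_tsv(se_frame, out / "super_enhancers.tsv")
    write_bed(peaks, out / "peaks.bed")
    _write_tsv(enh_truth, out / "truth_enhancers.tsv")
    truth_super = enh_truth.set_index(["chrom", "start"])["is_super"]
    called = se_frame.set_index(["chrom", "start"])["is_super"]
    common = truth_super.index.intersection(called.index)
    tp = int((truth_super.loc[common] & called.loc[common]).sum())
    summary["super_enhancers"] = {
        "n_regions": len(se_frame),
        "n_super_called": int(se_frame["is_super"].sum()),
        "n_super_true": int(enh_truth["is_super"].sum()),
        "recall": tp / max(int(enh_truth["is_super"].sum()), 1),
        "precision": tp / max(int(se_frame["is_super"].sum()), 1),
    }

    # --- DMRs ---------------------------------------------------------------
    cohort = CohortSpec(
        n_case=config.n_case, n_control=config.n_control,
        seed=seeds["methylome"], chrom_sizes=dict(config.chrom_sizes),
    )
    dmr_spec = DmrSpec(
        n_tiles=config.n_tiles, n_dmrs=config.n_dmrs, delta=config.dmr_delta,
        coverage_mean=config.coverage_mean, tile_size=config.tile_size,
    )
    meth_tables, dmr_truth = simulate_methylome(cohort, dmr_spec)
    tiles = filter_tiles(tile_methylation(meth_tables, tile_size=config.tile_size))
    tested = test_tiles(tiles, cohort.case_ids, cohort.control_ids)
    dmrs = call_dmrs(
        tested, q_threshold=config.q_threshold,
        delta_threshold=config.delta_threshold, merge_gap=config.merge_gap,
    )
    dmr_frame = dmrs_to_frame(dmrs)
    _write_tsv(dmr_frame, out / "dmrs.tsv")
    _write_tsv(dmr_truth, out / "truth_dmrs.tsv")
    recall, precision = _dmr_scores(dmr_frame, dmr_truth)
    summary["dmrs"] = {
        "n_called": len(dmr_frame), "n_true": len(dmr_truth),
        "recall": recall, "precision": precision,
    }

    # --- bulk MI ------------------------------------------------------------
    levels, groups = simulate_bulk_coupled_methylation(
        signal, n_case=config.n_case, n_control=config.n_control,
        coupling_case=config.coupling_case, coupling_control=config.coupling_control,
        seed=seeds["bulk"],
    )
    signal_df = pd.DataFrame({s: signal for s in levels.columns})
    bulk_mi = bulk_coordination_mi(levels, signal_df, n_bins=config.mi_bins)
    bulk_mi["group"] = bulk_mi["sample"].map(groups)
    _write_tsv(bulk_mi, out / "bulk_mi.tsv")
    mi_means = bulk_mi.groupby("group")["mi"].mean()
    summary["bulk_mi"] = {
        "mean_case": float(mi_means.get("case", np.nan)),
        "mean_control": float(mi_means.get("control", np.nan)),
    }

    # --- single-cell MI -----------------------------------------------------
    sc_results = {}
    per_cell_frames = []
    for group, mode, seed_key in (
        ("case", "admixture", "sc_case"), ("control", "homogeneous", "sc_control"),
    ):
        spec = ScJointSpec(
            n_cells=config.n_cells, n_genes=config.n_genes, coupling=config.sc_theta,
            heterogeneity_mode=mode, dropout_rate=config.dropout_rate, seed=seeds[seed_key],
        )
        joint, truth = simulate_sc_joint(spec)
        joint.cell_meta["group"] = group
        qc = sc_qc(joint, min_genes=config.sc_min_genes)
        expr = downsample_cells(qc.expression, seed=seeds["downsample"])
        rate = promoter_meth_rate(qc)
        genes = sc_gene_filter(expr, rate)
        matched = sc_matched_mi(expr, rate, genes)
        scrambled = sc_scrambled_mi(expr, rate, seed=seeds["scramble"], genes=genes)
        per_cell_frames.append(pd.DataFrame({
            "cell": matched.index, "group": group,
            "mi_matched": matched.to_numpy(), "mi_scrambled": scrambled.to_numpy(),
        }))
        sc_results[group] = (matched, scrambled)
    per_cell = pd.concat(per_cell_frames, ignore_index=True)
    matched_all = per_cell.set_index("cell")["mi_matched"]
    scrambled_all = per_cell.set_index("cell")["mi_scrambled"]
    group_all = per_cell.set_index("cell")["group"]
    report = mi_uplift_report(matched_all, scrambled_all, group_all, seed=seeds["uplift"])
    _write_tsv(report.per_cell, out / "sc_mi_per_cell.tsv")
    _write_tsv(report.per_group, out / "sc_mi_uplift.tsv")
    up = report.per_group.set_index("group")["uplift_percent"]
    summary["sc_mi"] = {
        "uplift_case": float(up.get("case", np.nan)),
        "uplift_control": float(up.get("control", np.nan)),
        "between_group_p": report.between_group_p,
    }

    # --- entropy ------------------------------------------------------------
    # entropy demonstration: a deeper, lower-dropout admixture library in which
    # heterogeneous genes show bimodal on/off detection across cells
    spec = ScJointSpec(
        n_cells=2 * config.n_cells, n_genes=config.n_genes, coupling=config.sc_theta,
        heterogeneity_mode="admixture", dropout_rate=0.1, seed=seeds["entropy"],
    )
    joint, truth = simulate_sc_joint(spec)
    qc = sc_qc(joint, min_genes=config.sc_min_genes)
    normalized = normalize_expression(qc.expression, qc.gene_meta["gene_length"])
    records = entropy_records(normalized)
    _write_tsv(records, out / "entropy_records.tsv", index=True)
    marked = truth["gene_class"][truth["gene_class"] == "heterogeneous"].index
    indicator = pd.Series(
        records.index.isin(set(marked)).astype(float), index=records.index
    )
    finite = records.replace([np.inf, -np.inf], np.nan).dropna()
    assoc = entropy_state_association(finite, indicator)
    summary["entropy"] = {
        "state_coefficient": assoc.coefficient, "se": assoc.se, "p": assoc.p,
    }
    _write_json(summary["entropy"], out / "entropy_association.json")

    # --- HMM segmentation ---------------------------------------------------
    state_spec = StateSimSpec(
        K=config.hmm_K, n_bins=config.hmm_bins,
        meth_rates=np.linspace(0.1, 0.9, config.hmm_K), seed=seeds["hmm"],
    )
    tracks, meth, labels = simulate_state_tracks(state_spec)
    model = hmm_fit(tracks, K=config.hmm_K, meth=meth, seed=seeds["hmm"])
    seg = posterior_decode(model, tracks, meth)
    accuracy = _best_label_accuracy(labels, seg.labels, config.hmm_K)
    seg_df = pd.DataFrame({"bin": np.arange(len(seg.labels)), "state": seg.labels,
                           "true_state": labels})
    _write_tsv(seg_df, out / "hmm_segmentation.tsv")
    _write_json(
        {
            "K": model.K,
            "loglik": model.loglik_trace[-1],
            "converged": model.converged,
            "nb_means": np.round(model.nb_mu, 6).tolist(),
            "decoding_accuracy": accuracy,
        },
        out / "hmm_model.json",
    )
    summary["hmm"] = {"decoding_accuracy": accuracy, "converged": model.converged}

    # --- DPM state gain -----------------------------------------------------
    # continuous normalized-signal substrate: a case-like regime in which
    # transcription varies within one epigenetic state, against a control-like
    # regime where RNA is a deterministic function of the state
    epi_var, rna_var, _ = simulate_state_signal_matrix(
        n_bins=config.hmm_bins, K=config.hmm_K, rna_mode="variable", seed=seeds["dpm"]
    )
    epi_uni, rna_uni, _ = simulate_state_signal_matrix(
        n_bins=config.hmm_bins, K=config.hmm_K, rna_mode="uniform", seed=seeds["dpm"]
    )
    gain_var = rna_state_gain(
        list(epi_var.T), rna_var, normalization="raw",
        truncation=config.dpm_truncation, seed=seeds["dpm"], n_restarts=config.dpm_restarts,
    )
    gain_uniform = rna_state_gain(
        list(epi_uni.T), rna_uni, normalization="raw",
        truncation=config.dpm_truncation, seed=seeds["dpm"], n_restarts=config.dpm_restarts,
    )
    summary["dpm"] = {"gain_variable_rna": gain_var, "gain_uniform_rna": gain_uniform}
    _write_json(summary["dpm"], out / "dpm_gain.json")

    _write_json(summary, out / "summary.json")
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "stage_seeds": seeds,
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    _write_json(manifest, out / "manifest.json")
    return summary


def _dmr_scores(called: pd.DataFrame, truth: pd.DataFrame) -> tuple[float, float]:
    """Recall/precision of called DMRs against implanted truth intervals
    (a call matches a truth region when they overlap and agree in direction)."""
    if truth.empty:
        return float("nan"), float("nan")
    if called.empty:
        return 0.0, float("nan")
    hit_truth = np.zeros(len(truth), dtype=bool)
    hit_called = np.zeros(len(called), dtype=bool)
    for i, t in truth.iterrows():
        for j, c in called.iterrows():
            if (
                t["chrom"] == c["chrom"]
                and t["start"] < c["end"]
                and c["start"] < t["end"]
                and t["direction"] == c["direction"]
            ):
                hit_truth[i] = True
                hit_called[j] = True
    return float(hit_truth.mean()), float(hit_called.mean())


def _best_label_accuracy(true_labels: np.ndarray, decoded: np.ndarray, K: int) -> float:
    """Decoding accuracy maximized over state relabelings (Hungarian matching)."""
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((K, K))
    np.add.at(conf, (true_labels, decoded), 1)
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / len(true_labels))
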