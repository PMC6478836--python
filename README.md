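# epicoherence

Quantitative machinery for studying **epigenetic–transcriptional
coordination** in two-group cohorts (e.g. a leukemia versus normal
B-lymphocyte design): how tightly DNA methylation, histone-mark signal and
gene expression track each other at the bulk level, and how much of any loss
of coordination is explained by cell-to-cell epigenetic heterogeneity.

The package implements, as a tested reusable pipeline:

- **Super-enhancer calling** (ROSE-style): H3K27ac peaks away from promoters
  (TSS ± 2.5 kb) are stitched when closer than 12.5 kb, ranked by total
  CPM-normalized signal, and split at the slope-1 tangent of the
  [0, 1]-scaled rank/signal curve — regions right of the tangent point are
  super-enhancers.
- **Tile-based DMR calling**: CpG coverage tables are aggregated into 500-bp
  tiles (coverage-weighted means), tiles covered with >10 reads in ≥70% of
  samples are tested by Fisher's exact test on read counts pooled within
  each group, Benjamini–Hochberg corrected; tiles with *q* ≤ 0.05 and
  |Δmethylation| ≥ 0.3 merge into DMRs when <400 bp apart with a shared
  direction.
- **Mutual-information coordination**. For discretized variables,
  MI(X;Y) = Σ p(x,y) log₂ [p(x,y)/(p(x)p(y))].
  Bulk mode: per-sample MI between region methylation and H3K27ac signal
  after equal-frequency binning. Single-cell mode: per-cell MI between
  zero-thresholded promoter methylation (TSS ± 2.5 kb, ≥10 CpG
  observations) and detection of expression, compared against a *scrambled*
  baseline in which each gene's methylation values are permuted across
  cells (as many rounds as cells; per-cell median). The headline statistic
  is the percentage MI **uplift** of matched over scrambled data — a
  measure of cell-level coordination beyond gene-level structure.
- **Single-cell expression entropy**: per gene,
  ent = −[fpc·log₂(fpc) + (1−fpc)·log₂(1−fpc)], where fpc is the fraction
  of cells with >0 reads; association with chromatin-state membership is
  tested with a backfitted additive model
  ent ~ s(log₁₀ mean expression) + state (lowess smooth + linear term).
- **NB-emission multivariate HMM** over 200-bp genome bins: count tracks are
  negative binomial and the methylation track binomial given the hidden
  state, fitted by Baum–Welch with exact M-steps (monotone log-likelihood),
  decoded by maximum posterior; state enrichment, cross-condition state
  overlap, dual-mark (bivalent-like) state detection and distance-stratified
  expression fold-change are built on the segmentation.
- **Dirichlet-process Gaussian mixture** state counting on the normalized
  signal matrix (truncated stick-breaking variational inference, diagonal
  covariances), with the "states gained when adding RNA" statistic,
  fit-on-a-tenth cross-validation and leave-one-out track contributions.
- A **synthetic multi-omic cohort generator** that produces every input the
  pipeline consumes together with ground truth: hockey-stick enhancer
  landscapes, methylomes with implanted DMRs, joint single-cell
  methylation/expression matrices with tunable coupling θ and a two-epistate
  admixture mode, and hidden-state multi-track signals.

## Worked example

Run the full synthetic demonstration (a 10-Mb genome, 3 case vs 3 control
bulk samples, 100 cells per group):

```bash
epicoherence run-all --seed 1 --out demo_out
```

This writes TSV/BED/JSON outputs plus a provenance manifest to `demo_out/`
and prints a summary. With seed 1 the summary contains:

```json
"super_enhancers": {"n_regions": 199, "n_super_called": 20, "n_super_true": 20,
                    "recall": 1.0, "precision": 1.0},
"dmrs":            {"n_called": 30, "n_true": 30, "recall": 1.0, "precision": 1.0},
"bulk_mi":         {"mean_case": 0.287, "mean_control": 1.337},
"sc_mi":           {"uplift_case": 1097.2, "uplift_control": 467.7,
                    "between_group_p": 2.3e-07},
"entropy":         {"state_coefficient": 0.081, "p": 6.3e-14},
"hmm":             {"decoding_accuracy": 1.0, "converged": true},
"dpm":             {"gain_variable_rna": {"gain": 1}, "gain_uniform_rna": {"gain": 0}}
```

Reading the numbers: all 20 implanted super-enhancers and all 30 implanted
DMRs are recovered exactly; bulk MI is lower in the case group (0.29 vs
1.34 bits), whose methylation–signal coupling the generator degrades; the
case group's single-cell MI uplift is far larger than the control's
(1097% vs 468%, rank-test p ≈ 2×10⁻⁷) because its cells are an admixture of
two epigenetic identities — per-gene scrambling destroys cell-level
coordination that survives in the homogeneous control; heterogeneous genes
carry +0.08 bits of detection entropy at matched expression; the chromatin
HMM decodes the true 3-state path perfectly; and the DP mixture gains one
state from RNA exactly when transcription varies within an epigenetic state.

Individual stages are available as subcommands (`se-call`, `dmr-call`,
`mi-bulk`, `mi-sc`, `entropy`, `hmm-seg`, `dpm-states`, `simulate`) over the
text formats documented in each module, or directly as library functions
(`epicoherence.enhancers`, `.dmr`, `.mi`, `.entropy`, `.hmm`, `.dpm`,
`.synthetic`).

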