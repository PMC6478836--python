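# Methods

This note documents the models, the numerical choices, what the synthetic
generators emulate, and the known limitations. Coordinates are 0-based
half-open (BED convention) everywhere; `chrom.sizes` entries are lengths and
are converted at the parser boundary.

## Super-enhancer calling

Peaks overlapping any promoter window (TSS ± 2.5 kb, overlap of ≥1 bp) are
removed; remaining peaks are stitched when the inter-peak gap is strictly
below 12.5 kb ("within 12.5 kb" is resolved as a strict `<` on the gap; both
the gap and the flank are parameters). Stitched regions are ranked by total
CPM-normalized signal. With rank and signal both scaled to [0, 1], the
super-enhancer cut-point is the tangent of slope 1 on the ranked curve,
located as **argmax(x − y)** — for a convex curve this is exactly where the
discrete slope crosses 1, and unlike a local finite-difference scan it is
insensitive to flat runs among the top-ranked regions (where two similar
super-enhancers would otherwise truncate a top-down slope scan). Ties,
including flat and exactly linear curves, resolve to the highest rank, so a
signal-free landscape calls zero super-enhancers. The call is invariant to
uniform rescaling of the signal. Fewer than three regions is an error (the
curve geometry is undefined).

Note that on a landscape with *no* implanted super-enhancers the tangent
still flags the upper tail of the signal distribution — of order 10% of
regions at n = 500 for a log-normal body, since the slope-1 crossing of a
normal-tailed ranked curve sits near the top decile. That is a property of
the ROSE geometry, not of this implementation.

Differential classification of regions reports the log2 fold-change of
group-mean CPM signal with a pseudocount, flagged at |log2FC| strictly above
the threshold (default 2) and optionally gated on a user-supplied q-value;
the negative-binomial Wald test itself is out of scope here.

Methylation summaries at regions use CpGs covered by ≥5 reads,
coverage-weighted region means, and the level categories [0, 0.2],
(0.2, 0.8], (0.8, 1] — a CpG exactly at a boundary falls in the lower
category (the bounds are parameters).

## DMR calling

CpGs are assigned to genome-anchored tiles (default 500 bp, anchored at
multiples of the tile size; a capture-target BED can restrict the tiling).
Per sample, the tile level is the coverage-weighted mean CpG level. Tiles
are retained when covered with **strictly more than** 10 reads in ≥70% of
samples. Read counts are then pooled within each group (summed, not
averaged) and each tile's 2×2 table (methylated/unmethylated ×
case/control) is tested with a two-sided Fisher's exact test under the
probability-mass criterion (total probability of tables at least as extreme
as observed). Benjamini–Hochberg correction runs over all tested (covered)
tiles. Tiles with q ≤ 0.05 and |Δ| ≥ 0.3 merge into DMRs when the gap is
strictly below 400 bp **and** the direction matches — merging hyper- with
hypomethylated tiles is forbidden, since a mixed-sign "region" is
uninterpretable. The DMR's Δ is the coverage-weighted mean of member deltas;
its p/q are the member minima.

Limitation: pooling reads ignores between-sample overdispersion, so with
biological replicate noise the Fisher p-values are slightly anticonservative
— on null simulations with 3% between-sample noise the q ≤ 0.05 tile
fraction sits near (just under) the nominal 5% rather than well below it.
A beta-binomial model would repair this but is out of scope.

## Mutual information

The plug-in estimator MI = Σ p(x,y) log₂[p(x,y)/(p(x)p(y))] with
0·log 0 := 0 is used throughout. Bulk coordination: per sample, paired
region vectors (coverage-weighted methylation, CPM signal) are discretized
into equal-frequency bins (default 4; values tied at a bin edge go to the
lower bin) and MI computed per sample, enabling a group comparison.
Equal-frequency binning is used because it is invariant to monotone scale
changes; the bin count is a parameter.

Single-cell pipeline, in order: (1) QC — cells with fewer than 500 detected
genes or mitochondrial+ribosomal read fraction above 20% removed, then
constitutive mito/ribo genes removed, then the bottom decile of cells by
total reads removed per sample (ties broken by cell id); the 500-gene cut
assumes transcriptome-scale data and is scaled down (to 50) for the
synthetic few-hundred-gene panels. (2) Downsampling — every cell above the
10th-percentile total count is binomially thinned to that cutoff.
(3) Promoter methylation rate — methylated/total CpG observations in
TSS ± 2.5 kb, requiring ≥10 observations per cell-gene. (4) Gene filter —
detected in ≥5 cells, valid methylation calls in ≥10 cells, >10% of cells
with non-zero expression. (5) Per-cell MI across genes, both variables
binarized at zero; cells with fewer than 20 usable genes are excluded
(plug-in MI on smaller samples is bias-dominated; the floor is a parameter).
(6) Scrambled baseline — per gene, the methylation values (with their
missingness pattern) are permuted across cells while expression stays fixed;
rounds equal the number of cells; the per-cell scrambled value is the median
over rounds. (7) Uplift — per group, 100·(mean matched − mean
scrambled)/mean scrambled, with a bootstrap CI over cells (1000 replicates)
and a two-sided rank test between groups on per-cell uplifts.

Interpretation: per-gene scrambling preserves *gene-level* structure (a gene
that is usually methylated and usually silent keeps that association) and
destroys only *cell-level* coordination. The uplift therefore measures
coordination attributable to cells, which is why an admixture of epigenetic
identities produces a much larger uplift than a population with the same
marginal frequencies but gene-anchored methylation.

Statistical caveat: under full independence the per-cell MI is
χ²₁-distributed around its bias, so single-run uplift medians at 100 cells
fluctuate by tens of percent; null calibration checks pool cells across
~40 replicate simulations.

## Expression entropy

Counts are TPM-normalized (count/length, rescaled to 10⁶ per cell). The
entropy uses detection only — ent(fpc) as the binary entropy of the fraction
of positive cells — exactly as defined, with no magnitude weighting. The
chromatin-state association is a backfitted additive model: a lowess smooth
(span 0.5) in log₁₀ population mean expression alternated with a centred
linear state term for two backfitting iterations; the state coefficient's
standard error comes from the residual variance of the combined fit. The
model errors out when the state indicator perfectly separates the expression
range (the smooth and the state term are then not identifiable). The
expression-window comparison draws a nearest-expression-matched control set
without replacement and applies a Mann–Whitney test; the "intermediate
entropy" band for cumulative summaries defaults to (0.25, 0.75) bits — the
notion is otherwise undefined, so it is an explicit parameter.

## Chromatin-state HMM

Genome bins (default 200 bp; ChIP reads are shifted 100 bp 5'→3' along
their strand before binning) carry count tracks modelled as negative
binomial NB(μ_ks, r_ks) and an optional methylation track modelled as
Binomial(coverage, β_k), conditionally independent given the state. The
methylation emission is binomial rather than a transformed count because it
respects per-bin coverage. Fitting is Baum–Welch: scaled forward–backward;
transition and initial updates from the same posterior; the NB M-step
profiles μ as the weighted mean and maximizes r by bounded 1-D likelihood
optimization on log r ∈ [log 10⁻³, log 10⁴] over the compressed unique-count
histogram, never accepting an r worse than the previous iterate — this keeps
EM monotone, which a method-of-moments update would not guarantee.
Initialization is k-means (5 restarts) on the standardized log1p count
matrix. Decoding is per-bin argmax posterior with ties to the lower state
index. `model_scan` fits one model per state count under a shared seed and
reports BIC as a guide; selection is left to the user.

On genuinely one-state data a K=2 fit converges to two near-identical
states sharing the bins unevenly (the likelihood is flat); the fit is
reported as-is rather than pruned.

State enrichment divides the fraction of a state's nucleotides inside a
feature by the feature's genome fraction. Cross-condition overlap is the
row-normalized confusion matrix of two segmentations on identical bins.
Dual-mark (bivalent-like) states are those whose emission means exceed the
across-state median for both marks of a pair. Distance-stratified
fold-change bins genes by TSS distance to the nearest region edge (default
edges 0, 10 kb, 50 kb, 250 kb, ∞) and attaches a Spearman trend test.

## Dirichlet-process mixture

The bins×tracks matrix (log1p CPM for counts, raw rate for methylation,
per-column z-score; continuous signal can enter raw) is modelled with
scikit-learn's `BayesianGaussianMixture` (stick-breaking truncation 30,
α = 1, diagonal covariances, 3 restarts keeping the best evidence lower
bound). The ELBO trace is recorded every few warm-started iterations so
monotonicity is verifiable; convergence uses a tight tolerance (10⁻⁵)
because the effective-state count depends on redundant components having
fully drained. Effective states are components holding ≥0.2% of
hard-assigned bins — an assignment-share rule, which unlike weight
thresholds is insensitive to the truncation level. The RNA gain statistic
fits with and without the RNA column under identical seed and
hyperparameters, isolating the RNA column's effect from initialization
noise. Cross-validation fits on a random bin fraction (default 1/10, 100
repetitions) and applies each model to the full matrix; leave-one-out
refits without each track in turn.

The DP-GMM is a Gaussian model: raw low NB counts (discrete spikes after
log1p) over-segment, so state counting operates on continuous normalized
signal; the synthetic substrate for this stage generates Gaussian
state-conditional signal directly. With diagonal covariances, two bitwise-
identical tracks induce within-cluster correlation 1 and force multi-
component tiling; redundancy tests therefore use tracks that share cluster
structure with independent noise.

## Synthetic cohort generators

All generators are pure functions of (spec, seed) via a single
`numpy.random.default_rng` instance — bit-identical outputs per seed.

**Enhancer landscape** — enhancer units placed sequentially with
inter-unit spacing above the stitch gap (so stitching recovers exactly the
units) and, for super-enhancers, 3–6 constituent peaks spaced below it.
Total signal: log-normal body (σ = 0.3) with super-enhancers boosted ×25 —
roughly 1.5 orders of magnitude above the median typical enhancer, as in
observed H3K27ac landscapes, yielding a clear hockey stick. Binned counts
are Poisson around each peak's signal plus a weak uniform background.

**Methylome** — tile-level background levels Beta(0.7, 0.7) shared across
samples with per-sample Gaussian noise (σ = 0.03); DMRs implanted on
2-tile blocks with the full |Δ| anchored inside [0, 1]; ~5 CpGs per tile,
Poisson coverage, binomial methylated counts. Optional
intermediate-methylation tiles pull the case level toward 0.5.

**Single-cell joint** — promoter methylation is a binary configuration per
cell-gene observed through bimodal Beta rates (methylated Beta(8, 2),
unmethylated Beta(0.25, 8)), so unmethylated promoters frequently yield
zero methylated CpG observations and the zero-threshold binarization is
meaningful. In the **homogeneous** mode the configuration is a property of
the gene (all cells share it up to an epimutation flip, rate 0.1); in the
**admixture** mode it is a property of the cell's epistate, with the two
epistates carrying opposite configurations over the heterogeneous genes
(30% of genes) — aggregate marginals match between modes. Expression is
"on" with probability logistic in the methylation rate with slope log θ
(θ = 1 gives exact independence; the slope multiplier 1.0 was fixed at
design time so coupling does not saturate over θ ∈ {1, 2, 4, 8}); on-genes
get Poisson counts from a log-normal abundance profile, then dropout.
Constitutive mito/ribo genes are added for the QC path. Coverage:
~15 CpG observations per promoter per cell (Poisson).

**State tracks** — a sticky Markov chain (diagonal 0.95 by default) emits
NB counts per track (well-separated default means 2/20/80 rotated across
tracks) and a binomial methylation track. A separate generator produces the
continuous Gaussian state-signal matrix for the DPM stage, with an RNA
column that is either a deterministic function of the state ("uniform") or
splits one state into two levels ("variable" — the incomplete-silencing
regime).

**Bulk coupled methylation** — region methylation anticorrelated with the
activity signal through a rank-based target mixed with independent Beta
noise; the case group's mixing weight (0.4 vs 0.9) degrades the coupling,
emulating the loss of bulk coordination.

What the generators do **not** emulate: read-level sequences, bisulfite
conversion errors, doublets, copy-number effects, batch structure, or
genome-wide scale (tests run on ~1–10 Mb genomes and gene panels of a few
hundred genes; parameter defaults document the scaled problem sizes).
Passing tests demonstrate correctness of the machinery and the direction of
the headline contrasts under these idealized conditions, not effect sizes on
real cohorts.

## Pipeline and determinism

`run_pipeline` derives one sub-seed per stage from the master seed, runs the
stages in dependency order, writes TSV/BED/JSON with fixed float formatting
and LF endings, and records a manifest (package version, config, stage
seeds, SHA-256 of every output). Reruns with the same configuration are
byte-identical. The full demonstration (10-Mb genome, 3+3 samples, 100
cells per group) completes in well under a minute on one CPU.
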