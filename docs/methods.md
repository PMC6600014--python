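# Methods

## Study design and model

The pipeline analyses a 2 diet (AL/DR) × 2 fraction (total/translated) ×
4 replicate count design. Gene counts are modelled as negative binomial,
NB(μ, φ), with log link and a treatment-coded design matrix
(intercept, diet, fraction, diet×fraction); `log(effective library
size)` enters as an offset, where effective size is the raw library size
times its TMM factor. The interaction coefficient is the DPAR. Named
contrasts: `transcription` = diet coefficient (DR_TO vs AL_TO on the
total fraction under the interaction parameterisation), `translation_AL`
= fraction coefficient, `translation_DR` = fraction + interaction,
`dpar` = interaction. The DPAR estimate therefore satisfies the exact
algebraic identity `dpar = translation_DR − translation_AL`.

**Fitting.** All genes are fit simultaneously by stacked IRLS (working
weights μ/(1+φμ), convergence at relative deviance change < 1e-8 or 50
iterations, linear systems ridge-stabilised at 1e-10). Genes that fail
to converge are flagged and excluded from classification rather than
silently dropped. Contrasts are tested by refitting each gene under the
single-df constraint (reduced design = full design projected onto the
contrast's null space) and referring the deviance difference to χ²(1).
p-values are BH-corrected within each contrast family separately; the
alternative of a joint correction across families was rejected because
the families answer different questions and are reported separately.

**Dispersion.** The Cox–Reid adjusted profile likelihood
APL(φ) = ℓ(β̂(φ), φ) − ½·log det(XᵀWX) is evaluated on a 25-point
log-spaced grid (1e-4 to 3) with quadratic interpolation of the argmax.
The common dispersion maximises the mean APL across genes; tagwise
values maximise `APL_g + prior_n · mean-APL` with
`prior_n = prior_df / residual df` and a default prior of 10 degrees of
freedom. The shared curve uses the global mean APL rather than an
abundance-local smooth; at the depth range the pipeline targets this
makes little difference and keeps the estimator transparent. Common-φ
recovery is verified at φ = 0 (Poisson) and φ = 0.1.

**Thresholds.** Mean CPM ≥ 8 across all 16 samples for quantifiability
("across all conditions" read as the grand mean, computed on
TMM-effective library sizes since filtering follows normalisation);
|log2FC| ≥ 1 with FDR < 0.05 for every regulated-gene set. TMM uses the
conventional 30% M-trim and 5% A-trim per tail with precision weights,
reference sample chosen by the upper-quartile rule; factors are verified
against edgeR's implementation on a frozen fixture.

## Profile clustering

DR-only translationally regulated genes are represented by their four
group-mean log2 CPM values, mean-centred per gene (rows sum to zero, so
the profile space has rank ≤ 3). PAM uses Euclidean dissimilarity —
the metric the reference R implementation defaults to — with
deterministic BUILD seeding and best-improvement SWAP; instances with at
most 5,000 candidate medoid sets are solved exactly by enumeration
because the swap neighbourhood admits local optima even at tiny n. The
number of clusters is the largest k in 2..k_max for which **every**
cluster's mean silhouette width is ≥ 0.25 ("substantial structure");
per-cluster mean (not per-point minimum) is used, matching the
cluster-structure reading of that rule of thumb. If no k qualifies the
data are reported as one cluster.

## Editing-site detection

A site is called per replicate when, on the gene strand, the reference
is A, at least 5 reads support G, and the frequency G/(A+G) is ≥ 10%.
Both thresholds are inclusive (the sources alternate between "minimum of
10%" and "greater than 10%"; inclusive was chosen and is configurable).
The frequency denominator is reference + edited reads rather than total
coverage: other-base reads at a true editing site are sequencing noise,
and per-substitution frequency is the convention of pileup-based editing
callers. Minus-strand genes are evaluated as T→C on the reference
strand. Read-level hygiene (unique mapping, proper pairs, 3′-end
trimming) is a contract on pileup construction, not re-checked here.
Group consensus needs the call in ≥ 3 of 4 replicates, generalised as
ceil(3/4·n) for other replicate numbers; consensus is formed per group
and overlaps are computed afterwards. Editing-vs-translation coupling is
the Spearman correlation between per-gene DR editing change
(freq(DR_TR) − freq(DR_TO)) and DPAR log2FC, separately for CDS- and
3′UTR-edited genes.

## Intron retention

Global retention is intronic / total aligned reads per sample, in
percent; the diet×fraction interaction of the global percentages is the
interaction term of the balanced two-way linear model (equivalent to the
two-way ANOVA test at 2×2). Per-gene retention is
log2((intronic+0.5)/(exonic+0.5)); the 0.5 pseudocount log-ratio was an
open choice (the upstream description never defines the per-gene
response) and is configurable. Genes need ≥ 4 intronic reads summed
over samples. OLS on diet + fraction + diet×fraction with a t test on
the interaction (12 residual df) and BH across genes; rank-sum
diet-within-fraction comparisons are emitted alongside. A read
overlapping ≥ 1 intronic base counts as intronic — junction-spanning
reads are retention evidence. PTC scanning translates the
intron-retained CDS from the annotated start and reports the first
premature stop, frame preservation (intron length mod 3) and, for
stop-free in-frame introns, the inserted residue count.

Note that the four group-level intron fractions themselves imply a
shared (gene-independent) diet×fraction interaction on the retention
ratio; the generator records it in the truth table
(`baseline_log2`) and per-gene planted effects ride on top. Calibration
experiments therefore use a balanced-fraction configuration whose shared
interaction is exactly zero.

## Regulatory features

Set enrichment uses Fisher's exact test of target vs background
membership; miRNA targets are pre-filtered to P_ct > 0.8. PWM scanning
scores log2((p+ε)/(0.25+ε)) per position against the uniform background
(ε = 0.01 applied to numerator and denominator so a flat matrix scores
exactly zero); motif-level group testing computes per-sequence
affinities (mean of 2^score over start positions, length-normalised),
fits a log-normal to the background affinities, and evaluates the
target-group mean against a moment-matched log-normal for a mean of n
background draws — an approximation in the spirit of log-normal
background correction, validated only on synthetic truth. 3′ UTRs
shorter than 12 nt are excluded everywhere. The folding-energy score is
a Nussinov-style nested-structure DP with pair energies GC = −3,
AU = −2, GU = −1 (arbitrary units) and hairpin loops of ≥ 3 unpaired
bases; it is *not* a thermodynamic model — it preserves relative
structure comparisons between sequence sets, and externally computed
minimum free energies can be supplied per gene instead. Motif scanning
is sense-strand only (3′ UTRs are single-stranded).

## qPCR scoring

Cp is log2-scale (one cycle per doubling). Values above the detection
cutoff (35) are censored; assays need ≥ 2 usable replicates per
condition. geNorm M is the mean over partner assays of the SD across
samples of the pairwise Cp difference (pairwise-complete). GPR scores
each assay by the fraction of partner-normalised ΔCp comparisons whose
two-sample t test gives p < 0.05; the aggregate p is defined here as the
median partner p (the "modified" aggregation of the original method is
undocumented, so this definition is ours). Fold changes use a universal
normalizer: the per-sample mean Cp of the 10 lowest-M assays, always
excluding the assay being measured — with an 11-assay panel this
necessarily leaks a changed assay into every stable assay's normalizer
(bias 2^(±1/10)), which the tests document explicitly. All three
statistics are exactly invariant to per-sample plate shifts.

## Synthetic data

The generator emulates: NB counts (per-gene means log-normal around a
baseline, spread σ = 0.5; per-sample depths log-normal σ = 0.2 so CPM
never equals raw counts) with planted transcriptional, DPAR and opposing
effects of |log2FC| = 2; gene models laid head-to-tail with 2–4 exons,
operons covering 18% of genes (downstream members SL2), SL1 at 73%,
3′ UTRs ≥ 12 nt with ~0.27 GC; pileups with Poisson coverage, binomial
edited-read counts and 0.1% misread rate (low enough that the 10%
frequency filter is never noise-triggered); intron/exon count pairs
reproducing global intron fractions of 1.5/1.0/2.2/1.2% (AL_TO/AL_TR/
DR_TO/DR_TR); Cp panels with per-assay baselines and planted fold
changes; and mean-centred profile archetypes (transcription-down offset
by translation-up; translation-down deepening under DR; DR-only
translation-up) with Student-t (df = 3) residuals — log-expression
profile scatter is heavy-tailed in real data — and uneven cluster sizes
in the proportion 530:492:643. What it does **not** emulate: mapping
artefacts, positional coverage bias, gene-length effects, correlated
gene-gene expression, SNP contamination of pileups, or amplification
efficiency differences in qPCR — so passing tests demonstrate correct
recovery of the modelled signal classes, not robustness to those
artefacts.

## Recovery experiments (problem sizes)

The self-validation experiments in `dparkit.experiments` use: DPAR
recovery at 10,000 genes (μ = 200, φ = 0.1, 500 promoted at +2, 500
transcriptionally down at −2); null calibration at 10,000 genes;
cluster-number selection over 100 simulations of ~600 profiles; editing
recovery with 150 planted (frequency ≥ 0.15, coverage ~150) plus 150
never-edited sites; intron-retention recovery at 500 genes with deep
coverage (μ = 3000) and low dispersion (φ = 0.01) — per-gene retention
power is depth-limited because intronic reads are ~2% of a gene's
total, so the recovery experiment is deliberately run in its low-noise
regime — with calibration on 2,000 balanced-null genes; and 500
11-assay qPCR panels at σ = 0.2 cycles. Classification accuracy is the
diagonal mass of the truth-vs-predicted class confusion matrix over all
genes.

## Known limitations

- The NB engine targets the full-rank 2×2 interaction design; arbitrary
  design matrices fit through the same IRLS core but the named contrasts
  assume the four-coefficient parameterisation.
- Tagwise dispersion shrinks toward the global mean APL curve, not an
  abundance-local one; very wide expression ranges may shrink low-count
  genes slightly too hard.
- The motif-group null is a moment-matched approximation; its p-values
  are calibrated to Monte-Carlo tolerance on synthetic backgrounds, not
  exact.
- `count_intron_exon` assumes non-overlapping gene models when resolving
  reads to genes; overlapping-gene annotations need pre-resolution.
- The folding proxy's absolute values are not kcal/mol; only set-level
  comparisons are meaningful.
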