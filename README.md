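# dparkit

Analysis toolkit for separating **transcriptional** from **translational**
gene regulation with paired total / polysome-profiling RNA-seq, built
around the study design of dietary restriction (DR) versus ad libitum (AL)
feeding in *C. elegans*: total (TO) and polysome-associated (TR) mRNA
sequenced for both diets in biological quadruplicate.

## The statistic at the core

For each gene the **differential polysome association ratio (DPAR)** is

```
DPAR = (TR/TO under DR) / (TR/TO under AL)
```

which in the log-linear negative-binomial GLM over the 2×2×4 design

```
log μ = β₀ + β₁·[DR] + β₂·[TR] + β₃·[DR][TR] + log(effective library size)
```

is the interaction contrast `(DR_TR − DR_TO) − (AL_TR − AL_TO)`, i.e. β₃.
A positive DPAR means the gene is *translationally promoted* under DR
independent of its transcript level; because both fractions share the
library-size offset, the DPAR responds only to relative redistribution
between pools. Counts are TMM-normalised, genes are kept at mean CPM ≥ 8,
dispersions are estimated by Cox–Reid adjusted profile likelihood (common
plus empirical-Bayes tagwise), and single-df contrasts are tested by
likelihood-ratio tests with Benjamini–Hochberg correction per contrast
family. Significance thresholds throughout are |log2FC| ≥ 1 and FDR < 0.05.

Around the DPAR engine the package implements the full downstream
analysis: expression-profile clustering (PAM with silhouette-gated choice
of k), A-to-I editing-site detection from base-count pileups (≥ 5
supporting reads, frequency ≥ 10%, 3-of-4 replicate consensus),
intron-retention modelling (per-gene diet×fraction interaction on
log2(intronic/exonic) with PTC scanning of retained-intron isoforms),
regulatory-feature enrichment (operons, spliced leaders, TargetScan-style
miRNA targets at P_ct > 0.8, PWM motifs over 3′ UTRs, UTR
length/GC/folding energy), and qPCR panel scoring (modified Global
Pattern Recognition with geNorm-based universal normalizers). A
synthetic-data module generates every input with planted ground truth so
each stage is testable without downloads.

## Worked example

Generate a synthetic study and run the DPAR analysis:

```sh
python analysis/01_simulate_data.py
python analysis/02_differential_translation.py
python analysis/03_cluster_profiles.py
```

which prints (3,000 genes, 150 planted DPAR-promoted, 90 repressed, 120
with opposing transcriptional/translational regulation):

```
3000 of 3000 genes quantifiable (mean CPM >= 8)
common dispersion 0.1019 (tagwise median 0.0986)
contrast transcription: 363 genes at |log2FC|>=1, FDR<0.05
contrast dpar: 345 genes at |log2FC|>=1, FDR<0.05
DPAR classes: {'unchanged': 2655, 'promoted': 249, 'repressed': 96}
...
selected k = 3; cluster mean silhouettes: {0: 0.718, 1: 0.792, 2: 0.731}
first two PCs hold 97.9% of profile variance
```

The common dispersion recovers the simulated value (0.1); the DPAR sets
recover the planted promoted/repressed/opposing genes; and the DR-only
translationally regulated genes cluster into the three planted profile
archetypes. The remaining drivers (`04`–`07`) run the editing,
intron-retention, feature-enrichment and qPCR stages on the same dataset.

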