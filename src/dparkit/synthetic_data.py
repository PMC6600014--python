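"""Synthetic-data generator with planted ground truth.

Emulates the 2 diet x 2 fraction x 4 replicate polysome-profiling design:
NB-distributed gene counts with planted transcriptional and DPAR effects,
gene models with operon / spliced-leader / 3' UTR annotation, per-site
base-count pileups with planted A-to-G edits, intron/exon count pairs with
planted diet x fraction retention interactions, and qPCR Cp panels with
planted fold changes.  Every planted quantity is recorded in a
:class:`SimTruth` so downstream stages can be scored for recovery.

Counts are drawn as NB(mean = library-scaled per-gene mean adjusted by the
planted contrast effects, dispersion phi); library depths are log-normal
so CPM never coincides with raw counts.  Pileup error rates default to
0.1% so the 10% frequency filter is never triggered by noise alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import GROUPS
from .counts_pipeline import CountMatrix, SampleDesign

__all__ = [
    "SimConfig",
    "SimTruth",
    "AnnotationSet",
    "IntronExonCounts",
    "simulate_counts",
    "simulate_annotation",
    "simulate_pileup",
    "simulate_intron_counts",
    "simulate_qpcr",
    "simulate_profiles",
    "edit_plan_coupled_to_dpar",
]

GENE_CLASSES = (
    "null",
    "transcriptional_up",
    "transcriptional_down",
    "dpar_promoted",
    "dpar_repressed",
    "opposing",
)


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults mirror the study design: biological quadruplicates per group,
    NB counts around a few hundred per gene, planted effects of |log2FC| 2,
    18% operonic genes, 73% SL1 trans-spliced genes, global intron
    fractions of 1.5% (AL) vs 2.2% (DR) in the total fraction.
    """

    n_genes: int = 2000
    n_reps: int = 4
    baseline_mu: float = 200.0
    gene_sigma: float = 0.5  # log-normal spread of per-gene means
    dispersion: float = 0.1
    frac_transcriptional_up: float = 0.0
    frac_transcriptional_down: float = 0.0
    frac_dpar_promoted: float = 0.0
    frac_dpar_repressed: float = 0.0
    frac_opposing: float = 0.0
    effect_log2fc: float = 2.0
    depth_sigma: float = 0.2  # log-normal spread of per-sample depth

    operon_fraction: float = 0.18
    sl1_fraction: float = 0.73
    utr_mean_len: float = 180.0
    utr_gc: float = 0.27
    planted_motif: str | None = None
    n_motif_targets: int = 0
    mirna_family: str = "miR-58"
    n_mirna_targets: int = 0

    n_edit_sites: int = 0
    n_background_sites: int = 0
    edit_coverage: float = 100.0
    error_rate: float = 0.001
    utr_edit_fraction: float = 0.35
    edit_active_prob: dict = field(
        default_factory=lambda: {"AL_TO": 0.6, "AL_TR": 0.35, "DR_TO": 0.75, "DR_TR": 0.25}
    )
    edit_frequency: dict = field(
        default_factory=lambda: {"AL_TO": 0.25, "AL_TR": 0.20, "DR_TO": 0.30, "DR_TR": 0.15}
    )

    n_intron_changed: int = 0
    intron_effect_log2: float = 2.0
    intron_fractions: dict = field(
        default_factory=lambda: {"AL_TO": 0.015, "AL_TR": 0.010, "DR_TO": 0.022, "DR_TR": 0.012}
    )

    n_assays: int = 11
    n_qpcr_reps: int = 3
    qpcr_sigma: float = 0.2
    qpcr_fold_changes: dict = field(default_factory=lambda: {"assay01": 2.0})

    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_transcriptional_up,
            self.frac_transcriptional_down,
            self.frac_dpar_promoted,
            self.frac_dpar_repressed,
            self.frac_opposing,
            self.operon_fraction,
            self.sl1_fraction,
            self.utr_edit_fraction,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("all proportions must lie in [0, 1]")
        class_sum = sum(fracs[:5])
        if class_sum > 1:
            raise ValueError(f"gene-class proportions sum to {class_sum} > 1")
        if self.n_reps < 2:
            raise ValueError("need n_reps >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent reproducible stream per generator stage."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class SimTruth:
    """Planted ground truth; filled in by each simulate_* stage."""

    gene_classes: pd.Series | None = None
    planted_logfc: pd.DataFrame | None = None
    edit_sites: pd.DataFrame | None = None
    intron_effects: pd.DataFrame | None = None
    qpcr_fold: pd.Series | None = None


@dataclass
class AnnotationSet:
    """Per-gene models plus regulatory-feature annotation.

    ``genes`` columns: chrom, strand, start, end, cds_start, cds_end,
    utr3_start, utr3_end, operon, operon_pos, sl_class (coordinates
    0-based half-open on the reference strand).
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    introns: pd.DataFrame
    mirna_targets: pd.DataFrame
    utr3: dict

    def gene_at(self, chrom: str, pos: int) -> str | None:
        g = self.genes[self.genes["chrom"] == chrom]
        hit = g[(g["start"] <= pos) & (pos < g["end"])]
        return None if hit.empty else hit.index[0]

    def region_of(self, gene: str, pos: int) -> str:
        row = self.genes.loc[gene]
        if row["utr3_start"] <= pos < row["utr3_end"]:
            return "UTR3"
        if row["cds_start"] <= pos < row["cds_end"]:
            return "CDS"
        return "other"


@dataclass
class IntronExonCounts:
    """Per-gene intronic/exonic counts plus per-sample totals."""

    intronic: pd.DataFrame
    exonic: pd.DataFrame
    total_aligned: pd.Series
    design: SampleDesign

    def __post_init__(self) -> None:
        if (self.intronic.values < 0).any() or (self.exonic.values < 0).any():
            raise ValueError("counts must be nonnegative")


def _make_design(n_reps: int) -> SampleDesign:
    rows = []
    for group in GROUPS:
        diet, frac = group.split("_")
        for r in range(1, n_reps + 1):
            rows.append({"sample": f"{group}_r{r}", "diet": diet, "fraction": frac, "replicate": r})
    return SampleDesign(pd.DataFrame(rows))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-8)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SampleDesign, SimTruth]:
    """Draw the 4-group NB count matrix with planted contrast effects."""
    rng = config.rng(0)
    design = _make_design(config.n_reps)
    genes = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene")

    # class assignment: counts per class from the configured proportions
    n = config.n_genes
    n_by_class = {
        "transcriptional_up": int(round(config.frac_transcriptional_up * n)),
        "transcriptional_down": int(round(config.frac_transcriptional_down * n)),
        "dpar_promoted": int(round(config.frac_dpar_promoted * n)),
        "dpar_repressed": int(round(config.frac_dpar_repressed * n)),
        "opposing": int(round(config.frac_opposing * n)),
    }
    labels = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    pos = 0
    for cls, k in n_by_class.items():
        labels[order[pos : pos + k]] = cls
        pos += k
    classes = pd.Series(labels, index=genes, name="class")

    e = config.effect_log2fc
    tx = pd.Series(0.0, index=genes)
    dp = pd.Series(0.0, index=genes)
    tx[classes == "transcriptional_up"] = e
    tx[classes == "transcriptional_down"] = -e
    dp[classes == "dpar_promoted"] = e
    dp[classes == "dpar_repressed"] = -e
    tx[classes == "opposing"] = -e
    dp[classes == "opposing"] = e

    mu_g = config.baseline_mu * rng.lognormal(0.0, config.gene_sigma, size=n)
    depth = rng.lognormal(0.0, config.depth_sigma, size=len(design.samples))

    is_dr = (design.table["diet"] == "DR").values
    is_tr = (design.table["fraction"] == "TR").values
    log2_effect = np.outer(tx.values, is_dr) + np.outer(dp.values, is_dr & is_tr)
    mean = mu_g[:, None] * depth[None, :] * 2.0 ** log2_effect
    counts = _nb_draw(rng, mean, config.dispersion)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=design.samples), design)
    truth = SimTruth(
        gene_classes=classes,
        planted_logfc=pd.DataFrame(
            {
                "transcription": tx,
                "dpar": dp,
                "translation_AL": 0.0,
                "translation_DR": dp,
            }
        ),
    )
    return cm, design, truth


# ----------------------------------------------------------------------
# annotation


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def simulate_annotation(config: SimConfig) -> tuple[AnnotationSet, dict]:
    """Gene models with operon/SL/3'UTR annotation and 3' UTR sequences.

    Genes are laid head-to-tail along one reference sequence with >= 2
    exons each; the 3' UTR occupies the tail of the last exon (>= 12 nt,
    the analysis floor).  Returns the annotation and the UTR sequence dict
    (also stored on the annotation).
    """
    rng = config.rng(1)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    gene_rows, exon_rows, intron_rows = [], [], []
    cursor = 1000
    for gid in genes:
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(120, 300, size=n_exons)
        intron_lens = rng.integers(40, 80, size=n_exons - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor
        p = start
        g_exons, g_introns = [], []
        for i in range(n_exons):
            g_exons.append((p, p + int(exon_lens[i])))
            p += int(exon_lens[i])
            if i < n_exons - 1:
                g_introns.append((p, p + int(intron_lens[i])))
                p += int(intron_lens[i])
        end = p
        utr_len = max(12, int(rng.lognormal(np.log(config.utr_mean_len), 0.4)))
        last = g_exons[-1]
        utr_len = min(utr_len, (last[1] - last[0]) - 30)
        # 3' UTR at the downstream end of the mRNA (strand-aware)
        if strand == "+":
            utr3 = (last[1] - utr_len, last[1])
            cds = (g_exons[0][0], utr3[0])
        else:
            first = g_exons[0]
            utr3 = (first[0], first[0] + utr_len)
            cds = (utr3[1], g_exons[-1][1])
        gene_rows.append(
            {
                "gene": gid,
                "chrom": "chrS",
                "strand": strand,
                "start": start,
                "end": end,
                "cds_start": cds[0],
                "cds_end": cds[1],
                "utr3_start": utr3[0],
                "utr3_end": utr3[1],
            }
        )
        for s, e2 in g_exons:
            exon_rows.append({"gene": gid, "start": s, "end": e2})
        for s, e2 in g_introns:
            intron_rows.append({"gene": gid, "start": s, "end": e2})
        cursor = end + 200

    gdf = pd.DataFrame(gene_rows).set_index("gene")

    # operons: runs of 2-3 consecutive genes up to the configured fraction
    operon_id = pd.Series(pd.NA, index=gdf.index, dtype=object)
    operon_pos = pd.Series(0, index=gdf.index)
    target = int(round(config.operon_fraction * config.n_genes))
    assigned = 0
    i = 0
    op = 0
    idx = list(gdf.index)
    while assigned < target and i < len(idx) - 1:
        size = int(rng.integers(2, 4))
        size = min(size, target - assigned) if target - assigned >= 2 else 2
        members = idx[i : i + size]
        if len(members) >= 2:
            op += 1
            for j, gid in enumerate(members):
                operon_id[gid] = f"CEOP{op:04d}"
                operon_pos[gid] = j + 1
            assigned += len(members)
        i += size + int(rng.integers(2, 6))
    gdf["operon"] = operon_id
    gdf["operon_pos"] = operon_pos

    # SL classes: downstream operonic genes are SL2; SL1 assigned among the
    # rest so the overall SL1 fraction matches the configured level
    sl = pd.Series("native", index=gdf.index, dtype=object)
    sl2_mask = operon_pos > 1
    sl[sl2_mask] = "SL2"
    eligible = ~sl2_mask
    n_sl1 = int(round(config.sl1_fraction * config.n_genes))
    p_sl1 = min(1.0, n_sl1 / max(eligible.sum(), 1))
    sl[eligible & (rng.random(len(sl)) < p_sl1)] = "SL1"
    gdf["sl_class"] = sl

    # 3' UTR sequences, with optional planted motif
    utr3 = {}
    for gid in gdf.index:
        row = gdf.loc[gid]
        utr3[gid] = _random_seq(rng, int(row["utr3_end"] - row["utr3_start"]), config.utr_gc)
    motif_targets = []
    if config.planted_motif and config.n_motif_targets > 0:
        motif = config.planted_motif.upper().replace("U", "T")
        motif_targets = list(rng.choice(gdf.index, size=config.n_motif_targets, replace=False))
        for gid in motif_targets:
            seq = utr3[gid]
            if len(seq) < len(motif):
                seq = seq + _random_seq(rng, len(motif) - len(seq), config.utr_gc)
            at = int(rng.integers(0, len(seq) - len(motif) + 1))
            utr3[gid] = seq[:at] + motif + seq[at + len(motif) :]
    gdf["motif_target"] = gdf.index.isin(motif_targets)

    # TargetScan-style miRNA target table: planted conserved targets
    # (P_ct > 0.8) plus an equal number of low-confidence decoys
    rows = []
    if config.n_mirna_targets > 0:
        targets = rng.choice(gdf.index, size=min(2 * config.n_mirna_targets, len(gdf)), replace=False)
        for j, gid in enumerate(targets):
            pct = rng.uniform(0.81, 0.99) if j < config.n_mirna_targets else rng.uniform(0.0, 0.79)
            rows.append({"gene": gid, "family": config.mirna_family, "pct": pct})
    mirna = pd.DataFrame(rows, columns=["gene", "family", "pct"])

    ann = AnnotationSet(
        genes=gdf,
        exons=pd.DataFrame(exon_rows),
        introns=pd.DataFrame(intron_rows),
        mirna_targets=mirna,
        utr3=utr3,
    )
    return ann, utr3


# ----------------------------------------------------------------------
# pileups


def _default_edit_plan(config: SimConfig, annotation: AnnotationSet, rng) -> pd.DataFrame:
    gdf = annotation.genes
    n_utr = int(round(config.utr_edit_fraction * config.n_edit_sites))
    regions = ["UTR3"] * n_utr + ["CDS"] * (config.n_edit_sites - n_utr)
    host_genes = rng.choice(gdf.index, size=config.n_edit_sites, replace=False)
    rows = []
    for sid, (gid, region) in enumerate(zip(host_genes, regions)):
        row = gdf.loc[gid]
        lo, hi = (
            (row["utr3_start"], row["utr3_end"])
            if region == "UTR3"
            else (row["cds_start"], row["cds_end"])
        )
        pos = int(rng.integers(lo, hi))
        rec = {
            "site": f"site{sid:04d}",
            "chrom": row["chrom"],
            "pos": pos,
            "gene": gid,
            "region": region,
            "strand": row["strand"],
        }
        for g in GROUPS:
            if rng.random() < config.edit_active_prob[g]:
                rec[f"freq_{g}"] = float(
                    np.clip(rng.normal(config.edit_frequency[g], 0.05), 0.12, 0.6)
                )
            else:
                rec[f"freq_{g}"] = 0.0
        rows.append(rec)
    # background (never-edited) sites
    bg_genes = rng.choice(gdf.index, size=config.n_background_sites, replace=True)
    for k, gid in enumerate(bg_genes):
        row = gdf.loc[gid]
        pos = int(rng.integers(row["cds_start"], row["cds_end"]))
        rec = {
            "site": f"bg{k:04d}",
            "chrom": row["chrom"],
            "pos": pos,
            "gene": gid,
            "region": "CDS",
            "strand": row["strand"],
        }
        for g in GROUPS:
            rec[f"freq_{g}"] = 0.0
        rows.append(rec)
    return pd.DataFrame(rows)


def edit_plan_coupled_to_dpar(
    annotation: AnnotationSet,
    dpar_logfc: pd.Series,
    n_sites: int,
    base_freq: float = 0.30,
    span: float = 0.25,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Edit-site plan whose DR editing change is anticorrelated with DPAR.

    Sites are placed in 3' UTRs of ``n_sites`` genes; the DR_TO frequency
    is held at ``base_freq`` while the DR_TR frequency decreases with the
    gene's DPAR log2FC rank, so genes edited more heavily in the total
    fraction relative to polysomes are the translationally suppressed ones.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    genes = list(rng.choice(dpar_logfc.index, size=n_sites, replace=False))
    ranks = dpar_logfc[genes].rank(pct=True)
    rows = []
    for sid, gid in enumerate(genes):
        row = annotation.genes.loc[gid]
        pos = int(rng.integers(row["utr3_start"], row["utr3_end"]))
        delta = -span * float(ranks[gid])  # higher DPAR -> larger TO-vs-TR drop
        rows.append(
            {
                "site": f"cpl{sid:04d}",
                "chrom": row["chrom"],
                "pos": pos,
                "gene": gid,
                "region": "UTR3",
                "strand": row["strand"],
                "freq_AL_TO": base_freq,
                "freq_AL_TR": base_freq,
                "freq_DR_TO": base_freq,
                "freq_DR_TR": float(np.clip(base_freq + delta, 0.02, 0.95)),
            }
        )
    return pd.DataFrame(rows)


def simulate_pileup(
    config: SimConfig,
    annotation: AnnotationSet,
    truth: SimTruth,
    plan: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site per-sample base counts with planted A-to-G edits.

    Plus-strand genes show ref A with G mismatches; minus-strand genes are
    reported on the reference strand as ref T with C mismatches.  Coverage
    is Poisson around ``edit_coverage``; non-edited reads are misread to a
    random other base at ``error_rate``.
    """
    rng = config.rng(2)
    if plan is None:
        plan = _default_edit_plan(config, annotation, rng)
    for _, site in plan.iterrows():
        if annotation.gene_at(site["chrom"], int(site["pos"])) is None:
            raise ValueError(f"site {site['site']} outside any gene")
    design = _make_design(config.n_reps)
    group_of = design.group_of()

    base_order = "ACGT"
    rows = []
    for _, site in plan.iterrows():
        minus = site["strand"] == "-"
        ref, edited = ("T", "C") if minus else ("A", "G")
        for sample in design.samples:
            freq = site[f"freq_{group_of[sample]}"]
            cov = max(int(rng.poisson(config.edit_coverage)), 1)
            n_edit = rng.binomial(cov, freq) if freq > 0 else 0
            n_ref = cov - n_edit
            counts = dict.fromkeys(base_order, 0)
            counts[edited] += int(n_edit)
            n_err = rng.binomial(n_ref, config.error_rate) if config.error_rate > 0 else 0
            counts[ref] += int(n_ref - n_err)
            others = [b for b in base_order if b != ref]
            for b in rng.choice(others, size=int(n_err)):
                counts[b] += 1
            rows.append(
                {
                    "chrom": site["chrom"],
                    "pos": int(site["pos"]),
                    "strand": site["strand"],
                    "ref": ref,
                    "sample": sample,
                    "nA": counts["A"],
                    "nC": counts["C"],
                    "nG": counts["G"],
                    "nT": counts["T"],
                }
            )
    truth.edit_sites = plan
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# intron/exon counts


def balanced_intron_fractions(
    al_to: float = 0.015, al_tr: float = 0.010, dr_to: float = 0.022
) -> dict:
    """Group intron fractions with zero shared diet x fraction interaction.

    Chooses the DR_TR fraction so the baseline log2(I/E) interaction is
    exactly 0 — the null configuration for calibrating the per-gene
    interaction test.
    """
    r = lambda f: f / (1 - f)
    r_dr_tr = r(dr_to) * r(al_tr) / r(al_to)
    return {
        "AL_TO": al_to,
        "AL_TR": al_tr,
        "DR_TO": dr_to,
        "DR_TR": r_dr_tr / (1 + r_dr_tr),
    }


def simulate_intron_counts(
    config: SimConfig, annotation: AnnotationSet, truth: SimTruth
) -> IntronExonCounts:
    """NB intron/exon count pairs with planted retention interactions.

    The expected intronic share per group follows ``intron_fractions``;
    ``n_intron_changed`` genes get a 2**intron_effect_log2 multiplier on
    their DR_TR retention ratio (half up, half down), i.e. a pure
    diet x fraction interaction on log2(I/E).
    """
    rng = config.rng(3)
    design = _make_design(config.n_reps)
    genes = annotation.genes.index
    n = len(genes)

    mu_g = config.baseline_mu * rng.lognormal(0.0, config.gene_sigma, size=n)
    depth = rng.lognormal(0.0, config.depth_sigma, size=len(design.samples))
    exon_mean = mu_g[:, None] * depth[None, :]

    is_dr = (design.table["diet"] == "DR").values
    is_tr = (design.table["fraction"] == "TR").values
    group_key = np.array([f"{d}_{f}" for d, f in zip(design.table["diet"], design.table["fraction"])])
    f_s = np.array([config.intron_fractions[g] for g in group_key])
    propensity = rng.lognormal(0.0, 0.3, size=n)
    propensity /= propensity.mean()

    beta = np.zeros(n)
    changed = rng.choice(n, size=min(config.n_intron_changed, n), replace=False)
    half = len(changed) // 2
    beta[changed[:half]] = config.intron_effect_log2
    beta[changed[half:]] = -config.intron_effect_log2

    ratio = (f_s / (1 - f_s))[None, :] * propensity[:, None]
    ratio = ratio * 2.0 ** np.outer(beta, is_dr & is_tr)
    intron_mean = exon_mean * ratio

    exonic = _nb_draw(rng, exon_mean, config.dispersion)
    intronic = _nb_draw(rng, intron_mean, config.dispersion)

    exonic = pd.DataFrame(exonic, index=genes, columns=design.samples)
    intronic = pd.DataFrame(intronic, index=genes, columns=design.samples)
    total = exonic.sum(axis=0) + intronic.sum(axis=0)
    # the four group fractions themselves imply a shared diet x fraction
    # interaction on log2(I/E); every gene carries it on top of its
    # planted effect (the study-level "retention ratio shrinks under DR")
    r = {g: f / (1 - f) for g, f in config.intron_fractions.items()}
    baseline = float(
        np.log2((r["DR_TR"] / r["DR_TO"]) / (r["AL_TR"] / r["AL_TO"]))
    )
    truth.intron_effects = pd.DataFrame(
        {
            "planted_log2": beta,
            "baseline_log2": baseline,
            "true_interaction": beta + baseline,
        },
        index=genes,
    )
    return IntronExonCounts(intronic=intronic, exonic=exonic, total_aligned=total, design=design)


# ----------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    config: SimConfig, conditions: tuple[str, ...] = ("AL", "DR")
) -> tuple[pd.DataFrame, SimTruth]:
    """Cp table for a qPCR panel with planted condition fold changes.

    Cp = assay baseline - log2(relative expression) + N(0, sigma); an
    assay with fold change f is shifted by -log2(f) in the second
    condition.  Returns (CpTable, truth-with-qpcr_fold).
    """
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    rng = config.rng(4)
    assays = [f"assay{i + 1:02d}" for i in range(config.n_assays)]
    baseline = {a: rng.uniform(20.0, 30.0) for a in assays}
    folds = pd.Series(1.0, index=pd.Index(assays, name="assay"))
    for a, f in config.qpcr_fold_changes.items():
        if a in folds.index:
            folds[a] = f
    rows = []
    for a in assays:
        for cond in conditions:
            shift = -np.log2(folds[a]) if cond != conditions[0] else 0.0
            for r in range(1, config.n_qpcr_reps + 1):
                cp = baseline[a] + shift + rng.normal(0.0, config.qpcr_sigma)
                rows.append({"assay": a, "condition": cond, "replicate": r, "Cp": cp})
    truth = SimTruth(qpcr_fold=folds)
    return pd.DataFrame(rows), truth


# ----------------------------------------------------------------------
# expression-profile archetypes (for clustering experiments)


#: mean-centred log2-CPM archetypes over (AL_TO, AL_TR, DR_TO, DR_TR):
#: transcription-down offset by translation-up; translation-down that
#: deepens under DR; translation-up only under DR
PROFILE_ARCHETYPES = {
    "tx_down_tl_up": np.array([0.75, 0.75, -1.25, -0.25]),
    "tl_down": np.array([0.625, -0.375, 0.625, -0.875]),
    "tl_up_dr_only": np.array([-0.375, -0.375, -0.625, 1.375]),
}


#: relative cluster sizes (transcription-down-offset : deepening
#: translation-down : DR-only translation-up)
PROFILE_PROPORTIONS = (530, 492, 643)


def simulate_profiles(
    n_per_cluster: int = 100,
    noise_sd: float = 0.3,
    noise_df: float = 3.0,
    archetypes: dict | None = None,
    proportions: tuple | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean-centred 4-group profiles around planted archetypes.

    Profile residuals are Student-t with ``noise_df`` degrees of freedom
    scaled by ``noise_sd`` (log-expression residuals are heavy-tailed);
    cluster sizes follow ``proportions`` (default: the uneven three-way
    split of the DR-only translationally regulated genes) scaled so the
    mean size is ``n_per_cluster``.  Returns the profile matrix (rows
    re-centred after noise) and true cluster labels.  ``archetypes=None``
    uses the three study archetypes; pass a single-entry dict for a
    one-blob control.
    """
    rng = np.random.default_rng(seed)
    if archetypes is None:
        archetypes = PROFILE_ARCHETYPES
    if proportions is None:
        proportions = PROFILE_PROPORTIONS[: len(archetypes)] or (1,)
    w = np.asarray(proportions[: len(archetypes)], dtype=float)
    sizes = np.maximum(1, np.round(w / w.mean() * n_per_cluster)).astype(int)
    rows, labels = [], []
    for (name, center), n_c in zip(archetypes.items(), sizes):
        noise = rng.standard_t(noise_df, size=(n_c, 4)) * noise_sd
        x = center[None, :] + noise
        rows.append(x)
        labels.extend([name] * n_c)
    X = np.vstack(rows)
    X = X - X.mean(axis=1, keepdims=True)
    idx = pd.Index([f"p{i:05d}" for i in range(len(labels))])
    return (
        pd.DataFrame(X, index=idx, columns=list(GROUPS)),
        pd.Series(labels, index=idx, name="cluster"),
    )
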