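"""Intron-retention quantification, interaction modelling, and PTC scanning.

Global retention is the percent of aligned reads falling in introns;
per-gene retention is the log2 ratio of intronic to exonic reads (0.5
pseudocount).  A gene's diet x fraction interaction on that ratio is
tested by ordinary least squares over the 16 samples with a t test on the
interaction coefficient and BH correction across genes — genes need at
least 4 intronic reads in total to enter.  Retained-intron isoforms are
scanned for premature termination codons (PTCs) by in-silico translation
of the intron-bearing CDS.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .counts_pipeline import SampleDesign
from .stats_core import bh_fdr, wilcoxon_rank_sum
from .synthetic_data import AnnotationSet, IntronExonCounts

__all__ = [
    "count_intron_exon",
    "global_intron_fraction",
    "retention_interaction_test",
    "classify_retention_change",
    "ptc_scan",
]

logger = logging.getLogger(__name__)

MIN_INTRONIC_READS = 4
PSEUDOCOUNT = 0.5


def count_intron_exon(
    alignments: pd.DataFrame, annotation: AnnotationSet, design: SampleDesign
) -> IntronExonCounts:
    """Classify interval reads as intronic or exonic per gene per sample.

    ``alignments`` columns: chrom, start, end, sample (0-based half-open).
    A read overlapping any intronic base of its gene by >= 1 bp counts as
    intronic (junction-spanning retained reads are retention evidence);
    reads overlapping no gene or more than one gene are discarded with a
    log entry.  Genes without annotated introns are excluded.
    """
    gdf = annotation.genes
    with_introns = set(annotation.introns["gene"])
    skipped = set(gdf.index) - with_introns
    for g in sorted(skipped):
        logger.info("gene %s has no annotated introns; excluded", g)

    starts = gdf["start"].values
    ends = gdf["end"].values
    order = np.argsort(starts)
    gene_ids = gdf.index.values[order]
    s_sorted, e_sorted = starts[order], ends[order]

    intron_by_gene = {
        g: list(zip(sub["start"], sub["end"]))
        for g, sub in annotation.introns.groupby("gene")
    }

    genes = [g for g in gdf.index if g in with_introns]
    intronic = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=design.samples)
    exonic = pd.DataFrame(0, index=intronic.index, columns=design.samples)
    total = pd.Series(0, index=design.samples, dtype=int)

    n_ambiguous = 0
    for _, read in alignments.iterrows():
        rs, re_, sample = int(read["start"]), int(read["end"]), read["sample"]
        total[sample] += 1
        # candidate genes: overlapping intervals among sorted non-overlapping genes
        i = np.searchsorted(s_sorted, re_) - 1
        hits = []
        j = i
        while j >= 0 and e_sorted[j] > rs:
            if s_sorted[j] < re_:
                hits.append(gene_ids[j])
            j -= 1
        if len(hits) != 1:
            if len(hits) > 1:
                n_ambiguous += 1
            continue
        gene = hits[0]
        if gene not in with_introns:
            continue
        is_intronic = any(rs < ie and re_ > istart for istart, ie in intron_by_gene[gene])
        if is_intronic:
            intronic.loc[gene, sample] += 1
        else:
            exonic.loc[gene, sample] += 1
    if n_ambiguous:
        logger.info("discarded %d reads ambiguous between genes", n_ambiguous)
    return IntronExonCounts(
        intronic=intronic, exonic=exonic, total_aligned=total, design=design
    )


def quantifiable_genes(counts: IntronExonCounts, min_reads: int = MIN_INTRONIC_READS) -> pd.Index:
    """Genes with at least ``min_reads`` intronic reads summed over samples."""
    return counts.intronic.index[counts.intronic.sum(axis=1) >= min_reads]


def global_intron_fraction(counts: IntronExonCounts) -> dict:
    """Per-sample/-group intron percentages with t tests and the 2x2 interaction.

    Percent = intronic / total aligned x 100 per sample.  Diet effects
    within fraction use two-tailed two-sample t tests; the diet x fraction
    interaction of the percentages is tested by the interaction term of
    the two-way (balanced 2x2) linear model, equivalent to the two-way
    ANOVA interaction test.
    """
    if (counts.total_aligned == 0).any():
        raise ValueError("zero total aligned reads in a sample")
    pct = counts.intronic.sum(axis=0) / counts.total_aligned * 100.0
    t = counts.design.table.set_index("sample")
    df = pd.DataFrame({"pct": pct, "diet": t["diet"], "fraction": t["fraction"]})
    group_means = df.groupby(["diet", "fraction"])["pct"].mean()

    tests = {}
    for frac in ("TO", "TR"):
        a = df[(df["diet"] == "AL") & (df["fraction"] == frac)]["pct"]
        d = df[(df["diet"] == "DR") & (df["fraction"] == frac)]["pct"]
        tests[f"AL_vs_DR_{frac}"] = stats.ttest_ind(a, d)
    for diet in ("AL", "DR"):
        to = df[(df["diet"] == diet) & (df["fraction"] == "TO")]["pct"]
        tr = df[(df["diet"] == diet) & (df["fraction"] == "TR")]["pct"]
        tests[f"TO_vs_TR_{diet}"] = stats.ttest_ind(to, tr)

    X = np.column_stack(
        [
            np.ones(len(df)),
            (df["diet"] == "DR").astype(float),
            (df["fraction"] == "TR").astype(float),
            ((df["diet"] == "DR") & (df["fraction"] == "TR")).astype(float),
        ]
    )
    beta, res_ss, interaction_p = _ols_t_on_last(X, df["pct"].values)
    return {
        "per_sample_percent": pct,
        "group_means": group_means,
        "tests": tests,
        "interaction_estimate": beta[3],
        "interaction_p": interaction_p,
    }


def _ols_t_on_last(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    """OLS fit returning (beta, residual SS, two-sided p of last coefficient)."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * XtX_inv[-1, -1])
    tval = beta[-1] / se if se > 0 else 0.0
    pval = 2.0 * stats.t.sf(abs(tval), dof)
    return beta, rss, float(pval)


def retention_interaction_test(
    counts: IntronExonCounts,
    min_reads: int = MIN_INTRONIC_READS,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene OLS of log2 retention ratio on diet * fraction.

    Response y = log2((intronic + pc) / (exonic + pc)) per sample; the
    interaction coefficient (log2 units) is tested with a t test and BH
    correction across genes.  Rank-sum diet comparisons within each
    fraction are emitted alongside (columns p_wilcoxon_TO/TR).
    """
    genes = quantifiable_genes(counts, min_reads)
    t = counts.design.table
    samples = list(t["sample"])
    X = np.column_stack(
        [
            np.ones(len(samples)),
            (t["diet"] == "DR").astype(float).values,
            (t["fraction"] == "TR").astype(float).values,
            ((t["diet"] == "DR") & (t["fraction"] == "TR")).astype(float).values,
        ]
    )
    sizes = t.groupby(["diet", "fraction"]).size()
    if (sizes < 2).any():
        raise ValueError("need >= 2 replicates per design cell")

    I = counts.intronic.loc[genes, samples].values.astype(float)
    E = counts.exonic.loc[genes, samples].values.astype(float)
    Y = np.log2((I + pseudocount) / (E + pseudocount))

    # vectorised OLS: same design for every gene
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    B = Y @ H.T
    resid = Y - B @ X.T
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(sigma2 * XtX_inv[3, 3])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, B[:, 3] / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)

    al_to = [s for s, d, f in zip(t["sample"], t["diet"], t["fraction"]) if d == "AL" and f == "TO"]
    dr_to = [s for s, d, f in zip(t["sample"], t["diet"], t["fraction"]) if d == "DR" and f == "TO"]
    al_tr = [s for s, d, f in zip(t["sample"], t["diet"], t["fraction"]) if d == "AL" and f == "TR"]
    dr_tr = [s for s, d, f in zip(t["sample"], t["diet"], t["fraction"]) if d == "DR" and f == "TR"]
    ydf = pd.DataFrame(Y, index=genes, columns=samples)

    def _wx(row, a, b):
        try:
            return wilcoxon_rank_sum(row[a].values, row[b].values).p_value
        except ValueError:
            return np.nan

    p_to = ydf.apply(_wx, axis=1, args=(al_to, dr_to))
    p_tr = ydf.apply(_wx, axis=1, args=(al_tr, dr_tr))

    out = pd.DataFrame(
        {
            "interaction_log2": B[:, 3],
            "PValue": pval,
            "FDR": bh_fdr(pval),
            "p_wilcoxon_TO": p_to,
            "p_wilcoxon_TR": p_tr,
        },
        index=genes,
    )
    return out


def classify_retention_change(
    results: pd.DataFrame,
    fold: float = 2.0,
    fdr: float = 0.05,
    estimate_col: str = "interaction_log2",
) -> pd.Series:
    """Label genes increased / decreased / unchanged on |fold| and FDR."""
    lfc = np.log2(fold)
    cls = pd.Series("unchanged", index=results.index)
    sig = (results["FDR"] < fdr) & (results[estimate_col].abs() >= lfc)
    cls[sig & (results[estimate_col] > 0)] = "increased"
    cls[sig & (results[estimate_col] < 0)] = "decreased"
    return cls


def ptc_scan(gene_model: dict, retained_intron: tuple[int, int], genome_seq: str) -> dict:
    """Scan the intron-retained isoform of a CDS for premature stops.

    ``gene_model``: dict with ``cds_exons`` (list of (start, end), 0-based
    half-open, genomic order) and ``strand``.  The retained intron must
    lie between two CDS exons; introns outside the CDS span report no
    coding consequence.  The isoform sequence is the CDS with the intron
    kept, translated from the annotated start; reported are whether a stop
    appears upstream of the annotated stop (PTC), whether the intron
    length preserves frame, and the first PTC's codon index.
    """
    exons = sorted(gene_model["cds_exons"])
    strand = gene_model.get("strand", "+")
    i_start, i_end = retained_intron
    cds_lo, cds_hi = exons[0][0], exons[-1][1]
    if i_end <= cds_lo or i_start >= cds_hi:
        return {"coding": False, "note": "UTR intron, no coding consequence"}

    pieces = []
    for (s, e) in exons:
        pieces.append((s, e))
    segments = sorted(pieces + [(i_start, i_end)])
    iso = "".join(genome_seq[s:e] for s, e in segments)
    spliced = "".join(genome_seq[s:e] for s, e in exons)
    if strand == "-":
        iso = str(Seq(iso).reverse_complement())
        spliced = str(Seq(spliced).reverse_complement())

    intron_len = i_end - i_start
    frame_preserved = intron_len % 3 == 0

    def first_stop(seq: str) -> int | None:
        for i in range(0, len(seq) - 2, 3):
            if seq[i : i + 3].upper() in ("TAA", "TAG", "TGA"):
                return i // 3
        return None

    stop_iso = first_stop(iso)
    annotated_stop = first_stop(spliced)
    expected_last = (len(iso) // 3) - 1
    if annotated_stop is not None:
        # position the annotated stop would occupy in the retained isoform
        expected_last = annotated_stop + (intron_len // 3 if frame_preserved else 0)
    has_ptc = stop_iso is not None and stop_iso < expected_last
    out = {
        "coding": True,
        "has_ptc": bool(has_ptc),
        "frame_preserved": frame_preserved,
        "first_stop_codon": stop_iso,
        "inserted_residues": intron_len // 3 if frame_preserved and not has_ptc else None,
    }
    return out
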