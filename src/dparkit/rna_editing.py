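"""A-to-I editing-site detection from per-site base-count pileups.

Inosine base-pairs like guanosine, so editing shows up as A-to-G
mismatches on the gene strand (T-to-C on the reference strand for
minus-strand genes).  A site is called in a replicate when at least
``min_support`` reads carry the edited base and the editing frequency —
edited / (reference + edited) reads — is at least ``min_freq`` (defaults
5 reads, 10%).  Per-group consensus requires the call in at least 3 of 4
replicates.  Summaries report per-group site counts, mean frequencies and
CDS vs 3' UTR composition; the coupling between DR editing change and
translational change is measured by Spearman correlation against the DPAR
log2 fold change.
"""

from __future__ import annotations

import logging
from math import ceil

import numpy as np
import pandas as pd

from . import GROUPS
from .counts_pipeline import SampleDesign
from .stats_core import correlation, wilcoxon_rank_sum

__all__ = [
    "call_edit_sites",
    "consensus_sites",
    "editing_group_summary",
    "editing_vs_translation",
]

logger = logging.getLogger(__name__)

MIN_SUPPORT = 5
MIN_FREQ = 0.10
MIN_REPS = 3


def call_edit_sites(
    pileup: pd.DataFrame,
    annotation,
    min_support: int = MIN_SUPPORT,
    min_freq: float = MIN_FREQ,
) -> pd.DataFrame:
    """Per-replicate editing calls from a base-count pileup.

    ``pileup`` columns: chrom, pos, strand (gene strand), ref, sample,
    nA, nC, nG, nT.  On the plus strand the reference must be A with G
    mismatches; minus-strand genes are evaluated as reference T with C
    mismatches.  Sites whose reference is not A on the gene strand are
    skipped with a log entry.  Both thresholds are inclusive.

    Returns one row per site x sample with frequency, support and the
    boolean ``called``, annotated with gene and region (CDS/UTR3/other).
    """
    rows = []
    for (chrom, pos, strand, ref), sub in pileup.groupby(["chrom", "pos", "strand", "ref"]):
        expected_ref = "T" if strand == "-" else "A"
        if ref != expected_ref:
            logger.info("skipping %s:%s: ref %s is not A on gene strand", chrom, pos, ref)
            continue
        ref_col, edit_col = ("nT", "nC") if strand == "-" else ("nA", "nG")
        gene = annotation.gene_at(chrom, int(pos))
        if gene is None:
            raise ValueError(f"site {chrom}:{pos} outside any annotated gene")
        region = annotation.region_of(gene, int(pos))
        for _, r in sub.iterrows():
            n_ref, n_edit = int(r[ref_col]), int(r[edit_col])
            denom = n_ref + n_edit
            freq = n_edit / denom if denom else 0.0
            rows.append(
                {
                    "site": f"{chrom}:{pos}",
                    "chrom": chrom,
                    "pos": int(pos),
                    "strand": strand,
                    "gene": gene,
                    "region": region,
                    "sample": r["sample"],
                    "support": n_edit,
                    "frequency": freq,
                    "called": (n_edit >= min_support) and (freq >= min_freq),
                }
            )
    return pd.DataFrame(rows)


def consensus_sites(
    calls: pd.DataFrame,
    design: SampleDesign,
    min_reps: int = MIN_REPS,
    n_reps: int = 4,
) -> pd.DataFrame:
    """Per-group replicate-consensus editing sites and group overlaps.

    A site is retained for a group when called in at least ``min_reps`` of
    that group's replicates; for designs with a different replicate number
    the threshold scales as ceil(min_reps / 4 * n_reps).  Returns a
    site x group membership table (boolean columns per group) with gene,
    region and per-group mean frequency.
    """
    actual_reps = design.table.groupby(["diet", "fraction"]).size().min()
    thr = min_reps if actual_reps == n_reps else ceil(min_reps / n_reps * actual_reps)
    group_of = design.group_of()
    calls = calls.assign(group=calls["sample"].map(group_of))

    agg = calls.groupby(["site", "group"]).agg(
        n_called=("called", "sum"), mean_freq=("frequency", "mean")
    )
    meta = calls.groupby("site").agg(
        gene=("gene", "first"), region=("region", "first"),
        chrom=("chrom", "first"), pos=("pos", "first"), strand=("strand", "first"),
    )
    out = meta.copy()
    for g in GROUPS:
        sub = agg.xs(g, level="group") if g in agg.index.get_level_values(1) else None
        if sub is None:
            out[f"in_{g}"] = False
            out[f"freq_{g}"] = np.nan
        else:
            out[f"in_{g}"] = (sub["n_called"] >= thr).reindex(out.index, fill_value=False)
            out[f"freq_{g}"] = sub["mean_freq"].reindex(out.index)
    out = out[[f"in_{g}" for g in GROUPS] + [f"freq_{g}" for g in GROUPS]
              + ["gene", "region", "chrom", "pos", "strand"]]
    return out[out[[f"in_{g}" for g in GROUPS]].any(axis=1)]


def venn_counts(consensus: pd.DataFrame) -> pd.Series:
    """Counts of sites per group-membership pattern (Venn cells)."""
    key = consensus[[f"in_{g}" for g in GROUPS]].apply(
        lambda r: "&".join(g for g in GROUPS if r[f"in_{g}"]), axis=1
    )
    return key.value_counts()


def editing_group_summary(
    consensus: pd.DataFrame, calls: pd.DataFrame, design: SampleDesign
) -> dict:
    """Per-group site counts, mean frequencies and region composition.

    Site counts are per-replicate numbers of called sites averaged within
    each group; groups are compared with the rank-sum test on those
    per-replicate counts.  Mean frequency averages over all dataset sites
    per group; region percentages split consensus sites CDS vs 3' UTR.
    """
    group_of = design.group_of()
    calls = calls.assign(group=calls["sample"].map(group_of))
    per_rep = calls[calls["called"]].groupby(["group", "sample"]).size()

    counts_by_group = {}
    for g in GROUPS:
        samples = design.samples_in(g)
        counts_by_group[g] = pd.Series(
            [per_rep.get((g, s), 0) for s in samples], index=samples, dtype=float
        )
    mean_counts = pd.Series({g: counts_by_group[g].mean() for g in GROUPS})
    mean_freq = pd.Series({g: consensus[f"freq_{g}"].mean() for g in GROUPS})

    tests = {}
    for ga, gb in [("AL_TO", "AL_TR"), ("DR_TO", "DR_TR"), ("AL_TO", "DR_TO"), ("AL_TR", "DR_TR")]:
        try:
            tests[f"{ga}_vs_{gb}"] = wilcoxon_rank_sum(
                counts_by_group[ga].values, counts_by_group[gb].values
            )
        except ValueError:
            tests[f"{ga}_vs_{gb}"] = None

    n_sites = len(consensus)
    region_pct = (
        consensus["region"].value_counts(normalize=True) * 100.0
        if n_sites
        else pd.Series(dtype=float)
    )
    return {
        "mean_site_count": mean_counts,
        "per_replicate_counts": counts_by_group,
        "mean_frequency": mean_freq,
        "region_percent": region_pct,
        "group_tests": tests,
    }


def editing_vs_translation(
    consensus: pd.DataFrame, dpar_table: pd.DataFrame, min_genes: int = 3
) -> dict:
    """Spearman correlation of DR editing change vs DPAR, per region.

    Per gene, the editing change is mean frequency(DR_TR) minus mean
    frequency(DR_TO), averaged over the gene's consensus sites; it is
    correlated with the gene's DPAR log2FC separately for 3'-UTR-edited
    and CDS-edited genes.  Regions with fewer than ``min_genes`` genes get
    ``None``.
    """
    missing = set(consensus["gene"]) - set(dpar_table.index)
    if missing:
        raise ValueError(f"genes missing from DPAR table: {sorted(missing)[:5]}")
    df = consensus.copy()
    df["delta_freq"] = df["freq_DR_TR"].fillna(0.0) - df["freq_DR_TO"].fillna(0.0)
    per_gene = df.groupby(["gene", "region"])["delta_freq"].mean().reset_index()
    out = {}
    for region in ("UTR3", "CDS"):
        sub = per_gene[per_gene["region"] == region]
        if len(sub) < min_genes:
            out[region] = None
            continue
        x = sub["delta_freq"].values
        y = dpar_table.loc[sub["gene"], "logFC"].values
        out[region] = correlation(x, y, method="spearman")
    return out
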