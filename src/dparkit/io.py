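"""Readers and writers for the pipeline's on-disk formats.

Counts and designs are TSV; annotation round-trips through GFF3 (1-based
inclusive on disk, 0-based half-open in memory); UTRs are FASTA; pileups
and result tables are TSV; truth and summaries are JSON; Cp panels are
CSV.  Consensus editing sites export as BED6 plus extra columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import GROUPS
from .counts_pipeline import CountMatrix, SampleDesign
from .synthetic_data import AnnotationSet

__all__ = [
    "read_counts", "write_counts",
    "read_design", "write_design",
    "read_count_matrix", "write_count_matrix",
    "read_fasta", "write_fasta",
    "write_gff3", "read_gff3",
    "read_pileup", "write_pileup",
    "read_cp_table", "write_cp_table",
    "write_edit_sites_bed",
    "read_pwm", "write_pwm",
    "write_json",
]


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_design(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t"))


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_count_matrix(counts_path, design_path) -> CountMatrix:
    return CountMatrix(read_counts(counts_path), read_design(design_path))


def write_count_matrix(cm: CountMatrix, counts_path, design_path) -> None:
    write_counts(cm.counts, counts_path)
    write_design(cm.design, design_path)


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(annotation: AnnotationSet, path) -> None:
    """GFF3 export: gene/exon/intron/CDS/three_prime_UTR features.

    Internal 0-based half-open coordinates become 1-based inclusive; the
    operon id, position and spliced-leader class ride in gene attributes.
    """
    lines = ["##gff-version 3"]
    g = annotation.genes
    for gid, row in g.iterrows():
        attrs = [f"ID={gid}", f"sl_class={row['sl_class']}"]
        if pd.notna(row["operon"]):
            attrs.append(f"operon={row['operon']};operon_pos={row['operon_pos']}")
        lines.append(
            "\t".join(
                [row["chrom"], "dparkit", "gene", str(row["start"] + 1), str(row["end"]),
                 ".", row["strand"], ".", ";".join(attrs)]
            )
        )
        for kind, lo, hi in (
            ("CDS", row["cds_start"], row["cds_end"]),
            ("three_prime_UTR", row["utr3_start"], row["utr3_end"]),
        ):
            lines.append(
                "\t".join(
                    [row["chrom"], "dparkit", kind, str(lo + 1), str(hi),
                     ".", row["strand"], ".", f"Parent={gid}"]
                )
            )
    for table, kind in ((annotation.exons, "exon"), (annotation.introns, "intron")):
        for _, row in table.iterrows():
            chrom = g.loc[row["gene"], "chrom"]
            strand = g.loc[row["gene"], "strand"]
            lines.append(
                "\t".join(
                    [chrom, "dparkit", kind, str(row["start"] + 1), str(row["end"]),
                     ".", strand, ".", f"Parent={row['gene']}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> AnnotationSet:
    """Re-assemble an :class:`AnnotationSet` from the GFF3 written above."""
    gene_rows, exon_rows, intron_rows = [], [], []
    extra: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _, kind, start, end, _, strand, _, attrs = line.split("\t")
        start0, end0 = int(start) - 1, int(end)
        a = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if kind == "gene":
            gene_rows.append(
                {
                    "gene": a["ID"], "chrom": chrom, "strand": strand,
                    "start": start0, "end": end0,
                    "operon": a.get("operon", pd.NA),
                    "operon_pos": int(a.get("operon_pos", 0)),
                    "sl_class": a.get("sl_class", "native"),
                }
            )
        elif kind == "CDS":
            extra.setdefault(a["Parent"], {})["cds"] = (start0, end0)
        elif kind == "three_prime_UTR":
            extra.setdefault(a["Parent"], {})["utr3"] = (start0, end0)
        elif kind == "exon":
            exon_rows.append({"gene": a["Parent"], "start": start0, "end": end0})
        elif kind == "intron":
            intron_rows.append({"gene": a["Parent"], "start": start0, "end": end0})
    gdf = pd.DataFrame(gene_rows).set_index("gene")
    gdf["cds_start"] = [extra.get(g, {}).get("cds", (pd.NA, pd.NA))[0] for g in gdf.index]
    gdf["cds_end"] = [extra.get(g, {}).get("cds", (pd.NA, pd.NA))[1] for g in gdf.index]
    gdf["utr3_start"] = [extra.get(g, {}).get("utr3", (pd.NA, pd.NA))[0] for g in gdf.index]
    gdf["utr3_end"] = [extra.get(g, {}).get("utr3", (pd.NA, pd.NA))[1] for g in gdf.index]
    return AnnotationSet(
        genes=gdf,
        exons=pd.DataFrame(exon_rows, columns=["gene", "start", "end"]),
        introns=pd.DataFrame(intron_rows, columns=["gene", "start", "end"]),
        mirna_targets=pd.DataFrame(columns=["gene", "family", "pct"]),
        utr3={},
    )


def read_pileup(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pileup(pileup: pd.DataFrame, path) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def read_cp_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cp_table(cp: pd.DataFrame, path) -> None:
    cp.to_csv(path, index=False)


def write_edit_sites_bed(consensus: pd.DataFrame, path) -> None:
    """BED6 + region + per-group frequency columns (0-based half-open)."""
    rows = []
    for site, row in consensus.iterrows():
        rows.append(
            [row["chrom"], row["pos"], row["pos"] + 1, site, 0, row["strand"], row["region"]]
            + [row[f"freq_{g}"] for g in GROUPS]
        )
    cols = ["chrom", "start", "end", "name", "score", "strand", "region"] + [
        f"freq_{g}" for g in GROUPS
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, header=False)


def read_pwm(path, motif_id: str | None = None, rbp: str = "") -> "PWM":
    """CISBP-RNA-style text matrix: header ``Pos A C G U``, one row per position."""
    from .regulatory_features import PWM

    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.upper() in {"A", "C", "G", "U", "T"}]
    mat = df[cols].values
    return PWM(motif_id or Path(path).stem, rbp, mat)


def write_pwm(pwm, path) -> None:
    df = pd.DataFrame(pwm.matrix, columns=["A", "C", "G", "U"])
    df.insert(0, "Pos", range(1, len(pwm) + 1))
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="index")
    raise TypeError(f"not JSON serialisable: {type(o)}")
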