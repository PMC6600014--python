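"""Generate the synthetic study and write every pipeline input to disk.

Outputs under results/data/: count matrix + design (TSV), annotation
(GFF3), 3' UTRs (FASTA), per-site pileups (TSV), intron/exon counts
(TSV), the qPCR Cp panel (CSV) and the planted truth (JSON).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _shared import CONFIG, RESULTS, study_dataset

from dparkit import io as dio
from dparkit import synthetic_data as sd


def main():
    out = RESULTS / "data"
    out.mkdir(parents=True, exist_ok=True)
    cfg, cm, design, truth, annotation, utr = study_dataset()

    dio.write_count_matrix(cm, out / "counts.tsv", out / "design.tsv")
    dio.write_gff3(annotation, out / "annotation.gff3")
    dio.write_fasta(utr, out / "utr3.fa")

    pileup = sd.simulate_pileup(cfg, annotation, truth)
    dio.write_pileup(pileup, out / "pileup.tsv")

    iec = sd.simulate_intron_counts(cfg, annotation, truth)
    dio.write_counts(iec.intronic, out / "intronic_counts.tsv")
    dio.write_counts(iec.exonic, out / "exonic_counts.tsv")

    cp_table, qtruth = sd.simulate_qpcr(cfg)
    dio.write_cp_table(cp_table, out / "qpcr_cp.csv")

    dio.write_json(
        {
            "gene_classes": truth.gene_classes,
            "planted_logfc": truth.planted_logfc,
            "qpcr_fold": qtruth.qpcr_fold,
        },
        out / "truth.json",
    )
    counts = truth.gene_classes.value_counts().to_dict()
    print(f"simulated {cfg.n_genes} genes x {len(design.samples)} samples; "
          f"planted classes: {counts}")
    print(f"{len(pileup)} pileup rows over {cfg.n_edit_sites} edit + "
          f"{cfg.n_background_sites} background sites; "
          f"{cfg.n_intron_changed} intron-effect genes; "
          f"{cfg.n_assays}-assay qPCR panel")


if __name__ == "__main__":
    main()
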