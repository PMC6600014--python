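"""Quantify intron retention, test the diet x fraction interaction, scan PTCs.

Reports global intron percentages per group with the two-way interaction
test, fits the per-gene retention-ratio interaction model with BH
correction, classifies changed genes, and demonstrates the PTC scan on
the three canonical retained-intron outcomes (frameshift PTC, in-frame
insertion, in-frame single PTC).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _shared import RESULTS

from dparkit import intron_retention as ir
from dparkit import io as dio
from dparkit import synthetic_data as sd


def main():
    data = RESULTS / "data"
    design = dio.read_design(data / "design.tsv")
    intronic = dio.read_counts(data / "intronic_counts.tsv")
    exonic = dio.read_counts(data / "exonic_counts.tsv")
    iec = sd.IntronExonCounts(
        intronic, exonic, intronic.sum() + exonic.sum(), design
    )

    glob = ir.global_intron_fraction(iec)
    print("global intron % by group:",
          {f"{d}_{f}": round(v, 2) for (d, f), v in glob["group_means"].items()})
    print(f"diet x fraction interaction on global %: "
          f"estimate {glob['interaction_estimate']:.3f}, p = {glob['interaction_p']:.2g}")

    res = ir.retention_interaction_test(iec)
    res.to_csv(RESULTS / "intron_interaction.tsv", sep="\t")
    classes = ir.classify_retention_change(res)
    print(f"{len(res)} genes pass the 4-intronic-read floor; "
          f"retention classes: {classes.value_counts().to_dict()}")
    n_nominal = int((res["PValue"] < 0.05).sum())
    print(f"({n_nominal} genes nominally significant before BH; per-gene "
          f"retention power is limited at this sequencing depth — intronic "
          f"reads are ~2% of a gene's total)")

    demos = {
        "frameshift PTC": ("ATG", "TAAG", "AAAGGGTGA"),
        "in-frame insertion": ("ATGAAA", "GGGCCC", "TGA"),
        "in-frame single PTC": ("ATGAAA", "GGGTAAGGG", "AAATGA"),
    }
    for name, (e1, intron, e2) in demos.items():
        genome = e1 + intron + e2
        model = {"cds_exons": [(0, len(e1)), (len(e1) + len(intron), len(genome))],
                 "strand": "+"}
        out = ir.ptc_scan(model, (len(e1), len(e1) + len(intron)), genome)
        print(f"PTC scan [{name}]: PTC={out['has_ptc']}, "
              f"frame_preserved={out['frame_preserved']}, "
              f"first_stop_codon={out['first_stop_codon']}")


if __name__ == "__main__":
    main()
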