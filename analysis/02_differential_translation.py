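"""Normalise, filter, and run all four contrasts; classify regulation.

Reads the simulated counts written by 01, applies TMM + the CPM>=8
filter, estimates Cox-Reid dispersions, tests the transcriptional,
per-diet translation-state and DPAR contrasts, and cross-classifies
DPAR genes by transcriptional status.  Writes per-contrast tables and
the classification under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _shared import RESULTS

from dparkit import counts_pipeline as cp
from dparkit import differential_translation as dt
from dparkit import io as dio


def main():
    data = RESULTS / "data"
    cm = dio.read_count_matrix(data / "counts.tsv", data / "design.tsv")

    factors = cp.tmm_factors(cm.counts)
    cpm = cp.cpm_matrix(cm.counts, factors=factors)
    kept = cp.filter_quantifiable(cpm)
    cm_f = cp.CountMatrix(cm.counts.loc[kept], cm.design)
    print(f"{len(kept)} of {len(cm.genes)} genes quantifiable (mean CPM >= 8)")

    disp = dt.estimate_dispersions(cm_f, factors=factors)
    print(f"common dispersion {disp.common:.4f} "
          f"(tagwise median {disp.tagwise.median():.4f})")

    tables = dt.run_dpar_analysis(cm_f, dispersions=disp, factors=factors)
    for name, tbl in tables.items():
        tbl.to_csv(RESULTS / f"contrast_{name}.tsv", sep="\t")
        n_sig = len(dt.significant_set(tbl))
        print(f"contrast {name}: {n_sig} genes at |log2FC|>=1, FDR<0.05")

    classes = dt.classify_regulation(tables["transcription"], tables["dpar"])
    classes.to_csv(RESULTS / "regulation_classes.tsv", sep="\t")
    dpar_sets = classes["dpar_class"].value_counts().to_dict()
    status = (
        classes[classes["dpar_class"] != "unchanged"]["transcription_status"]
        .value_counts()
        .to_dict()
    )
    print(f"DPAR classes: {dpar_sets}; transcriptional status of DPAR genes: {status}")


if __name__ == "__main__":
    main()
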