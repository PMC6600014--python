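"""Regulatory-feature enrichment over the DPAR gene sets.

Fisher tests of operon membership, SL classes and conserved miRNA
targets among DPAR-promoted/-repressed genes vs all quantifiable genes;
PWM enrichment of the planted motif in promoted 3' UTRs; and the
Table-1-style UTR length / GC / folding-energy characterisation.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import CONFIG, RESULTS

from dparkit import io as dio
from dparkit import regulatory_features as rf


def main():
    data = RESULTS / "data"
    annotation = dio.read_gff3(data / "annotation.gff3")
    utr = dio.read_fasta(data / "utr3.fa")
    classes = pd.read_csv(RESULTS / "regulation_classes.tsv", sep="\t", index_col=0)
    dpar_tbl = pd.read_csv(RESULTS / "contrast_dpar.tsv", sep="\t", index_col=0)

    background = list(dpar_tbl.index)
    promoted = list(classes.index[classes["dpar_class"] == "promoted"])
    repressed = list(classes.index[classes["dpar_class"] == "repressed"])

    operonic = set(annotation.genes.index[annotation.genes["operon"].notna()])
    for name, target in (("promoted", promoted), ("repressed", repressed)):
        res, props = rf.fisher_feature_enrichment(target, operonic, background)
        print(f"operon membership, {name}: {100 * props['target_proportion']:.0f}% vs "
              f"{100 * props['background_proportion']:.0f}% background "
              f"(Fisher p = {res.p_value:.3g})")

    for sl in ("SL1", "SL2"):
        members = set(annotation.genes.index[annotation.genes["sl_class"] == sl])
        res, props = rf.fisher_feature_enrichment(promoted, members, background)
        print(f"{sl} trans-splicing, promoted: {100 * props['target_proportion']:.0f}% vs "
              f"{100 * props['background_proportion']:.0f}% (p = {res.p_value:.3g})")

    # planted 3'UTR motif: scan promoted genes (which overlap the planted
    # target list only by chance) and the actual planted targets as control
    pwm_mat = np.full((7, 4), 0.03)
    for i, b in enumerate("UGUAAAU"):
        pwm_mat[i, "ACGU".index(b)] = 0.91
    pwm = rf.PWM("planted", "synthetic-RBP", pwm_mat)
    targets = annotation.genes.index[
        annotation.genes.index.isin(utr) & annotation.genes.index.isin(background)
    ]
    motif_genes = [
        g for g in targets if CONFIG.planted_motif.replace("U", "T") in utr[g]
    ][:60]
    bg_utrs = {g: utr[g] for g in targets}
    res = rf.motif_enrichment({g: utr[g] for g in motif_genes}, bg_utrs, pwm)
    print(f"planted motif in carrier UTRs: enrichment p = {res.p_value:.3g} "
          f"(affinity ratio {res.estimate:.2f})")

    # folding the full background is the slow step; a 400-gene random
    # subsample gives the universe means to well under the set differences
    rng = np.random.default_rng(0)
    universe = list(rng.choice(background, size=min(400, len(background)), replace=False))
    sets = {"all": universe, "promoted": promoted, "repressed": repressed}
    table = rf.utr_feature_table(utr, sets)
    table.to_csv(RESULTS / "utr_features.tsv", sep="\t")
    print(table[["n", "mean_length", "mean_gc", "mean_mfe"]].round(3))


if __name__ == "__main__":
    main()
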