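"""Call A-to-I editing sites, form consensus, and relate editing to DPAR.

Applies the 5-read / 10% per-replicate filters and the 3-of-4 replicate
consensus, summarises site counts and frequencies per group and region,
and correlates each edited gene's DR editing change with its DPAR
log2FC, separately for CDS and 3' UTR edits.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import RESULTS

from dparkit import io as dio
from dparkit import rna_editing as red


def main():
    data = RESULTS / "data"
    pileup = dio.read_pileup(data / "pileup.tsv")
    annotation = dio.read_gff3(data / "annotation.gff3")
    design = dio.read_design(data / "design.tsv")

    calls = red.call_edit_sites(pileup, annotation)
    consensus = red.consensus_sites(calls, design)
    dio.write_edit_sites_bed(consensus, RESULTS / "edit_sites.bed")

    summary = red.editing_group_summary(consensus, calls, design)
    print(f"{len(consensus)} consensus sites "
          f"(of {pileup.groupby(['chrom', 'pos']).ngroups} piled-up positions)")
    print(f"mean called sites per replicate by group: "
          f"{summary['mean_site_count'].round(1).to_dict()}")
    print(f"mean editing frequency by group: "
          f"{summary['mean_frequency'].round(3).to_dict()}")
    print(f"region composition (%): {summary['region_percent'].round(1).to_dict()}")
    venn = red.venn_counts(consensus)
    print(f"sites present in all four groups: "
          f"{venn.get('AL_TO&AL_TR&DR_TO&DR_TR', 0)}")

    dpar = pd.read_csv(RESULTS / "contrast_dpar.tsv", sep="\t", index_col=0)
    corr = red.editing_vs_translation(consensus, dpar)
    for region, res in corr.items():
        if res is None:
            print(f"{region}: too few edited genes for a correlation")
        else:
            print(f"{region}: Spearman rho = {res.statistic:.3f} "
                  f"(p = {res.p_value:.2g}) for editing change vs DPAR")


if __name__ == "__main__":
    main()
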