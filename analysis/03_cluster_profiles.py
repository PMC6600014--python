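"""Cluster the DR-only translationally regulated genes on their profiles.

Genes with a significant two-fold translation-state change under DR but
not AL are mean-centred on their four group-mean log2 CPM values and
clustered with PAM; k is chosen by the silhouette cutoff and the PCA
variance of the profile space is reported.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import RESULTS

from dparkit import counts_pipeline as cp
from dparkit import differential_translation as dt
from dparkit import io as dio
from dparkit import profile_clustering as pcl


def main():
    data = RESULTS / "data"
    cm = dio.read_count_matrix(data / "counts.tsv", data / "design.tsv")
    tr_al = pd.read_csv(RESULTS / "contrast_translation_AL.tsv", sep="\t", index_col=0)
    tr_dr = pd.read_csv(RESULTS / "contrast_translation_DR.tsv", sep="\t", index_col=0)

    dr_only = dt.significant_set(tr_dr).difference(dt.significant_set(tr_al))
    print(f"{len(dr_only)} genes translationally regulated under DR only")

    factors = cp.tmm_factors(cm.counts)
    log_cpm = cp.cpm_matrix(cm.counts, factors=factors, log=True)
    group_means = log_cpm.T.groupby(cm.design.group_of()).mean().T
    profiles = pcl.center_profiles(group_means.loc[dr_only])

    k, diagnostics = pcl.select_k(profiles.values, k_max=8)
    medoids, labels = pcl.pam_cluster(profiles.values, k)
    _, cluster_sil = pcl.silhouette_widths(profiles.values, labels)
    var_frac = pcl.pca_variance(profiles.values)

    out = profiles.copy()
    out["cluster"] = labels + 1
    out.to_csv(RESULTS / "profile_clusters.tsv", sep="\t")
    diagnostics.to_csv(RESULTS / "cluster_selection.tsv", sep="\t", index=False)

    print(f"selected k = {k}; cluster mean silhouettes: "
          f"{cluster_sil.round(3).to_dict()}")
    print(f"cluster sizes: {pd.Series(labels).value_counts().sort_index().to_dict()}")
    print(f"first two PCs hold {100 * var_frac[:2].sum():.1f}% of profile variance")
    for c in range(k):
        centroid = profiles.values[labels == c].mean(axis=0).round(2)
        print(f"  cluster {c + 1} centroid (AL_TO, AL_TR, DR_TO, DR_TR): {centroid}")


if __name__ == "__main__":
    main()
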