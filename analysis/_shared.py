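"""Shared configuration for the analysis drivers.

One synthetic study is generated with planted truth and analysed end to
end by the numbered scripts; every script loads the same dataset through
:func:`study_dataset` and writes its tables under ``results/``.
"""

from pathlib import Path

from dparkit import synthetic_data as sd

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 8301

#: the study conditions: 4-group x 4-replicate NB design with planted
#: transcriptional, DPAR and opposing regulation, editing sites, intron
#: effects and a qPCR panel
CONFIG = sd.SimConfig(
    n_genes=3000,
    baseline_mu=300.0,
    frac_transcriptional_up=0.03,
    frac_transcriptional_down=0.05,
    frac_dpar_promoted=0.05,
    frac_dpar_repressed=0.03,
    frac_opposing=0.04,
    n_edit_sites=120,
    n_background_sites=40,
    edit_coverage=150.0,
    n_intron_changed=60,
    planted_motif="UGUAAAU",
    n_motif_targets=80,
    n_mirna_targets=100,
    seed=SEED,
)


def study_dataset():
    cm, design, truth = sd.simulate_counts(CONFIG)
    annotation, utr = sd.simulate_annotation(CONFIG)
    return CONFIG, cm, design, truth, annotation, utr
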