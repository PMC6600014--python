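import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dparkit import synthetic_data as sd


@pytest.fixture(scope="session")
def small_sim():
    """300-gene simulation with planted DPAR and transcriptional effects."""
    cfg = sd.SimConfig(
        n_genes=300,
        frac_dpar_promoted=0.10,
        frac_transcriptional_down=0.10,
        baseline_mu=500.0,
        seed=101,
    )
    cm, design, truth = sd.simulate_counts(cfg)
    return cfg, cm, design, truth


@pytest.fixture(scope="session")
def annotation_sim():
    """400-gene annotation with operons, SL classes, UTRs and edit sites."""
    cfg = sd.SimConfig(
        n_genes=400,
        n_edit_sites=60,
        n_background_sites=20,
        planted_motif="UGUAAAU",
        n_motif_targets=50,
        n_mirna_targets=40,
        seed=202,
    )
    ann, utr = sd.simulate_annotation(cfg)
    return cfg, ann, utr


@pytest.fixture(scope="session")
def qpcr_tables():
    cfg = sd.SimConfig(seed=303)
    cp, truth = sd.simulate_qpcr(cfg)
    return cfg, cp, truth
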