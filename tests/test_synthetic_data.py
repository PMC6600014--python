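"""Generator contracts: determinism, bookkeeping, and planted-effect fidelity."""

import numpy as np
import pandas as pd
import pytest

from dparkit import GROUPS
from dparkit import synthetic_data as sd


class TestSimConfig:
    def test_class_proportions_must_sum_below_one(self):
        with pytest.raises(ValueError):
            sd.SimConfig(frac_dpar_promoted=0.6, frac_transcriptional_up=0.5)

    def test_invalid_reps_and_dispersion(self):
        with pytest.raises(ValueError):
            sd.SimConfig(n_reps=1)
        with pytest.raises(ValueError):
            sd.SimConfig(dispersion=-0.1)


class TestSimulateCounts:
    def test_same_seed_bit_identical(self):
        cfg = sd.SimConfig(n_genes=100, frac_dpar_promoted=0.1, seed=7)
        a = sd.simulate_counts(cfg)[0].counts
        b = sd.simulate_counts(cfg)[0].counts
        assert a.equals(b)

    def test_no_effects_all_null(self):
        cfg = sd.SimConfig(n_genes=50, dispersion=0.0, effect_log2fc=0.0, seed=1)
        _, _, truth = sd.simulate_counts(cfg)
        assert (truth.gene_classes == "null").all()
        assert (truth.planted_logfc == 0).all().all()

    def test_truth_bookkeeping_counts(self):
        cfg = sd.SimConfig(n_genes=1000, frac_dpar_promoted=0.1, seed=2)
        _, _, truth = sd.simulate_counts(cfg)
        assert (truth.gene_classes == "dpar_promoted").sum() == 100
        planted = truth.planted_logfc.loc[truth.gene_classes == "dpar_promoted"]
        assert (planted["dpar"] == 2.0).all()
        assert (planted["transcription"] == 0.0).all()

    def test_nb_mean_variance_relation(self):
        """Across-replicate moments match NB: var ~ mu + phi mu^2."""
        cfg = sd.SimConfig(
            n_genes=4000, baseline_mu=300, gene_sigma=0.0, depth_sigma=0.0,
            dispersion=0.2, seed=3,
        )
        cm, design, _ = sd.simulate_counts(cfg)
        cols = design.samples_in("AL_TO")
        x = cm.counts[cols].values
        mu = x.mean()
        implied_phi = (x.var(ddof=1, axis=1).mean() - mu) / mu**2
        assert implied_phi == pytest.approx(0.2, abs=0.03)

    def test_effect_recovery_from_group_means(self):
        """Planted log2FCs re-derivable from group means to within 0.1."""
        cfg = sd.SimConfig(
            n_genes=200, n_reps=60, baseline_mu=1000, dispersion=0.05,
            frac_dpar_promoted=0.25, frac_transcriptional_down=0.25,
            depth_sigma=0.0, seed=4,
        )
        cm, design, truth = sd.simulate_counts(cfg)
        gm = {g: cm.counts[design.samples_in(g)].mean(axis=1) for g in GROUPS}
        dpar_est = np.log2(
            (gm["DR_TR"] / gm["DR_TO"]) / (gm["AL_TR"] / gm["AL_TO"])
        )
        promoted = truth.gene_classes == "dpar_promoted"
        assert dpar_est[promoted].mean() == pytest.approx(2.0, abs=0.1)
        assert dpar_est[truth.gene_classes == "null"].mean() == pytest.approx(0.0, abs=0.1)

    def test_opposing_class_carries_both_effects(self):
        cfg = sd.SimConfig(n_genes=200, frac_opposing=0.1, seed=5)
        _, _, truth = sd.simulate_counts(cfg)
        opp = truth.planted_logfc.loc[truth.gene_classes == "opposing"]
        assert (opp["transcription"] == -2.0).all() and (opp["dpar"] == 2.0).all()


class TestSimulateAnnotation:
    def test_operon_fraction_and_positions(self, annotation_sim):
        cfg, ann, _ = annotation_sim
        n_operonic = ann.genes["operon"].notna().sum()
        assert n_operonic == pytest.approx(0.18 * cfg.n_genes, rel=0.15)
        in_op = ann.genes[ann.genes["operon"].notna()]
        assert (in_op.groupby("operon")["operon_pos"].min() == 1).all()

    def test_sl2_only_downstream_in_operons(self, annotation_sim):
        _, ann, _ = annotation_sim
        sl2 = ann.genes[ann.genes["sl_class"] == "SL2"]
        assert (sl2["operon_pos"] > 1).all()

    def test_sl1_fraction_near_target(self, annotation_sim):
        cfg, ann, _ = annotation_sim
        frac = (ann.genes["sl_class"] == "SL1").mean()
        assert frac == pytest.approx(cfg.sl1_fraction, abs=0.06)

    def test_utr_floor_respected(self, annotation_sim):
        _, _, utr = annotation_sim
        assert min(len(s) for s in utr.values()) >= 12

    def test_planted_motif_present_verbatim(self, annotation_sim):
        cfg, ann, utr = annotation_sim
        targets = ann.genes.index[ann.genes["motif_target"]]
        assert len(targets) == cfg.n_motif_targets
        motif = cfg.planted_motif.replace("U", "T")
        assert all(motif in utr[g] for g in targets)

    def test_mirna_targets_include_conserved_and_decoys(self, annotation_sim):
        cfg, ann, _ = annotation_sim
        t = ann.mirna_targets
        assert (t["pct"] > 0.8).sum() == cfg.n_mirna_targets

    def test_deterministic(self):
        cfg = sd.SimConfig(n_genes=50, seed=9)
        a, _ = sd.simulate_annotation(cfg)
        b, _ = sd.simulate_annotation(cfg)
        assert a.genes.equals(b.genes) and a.utr3 == b.utr3


class TestSimulatePileup:
    def test_planted_frequency_recovered(self):
        cfg = sd.SimConfig(
            n_genes=100, n_edit_sites=40, edit_coverage=400.0, error_rate=0.0,
            edit_active_prob={g: (1.0 if g == "DR_TO" else 0.0) for g in GROUPS},
            edit_frequency={g: 0.30 for g in GROUPS},
            seed=11,
        )
        ann, _ = sd.simulate_annotation(cfg)
        truth = sd.SimTruth()
        pile = sd.simulate_pileup(cfg, ann, truth)
        plan = truth.edit_sites.set_index("site")
        design = sd._make_design(cfg.n_reps)
        group_of = design.group_of()
        pile = pile.assign(group=pile["sample"].map(group_of))
        dr_to = pile[pile["group"] == "DR_TO"]
        plus = dr_to[dr_to["strand"] == "+"]
        freq = (plus["nG"] / (plus["nA"] + plus["nG"])).mean()
        expected = plan.loc[plan["strand"] == "+", "freq_DR_TO"].mean()
        assert freq == pytest.approx(expected, abs=0.02)
        # inactive groups carry no edited reads at zero error rate
        al = pile[(pile["group"] == "AL_TO") & (pile["strand"] == "+")]
        assert (al["nG"] == 0).all()

    def test_minus_strand_reported_as_t_to_c(self):
        cfg = sd.SimConfig(n_genes=100, n_edit_sites=30, seed=12)
        ann, _ = sd.simulate_annotation(cfg)
        truth = sd.SimTruth()
        pile = sd.simulate_pileup(cfg, ann, truth)
        minus = pile[pile["strand"] == "-"]
        assert (minus["ref"] == "T").all()
        active = minus[minus["nC"] >= 5]
        assert len(active) > 0  # edits appear as C on the reference strand

    def test_site_outside_gene_rejected(self):
        cfg = sd.SimConfig(n_genes=10, seed=13)
        ann, _ = sd.simulate_annotation(cfg)
        bad_plan = pd.DataFrame(
            [{"site": "x", "chrom": "chrS", "pos": 1, "gene": "g00000",
              "region": "CDS", "strand": "+",
              **{f"freq_{g}": 0.0 for g in GROUPS}}]
        )
        with pytest.raises(ValueError):
            sd.simulate_pileup(cfg, ann, sd.SimTruth(), plan=bad_plan)


class TestSimulateIntronCounts:
    def test_global_fractions_match_targets(self):
        cfg = sd.SimConfig(n_genes=2000, seed=14)
        ann, _ = sd.simulate_annotation(cfg)
        truth = sd.SimTruth()
        iec = sd.simulate_intron_counts(cfg, ann, truth)
        design = iec.design
        for g, target in cfg.intron_fractions.items():
            cols = design.samples_in(g)
            frac = iec.intronic[cols].values.sum() / (
                iec.intronic[cols].values.sum() + iec.exonic[cols].values.sum()
            )
            assert frac == pytest.approx(target, rel=0.12)

    def test_truth_interaction_includes_baseline(self):
        cfg = sd.SimConfig(n_genes=50, n_intron_changed=10, seed=15)
        ann, _ = sd.simulate_annotation(cfg)
        truth = sd.SimTruth()
        sd.simulate_intron_counts(cfg, ann, truth)
        eff = truth.intron_effects
        assert np.allclose(
            eff["true_interaction"], eff["planted_log2"] + eff["baseline_log2"]
        )
        assert (eff["planted_log2"] != 0).sum() == 10

    def test_balanced_fractions_have_zero_baseline(self):
        f = sd.balanced_intron_fractions()
        r = {g: v / (1 - v) for g, v in f.items()}
        assert np.log2((r["DR_TR"] / r["DR_TO"]) / (r["AL_TR"] / r["AL_TO"])) == pytest.approx(0.0)


class TestSimulateQpcr:
    def test_noiseless_fold_change_exact_delta_cp(self):
        cfg = sd.SimConfig(qpcr_sigma=0.0, qpcr_fold_changes={"assay01": 4.0}, seed=16)
        cp, truth = sd.simulate_qpcr(cfg)
        piv = cp.pivot_table(index="assay", columns="condition", values="Cp")
        dcp = piv["DR"] - piv["AL"]
        assert dcp["assay01"] == pytest.approx(-2.0)
        assert np.allclose(dcp.drop("assay01"), 0.0)

    def test_needs_two_conditions(self):
        with pytest.raises(ValueError):
            sd.simulate_qpcr(sd.SimConfig(seed=1), conditions=("AL",))


class TestSimulateProfiles:
    def test_rows_mean_centred_and_deterministic(self):
        X, labels = sd.simulate_profiles(50, seed=17)
        assert np.allclose(X.values.sum(axis=1), 0.0, atol=1e-12)
        Y, _ = sd.simulate_profiles(50, seed=17)
        assert X.equals(Y)
        assert set(labels.unique()) == set(sd.PROFILE_ARCHETYPES)
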