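"""NB-GLM engine: saturated-model identities, dispersion recovery, contrasts."""

import numpy as np
import pandas as pd
import pytest

from dparkit import counts_pipeline as cp
from dparkit import differential_translation as dt
from dparkit import synthetic_data as sd


def _design(n_reps=4):
    return sd._make_design(n_reps)


class TestFitNbGlm:
    def test_equal_group_means_zero_effects(self):
        design = _design()
        X = dt.build_design_matrix(design)
        y = np.full(16, 100.0)
        fit = dt.fit_nb_glm(y, X.values, 0.1, np.zeros(16))
        assert np.allclose(fit["coef"][1:], 0.0, atol=1e-6)

    def test_halved_dr_to_closed_form(self):
        """Saturated 2x2: halving DR_TO gives diet -log2 and interaction +log2."""
        design = _design()
        X = dt.build_design_matrix(design)
        groups = design.group_of()
        y = np.array([50.0 if groups[s] == "DR_TO" else 100.0 for s in design.samples])
        fit = dt.fit_nb_glm(y, X.values, 0.05, np.zeros(16))
        assert fit["coef"][1] == pytest.approx(-np.log(2), abs=1e-6)
        assert fit["coef"][3] == pytest.approx(np.log(2), abs=1e-6)
        assert fit["coef"][2] == pytest.approx(0.0, abs=1e-6)

    def test_saturated_fit_reproduces_group_means(self, small_sim):
        """With equal offsets per group the NB score equations force the
        fitted mean of each design cell to equal its observed mean."""
        _, cm, design, _ = small_sim
        X = dt.build_design_matrix(design)
        groups = design.group_of()
        for gene in cm.genes[:20]:
            y = cm.counts.loc[gene].values.astype(float)
            fit = dt.fit_nb_glm(y, X.values, 0.1, np.zeros(len(y)))
            if not fit["converged"]:
                continue
            for g in ("AL_TO", "DR_TR"):
                cols = [i for i, s in enumerate(design.samples) if groups[s] == g]
                assert y[cols].mean() == pytest.approx(fit["mu"][cols].mean(), rel=1e-5)

    def test_all_zero_gene_rejected(self):
        design = _design()
        X = dt.build_design_matrix(design)
        with pytest.raises(ValueError):
            dt.fit_nb_glm(np.zeros(16), X.values, 0.1, np.zeros(16))


class TestDispersions:
    def test_poisson_counts_give_near_zero_phi(self):
        cfg = sd.SimConfig(n_genes=2000, dispersion=0.0, seed=21)
        cm, _, _ = sd.simulate_counts(cfg)
        est = dt.estimate_dispersions(cm)
        assert est.common <= 0.01

    def test_recovers_planted_dispersion(self):
        cfg = sd.SimConfig(n_genes=2000, dispersion=0.1, seed=22)
        cm, _, _ = sd.simulate_counts(cfg)
        est = dt.estimate_dispersions(cm)
        assert 0.08 <= est.common <= 0.12

    def test_stronger_prior_shrinks_tagwise_spread(self):
        cfg = sd.SimConfig(n_genes=400, dispersion=0.1, seed=23)
        cm, _, _ = sd.simulate_counts(cfg)
        loose = dt.estimate_dispersions(cm, prior_df=2.0)
        tight = dt.estimate_dispersions(cm, prior_df=50.0)
        assert tight.tagwise.var() < loose.tagwise.var()


class TestContrasts:
    def test_contrast_algebra_exact(self, small_sim):
        """DPAR logFC equals translation_DR minus translation_AL exactly."""
        _, cm, design, _ = small_sim
        factors = cp.tmm_factors(cm.counts)
        res = {
            name: dt.test_contrast(cm, 0.1, name, factors=factors)
            for name in ("dpar", "translation_AL", "translation_DR")
        }
        diff = res["translation_DR"]["logFC"] - res["translation_AL"]["logFC"]
        assert np.allclose(res["dpar"]["logFC"], diff, atol=1e-8)

    def test_dpar_invariant_to_dr_depth(self, small_sim):
        """Scaling all DR libraries 10x leaves DPAR estimates unchanged."""
        _, cm, design, _ = small_sim
        scaled = cm.counts.copy()
        dr_cols = [s for s in design.samples if s.startswith("DR")]
        scaled[dr_cols] = (scaled[dr_cols] * 10).astype(int)
        cm2 = cp.CountMatrix(scaled, design)
        a = dt.test_contrast(cm, 0.1, "dpar")
        b = dt.test_contrast(cm2, 0.1, "dpar")
        assert np.allclose(a["logFC"], b["logFC"], atol=0.02)

    def test_planted_dpar_recovered(self, small_sim):
        _, cm, design, truth = small_sim
        factors = cp.tmm_factors(cm.counts)
        disp = dt.estimate_dispersions(cm, factors=factors)
        res = dt.test_contrast(cm, disp, "dpar", factors=factors)
        promoted = truth.gene_classes == "dpar_promoted"
        assert res.loc[promoted.values, "logFC"].mean() == pytest.approx(2.0, abs=0.2)

    def test_bad_contrast_rejected(self, small_sim):
        _, cm, _, _ = small_sim
        with pytest.raises(ValueError):
            dt.test_contrast(cm, 0.1, [0.0, 0.0, 0.0, 0.0])


class TestClassification:
    def _tables(self, rows):
        """rows: gene -> (dpar_lfc, dpar_fdr, tx_lfc, tx_fdr)"""
        idx = list(rows)
        dpar = pd.DataFrame(
            {
                "logFC": [rows[g][0] for g in idx],
                "FDR": [rows[g][1] for g in idx],
                "converged": True,
            },
            index=idx,
        )
        tx = pd.DataFrame(
            {
                "logFC": [rows[g][2] for g in idx],
                "FDR": [rows[g][3] for g in idx],
                "converged": True,
            },
            index=idx,
        )
        return tx, dpar

    def test_rule_application(self):
        tx, dpar = self._tables(
            {
                "opposite": (1.5, 0.01, -1.2, 0.01),
                "same": (1.5, 0.01, 1.2, 0.01),
                "ns": (1.5, 0.01, 1.2, 0.20),
                "weak": (0.5, 0.01, 1.2, 0.01),
            }
        )
        out = dt.classify_regulation(tx, dpar)
        assert out.loc["opposite", "dpar_class"] == "promoted"
        assert out.loc["opposite", "transcription_status"] == "opposite"
        assert out.loc["same", "transcription_status"] == "same_direction"
        assert out.loc["ns", "transcription_status"] == "not_significant"
        assert out.loc["weak", "dpar_class"] == "unchanged"

    def test_universe_mismatch_rejected(self):
        tx, dpar = self._tables({"a": (1.5, 0.01, 0.0, 0.9)})
        with pytest.raises(ValueError):
            dt.classify_regulation(tx.rename(index={"a": "b"}), dpar)

    def test_per_class_recall_at_high_depth(self):
        """Effects of size 2 at mu=500: every class recalled at >= 0.9."""
        cfg = sd.SimConfig(
            n_genes=3000, baseline_mu=500,
            frac_dpar_promoted=0.1, frac_transcriptional_down=0.1, seed=24,
        )
        cm, design, truth = sd.simulate_counts(cfg)
        factors = cp.tmm_factors(cm.counts)
        disp = dt.estimate_dispersions(cm, factors=factors)
        dpar = dt.test_contrast(cm, disp, "dpar", factors=factors)
        tx = dt.test_contrast(cm, disp, "transcription", factors=factors)
        from dparkit.experiments import _predicted_class

        pred = _predicted_class(tx, dpar)
        for cls in ("null", "dpar_promoted", "transcriptional_down"):
            mask = truth.gene_classes == cls
            assert (pred[mask.values] == cls).mean() >= 0.9, cls
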