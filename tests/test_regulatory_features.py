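"""Feature enrichment, PWM scanning, UTR characterisation, folding proxy."""

import numpy as np
import pandas as pd
import pytest

import oracles
from dparkit import regulatory_features as rf
from dparkit import stats_core as sc


def _pwm_from_consensus(consensus, p=0.91):
    idx = {b: i for i, b in enumerate("ACGU")}
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, idx[b]] = p
    return rf.PWM("m1", "RBP-1", mat)


class TestFisherFeatureEnrichment:
    def test_equal_proportions_p_near_one(self):
        background = [f"g{i}" for i in range(200)]
        members = background[::2]
        target = background[:40]  # also 50% members
        res, props = rf.fisher_feature_enrichment(target, members, background)
        assert res.p_value > 0.8
        assert props["target_proportion"] == pytest.approx(0.5)

    def test_planted_enrichment_strongly_significant(self):
        """50% membership in 100 targets vs 18% across 8,000 genes."""
        background = [f"g{i}" for i in range(8000)]
        members = background[:1440] + background[7900:7950]  # 18% overall-ish
        target = background[7900:8000]  # 50 members of 100
        res, props = rf.fisher_feature_enrichment(target, members, background)
        assert res.p_value < 0.001
        assert props["target_proportion"] == pytest.approx(0.5)

    def test_delegates_to_stats_core(self):
        background = [f"g{i}" for i in range(50)]
        members = background[:20]
        target = background[10:25]
        res, props = rf.fisher_feature_enrichment(target, members, background)
        direct = sc.fisher_exact_2x2(props["table"])
        assert res.p_value == direct.p_value

    def test_mirna_mode_filters_on_pct(self):
        background = ["a", "b", "c", "d"]
        pct = pd.DataFrame({"gene": ["a", "b"], "pct": [0.9, 0.5]})
        _, props = rf.fisher_feature_enrichment(
            ["a", "b"], ["a", "b"], background, mirna_pct=pct
        )
        assert props["table"][0][0] == 1  # only the P_ct>0.8 target counts

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError):
            rf.fisher_feature_enrichment(["x"], [], ["a", "b"])


class TestPwmScan:
    def test_uniform_pwm_scores_zero(self):
        pwm = rf.PWM("u", "", np.full((5, 4), 0.25))
        mx, scores = rf.pwm_scan("ACGUACGUACGU", pwm)
        assert np.allclose(scores, 0.0) and mx == 0.0

    def test_consensus_window_closed_form(self):
        pwm = _pwm_from_consensus("UGUAAAU")
        seq = "CCCCUGUAAAUCCCC"
        expected = 7 * np.log2((0.91 + pwm.pseudocount) / (0.25 + pwm.pseudocount))
        mx, _ = rf.pwm_scan(seq, pwm)
        assert mx == pytest.approx(expected, abs=1e-9)

    def test_prepending_bases_never_lowers_max(self):
        pwm = _pwm_from_consensus("GGAAUU")
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=30))
            mx, _ = rf.pwm_scan(seq, pwm)
            mx2, _ = rf.pwm_scan("AAAA" + seq, pwm)
            assert mx2 >= mx - 1e-12

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            rf.pwm_scan("ACG", _pwm_from_consensus("UGUAAAU"))


class TestMotifEnrichment:
    def _utrs(self, rng, n, length=60, motif=None, frac=0.0):
        out = {}
        for i in range(n):
            seq = "".join(rng.choice(list("ACGU"), size=length))
            if motif and i < frac * n:
                at = int(rng.integers(0, length - len(motif)))
                seq = seq[:at] + motif + seq[at + len(motif):]
            out[f"g{i}"] = seq
        return out

    def test_planted_motif_detected(self):
        rng = np.random.default_rng(1)
        pwm = _pwm_from_consensus("UGUAAAU", p=0.97)
        bg = self._utrs(rng, 400, motif="UGUAAAU", frac=0.05)
        tgt = self._utrs(rng, 60, motif="UGUAAAU", frac=0.5)
        res = rf.motif_enrichment(tgt, bg, pwm)
        assert res.p_value < 0.01

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        pwm = _pwm_from_consensus("UGUAAAU", p=0.97)
        bg = self._utrs(rng, 500)
        hits = 0
        reps = 60
        for _ in range(reps):
            keys = rng.choice(list(bg), size=50, replace=False)
            res = rf.motif_enrichment({k: bg[k] for k in keys}, bg, pwm)
            hits += res.p_value < 0.05
        assert hits / reps <= 0.15  # Monte-Carlo band around the nominal 5%

    def test_duplicating_background_leaves_null_unchanged(self):
        rng = np.random.default_rng(3)
        pwm = _pwm_from_consensus("GGAAUU")
        bg = self._utrs(rng, 100)
        tgt = self._utrs(rng, 20)
        a = rf.motif_enrichment(tgt, bg, pwm)
        doubled = {**bg, **{k + "_dup": v for k, v in bg.items()}}
        b = rf.motif_enrichment(tgt, doubled, pwm)
        assert a.p_value == pytest.approx(b.p_value, rel=0.05)


class TestMfeProxy:
    def test_unfoldable_and_hairpin(self):
        assert rf.mfe_proxy("AAAAAA") == 0.0
        assert rf.mfe_proxy("GGGAAAACCC") == -9.0

    def test_t_u_equivalence(self):
        assert rf.mfe_proxy("GGGTAAACCC") == rf.mfe_proxy("GGGUAAACCC")

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            assert rf.mfe_proxy(seq) == pytest.approx(oracles.mfe_enumerate(seq), abs=1e-9)

    def test_concatenation_with_spacer_never_raises_energy(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGU"), size=10))
            b = "".join(rng.choice(list("ACGU"), size=10))
            joined = rf.mfe_proxy(a + "AAAA" + b)
            assert joined <= min(rf.mfe_proxy(a), rf.mfe_proxy(b)) + 1e-9

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            rf.mfe_proxy("ACGX")


class TestUtrFeatureTable:
    def test_gc_and_identical_sets(self):
        seqs = {f"g{i}": "ATGCATGCATGC" for i in range(30)}
        sets = {"all": list(seqs), "sub": list(seqs)[:15]}
        out = rf.utr_feature_table(seqs, sets)
        assert out.loc["sub", "mean_gc"] == pytest.approx(0.5)
        assert out.loc["sub", "p_length"] == pytest.approx(1.0)

    def test_planted_shorter_utrs_detected(self):
        rng = np.random.default_rng(6)
        seqs = {}
        for i in range(300):
            n = int(rng.integers(150, 220)) if i >= 60 else int(rng.integers(80, 130))
            seqs[f"g{i}"] = "".join(rng.choice(list("ACGU"), size=n))
        sets = {"all": list(seqs), "promoted": [f"g{i}" for i in range(60)]}
        out = rf.utr_feature_table(seqs, sets, mfe_values={g: 0.0 for g in seqs})
        assert out.loc["promoted", "mean_length"] < out.loc["all", "mean_length"]
        assert out.loc["promoted", "p_length"] < 1e-6


class TestSlSummary:
    def test_planted_class_ordering_and_bookkeeping(self, annotation_sim):
        cfg, ann, _ = annotation_sim
        rng = np.random.default_rng(7)
        sl = ann.genes["sl_class"]
        advantage = sl.map({"SL1": 0.5, "SL2": 0.4, "native": 0.0})
        lfc_al = pd.Series(
            advantage.values + rng.normal(0, 0.1, size=len(sl)), index=sl.index
        )
        out = rf.sl_translation_summary(ann.genes, {"AL": lfc_al})
        means = out["means"]
        assert means[("AL", "SL1")] > means[("AL", "native")]
        assert out["tests"][("AL", "SL1_vs_native")].p_value < 1e-6

    def test_unknown_class_rejected(self):
        genes = pd.DataFrame({"sl_class": ["SL9"]}, index=["g1"])
        with pytest.raises(ValueError):
            rf.sl_translation_summary(genes, {"AL": pd.Series({"g1": 0.0})})
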