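"""Intron counting, retention modelling and PTC scanning."""

import numpy as np
import pandas as pd
import pytest

import oracles
from dparkit import intron_retention as ir
from dparkit import synthetic_data as sd
from dparkit.counts_pipeline import SampleDesign


def _toy_annotation():
    """One 2-exon plus-strand gene: exons [0,100) and [150,250)."""
    genes = pd.DataFrame(
        [{"gene": "gA", "chrom": "chrS", "strand": "+", "start": 0, "end": 250,
          "cds_start": 0, "cds_end": 200, "utr3_start": 200, "utr3_end": 250,
          "operon": pd.NA, "operon_pos": 0, "sl_class": "SL1"}]
    ).set_index("gene")
    exons = pd.DataFrame([
        {"gene": "gA", "start": 0, "end": 100},
        {"gene": "gA", "start": 150, "end": 250},
    ])
    introns = pd.DataFrame([{"gene": "gA", "start": 100, "end": 150}])
    return sd.AnnotationSet(genes, exons, introns,
                            pd.DataFrame(columns=["gene", "family", "pct"]), {})


def _design2():
    rows = []
    for d in ("AL", "DR"):
        for f in ("TO", "TR"):
            for r in (1, 2):
                rows.append({"sample": f"{d}_{f}_r{r}", "diet": d, "fraction": f, "replicate": r})
    return SampleDesign(pd.DataFrame(rows))


class TestCountIntronExon:
    def test_read_classification(self):
        ann = _toy_annotation()
        design = _design2()
        reads = pd.DataFrame([
            {"chrom": "chrS", "start": 10, "end": 60, "sample": "AL_TO_r1"},   # exonic
            {"chrom": "chrS", "start": 90, "end": 120, "sample": "AL_TO_r1"},  # straddles -> intronic
            {"chrom": "chrS", "start": 110, "end": 130, "sample": "AL_TO_r1"}, # inside intron
            {"chrom": "chrS", "start": 300, "end": 350, "sample": "AL_TO_r1"}, # outside any gene
        ])
        out = ir.count_intron_exon(reads, ann, design)
        assert out.exonic.loc["gA", "AL_TO_r1"] == 1
        assert out.intronic.loc["gA", "AL_TO_r1"] == 2
        assert out.total_aligned["AL_TO_r1"] == 4

    def test_min_four_intronic_reads_rule(self):
        ann = _toy_annotation()
        design = _design2()
        reads = pd.DataFrame(
            [{"chrom": "chrS", "start": 110, "end": 120, "sample": "AL_TO_r1"}] * 3
        )
        out = ir.count_intron_exon(reads, ann, design)
        assert len(ir.quantifiable_genes(out)) == 0
        reads4 = pd.concat([reads] * 2, ignore_index=True).iloc[:4]
        out4 = ir.count_intron_exon(reads4, ann, design)
        assert list(ir.quantifiable_genes(out4)) == ["gA"]


class TestGlobalFraction:
    def test_direct_percentage(self):
        ann = _toy_annotation()
        design = _design2()
        intronic = pd.DataFrame(15, index=["gA"], columns=design.samples)
        exonic = pd.DataFrame(985, index=["gA"], columns=design.samples)
        iec = sd.IntronExonCounts(intronic, exonic, intronic.sum() + exonic.sum(), design)
        out = ir.global_intron_fraction(iec)
        assert np.allclose(out["per_sample_percent"], 1.5)

    def test_configured_group_levels_recovered(self):
        cfg = sd.SimConfig(n_genes=1500, seed=41)
        ann, _ = sd.simulate_annotation(cfg)
        iec = sd.simulate_intron_counts(cfg, ann, sd.SimTruth())
        out = ir.global_intron_fraction(iec)
        gm = out["group_means"]
        assert gm[("AL", "TO")] == pytest.approx(1.5, rel=0.15)
        assert gm[("DR", "TO")] == pytest.approx(2.2, rel=0.15)

    def test_zero_total_rejected(self):
        ann = _toy_annotation()
        design = _design2()
        z = pd.DataFrame(0, index=["gA"], columns=design.samples)
        iec = sd.IntronExonCounts(z, z, z.sum(), design)
        with pytest.raises(ValueError):
            ir.global_intron_fraction(iec)


class TestInteraction:
    def test_equal_ratios_zero_interaction(self):
        design = _design2()
        intronic = pd.DataFrame(
            [[20] * 8, [10] * 8], index=["gA", "gB"], columns=design.samples
        )
        exonic = pd.DataFrame(
            [[1000] * 8, [500] * 8], index=["gA", "gB"], columns=design.samples
        )
        iec = sd.IntronExonCounts(intronic, exonic, intronic.sum() + exonic.sum(), design)
        res = ir.retention_interaction_test(iec)
        assert np.allclose(res["interaction_log2"], 0.0, atol=1e-9)

    def test_planted_interaction_recovered(self):
        cfg = sd.SimConfig(
            n_genes=300, baseline_mu=3000, dispersion=0.01, n_intron_changed=30, seed=42
        )
        ann, _ = sd.simulate_annotation(cfg)
        truth = sd.SimTruth()
        iec = sd.simulate_intron_counts(cfg, ann, truth)
        res = ir.retention_interaction_test(iec)
        eff = truth.intron_effects
        changed = eff.index[eff["planted_log2"] > 0]
        est = res["interaction_log2"].reindex(changed)
        assert est.mean() == pytest.approx(eff.loc[changed, "true_interaction"].mean(), abs=0.2)
        assert (res["FDR"].reindex(changed) < 0.05).mean() >= 0.8

    def test_antisymmetric_under_diet_swap(self):
        design = _design2()
        rng = np.random.default_rng(43)
        intronic = pd.DataFrame(
            rng.poisson(30, size=(5, 8)), index=list("abcde"), columns=design.samples
        )
        exonic = pd.DataFrame(
            rng.poisson(1000, size=(5, 8)), index=list("abcde"), columns=design.samples
        )
        iec = sd.IntronExonCounts(intronic, exonic, intronic.sum() + exonic.sum(), design)
        res = ir.retention_interaction_test(iec)
        swapped_table = design.table.copy()
        swapped_table["diet"] = swapped_table["diet"].map({"AL": "DR", "DR": "AL"})
        iec2 = sd.IntronExonCounts(
            intronic, exonic, intronic.sum() + exonic.sum(), SampleDesign(swapped_table)
        )
        res2 = ir.retention_interaction_test(iec2)
        assert np.allclose(res["interaction_log2"], -res2["interaction_log2"], atol=1e-9)


class TestClassify:
    def test_fold_and_fdr_rules(self):
        res = pd.DataFrame(
            {"interaction_log2": [np.log2(2.5), np.log2(3.0), 0.2],
             "FDR": [0.01, 0.2, 0.01]},
            index=["up", "nsig", "small"],
        )
        cls = ir.classify_retention_change(res)
        assert cls["up"] == "increased"
        assert cls["nsig"] == "unchanged"
        assert cls["small"] == "unchanged"


class TestPtcScan:
    GENOME = None

    def _scan(self, exon1, intron, exon2):
        genome = exon1 + intron + exon2
        model = {"cds_exons": [(0, len(exon1)), (len(exon1) + len(intron), len(genome))],
                 "strand": "+"}
        return ir.ptc_scan(model, (len(exon1), len(exon1) + len(intron)), genome)

    def test_frameshift_intron_with_stop(self):
        out = self._scan("ATG", "TAAG", "AAATGA")
        assert out["has_ptc"] and not out["frame_preserved"]
        assert out["first_stop_codon"] == 1

    def test_in_frame_stop_free_intron_inserts_residues(self):
        out = self._scan("ATGAAA", "GGGCCC", "TGA")
        assert not out["has_ptc"] and out["frame_preserved"]
        assert out["inserted_residues"] == 2

    def test_in_frame_intron_with_stop_is_single_ptc(self):
        out = self._scan("ATGAAA", "GGGTAAGGG", "AAATGA")
        assert out["has_ptc"] and out["frame_preserved"]

    def test_utr_intron_no_coding_consequence(self):
        model = {"cds_exons": [(0, 6)], "strand": "+"}
        out = ir.ptc_scan(model, (10, 20), "ATGAAA" + "T" * 30)
        assert not out["coding"]

    def test_agrees_with_translation_oracle_on_random_models(self):
        rng = np.random.default_rng(44)
        bases = np.array(list("ACGT"))
        n_checked = 0
        for _ in range(500):
            e1 = "ATG" + "".join(rng.choice(bases, size=3 * int(rng.integers(2, 8))))
            e2 = "".join(rng.choice(bases, size=3 * int(rng.integers(2, 8)))) + "TGA"
            intron = "".join(rng.choice(bases, size=int(rng.integers(4, 15))))
            genome = e1 + intron + e2
            model = {"cds_exons": [(0, len(e1)), (len(e1) + len(intron), len(genome))],
                     "strand": "+"}
            out = ir.ptc_scan(model, (len(e1), len(e1) + len(intron)), genome)
            iso = e1 + intron + e2
            stop = oracles.translate_first_stop(iso)
            spliced_stop = oracles.translate_first_stop(e1 + e2)
            if spliced_stop is None:
                continue
            expected_last = spliced_stop + (
                len(intron) // 3 if len(intron) % 3 == 0 else 0
            )
            n_checked += 1
            assert out["first_stop_codon"] == stop
            assert out["has_ptc"] == (stop is not None and stop < expected_last)
            assert out["frame_preserved"] == (len(intron) % 3 == 0)
        assert n_checked >= 400
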