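"""Variant classification cascade: thresholds, mapping rules and properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lofburden as lb
from lofburden.filters import (DEFAULT_RECURRENT_GENES, FilterConfig, GeneModel,
                               brain_pext, classify_variant, frequency_filter,
                               loftee_filter, map_splice_to_exon, mnv_phase_filter,
                               qc_genotype, recurrent_gene_filter, truncated_fraction)


def call(**kw):
    base = dict(depth=40.0, genotype_quality=60.0, allelic_fraction=0.5,
                call_rate=0.99, autosomal=True)
    base.update(kw)
    return base


MODEL = GeneModel("GENE", 3000, [(1, 1000), (1001, 2000), (2001, 3000)],
                  np.array([[0.9, 0.2, 0.1] + [np.nan] * 10,
                            [0.05] * 13,
                            [1.0] * 13]))


def variant(**kw):
    base = dict(gene_id="GENE", consequence="LoF", loftee_flag="high_confidence",
                loftee_aux_flags="", ref_pop_af=0.0, sample_af=0.001,
                cds_position=500, exon_index=0, is_splice_site=False, splice_offset=0)
    base.update(kw)
    return base


class TestGenotypeQC:
    @pytest.mark.parametrize("kw,expected,reason", [
        (dict(depth=21, genotype_quality=30, allelic_fraction=0.5, call_rate=0.95), True, None),
        (dict(depth=20), False, "depth"),                      # strict >
        (dict(genotype_quality=29.9), False, "genotype_quality"),
        (dict(genotype_quality=30), True, None),               # inclusive >=
        (dict(call_rate=0.9), False, "call_rate"),             # strict >
        (dict(allelic_fraction=0.25), True, None),             # inclusive >=
        (dict(allelic_fraction=0.249), False, "allelic_fraction_low"),
        (dict(allelic_fraction=0.80), False, "allelic_fraction_high"),
        (dict(allelic_fraction=0.80, autosomal=False), True, None),  # cap is autosomal-only
        (dict(allelic_fraction=0.75), True, None),             # inclusive <=
        (dict(depth=np.nan), False, "missing_metric"),
    ])
    def test_thresholds(self, kw, expected, reason):
        ok, why = qc_genotype(call(**kw))
        assert ok is expected
        if not expected:
            assert why == reason

    def test_missing_metric_key(self):
        c = call()
        del c["depth"]
        assert qc_genotype(c) == (False, "missing_metric")


class TestFrequencyFilter:
    def test_absent_and_rare_passes_both_modes(self):
        assert frequency_filter(0.0, 0.001, "strict")
        assert frequency_filter(0.0, 0.001, "maf")

    def test_low_nonzero_reference_af_distinguishes_modes(self):
        assert not frequency_filter(0.005, 0.001, "strict")
        assert frequency_filter(0.005, 0.001, "maf")

    def test_common_in_sample_fails_both(self):
        assert not frequency_filter(0.0, 0.015, "strict")
        assert not frequency_filter(0.0, 0.015, "maf")


class TestRecurrentAndLoftee:
    def test_blocklisted_gene_fails(self):
        assert not recurrent_gene_filter("TTN")
        assert len(DEFAULT_RECURRENT_GENES) == 9

    def test_other_gene_passes(self):
        assert recurrent_gene_filter("SCN2A")

    def test_empty_blocklist_is_identity(self):
        assert recurrent_gene_filter("TTN", blocklist=())

    def test_loftee_rules(self):
        assert loftee_filter("high_confidence", "")
        assert not loftee_filter("low_confidence", "")
        assert not loftee_filter("high_confidence", "PHYLOCSF_WEAK")


class TestSpliceMapping:
    def test_upstream_of_exon_start_maps_to_start(self):
        assert map_splice_to_exon(1, -2, MODEL) == (1, 1001)

    def test_three_bp_is_inclusive(self):
        assert map_splice_to_exon(1, 3, MODEL) == (1, 2000)

    def test_four_bp_is_unmapped(self):
        assert map_splice_to_exon(1, 4, MODEL) is None
        assert map_splice_to_exon(1, -4, MODEL) is None


class TestBrainPext:
    def test_max_over_tissues(self):
        assert brain_pext(0, MODEL) == 0.9

    def test_all_zero_gives_zero(self):
        m = GeneModel("Z", 100, [(1, 100)], np.zeros((1, 13)))
        assert brain_pext(0, m) == 0.0

    def test_max_over_available_when_some_missing(self):
        # exon 0 has 10 of 13 tissues missing; the max uses the rest
        assert brain_pext(0, MODEL) == 0.9

    def test_all_missing_errors(self):
        m = GeneModel("Z", 100, [(1, 100)], np.full((1, 13), np.nan))
        with pytest.raises(ValueError, match="missing_pext"):
            brain_pext(0, m)


class TestTruncatedFraction:
    def test_arithmetic(self):
        assert truncated_fraction(300, 3000) == pytest.approx(0.9)

    def test_boundary_below_ten_percent(self):
        assert truncated_fraction(2701, 3000) == pytest.approx(0.099666, abs=1e-5)

    def test_position_at_end_gives_zero(self):
        assert truncated_fraction(3000, 3000) == 0.0

    def test_out_of_cds_errors(self):
        with pytest.raises(ValueError, match="position_out_of_cds"):
            truncated_fraction(3001, 3000)


class TestMnvPhase:
    def pairs(self, phase="in_phase", dist=1, joint="missense"):
        return pd.DataFrame([dict(variant_id="V0", partner_id="V9",
                                  distance_bp=dist, phase=phase,
                                  joint_consequence=joint)])

    def test_in_phase_rescue_drops_candidate(self):
        assert mnv_phase_filter(["V0"], self.pairs())["V0"] is False

    def test_isolated_variant_retained(self):
        assert mnv_phase_filter(["V0"], None)["V0"] is True

    def test_pair_outside_window_retained(self):
        assert mnv_phase_filter(["V0"], self.pairs(dist=3))["V0"] is True

    def test_out_of_phase_retained(self):
        assert mnv_phase_filter(["V0"], self.pairs(phase="out_of_phase"))["V0"] is True

    def test_unknown_phase_retained_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            kept = mnv_phase_filter(["V0"], self.pairs(phase="unknown"))
        assert kept["V0"] is True
        assert "unknown phase" in caplog.text

    def test_joint_still_lof_retained(self):
        assert mnv_phase_filter(["V0"], self.pairs(joint="LoF"))["V0"] is True


class TestClassifyVariant:
    def test_clean_lof_is_slof(self):
        vc = classify_variant(variant(), call(), MODEL)
        assert vc.label == "S_LOF" and vc.failed == ()

    def test_pext_boundary_is_strict(self):
        # exon 0 max pext 0.9 passes; force a 0.10 exon via custom model
        m = GeneModel("B", 1000, [(1, 1000)], np.full((1, 13), 0.10))
        vc = classify_variant(variant(gene_id="B", cds_position=100), call(), m)
        assert vc.label == "OTHER" and "pext" in vc.failed

    def test_truncation_boundary_is_strict(self):
        vc = classify_variant(variant(cds_position=2701, exon_index=2), call(), MODEL)
        assert "truncation" in vc.failed
        # exon 2 pext is 1.0 so truncation is the only failure
        assert vc.failed == ("truncation",)

    def test_synonymous_all_pass_is_ssyn(self):
        vc = classify_variant(variant(consequence="synonymous"), call(), MODEL)
        assert vc.label == "S_SYN"

    def test_synonymous_skips_loftee(self):
        vc = classify_variant(variant(consequence="synonymous", loftee_flag="low_confidence"),
                              call(), MODEL)
        assert vc.label == "S_SYN"

    def test_failure_reasons_accumulate(self):
        vc = classify_variant(
            variant(ref_pop_af=0.5, sample_af=0.5, loftee_flag="low_confidence",
                    cds_position=2950, exon_index=2),
            call(depth=5), MODEL)
        assert vc.label == "OTHER"
        assert set(vc.failed) == {"qc:depth", "frequency", "loftee", "truncation"}

    def test_unmapped_splice(self):
        vc = classify_variant(variant(is_splice_site=True, splice_offset=5, exon_index=0),
                              call(), MODEL)
        assert "unmapped_splice" in vc.failed

    def test_mapped_splice_uses_boundary_position(self):
        # exon 2 starts at CDS 2001: truncation 1-2001/3000 = 0.333 > 0.10
        vc = classify_variant(variant(is_splice_site=True, splice_offset=-2, exon_index=2,
                                      cds_position=2999), call(), MODEL)
        assert vc.label == "S_LOF"

    def test_monotone_in_pext_threshold(self, classified, small_cohort, gene_panel):
        variants = classified.drop(columns=["variant_class", "failed_filters"])
        models = {g.gene_id: GeneModel.from_gene_spec(g) for g in gene_panel}
        counts = []
        for pext_min in (0.0, 0.1, 0.5, 0.9):
            cl = lb.classify_table(variants, None, models, FilterConfig(pext_min=pext_min))
            counts.append((cl["variant_class"] == "S_LOF").sum())
        assert counts == sorted(counts, reverse=True)

    def test_subset_property(self, classified):
        slof = classified[classified["variant_class"] == "S_LOF"]
        ssyn = classified[classified["variant_class"] == "S_SYN"]
        assert (slof["consequence"] == "LoF").all()
        assert (ssyn["consequence"] == "synonymous").all()

    def test_purity_under_row_shuffle(self, classified, small_cohort, gene_panel, simulated):
        variants, _, calls = simulated
        models = {g.gene_id: GeneModel.from_gene_spec(g) for g in gene_panel}
        perm = np.random.default_rng(5).permutation(len(variants))
        shuffled = lb.classify_table(variants.iloc[perm].reset_index(drop=True),
                                     calls, models)
        merged = classified.set_index("variant_id")["variant_class"]
        shuffled = shuffled.set_index("variant_id")["variant_class"]
        pd.testing.assert_series_equal(merged.sort_index(), shuffled.sort_index())


@settings(derandomize=True, max_examples=60, deadline=None)
@given(pext=st.floats(0, 1), pos=st.integers(1, 3000))
def test_classification_against_rule_conjunction(pext, pos):
    """Property: S_LOF iff every individual filter passes, by direct re-evaluation."""
    m = GeneModel("P", 3000, [(1, 3000)], np.full((1, 13), pext))
    vc = classify_variant(variant(gene_id="P", cds_position=pos, exon_index=0), call(), m)
    should_pass = pext > 0.10 and (1 - pos / 3000) > 0.10
    assert (vc.label == "S_LOF") == should_pass


class TestCarrierMatrix:
    def test_no_qualifying_variants_all_zero(self, small_cohort):
        empty = pd.DataFrame(columns=["gene_id", "individual_id", "variant_id"])
        cm = lb.CarrierMatrix(empty, pd.Index(small_cohort["individual_id"]), ["G1"])
        assert cm.carrier_counts().sum() == 0

    def test_two_slofs_same_gene_count_once(self, small_cohort):
        iid = small_cohort["individual_id"].iloc[0]
        entries = pd.DataFrame([
            dict(gene_id="G1", individual_id=iid, variant_id="V1"),
            dict(gene_id="G1", individual_id=iid, variant_id="V2"),
        ])
        cm = lb.CarrierMatrix(entries, pd.Index(small_cohort["individual_id"]), ["G1"])
        assert cm.carrier_counts()["G1"] == 1
        assert cm.bool_matrix().sum() == 1

    def test_conservation_between_margins(self, classified, small_cohort):
        cm = lb.carrier_matrix(classified, small_cohort, "S_LOF")
        assert cm.carrier_counts().sum() == cm.genes_carried_by().sum()
        assert cm.bool_matrix().sum() == cm.carrier_counts().sum()
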