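"""Concordance labeling and metrics: benchmark reproduction, truth-table
edge cases, brute-force recount oracle, and simulated-data recovery."""

import math

import pytest

from panelval import concordance, datasets, simulate
from panelval.errors import DataError
from panelval.model import TruthRecord

from conftest import small_sim_config
from test_filtering import make_call


def _sanger(sample, key, outcome="confirmed", gene="G"):
    return TruthRecord(sample=sample, scope="variant", gene=gene,
                       outcome=outcome, key=key)


class TestLabelCalls:
    def test_confirmed_and_refuted_calls(self, ref_labeled):
        by = {(c.sample, c.dna_change): c.label for c in ref_labeled}
        assert by[("1CB-a", "c.5611_5615delAGTAA")] == "TP"
        assert by[("1CAF-a", "c.802-2A>T")] == "FP"
        assert by[("1EAJ-a", "c.802-2A>T")] == "FP"

    def test_empty_call_set(self):
        assert concordance.label_calls([], []) == []

    def test_missing_truth_is_unresolved(self):
        labeled = concordance.label_calls([make_call()], [])
        assert labeled[0].label == "unresolved"

    def test_contradictory_sanger_records_rejected(self):
        key = ("chr1", 100, "A", "G")
        with pytest.raises(DataError, match="contradictory"):
            concordance.label_calls(
                [make_call()],
                [_sanger("s1", key), _sanger("s1", key, "not_confirmed")])

    def test_conservation_of_labels(self, ref_labeled):
        n = sum(1 for c in ref_labeled
                if c.label in ("TP", "FP", "unresolved"))
        assert n == len(ref_labeled) == 74


class TestKeyEquivalence:
    def test_shifted_deletion_names_match(self):
        # a deletion in a short tandem repeat has several legal names
        a = ("chr13", 32339966, "AGTAA", "-")
        b = ("chr13", 32339971, "AGTAA", "-")
        assert concordance.keys_equivalent(a, b)

    def test_snv_requires_exact_position(self):
        assert not concordance.keys_equivalent(
            ("chr1", 100, "A", "G"), ("chr1", 101, "A", "G"))

    def test_truth_with_alternative_deletion_name_still_labels(self, ref_calls):
        # shift only the deletion key; every call must still resolve
        truth = [_sanger(c.sample, (c.chrom, c.pos + (5 if c.ref == "AGTAA"
                                                      else 0), c.ref, c.alt))
                 for c in ref_calls]
        labeled = concordance.label_calls(ref_calls, truth)
        assert all(c.label != "unresolved" for c in labeled)


class TestDeriveFnTn:
    def test_benchmark_has_zero_false_negatives(self, ref_calls, ref_clinical):
        fn = concordance.derive_fn(ref_clinical, ref_calls)
        assert fn == {"BRCA1": 0, "BRCA2": 0}

    def test_removing_known_positive_call_creates_fn(self, ref_calls,
                                                     ref_clinical):
        calls = [c for c in ref_calls
                 if not (c.sample == "1CB-a" and c.ref == "AGTAA")]
        fn = concordance.derive_fn(ref_clinical, calls)
        assert fn == {"BRCA1": 0, "BRCA2": 1}

    def test_six_negative_screens_per_gene(self, ref_calls, ref_clinical):
        tn = concordance.derive_tn(ref_clinical, ref_calls)
        assert tn == {"BRCA1": 6, "BRCA2": 6}

    def test_targeted_negative_test_is_never_tn(self, ref_calls):
        only_targeted = [TruthRecord(sample="1CAD-f", scope="gene",
                                     gene="BRCA1", outcome="negative_targeted",
                                     key=("chr17", 43051071, "A", "C"))]
        assert concordance.derive_tn(only_targeted, ref_calls) == {"BRCA1": 0}

    def test_pathogenic_call_breaks_tn(self):
        clinical = [TruthRecord(sample="s1", scope="gene", gene="G",
                                outcome="negative_full_screen")]
        benign = make_call(clinvar="Benign")
        pathogenic = make_call(clinvar="Pathogenic")
        assert concordance.derive_tn(clinical, [benign]) == {"G": 1}
        assert concordance.derive_tn(clinical, [pathogenic]) == {"G": 0}

    def test_no_clinical_records_no_tn(self, ref_calls):
        assert concordance.derive_tn([], ref_calls) == {}


class TestMetrics:
    def test_per_gene_fdr_matches_brute_force(self, ref_labeled, ref_clinical):
        res = concordance.concordance_metrics(ref_labeled, ref_clinical)
        for gene, s in res["per_gene"].items():
            tp = sum(1 for c in ref_labeled
                     if c.gene == gene and c.label == "TP")
            fp = sum(1 for c in ref_labeled
                     if c.gene == gene and c.label == "FP")
            assert (s.tp, s.fp) == (tp, fp)
            if tp + fp:
                assert s.fdr == pytest.approx(fp / (tp + fp))
            else:
                assert math.isnan(s.fdr)

    def test_pten_fdr_both_modes(self, ref_labeled, ref_clinical):
        for mode in ("all", "ab_filtered"):
            res = concordance.concordance_metrics(ref_labeled, ref_clinical,
                                                  mode=mode)
            assert res["per_gene"]["PTEN"].fdr == pytest.approx(11 / 12)

    def test_ab_exclusion_clears_brca1_and_cdh1_fdr(self, ref_labeled,
                                                    ref_clinical):
        res = concordance.concordance_metrics(ref_labeled, ref_clinical,
                                              mode="ab_filtered")
        assert res["per_gene"]["BRCA1"].fdr == 0.0
        assert res["per_gene"]["CDH1"].fdr == 0.0
        all_mode = concordance.concordance_metrics(ref_labeled, ref_clinical)
        assert all_mode["per_gene"]["BRCA1"].fdr == pytest.approx(1 / 12)
        assert all_mode["per_gene"]["CDH1"].fdr == pytest.approx(1 / 4)

    def test_pooled_sensitivity_specificity(self, ref_labeled, ref_clinical):
        res = concordance.concordance_metrics(ref_labeled, ref_clinical)
        pooled = res["pooled"]
        assert (pooled.tp, pooled.fp, pooled.tn, pooled.fn) == (25, 1, 12, 0)
        assert pooled.sensitivity == 1.0
        assert pooled.specificity == pytest.approx(12 / 13)
        filt = concordance.concordance_metrics(ref_labeled, ref_clinical,
                                               mode="ab_filtered")["pooled"]
        assert filt.sensitivity == 1.0 and filt.specificity == 1.0

    def test_gene_without_calls_or_truth_is_all_nan(self, ref_labeled):
        res = concordance.concordance_metrics(ref_labeled, genes=["NOPE"])
        s = res["per_gene"]["NOPE"]
        assert math.isnan(s.fdr) and math.isnan(s.sensitivity)

    def test_fdr_filtered_never_exceeds_fdr_all_on_benchmark(
            self, ref_labeled, ref_clinical):
        res_a = concordance.concordance_metrics(ref_labeled, ref_clinical)
        res_f = concordance.concordance_metrics(ref_labeled, ref_clinical,
                                                mode="ab_filtered")
        for gene, s in res_a["per_gene"].items():
            f = res_f["per_gene"][gene]
            if not math.isnan(s.fdr) and not math.isnan(f.fdr):
                assert f.fdr <= s.fdr


class TestClassSummaries:
    def test_single_call_class(self):
        call = make_call(dp=200, ad_alt=100).annotated(label="TP")
        cs = concordance.class_summaries([call])
        assert cs["tp"]["dp_mean"] == 200 and cs["tp"]["ab_mean"] == 0.5
        assert cs["fp"]["n"] == 0 and math.isnan(cs["fp"]["dp_mean"])

    def test_benchmark_class_statistics(self, ref_labeled):
        cs = concordance.class_summaries(ref_labeled)
        assert round(cs["tp"]["dp_mean"]) == 659
        assert round(cs["tp"]["ab_mean"], 2) == 0.51
        assert round(cs["fp"]["dp_mean"]) == 34
        assert round(cs["fp"]["ab_mean"], 2) == 0.33
        assert (cs["fp"]["dp_min"], cs["fp"]["dp_max"]) == (12, 63)
        assert round(cs["below_depth_tp"]["dp_mean"]) == 60
        assert round(cs["at_or_above_depth_het"]["dp_mean"]) == 724
        assert round(cs["at_or_above_depth_het"]["ab_mean"], 2) == 0.50


class TestSimulatedRecovery:
    def test_zero_artifacts_gives_perfect_metrics(self):
        ds = simulate.simulate_panel(small_sim_config(
            seed=13, artifact_model=simulate.ArtifactModel(rate=0.0)))
        assert ds.missed == []  # every planted variant emitted
        labeled = concordance.label_calls(ds.calls, ds.sanger_truth)
        res = concordance.concordance_metrics(labeled, ds.clinical_truth)
        pooled = res["pooled"]
        assert pooled.fp == 0 and pooled.fn == 0
        assert pooled.fdr == 0.0 and pooled.sensitivity == 1.0
        if pooled.tn:
            assert pooled.specificity == 1.0

    def test_fdr_recovers_planted_artifact_fraction(self):
        ds = simulate.simulate_panel(small_sim_config(seed=29,
                                                      artifact_rate=2.0))
        labeled = concordance.label_calls(ds.calls, ds.sanger_truth)
        n = len(labeled)
        tp = sum(1 for c in labeled if c.label == "TP")
        fp = sum(1 for c in labeled if c.label == "FP")
        fdr = fp / (tp + fp)
        # the measured FDR is exactly the planted artifact fraction
        assert fdr == sum(p.is_artifact for p in ds.planted) / n
        # ... and recovers the configured artifact load within binomial error
        am = ds.config.artifact_model
        expected_artifacts = am.rate * len(ds.targets) + am.pseudogene_rate
        expected_frac = expected_artifacts / (expected_artifacts + tp)
        half_width = 1.96 * math.sqrt(expected_frac * (1 - expected_frac) / n)
        assert abs(fdr - expected_frac) <= half_width
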