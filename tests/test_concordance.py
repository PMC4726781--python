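"""Genotype comparison classes, the decision cascade, summaries and adjudication."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxconcord.callset_model import (
    Allele,
    FilterThresholds,
    HET,
    HOM_ALT,
    HOM_REF,
    NO_CALL_ALLELES,
    RELAXED_CUT,
    Tranche,
)
from pgxconcord.concordance import (
    AdjudicationRecord,
    Attribution,
    Classification,
    ClassifiedCall,
    adjudicate,
    build_stratified_report,
    classify_pair,
    classify_pair_detailed,
    compare_genotypes,
    summarize,
)

from conftest import build_count_fixture, make_site, panel_call, truth_call, wes_call

THR = FilterThresholds()
SITE = make_site(0)

GENOTYPES = {0: HOM_REF, 1: HET, 2: HOM_ALT}

# independent oracle: exhaustive 3x3 truth table over alt-copy counts,
# written from the definitions (extra test copies = FP, missed truth
# copies = FN, equal multisets = concordant)
TRUTH_TABLE = {
    (0, 0): Classification.CONCORDANT,
    (0, 1): Classification.FALSE_NEGATIVE,
    (0, 2): Classification.FALSE_NEGATIVE,
    (1, 0): Classification.FALSE_POSITIVE,
    (1, 1): Classification.CONCORDANT,
    (1, 2): Classification.FALSE_NEGATIVE,   # het vs hom-alt misses one alt copy
    (2, 0): Classification.FALSE_POSITIVE,
    (2, 1): Classification.FALSE_POSITIVE,
    (2, 2): Classification.CONCORDANT,
}


class TestCompareGenotypes:
    @pytest.mark.parametrize("test_copies,truth_copies", sorted(TRUTH_TABLE))
    def test_matches_exhaustive_truth_table(self, test_copies, truth_copies):
        got = compare_genotypes(
            wes_call("s", SITE, GENOTYPES[test_copies]),
            truth_call("s", SITE, GENOTYPES[truth_copies]),
        )
        assert got is TRUTH_TABLE[(test_copies, truth_copies)]

    @pytest.mark.parametrize("test_copies,truth_copies", sorted(TRUTH_TABLE))
    def test_fp_fn_symmetry_under_platform_swap(self, test_copies, truth_copies):
        forward = compare_genotypes(
            wes_call("s", SITE, GENOTYPES[test_copies]),
            truth_call("s", SITE, GENOTYPES[truth_copies]),
        )
        backward = compare_genotypes(
            wes_call("s", SITE, GENOTYPES[truth_copies]),
            truth_call("s", SITE, GENOTYPES[test_copies]),
        )
        swap = {
            Classification.FALSE_POSITIVE: Classification.FALSE_NEGATIVE,
            Classification.FALSE_NEGATIVE: Classification.FALSE_POSITIVE,
        }
        assert backward is swap.get(forward, forward)

    def test_foreign_allele_is_mixed(self):
        call = wes_call("s", SITE, (Allele.ALT, Allele.OTHER))
        assert compare_genotypes(call, truth_call("s", SITE, HET)) \
            is Classification.MIXED_DISCORDANT

    def test_site_mismatch_is_programming_error(self):
        with pytest.raises(ValueError):
            compare_genotypes(wes_call("s", make_site(1), HET),
                              truth_call("s", make_site(2), HET))


class TestClassifyPair:
    def test_tranche_exclusion_precedes_everything(self):
        # fails DP too, but stratification comes first
        call = wes_call("s", SITE, HET, ref_reads=1, alt_reads=1, gq=5,
                        tranche=Tranche.TRANCHE_99_999)
        assert classify_pair(call, truth_call("s", SITE, HET), THR) \
            is Classification.EXCLUDED_TRANCHE

    def test_low_depth_not_evaluable_regardless_of_truth(self):
        call = wes_call("s", SITE, HET, ref_reads=2, alt_reads=1, gq=99)
        assert classify_pair(call, None, THR) is Classification.NOT_EVALUABLE
        assert classify_pair(call, truth_call("s", SITE, HET), THR) \
            is Classification.NOT_EVALUABLE

    def test_no_call_with_adequate_metrics(self):
        call = wes_call("s", SITE, NO_CALL_ALLELES, ref_reads=None, alt_reads=None,
                        dp=20, gq=30)
        assert classify_pair(call, truth_call("s", SITE, HET), THR) \
            is Classification.NO_CALL

    @pytest.mark.parametrize(
        "truth,reason",
        [
            (None, "truth_absent"),
            (lambda: truth_call("s", SITE, NO_CALL_ALLELES), "truth_no_call"),
            (lambda: truth_call("s", SITE, HET, dp=8), "truth_under_depth"),
        ],
    )
    def test_missing_truth_routes(self, truth, reason):
        call = wes_call("s", SITE, HET)
        tc = truth() if callable(truth) else truth
        cls, sub = classify_pair_detailed(call, tc, THR)
        assert cls is Classification.MISSING_TRUTH and sub == reason

    def test_panel_truth_uses_call_rate(self):
        call = wes_call("s", SITE, HET)
        low = panel_call("s", SITE, HET, call_rate=80.0)
        ok = panel_call("s", SITE, HET, call_rate=97.0)
        assert classify_pair(call, low, THR) is Classification.MISSING_TRUTH
        assert classify_pair(call, ok, THR) is Classification.CONCORDANT


class TestSummarize:
    @pytest.mark.parametrize(
        "n_evaluated,n_discordant,expected",
        [(741, 3, 99.60), (1249, 136, 89.11), (719, 8, 98.89), (500, 0, 100.00)],
    )
    def test_concordance_rate_rounding(self, n_evaluated, n_discordant, expected):
        items = ([Classification.CONCORDANT] * (n_evaluated - n_discordant)
                 + [Classification.FALSE_NEGATIVE] * n_discordant)
        s = summarize(items, "stratum")
        assert s.concordance_rate == expected

    def test_empty_stratum_reports_blank(self):
        s = summarize([Classification.MISSING_TRUTH], "empty")
        assert s.concordance_rate is None and s.concordance_rate_str == ""

    def test_full_concordance_iff_zero_discordant(self):
        s = summarize([Classification.CONCORDANT] * 7, "x")
        assert s.concordance_rate == 100.00 and s.n_discordant == 0

    @given(
        counts=st.lists(st.integers(0, 40), min_size=8, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_partition_identities_on_random_inputs(self, counts):
        items = [c for cls, n in zip(Classification, counts) for c in [cls] * n]
        s = summarize(items, "rand")
        assert s.n_total_calls == (s.n_low_quality + s.n_no_calls
                                   + s.n_missing_truth + s.n_evaluated)
        assert s.n_evaluated == s.n_concordant + s.n_discordant
        assert s.n_discordant == s.n_false_positive + s.n_false_negative + s.n_mixed
        assert s.n_total_calls + s.n_excluded_tranche == len(items)


class TestAdjudicate:
    def _discordant(self, sample, site, test_alleles, truth_alleles, cls):
        return ClassifiedCall(
            sample=sample, site=site, classification=cls,
            test_call=wes_call(sample, site, test_alleles),
            truth_call=truth_call(sample, site, truth_alleles),
        )

    def test_platform_attribution(self):
        s1, s2, s3 = make_site(1), make_site(2), make_site(3)
        classified = [
            # exome hom-ref, truth het, orthogonal hom-ref -> exome vindicated
            self._discordant("a", s1, HOM_REF, HET, Classification.FALSE_NEGATIVE),
            # exome het, truth hom-alt, orthogonal hom-alt -> truth vindicated
            self._discordant("a", s2, HET, HOM_ALT, Classification.FALSE_NEGATIVE),
            # neither platform matches the orthogonal result
            self._discordant("a", s3, HOM_ALT, HOM_REF, Classification.FALSE_POSITIVE),
        ]
        records = [
            AdjudicationRecord("a", s1, HOM_REF),
            AdjudicationRecord("a", s2, HOM_ALT),
            AdjudicationRecord("a", s3, HET),
        ]
        report = adjudicate(classified, records)
        assert [e.attribution for e in report.entries] == [
            Attribution.TEST_CORRECT, Attribution.TRUTH_CORRECT, Attribution.BOTH_WRONG,
        ]
        # original classifications preserved alongside
        assert [e.classification for e in report.entries] == [
            Classification.FALSE_NEGATIVE, Classification.FALSE_NEGATIVE,
            Classification.FALSE_POSITIVE,
        ]

    def test_record_for_concordant_pair_ignored(self):
        site = make_site(1)
        cc = ClassifiedCall(sample="a", site=site,
                            classification=Classification.CONCORDANT,
                            test_call=wes_call("a", site, HET),
                            truth_call=truth_call("a", site, HET))
        report = adjudicate([cc], [AdjudicationRecord("a", site, HET)])
        assert report.entries == []


class TestStratifiedReport:
    def test_paper_count_bookkeeping(self, paper_count_fixture):
        test, truth = paper_count_fixture
        report = build_stratified_report(test, truth, THR)
        assert report.strict.n_total_calls == 943
        assert report.strict.n_total_calls - (
            report.strict.n_low_quality + report.strict.n_no_calls
            + report.strict.n_missing_truth
        ) == 741
        assert report.strict.n_evaluated == 741
        assert report.strict.n_discordant == 3
        assert report.relaxed.n_evaluated == 1249
        assert report.relaxed.n_discordant == 136
        assert report.relaxed.n_discordant - report.strict.n_discordant == 133
        assert report.n_strict_sites == 27
        assert report.n_tranche_only_sites == 16

    def test_strict_discordants_subset_of_relaxed(self, paper_count_fixture):
        test, truth = paper_count_fixture
        report = build_stratified_report(test, truth, THR)
        assert report.strict.n_discordant <= report.relaxed.n_discordant

    @given(
        n_pass=st.integers(0, 20), n_tranche=st.integers(0, 20),
        disc_pass=st.integers(0, 5), disc_tranche=st.integers(0, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_relaxed_counts_are_strict_plus_tranche_only(
        self, n_pass, n_tranche, disc_pass, disc_tranche
    ):
        disc_pass = min(disc_pass, n_pass)
        disc_tranche = min(disc_tranche, n_tranche)
        test, truth = build_count_fixture([
            (Tranche.PASS_99, max(1, -(-n_pass // 3)) if n_pass else 1,
             [("concordant", n_pass - disc_pass), ("fp", disc_pass)]),
            (Tranche.TRANCHE_99_999, max(1, -(-n_tranche // 3)) if n_tranche else 1,
             [("concordant", n_tranche - disc_tranche), ("fn", disc_tranche)]),
        ], n_samples=10)
        report = build_stratified_report(test, truth, THR)
        assert report.relaxed.n_evaluated == n_pass + n_tranche
        assert report.relaxed.n_discordant == disc_pass + disc_tranche
        assert report.strict.n_evaluated == n_pass
        assert report.strict.n_discordant == disc_pass
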