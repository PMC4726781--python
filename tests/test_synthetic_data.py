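"""Generator determinism, Hardy-Weinberg conformity, the genotype-quality
likelihood model, and recovery of injected error structure."""

import filecmp
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from pgxconcord.callset_model import (
    Allele,
    FilterThresholds,
    HET,
    HOM_ALT,
    HOM_REF,
    NO_CALL_ALLELES,
    Platform,
    Tranche,
)
from pgxconcord.concordance import build_stratified_report
from pgxconcord.errors import ConfigError
from pgxconcord.io_formats import write_panel_table, write_vcf_callset
from pgxconcord.synthetic_data import (
    GenotypeLikelihoodModel,
    SimulationConfig,
    generate_truth,
    genotype_quality,
    simulate_panel_callset,
    simulate_study,
    simulate_test_callset,
)


def _genotype_snapshot(callset):
    return {(c.sample, c.site.key): (c.alleles, c.ref_reads, c.alt_reads, c.dp,
                                     c.gq, c.tranche, c.call_rate)
            for c in callset.calls()}


class TestConfig:
    def test_invalid_fields_listed(self):
        cfg = SimulationConfig(n_samples=0, base_error=1.5)
        with pytest.raises(ConfigError) as exc:
            cfg.validate()
        assert "n_samples" in str(exc.value) and "base_error" in str(exc.value)

    def test_tranche_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="tranche_fractions"):
            SimulationConfig(tranche_fractions=(0.5, 0.2, 0.2)).validate()


class TestDeterminism:
    def test_identical_seed_gives_identical_callsets(self):
        cfg = SimulationConfig(seed=42, n_samples=6, n_sites=10)
        a, b = simulate_study(cfg), simulate_study(cfg)
        assert _genotype_snapshot(a.truth) == _genotype_snapshot(b.truth)
        assert _genotype_snapshot(a.test.callset) == _genotype_snapshot(b.test.callset)
        assert _genotype_snapshot(a.panel) == _genotype_snapshot(b.panel)
        assert a.test.injected_errors == b.test.injected_errors
        assert a.targets.by_contig == b.targets.by_contig

    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_samples=4, n_sites=8)
        for d in ("one", "two"):
            out = tmp_path / d
            out.mkdir()
            study = simulate_study(cfg)
            write_vcf_callset(study.test.callset, out / "test.vcf")
            write_vcf_callset(study.truth, out / "truth.vcf")
            write_panel_table(study.panel, out / "panel.tsv")
        for name in ("test.vcf", "truth.vcf", "panel.tsv"):
            assert filecmp.cmp(tmp_path / "one" / name, tmp_path / "two" / name,
                               shallow=False), name

    def test_different_seeds_differ(self):
        a = simulate_study(SimulationConfig(seed=1, n_samples=6, n_sites=10))
        b = simulate_study(SimulationConfig(seed=2, n_samples=6, n_sites=10))
        assert _genotype_snapshot(a.test.callset) != _genotype_snapshot(b.test.callset)


class TestGenerateTruth:
    def test_degenerate_frequencies(self):
        for q, expected in ((0.0, HOM_REF), (1.0, HOM_ALT)):
            cfg = SimulationConfig(seed=0, n_samples=20, n_sites=3, allele_freqs=q,
                                   missing_truth_rate=0.0)
            truth = generate_truth(cfg)
            assert all(c.alleles == expected for c in truth.calls())

    def test_het_fraction_near_binomial_expectation(self):
        # at q = 0.5 the het probability is 1/2; check within 3 standard errors
        cfg = SimulationConfig(seed=123, n_samples=10000, n_sites=1, allele_freqs=0.5,
                               missing_truth_rate=0.0)
        truth = generate_truth(cfg)
        n_het = sum(c.alleles == HET for c in truth.calls())
        se = math.sqrt(0.5 * 0.5 / 10000)
        assert abs(n_het / 10000 - 0.5) < 3 * se

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hwe_goodness_of_fit_not_rejected(self, seed):
        q = 0.3
        cfg = SimulationConfig(seed=seed, n_samples=6000, n_sites=1, allele_freqs=q,
                               missing_truth_rate=0.0)
        truth = generate_truth(cfg)
        counts = {g: 0 for g in (HOM_REF, HET, HOM_ALT)}
        for c in truth.calls():
            counts[c.alleles] += 1
        n = sum(counts.values())
        expected = [n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q ** 2]
        stat, p = chisquare([counts[HOM_REF], counts[HET], counts[HOM_ALT]], expected)
        assert p > 0.001

    def test_missing_truth_fraction_realized(self):
        cfg = SimulationConfig(seed=4, n_samples=100, n_sites=50,
                               missing_truth_rate=0.2)
        truth = generate_truth(cfg)
        thresholds = FilterThresholds()
        n_slots = 100 * 50
        n_unusable = n_slots - sum(
            1 for c in truth.calls() if c.depth is not None and c.depth >= 10
        )
        p = 0.2
        sd = math.sqrt(n_slots * p * (1 - p))
        assert abs(n_unusable - n_slots * p) < 4 * sd


def _oracle_gq(ref_reads, alt_reads, eps):
    """Independent likelihood enumeration (direct float products)."""
    depth = ref_reads + alt_reads
    liks = []
    for p_alt in (eps, 0.5, 1 - eps):
        lik = math.comb(depth, alt_reads) * (p_alt ** alt_reads) * \
            ((1 - p_alt) ** ref_reads)
        liks.append(lik)
    total = sum(liks)
    best = max(range(3), key=lambda i: liks[i])
    post_err = 1 - liks[best] / total
    if post_err <= 0:
        return best, 99
    return best, min(99, round(-10 * math.log10(post_err)))


class TestGenotypeQuality:
    MODEL = GenotypeLikelihoodModel(base_error=0.01)

    def test_clean_reference_reads_called_hom_ref(self):
        alleles, gq = genotype_quality(18, 0, self.MODEL)
        assert alleles == HOM_REF and gq is not None

    def test_overwhelming_alt_evidence_caps_gq(self):
        alleles, gq = genotype_quality(0, 40, self.MODEL)
        assert alleles == HOM_ALT and gq == 99

    def test_balanced_reads_called_het_with_oracle_gq(self):
        alleles, gq = genotype_quality(10, 10, self.MODEL)
        best, exp_gq = _oracle_gq(10, 10, 0.01)
        assert alleles == HET and best == 1
        assert gq == exp_gq

    def test_zero_reads_is_no_call(self):
        alleles, gq = genotype_quality(0, 0, self.MODEL)
        assert alleles == NO_CALL_ALLELES and gq is None

    def test_matches_enumerated_table_for_all_small_depths(self):
        classes = [HOM_REF, HET, HOM_ALT]
        for depth in range(1, 13):
            for alt in range(depth + 1):
                got_alleles, got_gq = genotype_quality(depth - alt, alt, self.MODEL)
                best, exp_gq = _oracle_gq(depth - alt, alt, 0.01)
                assert got_alleles == classes[best], (depth, alt)
                assert got_gq == exp_gq, (depth, alt)


#: clean regime: deep coverage, no read noise, complete truth
CLEAN = dict(base_error=0.0, min_depth=25, mean_depth=60, missing_truth_rate=0.0)


class TestErrorInjection:
    def test_zero_error_config_reports_perfect_concordance(self):
        cfg = SimulationConfig(seed=77, n_samples=20, n_sites=30,
                               error_rate_pass=0.0, error_rate_tranche=0.0, **CLEAN)
        truth = generate_truth(cfg)
        sim = simulate_test_callset(truth, cfg)
        assert sim.injected_errors == []
        report = build_stratified_report(sim.callset, truth, FilterThresholds())
        assert report.relaxed.concordance_rate == 100.00
        assert report.strict.concordance_rate == 100.00

    def test_ledger_count_equals_pipeline_discordant_count(self):
        cfg = SimulationConfig(seed=31, n_samples=25, n_sites=40,
                               error_rate_pass=0.05, error_rate_tranche=0.3,
                               tranche_fractions=(0.6, 0.4, 0.0), **CLEAN)
        truth = generate_truth(cfg)
        sim = simulate_test_callset(truth, cfg)
        report = build_stratified_report(sim.callset, truth, FilterThresholds())
        assert report.relaxed.n_evaluated == 25 * 40   # fully evaluable universe
        assert report.relaxed.n_discordant == len(sim.injected_errors)

    def test_tranche_error_contrast_reproduced(self):
        # corruption concentrated in the tranche: strict rate must exceed relaxed
        for seed in (5, 6, 7):
            cfg = SimulationConfig(seed=seed, n_samples=20, n_sites=40,
                                   error_rate_pass=0.002, error_rate_tranche=0.25,
                                   tranche_fractions=(0.6, 0.4, 0.0), **CLEAN)
            truth = generate_truth(cfg)
            sim = simulate_test_callset(truth, cfg)
            report = build_stratified_report(sim.callset, truth, FilterThresholds())
            assert report.strict.concordance_rate > report.relaxed.concordance_rate


class TestPanelSimulation:
    def test_zero_error_panel_fully_concordant(self):
        cfg = SimulationConfig(seed=13, n_samples=15, n_sites=20,
                               panel_error_rate=0.0,
                               panel_call_rate_params=(200.0, 1.0), **CLEAN)
        truth = generate_truth(cfg)
        panel = simulate_panel_callset(truth, cfg)
        truth_gt = {(c.sample, c.site.key): c.alleles for c in truth.calls()}
        assert all(c.alleles == truth_gt[(c.sample, c.site.key)]
                   for c in panel.calls())
        assert all(c.call_rate > 85 for c in panel.calls())

    def test_corrupted_count_within_binomial_bounds(self):
        rate = 0.05
        deviations = []
        for seed in (1, 2, 3, 4):
            cfg = SimulationConfig(seed=seed, n_samples=30, n_sites=60,
                                   panel_error_rate=rate, **CLEAN)
            truth = generate_truth(cfg)
            panel = simulate_panel_callset(truth, cfg)
            truth_gt = {(c.sample, c.site.key): c.alleles for c in truth.calls()}
            n = 30 * 60
            n_corrupt = sum(c.alleles != truth_gt[(c.sample, c.site.key)]
                            for c in panel.calls())
            sd = math.sqrt(n * rate * (1 - rate))
            deviations.append(abs(n_corrupt - n * rate) <= 3 * sd)
        assert all(deviations)

    def test_all_low_call_rates_yield_zero_evaluated(self):
        cfg = SimulationConfig(seed=21, n_samples=10, n_sites=10,
                               panel_call_rate_params=(1.0, 200.0), **CLEAN)
        truth = generate_truth(cfg)
        panel = simulate_panel_callset(truth, cfg)
        sim = simulate_test_callset(truth, cfg)
        assert all(c.call_rate <= 85 for c in panel.calls())
        report = build_stratified_report(sim.callset, panel, FilterThresholds())
        assert report.relaxed.n_evaluated == 0
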