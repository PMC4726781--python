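"""Shared builders for hand-constructed callset fixtures."""

from __future__ import annotations

from itertools import product
from typing import Iterable, Optional

import pytest

from pgxconcord.callset_model import (
    Allele,
    Callset,
    GenotypeCall,
    HET,
    HOM_ALT,
    HOM_REF,
    NO_CALL_ALLELES,
    Platform,
    Tranche,
    VariantSite,
)

BASE_POS = 42_000_000


def make_site(i: int = 0, ref: str = "G", alt: str = "A", contig: str = "chr22",
              rsid: Optional[str] = None, **kw) -> VariantSite:
    return VariantSite(contig=contig, position=BASE_POS + 1000 * i, ref=ref, alt=alt,
                       rsid=rsid, **kw)


def wes_call(sample: str, site: VariantSite, alleles, ref_reads=15, alt_reads=15,
             gq=99, tranche=Tranche.PASS_99, dp=None) -> GenotypeCall:
    return GenotypeCall(sample=sample, site=site, alleles=alleles,
                        platform=Platform.TEST_WES, ref_reads=ref_reads,
                        alt_reads=alt_reads, gq=gq, tranche=tranche, dp=dp)


def truth_call(sample: str, site: VariantSite, alleles, dp=250) -> GenotypeCall:
    return GenotypeCall(sample=sample, site=site, alleles=alleles,
                        platform=Platform.TRUTH_AMPLICON, dp=dp)


def panel_call(sample: str, site: VariantSite, alleles, call_rate=97.0) -> GenotypeCall:
    return GenotypeCall(sample=sample, site=site, alleles=alleles,
                        platform=Platform.PANEL, call_rate=call_rate)


#: per-slot categories a count fixture can request
_CATEGORY_BUILDERS = {
    # name -> (test call kwargs or None, truth alleles or None)
    "concordant": (dict(alleles=HET, ref_reads=15, alt_reads=15, gq=99), HET),
    "fn": (dict(alleles=HOM_REF, ref_reads=18, alt_reads=0, gq=54), HET),
    "fp": (dict(alleles=HET, ref_reads=15, alt_reads=15, gq=99), HOM_REF),
    "lowq": (dict(alleles=HET, ref_reads=2, alt_reads=1, gq=5), HET),
    "nocall": (dict(alleles=NO_CALL_ALLELES, ref_reads=None, alt_reads=None,
                    dp=20, gq=30), HET),
    "missing": (dict(alleles=HET, ref_reads=15, alt_reads=15, gq=99), None),
}


def build_count_fixture(
    strata: Iterable[tuple[Tranche, int, list[tuple[str, int]]]],
    n_samples: int = 36,
) -> tuple[Callset, Callset]:
    """Build aligned test/truth callsets realizing prescribed per-class counts.

    ``strata`` is a list of (tranche, n_sites, [(category, count), ...]);
    slots are (sample, site) pairs filled in order, so the per-class counts
    of the resulting comparison equal the requested counts exactly.  Slots
    beyond the requested total carry no test call at all.
    """
    samples = [f"S{i:03d}" for i in range(n_samples)]
    test = Callset(platform=Platform.TEST_WES)
    truth = Callset(platform=Platform.TRUTH_AMPLICON)
    test.samples.extend(samples)
    truth.samples.extend(samples)
    site_counter = 0
    for tranche, n_sites, categories in strata:
        sites = [make_site(site_counter + j, rsid=f"rs{100000 + site_counter + j}")
                 for j in range(n_sites)]
        site_counter += n_sites
        for s in sites:
            test.add_site(s)
            truth.add_site(s)
        slots = product(sites, samples)
        total = sum(c for _, c in categories)
        assert total <= n_sites * n_samples, "not enough slots for requested counts"
        flat = [name for name, count in categories for _ in range(count)]
        for name, (site, sample) in zip(flat, slots):
            test_kw, truth_alleles = _CATEGORY_BUILDERS[name]
            test.add(wes_call(sample, site, tranche=tranche, **test_kw))
            if truth_alleles is not None:
                truth.add(truth_call(sample, site, truth_alleles))
    return test, truth


@pytest.fixture
def paper_count_fixture() -> tuple[Callset, Callset]:
    """Callsets realizing the published strict/relaxed bookkeeping.

    Strict stratum (27 pass-filter sites): 943 calls = 741 evaluated
    (738 concordant + 3 false-negative) + 202 excluded for quality,
    no-calls or missing truth.  The 16 tranche sites add 569 calls of
    which 508 evaluate with 133 discordant, giving the relaxed universe
    1512 calls, 1249 evaluated, 136 discordant.
    """
    return build_count_fixture([
        (Tranche.PASS_99, 27, [
            ("concordant", 738), ("fn", 3),
            ("lowq", 149), ("nocall", 29), ("missing", 24),
        ]),
        (Tranche.TRANCHE_99_999, 16, [
            ("concordant", 375), ("fp", 120), ("fn", 13),
            ("lowq", 40), ("nocall", 10), ("missing", 11),
        ]),
    ])
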