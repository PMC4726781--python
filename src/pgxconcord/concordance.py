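"""Per-call concordance classification, adjudication and stratified summaries.

Every (sample, site) comparison between a test (exome) callset and a truth
callset (amplicon sequencing, or a genotyping panel) falls into exactly one
class:

* ``EXCLUDED_TRANCHE`` — the test call's VQSR tranche is outside the cut;
* ``NOT_EVALUABLE``   — the test call fails the DP/GQ evaluability rule;
* ``NO_CALL``         — the test platform emitted no genotype;
* ``MISSING_TRUTH``   — the truth side is absent, a no-call, or unconfident;
* ``CONCORDANT`` / ``FALSE_POSITIVE`` / ``FALSE_NEGATIVE`` / ``MIXED_DISCORDANT``
  — the genotype comparison proper.

A false positive is the calling of an alternate allele determined to be
absent by the truth platform; a false negative is the failure to detect one
or more truth alternate-allele copies (so a het call against a hom-alt
truth is a false negative).  Comparison counts allele copies as multisets,
so 0/1 and 1/0 are equal.  Any involvement of an allele foreign to the
biallelic site ("other"), a partially missing genotype, or a simultaneous
introduce-and-miss, is classed ``MIXED_DISCORDANT``.

Tranche stratification precedes evaluability: a call failing both is
counted once, in the tranche-exclusion bucket.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .callset_model import (
    Allele,
    Callset,
    FilterThresholds,
    GenotypeCall,
    Platform,
    RELAXED_CUT,
    STRICT_CUT,
    SiteMatch,
    Tranche,
    VariantSite,
    match_sites,
    sort_alleles,
)
from .quality_filters import (
    in_tranche_cut,
    panel_call_confident,
    test_call_evaluable,
    truth_call_confident,
)

logger = logging.getLogger(__name__)


class Classification(str, enum.Enum):
    EXCLUDED_TRANCHE = "EXCLUDED_TRANCHE"
    NOT_EVALUABLE = "NOT_EVALUABLE"
    NO_CALL = "NO_CALL"
    MISSING_TRUTH = "MISSING_TRUTH"
    CONCORDANT = "CONCORDANT"
    FALSE_POSITIVE = "FALSE_POSITIVE"
    FALSE_NEGATIVE = "FALSE_NEGATIVE"
    MIXED_DISCORDANT = "MIXED_DISCORDANT"


DISCORDANT_CLASSES = frozenset(
    {Classification.FALSE_POSITIVE, Classification.FALSE_NEGATIVE,
     Classification.MIXED_DISCORDANT}
)
EVALUATED_CLASSES = DISCORDANT_CLASSES | {Classification.CONCORDANT}


class Attribution(str, enum.Enum):
    """Which platform the orthogonal (Sanger) result vindicates."""

    TEST_CORRECT = "TEST_CORRECT"
    TRUTH_CORRECT = "TRUTH_CORRECT"
    BOTH_WRONG = "BOTH_WRONG"


def round_rate(value: float | Decimal) -> float:
    """Round a percentage half-up to 2 decimals (reporting convention)."""
    return float(Decimal(str(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compare_genotypes(test_call: GenotypeCall, truth_call: GenotypeCall) -> Classification:
    """Classify two evaluable, confident, non-missing calls at one site.

    Counts alternate-allele copies on each side: equal multisets are
    concordant; extra test copies with none missed are false positives;
    missed truth copies with none introduced are false negatives;
    everything else (foreign alleles, half-missing genotypes) is mixed.
    """
    ta, tb = test_call.site.coordinate_key, truth_call.site.coordinate_key
    if ta is not None and tb is not None and ta != tb:
        raise ValueError(f"site mismatch: {test_call.site.label} vs {truth_call.site.label}")
    if test_call.is_no_call or truth_call.is_no_call:
        raise ValueError("compare_genotypes requires non-missing genotypes on both sides")
    if (test_call.has_other_allele or truth_call.has_other_allele
            or test_call.has_missing_allele or truth_call.has_missing_allele):
        return Classification.MIXED_DISCORDANT
    a_test, a_truth = test_call.alt_copies, truth_call.alt_copies
    if a_test == a_truth:
        return Classification.CONCORDANT
    return (Classification.FALSE_POSITIVE if a_test > a_truth
            else Classification.FALSE_NEGATIVE)


def classify_pair_detailed(
    test_call: Optional[GenotypeCall],
    truth_call: Optional[GenotypeCall],
    thresholds: FilterThresholds,
) -> tuple[Classification, Optional[str]]:
    """Full decision cascade, returning the class plus a sub-reason.

    Cascade order: tranche cut, test evaluability, test no-call, truth
    availability/confidence, genotype comparison.  An entirely absent test
    call is treated as a no-call (the platform emitted nothing).  The
    sub-reason distinguishes why truth was unusable (absent / no-call /
    under-depth / low call rate).
    """
    if test_call is None:
        return Classification.NO_CALL, "test_absent"
    if not in_tranche_cut(test_call, thresholds):
        return Classification.EXCLUDED_TRANCHE, None
    if not test_call_evaluable(test_call, thresholds):
        return Classification.NOT_EVALUABLE, None
    if test_call.is_no_call:
        return Classification.NO_CALL, None
    if truth_call is None:
        return Classification.MISSING_TRUTH, "truth_absent"
    if truth_call.is_no_call:
        return Classification.MISSING_TRUTH, "truth_no_call"
    if truth_call.platform is Platform.PANEL:
        if not panel_call_confident(truth_call, thresholds):
            return Classification.MISSING_TRUTH, "low_call_rate"
    elif not truth_call_confident(truth_call, thresholds):
        return Classification.MISSING_TRUTH, "truth_under_depth"
    return compare_genotypes(test_call, truth_call), None


def classify_pair(
    test_call: Optional[GenotypeCall],
    truth_call: Optional[GenotypeCall],
    thresholds: FilterThresholds,
) -> Classification:
    return classify_pair_detailed(test_call, truth_call, thresholds)[0]


@dataclass
class ClassifiedCall:
    """One classified (sample, site) comparison, with its evidence."""

    sample: str
    site: VariantSite
    classification: Classification
    test_call: Optional[GenotypeCall] = None
    truth_call: Optional[GenotypeCall] = None
    sub_reason: Optional[str] = None

    @property
    def is_discordant(self) -> bool:
        return self.classification in DISCORDANT_CLASSES


@dataclass
class ConcordanceSummary:
    """Stratified call bookkeeping with the concordance rate.

    ``n_total_calls`` counts calls inside the tranche cut;
    ``n_excluded_tranche`` counts those outside it, kept separate so the
    partition identity ``n_total_calls = n_low_quality + n_no_calls +
    n_missing_truth + n_evaluated`` holds in every stratum.
    """

    stratum: str
    n_variant_sites: int = 0
    n_total_calls: int = 0
    n_excluded_tranche: int = 0
    n_low_quality: int = 0
    n_no_calls: int = 0
    n_missing_truth: int = 0
    n_concordant: int = 0
    n_false_positive: int = 0
    n_false_negative: int = 0
    n_mixed: int = 0

    @property
    def n_discordant(self) -> int:
        return self.n_false_positive + self.n_false_negative + self.n_mixed

    @property
    def n_evaluated(self) -> int:
        return self.n_concordant + self.n_discordant

    @property
    def concordance_rate(self) -> Optional[float]:
        """Percent concordance over evaluated calls, rounded half-up to 2 dp;
        ``None`` (reported blank) when nothing was evaluated."""
        if self.n_evaluated == 0:
            return None
        return round_rate(Decimal(100 * self.n_concordant) / Decimal(self.n_evaluated))

    @property
    def concordance_rate_str(self) -> str:
        r = self.concordance_rate
        return "" if r is None else f"{r:.2f}"

    def check_identities(self) -> None:
        assert self.n_total_calls == (
            self.n_low_quality + self.n_no_calls + self.n_missing_truth + self.n_evaluated
        ), "summary counts do not partition the total"
        assert self.n_total_calls >= 0 and self.n_excluded_tranche >= 0


def summarize(
    classifications: Iterable["ClassifiedCall | Classification"],
    stratum_label: str,
) -> ConcordanceSummary:
    """Aggregate per-call classifications into a summary block.

    Accepts either bare :class:`Classification` values or full
    :class:`ClassifiedCall` records (only the latter contribute a distinct
    variant-site count).  The partition identities are asserted before
    returning.
    """
    s = ConcordanceSummary(stratum=stratum_label)
    sites: set[tuple] = set()
    for item in classifications:
        if isinstance(item, ClassifiedCall):
            c = item.classification
        else:
            c = item
        if c is Classification.EXCLUDED_TRANCHE:
            s.n_excluded_tranche += 1
            continue
        if isinstance(item, ClassifiedCall):
            sites.add(item.site.key)   # sites outside the cut don't count
        s.n_total_calls += 1
        if c is Classification.NOT_EVALUABLE:
            s.n_low_quality += 1
        elif c is Classification.NO_CALL:
            s.n_no_calls += 1
        elif c is Classification.MISSING_TRUTH:
            s.n_missing_truth += 1
        elif c is Classification.CONCORDANT:
            s.n_concordant += 1
        elif c is Classification.FALSE_POSITIVE:
            s.n_false_positive += 1
        elif c is Classification.FALSE_NEGATIVE:
            s.n_false_negative += 1
        elif c is Classification.MIXED_DISCORDANT:
            s.n_mixed += 1
    s.n_variant_sites = len(sites)
    s.check_identities()
    return s


@dataclass(frozen=True)
class AdjudicationRecord:
    """An orthogonal (Sanger) genotype for one sample at one site."""

    sample: str
    site: VariantSite
    alleles: tuple[Allele, Allele]


@dataclass
class AdjudicatedCall:
    sample: str
    site: VariantSite
    classification: Classification
    test_alleles: tuple[Allele, Allele]
    truth_alleles: tuple[Allele, Allele]
    sanger_alleles: tuple[Allele, Allele]
    attribution: Attribution


@dataclass
class AdjudicationReport:
    entries: list[AdjudicatedCall] = field(default_factory=list)

    def counts(self) -> dict[Attribution, int]:
        out = {a: 0 for a in Attribution}
        for e in self.entries:
            out[e.attribution] += 1
        return out


def adjudicate(
    classified: Sequence[ClassifiedCall],
    records: Sequence[AdjudicationRecord],
) -> AdjudicationReport:
    """Attribute each adjudicated discordance to a platform.

    The platform whose genotype matches the Sanger alleles is vindicated:
    ``TEST_CORRECT`` when the test genotype equals Sanger, ``TRUTH_CORRECT``
    when the truth genotype does, ``BOTH_WRONG`` when neither does.
    Original classifications are never overwritten.  Records for
    non-discordant pairs are warned about and ignored.
    """
    by_key: dict[tuple, ClassifiedCall] = {}
    by_rsid: dict[tuple, ClassifiedCall] = {}
    for cc in classified:
        by_key[(cc.sample, cc.site.key)] = cc
        if cc.site.rsid:
            by_rsid[(cc.sample, cc.site.rsid)] = cc

    report = AdjudicationReport()
    for rec in records:
        cc = by_key.get((rec.sample, rec.site.key))
        if cc is None and rec.site.rsid:
            cc = by_rsid.get((rec.sample, rec.site.rsid))
        if cc is None:
            logger.warning("adjudication record for unknown pair (%s, %s); ignored",
                           rec.sample, rec.site.label)
            continue
        if not cc.is_discordant:
            logger.warning("adjudication record for non-discordant pair (%s, %s); ignored",
                           rec.sample, rec.site.label)
            continue
        sanger = sort_alleles(rec.alleles)
        test_alleles = cc.test_call.alleles if cc.test_call else None
        truth_alleles = cc.truth_call.alleles if cc.truth_call else None
        test_ok = test_alleles == sanger
        truth_ok = truth_alleles == sanger
        if test_ok and not truth_ok:
            attribution = Attribution.TEST_CORRECT
        elif truth_ok and not test_ok:
            attribution = Attribution.TRUTH_CORRECT
        elif not test_ok and not truth_ok:
            attribution = Attribution.BOTH_WRONG
        else:
            logger.warning("Sanger agrees with both platforms at (%s, %s); ignored",
                           rec.sample, rec.site.label)
            continue
        report.entries.append(AdjudicatedCall(
            sample=rec.sample, site=cc.site, classification=cc.classification,
            test_alleles=test_alleles, truth_alleles=truth_alleles,
            sanger_alleles=sanger, attribution=attribution,
        ))
    return report


@dataclass
class SiteRow:
    """Per-site line of the stratified report."""

    site: VariantSite
    tranche: Tranche
    n_calls: int = 0
    n_evaluated: int = 0
    n_discordant: int = 0


@dataclass
class StratifiedReport:
    """Both tranche strata of one test-vs-truth comparison."""

    strict: ConcordanceSummary
    relaxed: ConcordanceSummary
    strict_calls: list[ClassifiedCall]
    relaxed_calls: list[ClassifiedCall]
    site_rows: list[SiteRow]

    @property
    def n_strict_sites(self) -> int:
        return sum(1 for r in self.site_rows if r.tranche in STRICT_CUT)

    @property
    def n_tranche_only_sites(self) -> int:
        return sum(1 for r in self.site_rows
                   if r.tranche in RELAXED_CUT and r.tranche not in STRICT_CUT)


def _classify_universe(
    test: Callset,
    truth: Callset,
    matches: Sequence[SiteMatch],
    thresholds: FilterThresholds,
) -> list[ClassifiedCall]:
    out: list[ClassifiedCall] = []
    for m in matches:
        if not m.in_a:
            continue  # truth-only sites carry no test calls to classify
        truth_site = m.site_in_b
        for sample in test.samples:
            tcall = test.get(sample, m.site)
            if tcall is None:
                continue  # this platform never reported the slot
            vcall = truth.get(sample, truth_site) if truth_site is not None else None
            cls, reason = classify_pair_detailed(tcall, vcall, thresholds)
            out.append(ClassifiedCall(sample=sample, site=m.site, classification=cls,
                                      test_call=tcall, truth_call=vcall,
                                      sub_reason=reason))
    return out


def build_stratified_report(
    test: Callset,
    truth: Callset,
    thresholds: FilterThresholds,
) -> StratifiedReport:
    """Classify every test call under both tranche cuts and summarize.

    The universe is every (sample, site) slot recorded by the test
    platform, at sites aligned across platforms by :func:`match_sites`.
    The strict stratum admits only pass-filter calls; the relaxed stratum
    adds the 99-99.9% tranche.  Per-site rows carry the tranche membership
    split plus relaxed-cut evaluation counts.
    """
    matches = match_sites(test, truth)
    strict_thr = replace(thresholds, tranche_cut=STRICT_CUT)
    relaxed_thr = replace(thresholds, tranche_cut=RELAXED_CUT)
    strict_calls = _classify_universe(test, truth, matches, strict_thr)
    relaxed_calls = _classify_universe(test, truth, matches, relaxed_thr)
    strict = summarize(strict_calls, "strict(<99%)")
    relaxed = summarize(relaxed_calls, "relaxed(<99.9%)")

    rows: dict[tuple, SiteRow] = {}
    for cc in relaxed_calls:
        row = rows.get(cc.site.key)
        if row is None:
            tranche = cc.test_call.tranche if cc.test_call else Tranche.NOT_APPLICABLE
            row = rows[cc.site.key] = SiteRow(site=cc.site, tranche=tranche)
        row.n_calls += 1
        if cc.classification in EVALUATED_CLASSES:
            row.n_evaluated += 1
        if cc.is_discordant:
            row.n_discordant += 1
    # sites only seen under exclusion (e.g. above-99.9% tranche) still get rows
    for cc in strict_calls:
        if cc.site.key not in rows:
            tranche = cc.test_call.tranche if cc.test_call else Tranche.NOT_APPLICABLE
            rows[cc.site.key] = SiteRow(site=cc.site, tranche=tranche)
    return StratifiedReport(strict=strict, relaxed=relaxed,
                            strict_calls=strict_calls, relaxed_calls=relaxed_calls,
                            site_rows=list(rows.values()))
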