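"""Domain model for cross-platform genotype comparison.

The central objects are :class:`VariantSite` (a normalized biallelic
variant), :class:`GenotypeCall` (one sample's diploid call at one site on
one platform, with its quality evidence) and :class:`Callset` (a platform's
collection of calls).  Sites are normalized by local allele trimming so that
VCF-styled and panel-styled representations of the same variant compare
equal, and callsets from different platforms are aligned with
:func:`match_sites`.

Conventions
-----------
* All in-memory positions are 1-based (VCF/dbSNP style).  BED input is
  converted on read.
* Genotypes are unordered and unphased diploid pairs; phase in input files
  is discarded.  Haploid or polyploid records are rejected.
* In a biallelic view of a multiallelic record, any allele that is neither
  the site's ref nor its alt is carried as ``Allele.OTHER`` rather than
  being silently folded into the reference class, so cross-allele
  disagreements stay visible downstream.
* Indel left-alignment against a reference genome is NOT performed;
  normalization is purely local suffix/prefix trimming.  Inputs that place
  the same indel at different anchor coordinates will not match (documented
  limitation; all supported comparisons declare identical coordinates).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .errors import (
    AmbiguousSiteError,
    DuplicateCallError,
    MalformedAlleleError,
    NoVariantError,
    PloidyError,
)

logger = logging.getLogger(__name__)

_DNA_RE = re.compile(r"^[ACGT]+$")


class Tranche(str, enum.Enum):
    """VQSR truth-sensitivity tranche of a test-platform call.

    ``PASS_99`` are calls below the 99% truth-sensitivity threshold
    ("pass-filter"); ``TRANCHE_99_999`` sit between 99% and 99.9%;
    ``ABOVE_999`` beyond that.  Non-exome platforms use ``NOT_APPLICABLE``.
    """

    PASS_99 = "PASS_99"
    TRANCHE_99_999 = "TRANCHE_99_999"
    ABOVE_999 = "ABOVE_999"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class Platform(str, enum.Enum):
    TEST_WES = "TEST_WES"
    TRUTH_AMPLICON = "TRUTH_AMPLICON"
    PANEL = "PANEL"
    SANGER = "SANGER"


class Allele(str, enum.Enum):
    """Allele class relative to a biallelic site."""

    REF = "ref"
    ALT = "alt"
    OTHER = "other"   # an allele foreign to this biallelic view
    MISSING = "."

    def __repr__(self) -> str:  # terse in test diffs
        return f"Allele.{self.name}"


#: canonical sort order inside an unordered genotype pair
_ALLELE_ORDER = {Allele.REF: 0, Allele.ALT: 1, Allele.OTHER: 2, Allele.MISSING: 3}

NO_CALL_ALLELES: tuple[Allele, Allele] = (Allele.MISSING, Allele.MISSING)
HOM_REF: tuple[Allele, Allele] = (Allele.REF, Allele.REF)
HET: tuple[Allele, Allele] = (Allele.REF, Allele.ALT)
HOM_ALT: tuple[Allele, Allele] = (Allele.ALT, Allele.ALT)


def sort_alleles(pair: Iterable[Allele]) -> tuple[Allele, Allele]:
    """Return the canonical (unordered) representation of a diploid pair."""
    a, b = pair
    return tuple(sorted((a, b), key=_ALLELE_ORDER.__getitem__))  # type: ignore[return-value]


# strict tranche cut: only pass-filter calls; relaxed adds the 99-99.9% tranche
STRICT_CUT: frozenset[Tranche] = frozenset({Tranche.PASS_99})
RELAXED_CUT: frozenset[Tranche] = frozenset({Tranche.PASS_99, Tranche.TRANCHE_99_999})


@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant site.

    Either full coordinates (contig, position, ref, alt) or at least an
    rsID must be present; panel export tables sometimes identify variants
    by rsID alone, and such sites participate in matching via the rsID
    fallback.

    ``position`` is the 1-based leftmost coordinate of ``ref``.
    """

    contig: Optional[str] = None
    position: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    rsid: Optional[str] = None
    gene: Optional[str] = None
    star_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref is not None or self.alt is not None:
            for name in ("ref", "alt"):
                allele = getattr(self, name)
                if allele is None or not _DNA_RE.match(allele or ""):
                    raise MalformedAlleleError(
                        f"{name} allele {allele!r} is not a non-empty A/C/G/T string"
                    )
            if self.ref == self.alt:
                raise MalformedAlleleError(f"ref and alt are both {self.ref!r}")
        if self.position is not None and self.position < 1:
            raise MalformedAlleleError(f"position {self.position} < 1 (positions are 1-based)")
        if self.coordinate_key is None and not self.rsid:
            raise MalformedAlleleError(
                "site needs either full coordinates (contig, position, ref, alt) or an rsID"
            )

    @property
    def coordinate_key(self) -> Optional[tuple[str, int, str, str]]:
        """Primary matching key; ``None`` for rsID-only sites."""
        if None in (self.contig, self.position, self.ref, self.alt):
            return None
        return (self.contig, self.position, self.ref, self.alt)  # type: ignore[return-value]

    @property
    def key(self) -> tuple:
        """Hashable identity used by callset dictionaries."""
        return self.coordinate_key or ("rsid", self.rsid)

    @property
    def label(self) -> str:
        if self.coordinate_key is not None:
            lab = f"{self.contig}:{self.position}{self.ref}>{self.alt}"
            return f"{lab} ({self.rsid})" if self.rsid else lab
        return self.rsid or "?"

    def allele_token(self, letters: str) -> Allele:
        """Classify a concrete allele string against this site's ref/alt."""
        if letters in (".", ""):
            return Allele.MISSING
        if letters == self.ref:
            return Allele.REF
        if letters == self.alt:
            return Allele.ALT
        return Allele.OTHER


def normalize_site(site: VariantSite) -> VariantSite:
    """Canonicalize a site by local allele trimming.

    The common suffix is removed first, then the common prefix (advancing
    ``position`` by one per removed leading base), always keeping both
    alleles non-empty — so an indel retains one shared anchor base.  The
    operation is idempotent and preserves the edit the alleles describe.
    """
    if site.coordinate_key is None:
        return site  # rsID-only sites have nothing to trim
    ref, alt, pos = site.ref, site.alt, site.position
    assert ref is not None and alt is not None and pos is not None
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (site.ref, site.alt, site.position):
        return site
    return replace(site, ref=ref, alt=alt, position=pos)


def split_multiallelic(
    contig: str,
    position: int,
    ref: str,
    alts: Sequence[str],
    genotypes: Mapping[str, tuple[Optional[int], Optional[int]]] | None = None,
    rsid: Optional[str] = None,
    gene: Optional[str] = None,
) -> list[tuple[VariantSite, dict[str, tuple[Allele, Allele]]]]:
    """Decompose a raw variant record with ``k`` alts into ``k`` biallelic sites.

    ``genotypes`` maps sample name to a diploid pair of allele *indices*
    (0 = ref, j = j-th alt, ``None`` = missing).  For each emitted biallelic
    site, each sample's indices are projected: 0 becomes ``REF``, the
    focal alt becomes ``ALT``, any other alt becomes ``OTHER``.  Allele
    copies are conserved across the emitted sites.

    Raises :class:`NoVariantError` when ``alts`` is empty and
    :class:`PloidyError` for non-diploid genotype tuples.
    """
    if len(alts) == 0:
        raise NoVariantError(f"{contig}:{position} has no alternate allele")
    out: list[tuple[VariantSite, dict[str, tuple[Allele, Allele]]]] = []
    genotypes = genotypes or {}
    for j, alt in enumerate(alts, start=1):
        site = normalize_site(
            VariantSite(contig=contig, position=position, ref=ref, alt=alt,
                        rsid=rsid, gene=gene)
        )
        projected: dict[str, tuple[Allele, Allele]] = {}
        for sample, idx_pair in genotypes.items():
            if len(idx_pair) != 2:
                raise PloidyError(
                    f"sample {sample} at {contig}:{position} has ploidy "
                    f"{len(idx_pair)}; only diploid calls are supported"
                )
            alleles = []
            for idx in idx_pair:
                if idx is None:
                    alleles.append(Allele.MISSING)
                elif idx == 0:
                    alleles.append(Allele.REF)
                elif idx == j:
                    alleles.append(Allele.ALT)
                else:
                    alleles.append(Allele.OTHER)
            projected[sample] = sort_alleles(alleles)
        out.append((site, projected))
    return out


@dataclass
class GenotypeCall:
    """One sample's diploid call at one site on one platform.

    Evidence fields are optional: absent means the platform did not report
    them (never zero).  ``depth`` is ``ref_reads + alt_reads`` when both
    read counts are present, otherwise the explicitly reported ``dp``.
    """

    sample: str
    site: VariantSite
    alleles: tuple[Allele, Allele]
    platform: Platform
    ref_reads: Optional[int] = None
    alt_reads: Optional[int] = None
    dp: Optional[int] = None
    gq: Optional[int] = None
    tranche: Tranche = Tranche.NOT_APPLICABLE
    call_rate: Optional[float] = None

    def __post_init__(self) -> None:
        self.alleles = sort_alleles(self.alleles)
        for name in ("ref_reads", "alt_reads", "dp", "gq"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.call_rate is not None and not (0.0 <= self.call_rate <= 100.0):
            raise ValueError(f"call_rate must be in [0, 100], got {self.call_rate}")

    @property
    def depth(self) -> Optional[int]:
        if self.ref_reads is not None and self.alt_reads is not None:
            return self.ref_reads + self.alt_reads
        return self.dp

    @property
    def is_no_call(self) -> bool:
        return self.alleles == NO_CALL_ALLELES

    @property
    def alt_copies(self) -> int:
        return sum(1 for a in self.alleles if a is Allele.ALT)

    @property
    def has_other_allele(self) -> bool:
        return Allele.OTHER in self.alleles

    @property
    def has_missing_allele(self) -> bool:
        return Allele.MISSING in self.alleles

    def genotype_string(self) -> str:
        """Concrete genotype, e.g. ``"T/C"``, using the site's allele letters."""
        letters = []
        for a in self.alleles:
            if a is Allele.REF:
                letters.append(self.site.ref or "ref")
            elif a is Allele.ALT:
                letters.append(self.site.alt or "alt")
            elif a is Allele.OTHER:
                letters.append("*")
            else:
                letters.append(".")
        return "/".join(letters)


@dataclass
class FilterThresholds:
    """Evaluability constants for the three platforms.

    Defaults implement the published rules: test calls need read depth >= 4
    and genotype quality >= 10; amplicon truth calls need depth >= 10;
    panel calls need a call rate strictly greater than 85%; and the tranche
    cut selects which VQSR strata enter the comparison.
    """

    test_dp_min: int = 4
    test_gq_min: int = 10
    truth_dp_min: int = 10
    panel_call_rate_min: float = 85.0   # exclusive bound
    tranche_cut: frozenset[Tranche] = STRICT_CUT

    def __post_init__(self) -> None:
        if min(self.test_dp_min, self.test_gq_min, self.truth_dp_min) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.panel_call_rate_min < 0:
            raise ValueError("panel_call_rate_min must be >= 0")
        self.tranche_cut = frozenset(self.tranche_cut)
        if not self.tranche_cut:
            raise ValueError("tranche_cut must be non-empty")


@dataclass
class Callset:
    """All calls from one platform, keyed by (sample, normalized site)."""

    platform: Platform
    samples: list[str] = field(default_factory=list)
    sites: list[VariantSite] = field(default_factory=list)
    _calls: dict[tuple[str, tuple], GenotypeCall] = field(default_factory=dict)
    _site_index: dict[tuple, VariantSite] = field(default_factory=dict)

    def add_site(self, site: VariantSite) -> VariantSite:
        existing = self._site_index.get(site.key)
        if existing is None:
            self._site_index[site.key] = site
            self.sites.append(site)
            return site
        return existing

    def add(self, call: GenotypeCall) -> None:
        if call.platform is not self.platform:
            raise ValueError(
                f"call platform {call.platform} does not match callset {self.platform}"
            )
        key = (call.sample, call.site.key)
        if key in self._calls:
            raise DuplicateCallError(
                f"duplicate call for sample {call.sample} at {call.site.label}"
            )
        self.add_site(call.site)
        if call.sample not in self.samples:
            self.samples.append(call.sample)
        self._calls[key] = call

    def get(self, sample: str, site: VariantSite) -> Optional[GenotypeCall]:
        return self._calls.get((sample, site.key))

    def get_by_key(self, sample: str, site_key: tuple) -> Optional[GenotypeCall]:
        return self._calls.get((sample, site_key))

    def calls(self) -> Iterable[GenotypeCall]:
        return self._calls.values()

    def site_by_key(self, key: tuple) -> Optional[VariantSite]:
        return self._site_index.get(key)

    def __len__(self) -> int:
        return len(self._calls)


@dataclass(frozen=True)
class SiteMatch:
    """One entry of the cross-callset site union with membership flags."""

    site: VariantSite
    in_a: bool
    in_b: bool
    site_in_b: Optional[VariantSite] = None   # b's representation when matched
    matched_by_rsid: bool = False

    @property
    def in_both(self) -> bool:
        return self.in_a and self.in_b


def _rsid_index(callset: Callset) -> dict[str, list[VariantSite]]:
    idx: dict[str, list[VariantSite]] = {}
    for site in callset.sites:
        if site.rsid:
            idx.setdefault(site.rsid, []).append(site)
    return idx


def _rsid_lookup(idx: dict[str, list[VariantSite]], rsid: str) -> Optional[VariantSite]:
    hits = idx.get(rsid, [])
    if not hits:
        return None
    coord_keys = {s.coordinate_key for s in hits if s.coordinate_key is not None}
    if len(coord_keys) > 1:
        raise AmbiguousSiteError(
            f"rsID {rsid} maps to conflicting coordinates: "
            + "; ".join(sorted(str(k) for k in coord_keys))
        )
    return hits[0]


def match_sites(a: Callset, b: Callset) -> list[SiteMatch]:
    """Align the site rosters of two callsets.

    The primary key is (contig, position, ref, alt); when either side
    carries only an rsID, rsID matching is the fallback (fallback matches
    are logged).  The output covers the union of sites, with membership
    flags that partition it into a-only / both / b-only.
    """
    b_coords = {s.coordinate_key: s for s in b.sites if s.coordinate_key is not None}
    a_rsids = _rsid_index(a)
    b_rsids = _rsid_index(b)

    matches: list[SiteMatch] = []
    matched_b_keys: set[tuple] = set()
    for site in a.sites:
        b_site: Optional[VariantSite] = None
        by_rsid = False
        if site.coordinate_key is not None and site.coordinate_key in b_coords:
            b_site = b_coords[site.coordinate_key]
        elif site.rsid:
            candidate = _rsid_lookup(b_rsids, site.rsid)
            # fall back to rsID only when one side lacks coordinates
            if candidate is not None and (
                site.coordinate_key is None or candidate.coordinate_key is None
            ):
                if site.coordinate_key is not None:
                    _rsid_lookup(a_rsids, site.rsid)  # surface a-side conflicts too
                b_site = candidate
                by_rsid = True
                logger.info("site %s matched to %s via rsID fallback",
                            site.label, b_site.label)
        if b_site is not None:
            matched_b_keys.add(b_site.key)
        matches.append(SiteMatch(site=site, in_a=True, in_b=b_site is not None,
                                 site_in_b=b_site, matched_by_rsid=by_rsid))
    for site in b.sites:
        if site.key not in matched_b_keys:
            matches.append(SiteMatch(site=site, in_a=False, in_b=True, site_in_b=site))
    return matches
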