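"""Readers and writers for every external representation the pipeline touches.

Formats: VCF 4.x (via pysam) for test and truth callsets, BED3 for capture
targets, tab-separated tables for the genotyping-panel export, Sanger
adjudication results, per-call reports and stratified summaries, and YAML
for threshold configuration.

Tranche dialect
---------------
VQSR tranche membership arrives in the VCF FILTER column.  The default
dialect maps ``PASS`` (or ``.``) to the pass-filter stratum, any filter
string matching ``VQSRTranche*99.00to99.90`` to the 99-99.9% tranche, and
any other non-empty FILTER to the beyond-99.9% stratum with a logged
warning.  Because variant-caller versions differ in the exact strings they
emit, the dialect is an ordered, user-extensible list of regex rules.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
import yaml

from .callset_model import (
    Allele,
    Callset,
    FilterThresholds,
    GenotypeCall,
    Platform,
    RELAXED_CUT,
    STRICT_CUT,
    Tranche,
    VariantSite,
    normalize_site,
    sort_alleles,
    split_multiallelic,
)
from .concordance import (
    AdjudicationRecord,
    Classification,
    ClassifiedCall,
    ConcordanceSummary,
    StratifiedReport,
)
from .errors import (
    ForeignAlleleError,
    MalformedIntervalError,
    ParseError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tranche dialect

@dataclass(frozen=True)
class TrancheRule:
    pattern: re.Pattern
    tranche: Tranche


DEFAULT_TRANCHE_DIALECT: tuple[TrancheRule, ...] = (
    TrancheRule(re.compile(r"^(PASS|\.)$"), Tranche.PASS_99),
    TrancheRule(re.compile(r"VQSRTranche\w*99\.00to99\.90"), Tranche.TRANCHE_99_999),
)

#: FILTER strings written back out for each tranche
TRANCHE_FILTER_STRINGS = {
    Tranche.PASS_99: "PASS",
    Tranche.TRANCHE_99_999: "VQSRTrancheSNP99.00to99.90",
    Tranche.ABOVE_999: "VQSRTrancheSNP99.90to100.00",
    Tranche.NOT_APPLICABLE: "PASS",
}


def filter_to_tranche(
    filter_string: str,
    dialect: Sequence[TrancheRule] = DEFAULT_TRANCHE_DIALECT,
) -> Tranche:
    """Map a VCF FILTER string to a tranche via the first matching rule.

    Unrecognized non-empty strings fall through to ``ABOVE_999`` with a
    warning: an unknown filter means the call failed some tranche beyond
    the ones we stratify, and must not silently enter the pass stratum.
    """
    for rule in dialect:
        if rule.pattern.search(filter_string):
            return rule.tranche
    logger.warning("unrecognized FILTER %r mapped to ABOVE_999", filter_string)
    return Tranche.ABOVE_999


def dialect_from_config(rules: Iterable[dict]) -> tuple[TrancheRule, ...]:
    """Build a dialect from config entries like {pattern: ..., tranche: ...}."""
    return tuple(
        TrancheRule(re.compile(r["pattern"]), Tranche(r["tranche"])) for r in rules
    )


# ---------------------------------------------------------------------------
# VCF

def read_vcf_callset(
    path: str | Path,
    platform: Platform,
    tranche_dialect: Sequence[TrancheRule] = DEFAULT_TRANCHE_DIALECT,
) -> Callset:
    """Load a multi-sample VCF into a normalized, biallelic callset.

    Multiallelic records are split and each sample's genotype projected
    onto every emitted biallelic site.  ``./.`` genotypes become no-calls;
    absent DP/GQ/AD are recorded as absent, never zero; AD supplies the
    per-allele read counts, with DP reconstructed from AD when both counts
    are present.
    """
    callset = Callset(platform=platform)
    with pysam.VariantFile(str(path)) as vcf:
        if "GT" not in vcf.header.formats:
            raise ParseError(f"{path}: VCF has no GT FORMAT definition")
        sample_names = list(vcf.header.samples)
        callset.samples.extend(sample_names)
        for rec in vcf:
            alts = [a for a in (rec.alts or []) if a is not None]
            if not alts or any(not re.match(r"^[ACGTacgt]+$", a) for a in [rec.ref, *alts]):
                logger.warning("skipping non-sequence record at %s:%s", rec.contig, rec.pos)
                continue
            filters = list(rec.filter.keys())
            filter_string = ";".join(filters) if filters else "."
            tranche = (filter_to_tranche(filter_string, tranche_dialect)
                       if platform is Platform.TEST_WES else Tranche.NOT_APPLICABLE)
            genotypes: dict[str, tuple[Optional[int], Optional[int]]] = {}
            for s in sample_names:
                gt = rec.samples[s].get("GT")
                if gt is None or all(a is None for a in gt):
                    gt = (None, None)
                genotypes[s] = tuple(gt)  # ploidy checked in split_multiallelic
            rsid = rec.id if rec.id not in (None, ".") else None
            for j, (site, projected) in enumerate(
                split_multiallelic(rec.contig, rec.pos, rec.ref.upper(),
                                   [a.upper() for a in alts], genotypes, rsid=rsid),
                start=1,
            ):
                for s in sample_names:
                    fmt = rec.samples[s]
                    ad = fmt.get("AD")
                    ref_reads = alt_reads = None
                    if ad is not None and len(ad) > j and ad[0] is not None:
                        ref_reads = int(ad[0])
                        alt_reads = int(ad[j]) if ad[j] is not None else None
                    dp = fmt.get("DP")
                    gq = fmt.get("GQ")
                    callset.add(GenotypeCall(
                        sample=s, site=site, alleles=projected[s], platform=platform,
                        ref_reads=ref_reads, alt_reads=alt_reads,
                        dp=int(dp) if dp is not None else None,
                        gq=int(gq) if gq is not None else None,
                        tranche=tranche,
                    ))
    return callset


def write_vcf_callset(callset: Callset, path: str | Path) -> None:
    """Write a callset as an uncompressed multi-sample VCF 4.2 file.

    Tranches are encoded in FILTER using the default dialect's canonical
    strings.  Sites with foreign ("other") alleles cannot be represented in
    a biallelic record and are rejected.
    """
    header = pysam.VariantHeader()
    contigs: dict[str, int] = {}
    for site in callset.sites:
        if site.coordinate_key is None:
            raise ParseError(f"cannot write coordinate-less site {site.label} to VCF")
        end = site.position + len(site.ref)
        contigs[site.contig] = max(contigs.get(site.contig, 0), end + 1000)
    for contig, length in sorted(contigs.items()):
        header.contigs.add(contig, length=length)
    for name, string in TRANCHE_FILTER_STRINGS.items():
        if string != "PASS":
            header.filters.add(string, None, None, f"VQSR tranche {name.value}")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Approximate read depth")
    header.formats.add("GQ", 1, "Integer", "Phred-scaled genotype quality")
    for s in callset.samples:
        header.add_sample(s)

    def sort_key(site: VariantSite):
        return (site.contig, site.position, site.ref, site.alt)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sorted(callset.sites, key=sort_key):
            rec = out.new_record(contig=site.contig, start=site.position - 1,
                                 alleles=(site.ref, site.alt), id=site.rsid)
            tranche = Tranche.NOT_APPLICABLE
            for s in callset.samples:
                call = callset.get(s, site)
                fmt = rec.samples[s]
                if call is None or call.is_no_call:
                    fmt["GT"] = (None, None)
                else:
                    if call.has_other_allele:
                        raise ParseError(
                            f"cannot write foreign allele at {site.label} to biallelic VCF"
                        )
                    idx = tuple(0 if a is Allele.REF else 1 for a in call.alleles)
                    fmt["GT"] = idx
                if call is not None:
                    if call.ref_reads is not None and call.alt_reads is not None:
                        fmt["AD"] = (call.ref_reads, call.alt_reads)
                    if call.depth is not None:
                        fmt["DP"] = call.depth
                    if call.gq is not None:
                        fmt["GQ"] = call.gq
                    tranche = call.tranche
            filter_string = TRANCHE_FILTER_STRINGS[tranche]
            rec.filter.add(filter_string if filter_string != "PASS" else "PASS")
            out.write(rec)


# ---------------------------------------------------------------------------
# BED capture targets

@dataclass
class TargetIntervals:
    """Capture-target intervals, 1-based closed, merged and sorted per contig."""

    by_contig: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "TargetIntervals":
        """Build from 1-based closed (contig, start, end) triples, merging overlaps."""
        raw: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            if start > end:
                raise MalformedIntervalError(f"interval [{start}, {end}] has start > end")
            raw.setdefault(contig, []).append((start, end))
        merged: dict[str, list[tuple[int, int]]] = {}
        for contig, ivs in raw.items():
            ivs.sort()
            acc: list[tuple[int, int]] = []
            for s, e in ivs:
                if acc and s <= acc[-1][1] + 1:  # adjacent closed intervals merge
                    acc[-1] = (acc[-1][0], max(acc[-1][1], e))
                else:
                    acc.append((s, e))
            merged[contig] = acc
        return cls(by_contig=merged)

    @property
    def n_intervals(self) -> int:
        return sum(len(v) for v in self.by_contig.values())

    def total_bases(self) -> int:
        return sum(e - s + 1 for ivs in self.by_contig.values() for s, e in ivs)


def read_target_bed(path: str | Path) -> TargetIntervals:
    """Read BED3 (0-based half-open) capture targets into 1-based closed intervals."""
    triples: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise MalformedIntervalError(f"{path}:{lineno}: fewer than 3 BED columns")
            contig, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise MalformedIntervalError(f"{path}:{lineno}: non-integer bounds") from exc
            if start >= end:
                raise MalformedIntervalError(
                    f"{path}:{lineno}: start {start} >= end {end} (BED is half-open)"
                )
            triples.append((contig, start + 1, end))
    return TargetIntervals.from_intervals(triples)


def write_target_bed(targets: TargetIntervals, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig in sorted(targets.by_contig):
            for s, e in targets.by_contig[contig]:
                fh.write(f"{contig}\t{s - 1}\t{e}\n")


# ---------------------------------------------------------------------------
# panel table (tab-separated genotyping-panel export)

PANEL_COLUMNS = ["sample_id", "rsid", "contig", "position", "ref", "alt",
                 "genotype", "call_rate"]


def _parse_genotype_cell(cell: str, site: VariantSite, row_label: str) -> tuple[Allele, Allele]:
    if cell is None or str(cell).strip() in ("", ".", "./.", "nan"):
        return (Allele.MISSING, Allele.MISSING)
    letters = re.split(r"[/|]", str(cell).strip())
    if len(letters) != 2:
        raise ParseError(f"{row_label}: genotype {cell!r} is not a diploid pair")
    alleles = []
    for letter in letters:
        token = site.allele_token(letter.upper())
        if token is Allele.OTHER:
            raise ForeignAlleleError(
                f"{row_label}: genotype letter {letter!r} matches neither "
                f"ref {site.ref!r} nor alt {site.alt!r}"
            )
        alleles.append(token)
    return sort_alleles(alleles)


def read_panel_table(path: str | Path) -> Callset:
    """Read a genotyping-panel export table into a PANEL callset.

    Expected tab-separated columns: ``sample_id  rsid  contig  position
    ref  alt  genotype  call_rate``; contig/position may be empty (the site
    then participates in matching by rsID only).  An empty genotype cell is
    a no-call; a genotype letter matching neither ref nor alt is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "rsid", "ref", "alt", "genotype", "call_rate")
               if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: panel table lacks columns {missing}")
    callset = Callset(platform=Platform.PANEL)
    for i, row in df.iterrows():
        row_label = f"{path}:row {i + 2}"   # +2: header and 1-based
        contig = row.get("contig")
        position = row.get("position")
        has_coords = pd.notna(contig) and pd.notna(position) and str(contig).strip()
        site = VariantSite(
            contig=str(contig) if has_coords else None,
            position=int(position) if has_coords else None,
            ref=str(row["ref"]).upper(), alt=str(row["alt"]).upper(),
            rsid=str(row["rsid"]) if pd.notna(row["rsid"]) else None,
        )
        site = normalize_site(site)
        alleles = _parse_genotype_cell(row["genotype"], site, row_label)
        call_rate = (float(row["call_rate"])
                     if pd.notna(row["call_rate"]) and str(row["call_rate"]).strip() != ""
                     else None)
        callset.add(GenotypeCall(
            sample=str(row["sample_id"]), site=site, alleles=alleles,
            platform=Platform.PANEL, call_rate=call_rate,
        ))
    return callset


def write_panel_table(callset: Callset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PANEL_COLUMNS)
        for call in callset.calls():
            site = call.site
            gt = "" if call.is_no_call else call.genotype_string()
            w.writerow([
                call.sample, site.rsid or "", site.contig or "",
                site.position if site.position is not None else "",
                site.ref or "", site.alt or "", gt,
                f"{call.call_rate:.1f}" if call.call_rate is not None else "",
            ])


def read_truth_table(path: str | Path) -> Callset:
    """Read an amplicon-truth genotype table (TSV alternative to a truth VCF).

    Columns as in the panel table but with ``depth`` (approximate read
    depth) in place of ``call_rate``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "ref", "alt", "genotype") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: truth table lacks columns {missing}")
    callset = Callset(platform=Platform.TRUTH_AMPLICON)
    for i, row in df.iterrows():
        row_label = f"{path}:row {i + 2}"
        contig = row.get("contig")
        position = row.get("position")
        has_coords = pd.notna(contig) and pd.notna(position) and str(contig).strip()
        site = normalize_site(VariantSite(
            contig=str(contig) if has_coords else None,
            position=int(position) if has_coords else None,
            ref=str(row["ref"]).upper(), alt=str(row["alt"]).upper(),
            rsid=str(row["rsid"]) if pd.notna(row.get("rsid")) else None,
        ))
        alleles = _parse_genotype_cell(row["genotype"], site, row_label)
        depth = row.get("depth")
        callset.add(GenotypeCall(
            sample=str(row["sample_id"]), site=site, alleles=alleles,
            platform=Platform.TRUTH_AMPLICON,
            dp=int(depth) if pd.notna(depth) and str(depth).strip() != "" else None,
        ))
    return callset


# ---------------------------------------------------------------------------
# adjudication table

def read_adjudication_table(path: str | Path) -> list[AdjudicationRecord]:
    """Read Sanger adjudication results.

    Tab-separated columns: ``sample_id  rsid  contig  position  ref  alt
    sanger_genotype`` (coordinates optional when an rsID is given).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = [c for c in ("sample_id", "ref", "alt", "sanger_genotype") if c not in df.columns]
    if needed:
        raise ParseError(f"{path}: adjudication table lacks columns {needed}")
    records: list[AdjudicationRecord] = []
    for i, row in df.iterrows():
        row_label = f"{path}:row {i + 2}"
        contig = row.get("contig")
        position = row.get("position")
        has_coords = pd.notna(contig) and pd.notna(position) and str(contig).strip()
        site = normalize_site(VariantSite(
            contig=str(contig) if has_coords else None,
            position=int(position) if has_coords else None,
            ref=str(row["ref"]).upper(), alt=str(row["alt"]).upper(),
            rsid=str(row["rsid"]) if pd.notna(row.get("rsid")) else None,
        ))
        alleles = _parse_genotype_cell(row["sanger_genotype"], site, row_label)
        records.append(AdjudicationRecord(sample=str(row["sample_id"]), site=site,
                                          alleles=alleles))
    return records


# ---------------------------------------------------------------------------
# per-call report

REPORT_COLUMNS = [
    "sample", "contig", "position", "ref", "alt", "rsid", "gene", "tranche",
    "test_genotype", "truth_genotype", "ref_reads", "alt_reads", "gq",
    "truth_depth", "call_rate", "classification", "sub_reason",
]


def _opt(v) -> str:
    return "" if v is None else str(v)


def write_call_report(classified: Sequence[ClassifiedCall], path: str | Path) -> None:
    """One row per classified (sample, site) pair with evidence and class."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REPORT_COLUMNS)
        for cc in classified:
            site = cc.site
            t, v = cc.test_call, cc.truth_call
            w.writerow([
                cc.sample, _opt(site.contig), _opt(site.position), _opt(site.ref),
                _opt(site.alt), _opt(site.rsid), _opt(site.gene),
                t.tranche.value if t else "",
                t.genotype_string() if t else "",
                v.genotype_string() if v else "",
                _opt(t.ref_reads if t else None), _opt(t.alt_reads if t else None),
                _opt(t.gq if t else None), _opt(v.depth if v else None),
                _opt(v.call_rate if v else None),
                cc.classification.value, _opt(cc.sub_reason),
            ])


def read_call_report(path: str | Path) -> list[ClassifiedCall]:
    """Re-read a call report (identity round-trip for sample/site/genotypes/class)."""
    out: list[ClassifiedCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            has_coords = row["contig"] != "" and row["position"] != ""
            site = VariantSite(
                contig=row["contig"] or None,
                position=int(row["position"]) if has_coords else None,
                ref=row["ref"] or None, alt=row["alt"] or None,
                rsid=row["rsid"] or None, gene=row["gene"] or None,
            )
            def call_from(gt_cell: str, platform: Platform, **kw) -> Optional[GenotypeCall]:
                if gt_cell == "":
                    return None
                alleles = _parse_genotype_cell(gt_cell, site, str(path))
                return GenotypeCall(sample=row["sample"], site=site, alleles=alleles,
                                    platform=platform, **kw)
            test_call = call_from(
                row["test_genotype"], Platform.TEST_WES,
                ref_reads=int(row["ref_reads"]) if row["ref_reads"] else None,
                alt_reads=int(row["alt_reads"]) if row["alt_reads"] else None,
                gq=int(row["gq"]) if row["gq"] else None,
                tranche=Tranche(row["tranche"]) if row["tranche"] else Tranche.NOT_APPLICABLE,
            )
            truth_call = call_from(
                row["truth_genotype"], Platform.TRUTH_AMPLICON,
                dp=int(row["truth_depth"]) if row["truth_depth"] else None,
                call_rate=float(row["call_rate"]) if row["call_rate"] else None,
            )
            out.append(ClassifiedCall(
                sample=row["sample"], site=site,
                classification=Classification(row["classification"]),
                test_call=test_call, truth_call=truth_call,
                sub_reason=row["sub_reason"] or None,
            ))
    return out


# ---------------------------------------------------------------------------
# summary table

SUMMARY_ROWS = [
    ("Variant sites", "n_variant_sites"),
    ("Total genotype calls", "n_total_calls"),
    ("DP/GQ below threshold", "n_low_quality"),
    ("No-calls", "n_no_calls"),
    ("Missing truth data", "n_missing_truth"),
    ("Total calls evaluated", "n_evaluated"),
    ("Discordant calls", "n_discordant"),
    ("False-positives", "n_false_positive"),
    ("False-negatives", "n_false_negative"),
    ("Mixed-discordant", "n_mixed"),
]


def write_summary(
    summaries: Sequence[ConcordanceSummary] | StratifiedReport,
    path: str | Path,
) -> None:
    """Write the two-column (strict | relaxed) stratified summary block."""
    if isinstance(summaries, StratifiedReport):
        summaries = [summaries.strict, summaries.relaxed]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["Metric", *(s.stratum for s in summaries)])
        for label, attr in SUMMARY_ROWS:
            w.writerow([label, *(getattr(s, attr) for s in summaries)])
        w.writerow(["Concordance rate (%)", *(s.concordance_rate_str for s in summaries)])


def write_site_table(report: StratifiedReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig", "position", "ref", "alt", "rsid", "gene", "tranche",
                    "n_calls", "n_evaluated", "n_discordant"])
        for r in report.site_rows:
            s = r.site
            w.writerow([_opt(s.contig), _opt(s.position), _opt(s.ref), _opt(s.alt),
                        _opt(s.rsid), _opt(s.gene), r.tranche.value,
                        r.n_calls, r.n_evaluated, r.n_discordant])


# ---------------------------------------------------------------------------
# site catalog (gene / region / id / star allele / tranche lists)

@dataclass(frozen=True)
class SiteListEntry:
    gene: str
    region: str
    identifier: str        # rsID or "contig:position REF>ALT" style label
    star_allele: Optional[str]
    tranche: Tranche


def read_site_list(path: str | Path) -> list[SiteListEntry]:
    """Read a catalog of known sites with their tranche assignment.

    Tab-separated columns: ``gene  region  id  star_allele  tranche``.
    """
    entries: list[SiteListEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            entries.append(SiteListEntry(
                gene=row["gene"], region=row["region"], identifier=row["id"],
                star_allele=row["star_allele"] or None,
                tranche=Tranche(row["tranche"]),
            ))
    return entries


def load_pharmacogene_site_catalog() -> list[SiteListEntry]:
    """The shipped catalog of CYP2D6/CYP2C19 variant sites with their VQSR
    tranche assignments (43 sites: 27 pass-filter, 16 in the 99-99.9%
    tranche)."""
    from importlib.resources import files

    path = files("pgxconcord").joinpath("data/cyp2d6_cyp2c19_sites.tsv")
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [SiteListEntry(
            gene=row["gene"], region=row["region"], identifier=row["id"],
            star_allele=row["star_allele"] or None, tranche=Tranche(row["tranche"]),
        ) for row in reader]


# ---------------------------------------------------------------------------
# YAML thresholds

def load_thresholds(path: str | Path) -> FilterThresholds:
    """Load filter thresholds from a YAML mapping.

    Recognized keys: ``test_dp_min``, ``test_gq_min``, ``truth_dp_min``,
    ``panel_call_rate_min``, ``tranche`` ("strict" or "relaxed").
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cut = {"strict": STRICT_CUT, "relaxed": RELAXED_CUT}[cfg.pop("tranche", "strict")]
    return FilterThresholds(tranche_cut=cut, **cfg)
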