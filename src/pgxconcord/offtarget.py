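"""Distance-to-capture-target annotation and coverage-by-distance analysis.

Exome capture produces usable calls some distance beyond the declared
target intervals, because contiguous probes capture overhanging fragment
sequence.  This module measures, for each variant site, the gap in bases
to the nearest target interval (0 when the position lies inside one),
classifies sites against a padding radius (default 100 bases, the distance
beyond which aggregate coverage is consistently poor), and bins aggregate
read depth by distance to expose that decay.

Distances are measured from the variant's normalized leftmost position
only; indel end positions are ignored (each site gets a single base
distance).  For position p left of a 1-based closed interval [s, e] the
gap is s - p; to the right it is e is p - e.  A site on a contig with no
targets at all is flagged uncapturable (infinite distance).
"""

from __future__ import annotations

import csv
import math
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .callset_model import VariantSite
from .io_formats import TargetIntervals

DEFAULT_PADDING = 100          # bases
DEFAULT_LOW_COVERAGE = 150     # summed read depth across samples


def distance_to_target(site: VariantSite, targets: TargetIntervals) -> float:
    """Gap in bases from a site's position to the nearest target interval.

    Returns 0 inside an interval, a positive integer otherwise, and
    ``math.inf`` when the site's contig carries no targets.
    """
    if site.position is None:
        raise ValueError(f"site {site.label} has no coordinates")
    intervals = targets.by_contig.get(site.contig or "", [])
    if not intervals:
        return math.inf
    pos = site.position
    starts = [s for s, _ in intervals]
    i = bisect_right(starts, pos) - 1   # last interval starting at or before pos
    best = math.inf
    if i >= 0:
        s, e = intervals[i]
        best = 0 if pos <= e else pos - e
    if i + 1 < len(intervals):
        s, _ = intervals[i + 1]
        best = min(best, s - pos)
    return float(best) if best != int(best) else int(best)


@dataclass
class OffTargetAnnotation:
    """One site's relation to the capture design."""

    site: VariantSite
    distance: float                      # bases; 0 = on-target; inf = uncapturable
    aggregate_depth: Optional[int] = None  # summed across samples
    padding: int = DEFAULT_PADDING

    @property
    def on_target(self) -> bool:
        return self.distance == 0

    @property
    def within_padding(self) -> bool:
        return self.distance <= self.padding

    @property
    def uncapturable(self) -> bool:
        return math.isinf(self.distance)

    @property
    def category(self) -> str:
        if self.on_target:
            return "on_target"
        if self.within_padding:
            return "within_padding"
        return "beyond_padding"


def classify_off_target(
    sites: Iterable[VariantSite],
    targets: TargetIntervals,
    padding: int = DEFAULT_PADDING,
    depths: Optional[dict[tuple, int]] = None,
) -> list[OffTargetAnnotation]:
    """Annotate sites with distance and padding class.

    ``depths`` optionally maps site keys to aggregate (summed-over-samples)
    read depth for the coverage analysis.
    """
    out = []
    for site in sites:
        d = distance_to_target(site, targets)
        depth = depths.get(site.key) if depths else None
        out.append(OffTargetAnnotation(site=site, distance=d,
                                       aggregate_depth=depth, padding=padding))
    return out


@dataclass
class DistanceBin:
    """Aggregate-depth statistics for one distance bin [lo, hi)."""

    lo: float
    hi: float
    n_sites: int
    median_depth: Optional[float]
    max_depth: Optional[float]
    low_coverage: bool

    @property
    def label(self) -> str:
        hi = "inf" if math.isinf(self.hi) else f"{self.hi:g}"
        return f"[{self.lo:g}, {hi})"


DEFAULT_BIN_EDGES: tuple[float, ...] = (0, 1, 26, 51, 101, 201, math.inf)


def coverage_by_distance(
    annotations: Sequence[OffTargetAnnotation],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    low_coverage_threshold: float = DEFAULT_LOW_COVERAGE,
) -> list[DistanceBin]:
    """Bin sites by distance and summarize aggregate depth per bin.

    Bins are half-open ``[edge[i], edge[i+1])``; a final edge of ``inf``
    collects uncapturable sites.  A bin is flagged low-coverage when its
    maximum aggregate depth falls below the threshold; empty bins report
    blank depths and no flag.
    """
    bins: list[DistanceBin] = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        depths = [a.aggregate_depth for a in annotations
                  if lo <= a.distance < hi or (math.isinf(hi) and math.isinf(a.distance))]
        n = len(depths)
        known = [d for d in depths if d is not None]
        median = float(np.median(known)) if known else None
        mx = float(max(known)) if known else None
        low = mx is not None and mx < low_coverage_threshold
        bins.append(DistanceBin(lo=lo, hi=hi, n_sites=n,
                                median_depth=median, max_depth=mx, low_coverage=low))
    return bins


def write_offtarget_report(
    annotations: Sequence[OffTargetAnnotation],
    path: str | Path,
    beyond_padding_only: bool = False,
) -> None:
    """Tab-separated per-site annotation report (gene, rsid, distance, class)."""
    rows = [a for a in annotations
            if not beyond_padding_only or a.category == "beyond_padding"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig", "position", "ref", "alt", "rsid", "gene",
                    "distance", "category", "aggregate_depth"])
        for a in rows:
            s = a.site
            dist = "uncapturable" if a.uncapturable else str(int(a.distance))
            w.writerow([s.contig or "", s.position or "", s.ref or "", s.alt or "",
                        s.rsid or "", s.gene or "", dist, a.category,
                        a.aggregate_depth if a.aggregate_depth is not None else ""])
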