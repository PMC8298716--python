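"""Locus multiplicity classes and region membership.

A piRNA's multiplicity is the number of distinct genomic intervals it is
annotated at.  Default bins: single (1), oligo (2-9), mid (10-100),
high (>100).  Membership against a region set (piRNA clusters, the
mitochondrial genome, a named imprinted interval) is piRNA-level: the flag
is true iff >= 1 of the piRNA's loci overlaps the set by >= 1 bp
(half-open; strand ignored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .core import BIN_LABELS, CHROM_MT, FilterConfig, GenomicInterval, PiRNARecord, RegionSet


def locus_count(pirna: PiRNARecord) -> int:
    """Number of distinct genomic loci (the loci set de-duplicates)."""
    return len(pirna.loci)


def classify_multiplicity(count: int, config: FilterConfig) -> str:
    """Bin a locus count by the configured edges (default 1 | 2-9 | 10-100 | >100)."""
    if count < 1:
        raise ValueError(f"locus count must be >= 1, got {count}")
    e1, e2, e3 = config.multiplicity_bins
    if count <= e1:
        return "single"
    if count <= e2:
        return "oligo"
    if count <= e3:
        return "mid"
    return "high"


class RegionIndex:
    """Interval-tree index over a RegionSet for fast overlap queries."""

    def __init__(self, regions: RegionSet) -> None:
        self.name = regions.name
        self._trees: dict[str, IntervalTree] = {}
        for r in regions.regions:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)

    def overlaps(self, locus: GenomicInterval) -> bool:
        tree = self._trees.get(locus.chrom)
        return bool(tree is not None and tree.overlap(locus.start, locus.end))


def overlaps_region(locus: GenomicInterval, regions: RegionSet | RegionIndex) -> bool:
    """True iff the locus shares >= 1 bp with any region (same chromosome).

    Half-open convention: abutting intervals (end == start) do not overlap.
    """
    if isinstance(regions, RegionSet):
        regions = RegionIndex(regions)
    return regions.overlaps(locus)


@dataclass
class MultiplicityReport:
    """Per-piRNA locus counts/bins plus set-level totals."""

    per_pirna: pd.DataFrame
    bin_totals: dict[str, int]
    n_distinct_loci: int
    n_distinct_loci_low: int
    low_multiplicity_ceiling: int
    per_chromosome: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "bin_totals": self.bin_totals,
            "n_distinct_loci": self.n_distinct_loci,
            "low_multiplicity_ceiling": self.low_multiplicity_ceiling,
            "n_distinct_loci_low_multiplicity": self.n_distinct_loci_low,
            "per_chromosome": self.per_chromosome,
        }


def multiplicity_report(
    pirnas: dict[str, PiRNARecord],
    config: FilterConfig,
    low_multiplicity_ceiling: int | None = None,
) -> MultiplicityReport:
    """Bin the analysed piRNAs and tally their loci.

    Distinct-locus totals de-duplicate identical intervals shared across
    piRNAs.  ``n_distinct_loci_low`` counts the distinct loci contributed by
    piRNAs with fewer than ``low_multiplicity_ceiling`` loci (default: the
    lower edge of the "mid" bin, i.e. < 10 loci).
    """
    if not pirnas:
        raise ValueError("empty piRNA set")
    if low_multiplicity_ceiling is None:
        low_multiplicity_ceiling = config.multiplicity_bins[1] + 1
    rows = []
    all_loci: set[tuple[str, int, int]] = set()
    low_loci: set[tuple[str, int, int]] = set()
    for pid in sorted(pirnas):
        rec = pirnas[pid]
        n = locus_count(rec)
        rows.append({"pirna_id": pid, "locus_count": n,
                     "bin": classify_multiplicity(n, config)})
        keys = {(l.chrom, l.start, l.end) for l in rec.loci}
        all_loci |= keys
        if n < low_multiplicity_ceiling:
            low_loci |= keys
    per = pd.DataFrame(rows).set_index("pirna_id")
    bins = {label: int((per["bin"] == label).sum()) for label in BIN_LABELS}
    chrom_tally: dict[str, int] = {}
    for chrom, _, _ in all_loci:
        chrom_tally[chrom] = chrom_tally.get(chrom, 0) + 1
    return MultiplicityReport(
        per_pirna=per,
        bin_totals=bins,
        n_distinct_loci=len(all_loci),
        n_distinct_loci_low=len(low_loci),
        low_multiplicity_ceiling=low_multiplicity_ceiling,
        per_chromosome=dict(sorted(chrom_tally.items())),
    )


@dataclass
class MembershipReport:
    """Per-piRNA region-membership flags and per-flag totals.

    ``percent_of_reference`` holds, for each region set with a supplied
    reference size, the flagged total as a percent of that reference,
    rounded to the nearest integer (e.g. 19 detected of 42 known
    mitochondrial piRNA loci -> 45).
    """

    per_pirna: pd.DataFrame
    totals: dict[str, int]
    percent_of_reference: dict[str, int]

    def to_dict(self) -> dict:
        return {"totals": self.totals, "percent_of_reference": self.percent_of_reference}


def percent_of_reference(detected: int, known: int) -> int:
    """Detected as a nearest-integer percent of a known reference total."""
    if known <= 0:
        raise ValueError("reference size must be positive")
    return round(100.0 * detected / known)


def membership_report(
    pirnas: dict[str, PiRNARecord],
    region_sets: list[RegionSet],
    reference_sizes: dict[str, int] | None = None,
) -> MembershipReport:
    """Flag each piRNA against every region set plus the mitochondrial genome.

    A piRNA is mitochondrial iff any locus lies on chrM.  ``reference_sizes``
    maps a flag name (region-set name or "mitochondrial") to a known total,
    reported as a rounded percent.
    """
    if not pirnas:
        raise ValueError("empty piRNA set")
    indices = [RegionIndex(rs) for rs in region_sets]
    rows = []
    for pid in sorted(pirnas):
        rec = pirnas[pid]
        row = {"pirna_id": pid, "mitochondrial": rec.is_mitochondrial}
        for idx in indices:
            row[f"in_{idx.name}"] = any(idx.overlaps(l) for l in rec.loci)
        rows.append(row)
    per = pd.DataFrame(rows).set_index("pirna_id")
    totals = {c: int(per[c].sum()) for c in per.columns}
    pct = {}
    for name, known in (reference_sizes or {}).items():
        col = name if name in per.columns else f"in_{name}"
        if col in per.columns:
            pct[name] = percent_of_reference(totals[col], known)
    return MembershipReport(per_pirna=per, totals=totals, percent_of_reference=pct)
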