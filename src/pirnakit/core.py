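"""Core domain types shared across the pipeline.

The unit of quantification throughout is the annotated piRNA: a mature
sequence (23-40 nt) together with the set of genomic loci it maps to.
All genomic coordinates are 0-based half-open (BED convention); any
1-based input dialect must be converted at the reader boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, NamedTuple

import numpy as np

logger = logging.getLogger("pirnakit")

#: Strand values accepted on a genomic interval.
STRANDS = ("+", "-", ".")

#: Canonical mitochondrial chromosome name (readers normalise "MT"/"M" to this).
CHROM_MT = "chrM"

#: Phred+33 offset for FASTQ quality strings.
PHRED_OFFSET = 33

#: Multiplicity bin labels in increasing locus-count order.
BIN_LABELS = ("single", "oligo", "mid", "high")


def normalize_chrom(chrom: str) -> str:
    """Normalise a chromosome name to the internal "chr"-prefixed dialect."""
    c = chrom.strip()
    if not c:
        raise ValueError("empty chromosome name")
    if c.lower().startswith("chr"):
        c = "chr" + c[3:]
    else:
        c = "chr" + c
    if c in ("chrMT", "chrmt", "chrm"):
        c = CHROM_MT
    return c


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional strand.

    Strand is stored but ignored by overlap queries (see
    :func:`pirnakit.multiplicity.overlaps_region`).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start ({self.chrom}:{self.start}-{self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the half-open intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PiRNARecord:
    """One annotated piRNA: identifier, mature sequence, genomic loci."""

    pirna_id: str
    sequence: str
    loci: frozenset[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.pirna_id:
            raise ValueError("pirna_id must be non-empty")
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not seq or set(seq) - set("ACGT"):
            raise ValueError(f"invalid sequence for {self.pirna_id}: {self.sequence!r}")
        if not isinstance(self.loci, frozenset):
            object.__setattr__(self, "loci", frozenset(self.loci))
        if not self.loci:
            raise ValueError(f"piRNA {self.pirna_id} must have >= 1 locus")

    @property
    def locus_count(self) -> int:
        return len(self.loci)

    @property
    def is_mitochondrial(self) -> bool:
        return any(loc.chrom == CHROM_MT for loc in self.loci)


@dataclass
class RegionSet:
    """A named collection of genomic intervals (e.g. piRNA clusters, MEG8)."""

    name: str
    regions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("RegionSet name must be non-empty")

    def __len__(self) -> int:
        return len(self.regions)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for r in self.regions:
            out.setdefault(r.chrom, []).append(r)
        return out


@dataclass(frozen=True)
class SampleMetadata:
    """Sample identity and tissue label; ``group`` is a free analysis label."""

    sample_id: str
    tissue: str
    group: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.tissue:
            raise ValueError(f"sample {self.sample_id}: tissue must be non-empty")


class ReadRecord(NamedTuple):
    """A sequencing read: id, sequence and Phred+33 quality string."""

    read_id: str
    sequence: str
    qual: str

    def phred(self) -> np.ndarray:
        """Per-base Phred scores as an int array."""
        return np.frombuffer(self.qual.encode("ascii"), dtype=np.uint8).astype(
            np.int64
        ) - PHRED_OFFSET

    def mean_phred(self) -> float:
        if not self.qual:
            return 0.0
        return float(self.phred().mean())


@dataclass
class FilterConfig:
    """Every threshold applied by the pipeline, with the default cut-offs.

    min_read_len / max_read_len
        Retained read length window in nt (inclusive at both ends).
    pirna_min_len
        Reads shorter than this are treated as miRNA-length and excluded
        from piRNA assignment; also the minimum substring length for
        read-to-piRNA matching.
    min_mean_phred
        Quality floor: reads with mean per-base Phred below this are dropped.
    min_total_reads / min_rpm / min_sample_frac
        The two-criterion consistent-expression filter: a piRNA is kept iff
        its summed count over the cohort is >= min_total_reads AND it reaches
        min_rpm RPM in at least ceil(min_sample_frac * n_samples) samples
        (never fewer than 1).
    fold_threshold
        Median-RPM ratio at or above which a piRNA is called fold-biased
        toward one tissue.
    multiplicity_bins
        Upper edges (inclusive) of the first three locus-count bins; counts
        above the last edge fall in the open-ended top bin.
    pseudocount
        RPM pseudocount added to both medians in fold-ratio computations.
    phred_summary
        "mean" (default) or "min": how a read's quality is summarised
        against min_mean_phred.
    strand_aware
        Reserved strict mode; overlap queries currently ignore strand.
    """

    min_read_len: int = 16
    max_read_len: int = 40
    pirna_min_len: int = 23
    min_mean_phred: float = 20.0
    min_total_reads: int = 10
    min_rpm: float = 1.0
    min_sample_frac: float = 0.10
    fold_threshold: float = 5.0
    multiplicity_bins: tuple[int, int, int] = (1, 9, 100)
    pseudocount: float = 0.0
    phred_summary: str = "mean"
    strand_aware: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.min_read_len <= self.pirna_min_len <= self.max_read_len):
            raise ValueError(
                "require min_read_len <= pirna_min_len <= max_read_len, got "
                f"{self.min_read_len}/{self.pirna_min_len}/{self.max_read_len}"
            )
        for name in ("min_read_len", "max_read_len", "pirna_min_len",
                     "min_mean_phred", "min_total_reads", "min_rpm",
                     "fold_threshold", "pseudocount"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.min_sample_frac <= 1):
            raise ValueError("min_sample_frac must be in (0, 1]")
        edges = tuple(self.multiplicity_bins)
        if len(edges) != 3 or list(edges) != sorted(edges) or edges[0] < 1:
            raise ValueError("multiplicity_bins must be 3 increasing edges >= 1")
        if self.phred_summary not in ("mean", "min"):
            raise ValueError("phred_summary must be 'mean' or 'min'")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        kwargs = dict(d)
        if "multiplicity_bins" in kwargs:
            kwargs["multiplicity_bins"] = tuple(kwargs["multiplicity_bins"])
        return cls(**kwargs)

    def updated(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)

    def log_effective(self) -> None:
        """Log every effective threshold (called at the start of each run)."""
        logger.info("effective thresholds: %s", self.to_dict())


def as_interval_set(intervals: Iterable[GenomicInterval]) -> frozenset[GenomicInterval]:
    return frozenset(intervals)
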