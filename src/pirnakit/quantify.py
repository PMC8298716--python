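"""Read-to-piRNA assignment, RPM normalisation and the consistency filter.

Assignment is by exact sequence identity: a read supports piRNA *p* when it
equals *p*'s annotated mature sequence or is a contiguous subsequence of it
of length >= pirna_min_len.  A read matching k > 1 distinct piRNAs
increments each of the k counts by 1; counting is per piRNA, never
multiplied by the piRNA's locus number.  Assignment is implemented with a
precomputed substring index so each read costs one dictionary lookup.

RPM (reads per million) normalises each count by the sample's library size
(the QC-retained piRNA-candidate read total) times 1e6.

The consistent-expression filter keeps a piRNA iff
(i)  its summed count over the cohort is >= min_total_reads, and
(ii) it reaches min_rpm RPM in at least ceil(min_sample_frac * n) samples
     (minimum 1) of the n-sample cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FilterConfig, PiRNARecord, ReadRecord, logger


@dataclass
class CountsMatrix:
    """piRNA x sample integer read counts plus per-sample library sizes."""

    counts: pd.DataFrame
    library_sizes: pd.Series
    unassigned: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate pirna_id rows")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample columns")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = self.library_sizes[self.library_sizes.isna()].index.tolist()
            raise ValueError(f"missing library sizes for samples {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def pirna_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, sample_ids: list[str]) -> "CountsMatrix":
        return CountsMatrix(
            self.counts[sample_ids],
            self.library_sizes.loc[sample_ids],
            self.unassigned.loc[sample_ids] if self.unassigned is not None else None,
        )


@dataclass
class ExpressionMatrix:
    """piRNA x sample RPM values (same layout as CountsMatrix)."""

    rpm: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.rpm.to_numpy() < 0).any():
            raise ValueError("negative RPM values")

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.rpm[sample_ids], self.library_sizes.loc[sample_ids])


class SubstringIndex:
    """Maps every >= min_len contiguous subsequence of the annotated piRNA
    sequences to the piRNA ids it supports."""

    def __init__(self, annotation: dict[str, PiRNARecord], min_len: int) -> None:
        if not annotation:
            raise ValueError("empty annotation")
        self.min_len = min_len
        index: dict[str, list[str]] = {}
        for pid, rec in annotation.items():
            seq = rec.sequence
            seen: set[str] = set()
            for k in range(min_len, len(seq) + 1):
                for i in range(len(seq) - k + 1):
                    sub = seq[i : i + k]
                    if sub not in seen:
                        seen.add(sub)
                        index.setdefault(sub, []).append(pid)
        self._index = index

    def lookup(self, read_seq: str) -> list[str]:
        return self._index.get(read_seq, [])


def assign_sample(
    reads: list[ReadRecord] | list[str], index: SubstringIndex
) -> tuple[dict[str, int], int]:
    """Count read support per piRNA for one sample.

    Returns (pirna_id -> count, n_unassigned).  Accepts ReadRecords or bare
    sequence strings.
    """
    counts: dict[str, int] = {}
    unassigned = 0
    lookup = index.lookup
    for r in reads:
        seq = r if isinstance(r, str) else r.sequence
        hits = lookup(seq)
        if hits:
            for pid in hits:
                counts[pid] = counts.get(pid, 0) + 1
        else:
            unassigned += 1
    return counts, unassigned


def assign_reads(
    reads_by_sample: dict[str, list],
    annotation: dict[str, PiRNARecord],
    config: FilterConfig,
    library_sizes: dict[str, int] | None = None,
) -> CountsMatrix:
    """Build the CountsMatrix over all samples.

    ``library_sizes`` defaults to each sample's piRNA-candidate read total
    (the length of its read list), the RPM denominator.
    """
    if not annotation:
        raise ValueError("empty annotation")
    index = SubstringIndex(annotation, config.pirna_min_len)
    pirna_ids = sorted(annotation)
    sample_ids = list(reads_by_sample)
    mat = np.zeros((len(pirna_ids), len(sample_ids)), dtype=np.int64)
    row = {pid: i for i, pid in enumerate(pirna_ids)}
    unassigned = {}
    libs = {}
    for j, sid in enumerate(sample_ids):
        reads = reads_by_sample[sid]
        counts, n_un = assign_sample(reads, index)
        for pid, c in counts.items():
            mat[row[pid], j] = c
        unassigned[sid] = n_un
        libs[sid] = len(reads)
    if library_sizes is not None:
        libs = dict(library_sizes)
    return CountsMatrix(
        pd.DataFrame(mat, index=pirna_ids, columns=sample_ids),
        pd.Series(libs, dtype=np.int64),
        pd.Series(unassigned, dtype=np.int64),
    )


def rpm_normalize(counts: CountsMatrix) -> ExpressionMatrix:
    """Scale counts to reads-per-million of each sample's library size."""
    zero = counts.library_sizes[counts.library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s) {list(zero.index)}")
    rpm = counts.counts * 1e6 / counts.library_sizes
    return ExpressionMatrix(rpm, counts.library_sizes)


def min_sample_threshold(n_samples: int, frac: float) -> int:
    """ceil(frac * n_samples), never below 1.

    With the default 10% fraction this yields 3 for a 30-sample cohort and
    1 for a 3-sample cohort.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    return max(1, math.ceil(frac * n_samples))


def detected_ids(counts: CountsMatrix) -> list[str]:
    """piRNAs with >= 1 assigned read in >= 1 sample ("detectable expression")."""
    mask = counts.counts.sum(axis=1) >= 1
    return list(counts.counts.index[mask])


def consistent_expression_filter(
    counts: CountsMatrix, rpm: ExpressionMatrix, config: FilterConfig
) -> tuple[list[str], pd.DataFrame]:
    """Apply the two-criterion consistency filter.

    Returns the kept pirna_ids (input order) and a per-piRNA diagnostics
    frame with the measured total, the per-sample RPM pass count, both
    criterion booleans and the failure reason for every dropped piRNA.
    """
    if list(counts.counts.index) != list(rpm.rpm.index) or list(
        counts.counts.columns
    ) != list(rpm.rpm.columns):
        raise ValueError("counts and RPM matrices must share row/column layout")
    n = len(counts.counts.columns)
    need = min_sample_threshold(n, config.min_sample_frac)
    total = counts.counts.sum(axis=1)
    n_pass = (rpm.rpm >= config.min_rpm).sum(axis=1)
    crit_total = total >= config.min_total_reads
    crit_rpm = n_pass >= need
    keep = crit_total & crit_rpm
    reason = np.where(
        keep,
        "kept",
        np.where(
            ~crit_total & ~crit_rpm,
            "total_reads+rpm_samples",
            np.where(~crit_total, "total_reads", "rpm_samples"),
        ),
    )
    diag = pd.DataFrame(
        {
            "total_reads": total,
            "n_samples_at_min_rpm": n_pass,
            "min_samples_required": need,
            "pass_total_reads": crit_total,
            "pass_rpm_samples": crit_rpm,
            "kept": keep,
            "reason": reason,
        }
    )
    kept = list(counts.counts.index[keep])
    logger.info(
        "consistency filter: kept %d / %d piRNAs (>=%d reads; >=%g RPM in >=%d/%d samples)",
        len(kept), len(total), config.min_total_reads, config.min_rpm, need, n,
    )
    return kept, diag
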