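"""Read-level quality control.

Three stages, applied in order to each small-RNA library:

1. 3' adapter trimming — the 3'-most occurrence of an adapter prefix
   (>= 5 nt exact match) is removed together with everything after it.
2. Length window and quality floor — retained reads satisfy
   min_read_len <= length <= max_read_len and summary Phred >= min_mean_phred.
   Removal reasons are assigned in the fixed order too_short, too_long,
   low_quality (a read empty after trimming counts as adapter_only).
3. miRNA-length exclusion — reads shorter than pirna_min_len (default 23 nt)
   are set aside before piRNA assignment, since that length range is
   dominated by miRNAs.

Boundary semantics are strict as printed: length 16 and length 23 are
retained; length 40 is retained as the inclusive window maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PHRED_OFFSET, FilterConfig, ReadRecord

MIN_ADAPTER_MATCH = 5


@dataclass
class QCReport:
    """Per-library tally of read fates; categories partition the input."""

    adapter_only: int = 0
    too_short: int = 0
    too_long: int = 0
    low_quality: int = 0
    mirna_length: int = 0
    retained: int = 0
    n_input: int = 0

    REASONS = ("adapter_only", "too_short", "too_long", "low_quality", "mirna_length")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            **{r: getattr(self, r) for r in self.REASONS},
            "retained": self.retained,
        }

    def check_partition(self) -> None:
        total = self.retained + sum(getattr(self, r) for r in self.REASONS)
        if total != self.n_input:
            raise AssertionError(
                f"QC categories sum to {total}, expected n_input={self.n_input}"
            )


def trim_adapter(read: ReadRecord, adapter: str) -> ReadRecord:
    """Remove the 3'-most >= 5 nt adapter(-prefix) match and everything after.

    A read with no match is returned unchanged; qualities are trimmed in
    lockstep with the sequence.
    """
    if len(adapter) < MIN_ADAPTER_MATCH:
        raise ValueError(f"adapter must be >= {MIN_ADAPTER_MATCH} nt")
    adapter = adapter.upper()
    cut = _find_adapter(read.sequence, adapter)
    if cut is None:
        return read
    return ReadRecord(read.read_id, read.sequence[:cut], read.qual[:cut])


def _find_adapter(seq: str, adapter: str) -> int | None:
    """Rightmost position where a >= 5 nt adapter prefix matches through to a
    full-adapter or end-of-read boundary; None when absent."""
    seed = adapter[:MIN_ADAPTER_MATCH]
    pos = seq.rfind(seed)
    while pos >= 0:
        k = min(len(adapter), len(seq) - pos)
        if seq[pos : pos + k] == adapter[:k]:
            return pos
        pos = seq.rfind(seed, 0, pos + MIN_ADAPTER_MATCH - 1)
    return None


def _summary_phred(qual: str, how: str) -> float:
    if not qual:
        return 0.0
    arr = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
    v = arr.min() if how == "min" else arr.mean()
    return float(v) - PHRED_OFFSET


def qc_filter(
    reads: list[ReadRecord], config: FilterConfig
) -> tuple[list[ReadRecord], QCReport]:
    """Apply the length window and quality floor to adapter-trimmed reads."""
    report = QCReport(n_input=len(reads))
    kept: list[ReadRecord] = []
    lo, hi, minq = config.min_read_len, config.max_read_len, config.min_mean_phred
    how = config.phred_summary
    for read in reads:
        n = len(read.sequence)
        if n == 0:
            report.adapter_only += 1
        elif n < lo:
            report.too_short += 1
        elif n > hi:
            report.too_long += 1
        elif _summary_phred(read.qual, how) < minq:
            report.low_quality += 1
        else:
            kept.append(read)
    report.retained = len(kept)
    return kept, report


def exclude_mirna_length(
    reads: list[ReadRecord], config: FilterConfig
) -> tuple[list[ReadRecord], int]:
    """Drop QC-passed reads below pirna_min_len (likely miRNAs); strict '<'."""
    cut = config.pirna_min_len
    kept = [r for r in reads if len(r.sequence) >= cut]
    return kept, len(reads) - kept.__len__()


def preprocess_reads(
    reads: list[ReadRecord], adapter: str | None, config: FilterConfig
) -> tuple[list[ReadRecord], QCReport]:
    """Full read QC chain: trim, length/quality filter, miRNA-length exclusion.

    Returns the piRNA-candidate reads and a QCReport whose categories
    partition the input; ``retained`` counts the final candidates.
    """
    if adapter is not None:
        reads = [trim_adapter(r, adapter) for r in reads]
    kept, report = qc_filter(reads, config)
    candidates, n_mirna = exclude_mirna_length(kept, config)
    report.mirna_length = n_mirna
    report.retained = len(candidates)
    report.check_partition()
    return candidates, report
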