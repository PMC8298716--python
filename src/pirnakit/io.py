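"""Readers and writers for the external formats the pipeline exchanges.

Formats: FASTQ (Phred+33), BED3+ region files, the merged piRNA annotation
TSV (chrom, start, end, pirna_id, sequence, strand — one row per locus),
sample-metadata TSV, and counts/RPM matrices as TSV with a ``pirna_id``
first column.  All coordinates are 0-based half-open on disk and in memory.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import (
    GenomicInterval,
    PiRNARecord,
    ReadRecord,
    RegionSet,
    SampleMetadata,
    normalize_chrom,
)

ANNOTATION_COLUMNS = ["chrom", "start", "end", "pirna_id", "sequence", "strand"]


class FastqParseError(ValueError):
    pass


def iter_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from a Phred+33 FASTQ file.

    Raises :class:`FastqParseError` naming the approximate line of the first
    malformed 4-line block; a sequence/quality length mismatch is reported
    for the offending record.
    """
    n = 0
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"{path}: malformed FASTQ near line {4 * n + 1}: {exc}"
                ) from exc
            n += 1
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: record {title!r} (near line {4 * (n - 1) + 1}): "
                    f"sequence length {len(seq)} != quality length {len(qual)}"
                )
            yield ReadRecord(title.split()[0] if title else title, seq.upper(), qual)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a whole FASTQ file into a list of :class:`ReadRecord` (order kept)."""
    return list(iter_fastq(path))


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        chunks = []
        for r in reads:
            chunks.append(f"@{r.read_id}\n{r.sequence}\n+\n{r.qual}\n")
            if len(chunks) >= 10000:
                out.write("".join(chunks))
                chunks = []
        out.write("".join(chunks))


def read_annotation(path: str | Path) -> dict[str, PiRNARecord]:
    """Load the merged annotation TSV into a pirna_id -> PiRNARecord map.

    Rows sharing a pirna_id are merged into one record with one locus per
    distinct interval; duplicate identical rows de-duplicate.  A conflicting
    sequence for one id, or end <= start, is an error.  The result is
    independent of row order.
    """
    seqs: dict[str, str] = {}
    loci: dict[str, set[GenomicInterval]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(ANNOTATION_COLUMNS)] != ANNOTATION_COLUMNS:
            raise ValueError(
                f"{path}: expected header columns {ANNOTATION_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            chrom, start, end, pid, seq, strand = parts[:6]
            try:
                iv = GenomicInterval(
                    normalize_chrom(chrom), int(start), int(end), strand or "."
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            seq = seq.upper().replace("U", "T")
            if pid in seqs and seqs[pid] != seq:
                raise ValueError(
                    f"{path}:{lineno}: conflicting sequences for {pid}"
                )
            seqs[pid] = seq
            loci.setdefault(pid, set()).add(iv)
    return {
        pid: PiRNARecord(pid, seqs[pid], frozenset(loci[pid])) for pid in seqs
    }


def write_annotation(annotation: dict[str, PiRNARecord], path: str | Path) -> None:
    rows = []
    for pid in sorted(annotation):
        rec = annotation[pid]
        for loc in sorted(rec.loci):
            rows.append(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{pid}\t{rec.sequence}\t{loc.strand}"
            )
    Path(path).write_text("\t".join(ANNOTATION_COLUMNS) + "\n" + "\n".join(rows) + "\n")


def read_bed(path: str | Path, name: str) -> RegionSet:
    """Read a BED3+ file (0-based half-open) into a named RegionSet.

    Comment (#), ``track`` and ``browser`` lines are skipped.
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED rows need >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates {parts[1]!r}/{parts[2]!r}"
                ) from exc
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                regions.append(
                    GenomicInterval(normalize_chrom(parts[0]), start, end, strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(name, regions)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as out:
        for i, r in enumerate(regions.regions):
            out.write(f"{r.chrom}\t{r.start}\t{r.end}\t{regions.name}_{i}\t0\t{r.strand}\n")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample metadata TSV (sample_id, tissue[, group])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample_id" not in df.columns or "tissue" not in df.columns:
        raise ValueError(f"{path}: metadata needs 'sample_id' and 'tissue' columns")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    groups = df["group"] if "group" in df.columns else [""] * len(df)
    return [
        SampleMetadata(s, t, g or "")
        for s, t, g in zip(df["sample_id"], df["tissue"], groups)
    ]


def write_metadata(samples: Iterable[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [{"sample_id": s.sample_id, "tissue": s.tissue, "group": s.group} for s in samples]
    ).to_csv(path, sep="\t", index=False)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a piRNA x sample matrix as TSV with a ``pirna_id`` first column."""
    if df.index.duplicated().any():
        raise ValueError("duplicate row (pirna_id) labels")
    if df.columns.duplicated().any():
        raise ValueError("duplicate column (sample_id) labels")
    out = df.copy()
    out.index.name = "pirna_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="pirna_id")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate pirna_id rows")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample columns")
    return df


def write_series(series: pd.Series, path: str | Path, value_name: str) -> None:
    s = series.rename(value_name)
    s.index.name = "sample_id"
    s.to_csv(path, sep="\t")


def read_series(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if hasattr(o, "tolist"):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
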