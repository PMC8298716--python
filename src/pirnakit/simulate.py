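"""Synthetic small-RNA study generator with a planted truth table.

Emulates a multi-tissue piRNA profiling cohort end to end: an annotation of
piRNAs spanning the locus-multiplicity spectrum (single / 2-9 / 10-100 /
>100 loci), a genome layout with piRNA-cluster regions, a short
mitochondrial chromosome and one named imprinted interval (MEG8-like), and
per-sample read libraries containing piRNA-derived reads plus the
contaminant classes the read-QC stage must remove (miRNA-length reads,
low-quality reads, adapter dimers, random fragments).

Planted structure (the defaults, mirroring the placenta study design):

* 297 consistently expressed piRNAs with multiplicity mix 151/116/0/30 and
  636 distinct loci among those with < 10 loci;
* 19 of the 42 annotated mitochondrial piRNAs expressed; no expressed
  piRNA inside a cluster region;
* specificity groups within the expressed set: 11 exclusive to the focus
  tissue, 53 ubiquitous, 22 focus-biased (>= 5x), 95 reference-biased,
  a 16-member node highly and nearly exclusively expressed in the focus
  tissue (15 of them single-locus inside the imprinted region), and 100
  broadly-but-unevenly expressed piRNAs;
* 80 background piRNAs with sample-private sporadic expression that the
  consistency filter must reject;
* 30 focus ("placenta") samples, 3 reference ("testis") samples and five
  further tissues of 3 samples each, at a depth of 2e5 reads per sample.

Per-(piRNA, sample) read counts are Poisson around the planted means;
piRNA-derived reads are exact copies of the annotated sequences (an
optional 1-nt end-trim rate is off by default).  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CHROM_MT,
    FilterConfig,
    GenomicInterval,
    ReadRecord,
    RegionSet,
    SampleMetadata,
    logger,
)
from .multiplicity import RegionIndex

READ_CLASSES = ("pirna", "mirna_length", "low_quality", "adapter_artifact", "random_fragment")

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeModel:
    """Chromosome lengths plus the named regions loci are planted against."""

    chromosomes: dict[str, int]
    imprinted_region: GenomicInterval
    imprinted_name: str = "MEG8"
    cluster_regions: RegionSet = field(default_factory=lambda: RegionSet("piRNA_clusters"))

    def __post_init__(self) -> None:
        if CHROM_MT not in self.chromosomes:
            raise ValueError(f"genome must declare a {CHROM_MT} chromosome")
        self._check_within(self.imprinted_region)
        for r in self.cluster_regions.regions:
            self._check_within(r)
            if r.overlaps(self.imprinted_region):
                raise ValueError(
                    f"cluster region {r} overlaps the imprinted region"
                )

    def _check_within(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.chromosomes:
            raise ValueError(f"region on undeclared chromosome {iv.chrom}")
        if iv.end > self.chromosomes[iv.chrom]:
            raise ValueError(f"region {iv} exceeds chromosome bounds")

    def imprinted_region_set(self) -> RegionSet:
        return RegionSet(self.imprinted_name, [self.imprinted_region])


def default_genome() -> GenomeModel:
    """Compact hg19-like layout: 24 nuclear chromosomes of 2 Mb, a 16.6 kb
    chrM, 20 cluster regions of 60 kb, and a 40 kb imprinted interval on
    chr14 (MEG8-like)."""
    chroms = {f"chr{i}": 2_000_000 for i in range(1, 23)}
    chroms["chrX"] = 2_000_000
    chroms["chrY"] = 2_000_000
    chroms[CHROM_MT] = 16_569
    clusters = RegionSet(
        "piRNA_clusters",
        [GenomicInterval(f"chr{i}", 500_000, 560_000, "+") for i in range(1, 21)],
    )
    return GenomeModel(
        chromosomes=chroms,
        imprinted_region=GenomicInterval("chr14", 1_200_000, 1_240_000, "+"),
        imprinted_name="MEG8",
        cluster_regions=clusters,
    )


@dataclass
class NoiseModel:
    """Library composition and artifact knobs for read generation.

    Fractions are of the total per-sample depth; their sum must stay below 1
    and the remainder is the piRNA-derived fraction.  ``adapter_tag_frac``
    appends the 3' adapter to that fraction of piRNA-derived reads (they
    remain countable after trimming); ``end_trim_rate`` shortens a
    piRNA-derived read by 1 nt at a random end (off by default so assigned
    counts equal the planted counts exactly).
    """

    frac_mirna: float = 0.15
    frac_low_quality: float = 0.05
    frac_adapter: float = 0.03
    frac_random: float = 0.07
    adapter: str = "AGATCGGAAG"
    adapter_tag_frac: float = 0.10
    end_trim_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("frac_mirna", "frac_low_quality", "frac_adapter", "frac_random",
                     "adapter_tag_frac", "end_trim_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.contaminant_fraction >= 1:
            raise ValueError("contaminant fractions must sum to < 1")
        if len(self.adapter) < 5:
            raise ValueError("adapter must be >= 5 nt")

    @property
    def contaminant_fraction(self) -> float:
        return self.frac_mirna + self.frac_low_quality + self.frac_adapter + self.frac_random

    @property
    def frac_pirna(self) -> float:
        return 1.0 - self.contaminant_fraction

    def to_dict(self) -> dict:
        return {
            "frac_mirna": self.frac_mirna,
            "frac_low_quality": self.frac_low_quality,
            "frac_adapter": self.frac_adapter,
            "frac_random": self.frac_random,
            "adapter": self.adapter,
            "adapter_tag_frac": self.adapter_tag_frac,
            "end_trim_rate": self.end_trim_rate,
        }


@dataclass
class TruthTable:
    """Planted ground truth for every downstream recovery test.

    ``pirnas`` carries per-piRNA structural truth (bin, locus count, region
    flags, expression class); ``tissue_means`` the unscaled per-tissue mean
    expression profile; ``private_means`` sample-private sporadic expression
    for background piRNAs.  ``generate_reads`` completes the table with the
    per-sample scaled expected means, the realized Poisson counts and the
    per-class read tallies.
    """

    pirnas: pd.DataFrame
    tissue_means: pd.DataFrame
    private_means: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None
    expected_counts: pd.DataFrame | None = None
    realized_counts: pd.DataFrame | None = None
    class_counts: pd.DataFrame | None = None

    @property
    def expressed_ids(self) -> list[str]:
        return list(self.pirnas.index[self.pirnas["expressed"]])

    def node_members(self) -> list[str]:
        return list(self.pirnas.index[self.pirnas["node_member"]])


def _random_seqs(
    rng: np.random.Generator, lengths: np.ndarray, avoid_motif: str | None = None
) -> list[str]:
    total = int(lengths.sum())
    if total == 0:
        return ["" for _ in lengths]
    text = _LETTERS[rng.integers(0, 4, size=total)].tobytes().decode("ascii")
    out = []
    pos = 0
    for n in lengths:
        s = text[pos : pos + int(n)]
        pos += int(n)
        if avoid_motif:
            # keep contaminant classes free of the adapter seed so trimming
            # never moves a read between planted QC categories
            while avoid_motif in s:
                s = _LETTERS[rng.integers(0, 4, size=int(n))].tobytes().decode("ascii")
        out.append(s)
    return out


def _unique_sequences(
    rng: np.random.Generator,
    n: int,
    min_len: int,
    max_len: int,
    forbidden_motifs: tuple[str, ...],
) -> list[str]:
    """Random sequences, mutually non-substring (so exact-match assignment
    is one-to-one) and free of the adapter seed motif."""
    seqs: list[str] = []
    attempts = 0
    while len(seqs) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise RuntimeError("could not generate enough unique sequences")
        length = int(rng.integers(min_len, max_len + 1))
        s = _random_seqs(rng, np.array([length]))[0]
        if any(m in s for m in forbidden_motifs):
            continue
        if any(s in t or t in s for t in seqs):
            continue
        seqs.append(s)
    return seqs


def _place_interval(
    rng: np.random.Generator,
    chrom: str,
    chrom_len: int,
    length: int,
    used: set[tuple[str, int, int]],
    avoid: list[RegionIndex],
    within: GenomicInterval | None = None,
    disjoint_from: list[GenomicInterval] | None = None,
    max_tries: int = 2000,
) -> GenomicInterval:
    lo = within.start if within is not None else 0
    hi = (within.end if within is not None else chrom_len) - length
    if hi < lo:
        raise ValueError(f"region too small to place a {length} bp locus on {chrom}")
    for _ in range(max_tries):
        start = int(rng.integers(lo, hi + 1))
        iv = GenomicInterval(chrom, start, start + length,
                             "+" if rng.random() < 0.5 else "-")
        if (iv.chrom, iv.start, iv.end) in used:
            continue
        if any(a.overlaps(iv) for a in avoid):
            continue
        if disjoint_from and any(iv.overlaps(o) for o in disjoint_from):
            continue
        used.add((iv.chrom, iv.start, iv.end))
        return iv
    raise ValueError(
        f"region too small to place requested loci without overlap on {chrom}"
    )


def generate_annotation(
    n_pirnas: int,
    multiplicity_mix: dict[str, int],
    genome: GenomeModel,
    n_imprinted_single_locus: int,
    n_mito: int,
    n_in_clusters: int,
    seed: int | np.random.Generator,
    config: FilterConfig | None = None,
    oligo_locus_counts: list[int] | None = None,
    id_prefix: str = "piR-syn",
    id_start: int = 1,
    forbidden_motifs: tuple[str, ...] = ("AGATC",),
) -> tuple[dict, pd.DataFrame]:
    """Generate an annotation with exact per-bin counts plus its truth frame.

    Imprinted-designated piRNAs are single-locus with their unique locus
    inside the genome's imprinted region (mutually non-overlapping);
    mitochondrial piRNAs are single-locus on chrM; cluster-designated
    piRNAs get their first locus inside a cluster region.  All other loci
    avoid cluster and imprinted regions and chrM.  Sequence lengths are
    uniform in [pirna_min_len, 32]; sequences are unique and mutually
    non-substring.
    """
    from .core import PiRNARecord  # local import to keep module top light

    config = config or FilterConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mix = {label: int(multiplicity_mix.get(label, 0)) for label in ("single", "oligo", "mid", "high")}
    if sum(mix.values()) != n_pirnas:
        raise ValueError(f"multiplicity_mix sums to {sum(mix.values())}, expected {n_pirnas}")
    if n_imprinted_single_locus + n_mito > mix["single"]:
        raise ValueError("imprinted + mito piRNAs must fit in the single-locus bin")
    if n_imprinted_single_locus + n_mito + n_in_clusters > n_pirnas:
        raise ValueError("designated counts exceed n_pirnas")
    if oligo_locus_counts is not None and len(oligo_locus_counts) != mix["oligo"]:
        raise ValueError("oligo_locus_counts length must equal the oligo bin count")

    e1, e2, e3 = config.multiplicity_bins
    seqs = _unique_sequences(rng, n_pirnas, config.pirna_min_len, 32, forbidden_motifs)

    # locus count per piRNA, bin by bin
    locus_counts: list[int] = []
    bins: list[str] = []
    for _ in range(mix["single"]):
        locus_counts.append(1)
        bins.append("single")
    if oligo_locus_counts is not None:
        oligo_counts = [int(c) for c in oligo_locus_counts]
        if any(not (e1 < c <= e2) for c in oligo_counts):
            raise ValueError("oligo_locus_counts outside the oligo bin")
    else:
        oligo_counts = [int(rng.integers(e1 + 1, e2 + 1)) for _ in range(mix["oligo"])]
    locus_counts += oligo_counts
    bins += ["oligo"] * mix["oligo"]
    for _ in range(mix["mid"]):
        locus_counts.append(int(rng.integers(e2 + 1, e3 + 1)))
        bins.append("mid")
    for _ in range(mix["high"]):
        locus_counts.append(int(rng.integers(e3 + 1, e3 + 51)))
        bins.append("high")

    # role flags: imprinted then mito within the single bin; clusters fill
    # non-imprinted, non-mito piRNAs starting from the oligo bin.
    n = n_pirnas
    imprinted = [i < n_imprinted_single_locus for i in range(n)]
    mito = [n_imprinted_single_locus <= i < n_imprinted_single_locus + n_mito for i in range(n)]
    cluster_flags = [False] * n
    free = [i for i in range(n) if not imprinted[i] and not mito[i]]
    free = [i for i in free if bins[i] != "single"] + [i for i in free if bins[i] == "single"]
    for i in free[:n_in_clusters]:
        cluster_flags[i] = True

    avoid = [RegionIndex(genome.cluster_regions), RegionIndex(genome.imprinted_region_set())]
    nuclear = [c for c in genome.chromosomes if c != CHROM_MT]
    nuc_lens = np.array([genome.chromosomes[c] for c in nuclear], dtype=float)
    nuc_p = nuc_lens / nuc_lens.sum()
    used: set[tuple[str, int, int]] = set()
    imprinted_placed: list[GenomicInterval] = []
    mito_placed: list[GenomicInterval] = []

    annotation = {}
    rows = []
    width = max(4, len(str(id_start + n - 1)))
    for i in range(n):
        pid = f"{id_prefix}-{id_start + i:0{width}d}"
        length = len(seqs[i])
        loci: list[GenomicInterval] = []
        if imprinted[i]:
            iv = _place_interval(
                rng, genome.imprinted_region.chrom,
                genome.chromosomes[genome.imprinted_region.chrom], length, used,
                avoid=[], within=genome.imprinted_region, disjoint_from=imprinted_placed,
            )
            imprinted_placed.append(iv)
            loci.append(iv)
        elif mito[i]:
            iv = _place_interval(
                rng, CHROM_MT, genome.chromosomes[CHROM_MT], length, used,
                avoid=[], disjoint_from=mito_placed,
            )
            mito_placed.append(iv)
            loci.append(iv)
        else:
            if cluster_flags[i]:
                region = genome.cluster_regions.regions[
                    int(rng.integers(0, len(genome.cluster_regions)))
                ]
                loci.append(_place_interval(
                    rng, region.chrom, genome.chromosomes[region.chrom], length,
                    used, avoid=[], within=region,
                ))
            while len(loci) < locus_counts[i]:
                chrom = nuclear[int(rng.choice(len(nuclear), p=nuc_p))]
                loci.append(_place_interval(
                    rng, chrom, genome.chromosomes[chrom], length, used, avoid=avoid,
                ))
        annotation[pid] = PiRNARecord(pid, seqs[i], frozenset(loci))
        rows.append({
            "pirna_id": pid,
            "bin": bins[i],
            "locus_count": locus_counts[i],
            "imprinted": imprinted[i],
            "mitochondrial": mito[i],
            "in_cluster": cluster_flags[i],
        })
    truth = pd.DataFrame(rows).set_index("pirna_id")
    return annotation, truth


def _qual_string(q: int, length: int, cache: dict) -> str:
    key = (q, length)
    s = cache.get(key)
    if s is None:
        s = chr(33 + q) * length
        cache[key] = s
    return s


def generate_sample_reads(
    annotation: dict,
    truth: TruthTable,
    sample: SampleMetadata,
    depth: float,
    noise: NoiseModel,
    rng: np.random.Generator,
    count_noise: str = "poisson",
) -> tuple[list[ReadRecord], np.ndarray, np.ndarray, dict[str, int]]:
    """Generate one sample's reads.

    Returns (reads, expected_means, realized_counts, class_counts); the
    mean/count vectors follow truth.pirnas row order.
    """
    ids = list(truth.pirnas.index)
    seqs = [annotation[pid].sequence for pid in ids]
    if sample.tissue not in truth.tissue_means.columns:
        raise ValueError(f"tissue {sample.tissue!r} has no planted mean profile")
    means = truth.tissue_means[sample.tissue].reindex(ids).fillna(0.0).to_numpy(float)
    if truth.private_means is not None and sample.sample_id in truth.private_means.columns:
        means = means + truth.private_means[sample.sample_id].reindex(ids).fillna(0.0).to_numpy(float)
    total_mean = means.sum()
    budget = depth * noise.frac_pirna
    expected = means * (budget / total_mean) if total_mean > 0 and depth > 0 else np.zeros_like(means)

    if count_noise == "poisson":
        counts = rng.poisson(expected)
    elif count_noise == "exact":
        counts = np.rint(expected).astype(np.int64)
    else:
        raise ValueError("count_noise must be 'poisson' or 'exact'")

    qcache: dict = {}
    reads: list[ReadRecord] = []
    adapter = noise.adapter

    # piRNA-derived reads: exact copies, a fraction tagged with the adapter
    idx = np.repeat(np.arange(len(ids)), counts)
    n_p = len(idx)
    tag = rng.random(n_p) < noise.adapter_tag_frac
    trim = rng.random(n_p) < noise.end_trim_rate if noise.end_trim_rate > 0 else np.zeros(n_p, bool)
    trim_side = rng.random(n_p) < 0.5
    quals = rng.integers(30, 41, size=n_p)
    for k in range(n_p):
        s = seqs[idx[k]]
        if trim[k]:
            s = s[1:] if trim_side[k] else s[:-1]
        if tag[k]:
            s = s + adapter
        reads.append(ReadRecord("", s, _qual_string(int(quals[k]), len(s), qcache)))

    def contaminant_count(frac: float) -> int:
        lam = depth * frac
        if lam <= 0:
            return 0
        return int(rng.poisson(lam)) if count_noise == "poisson" else int(round(lam))

    seed_motif = adapter[:5]
    n_mir = contaminant_count(noise.frac_mirna)
    for s, q in zip(
        _random_seqs(rng, rng.integers(16, 23, size=n_mir), seed_motif),
        rng.integers(30, 41, size=n_mir),
    ):
        reads.append(ReadRecord("", s, _qual_string(int(q), len(s), qcache)))

    n_lq = contaminant_count(noise.frac_low_quality)
    for s, q in zip(
        _random_seqs(rng, rng.integers(23, 33, size=n_lq), seed_motif),
        rng.integers(5, 16, size=n_lq),
    ):
        reads.append(ReadRecord("", s, _qual_string(int(q), len(s), qcache)))

    n_ad = contaminant_count(noise.frac_adapter)
    for _ in range(n_ad):
        reads.append(ReadRecord("", adapter, _qual_string(35, len(adapter), qcache)))

    n_rf = contaminant_count(noise.frac_random)
    for s, q in zip(
        _random_seqs(rng, rng.integers(23, 33, size=n_rf), seed_motif),
        rng.integers(30, 41, size=n_rf),
    ):
        reads.append(ReadRecord("", s, _qual_string(int(q), len(s), qcache)))

    order = rng.permutation(len(reads))
    reads = [
        ReadRecord(f"{sample.sample_id}_r{j + 1}", reads[i].sequence, reads[i].qual)
        for j, i in enumerate(order)
    ]
    class_counts = {
        "pirna": n_p,
        "mirna_length": n_mir,
        "low_quality": n_lq,
        "adapter_artifact": n_ad,
        "random_fragment": n_rf,
    }
    return reads, expected, counts, class_counts


def iter_sample_reads(
    annotation: dict,
    truth: TruthTable,
    samples: list[SampleMetadata],
    depth: float,
    noise: NoiseModel,
    seed: int,
    count_noise: str = "poisson",
):
    """Yield (sample, reads) per sample while completing the truth table.

    Each sample draws from its own child of the seed sequence, so output is
    byte-deterministic and independent of how far the iterator is consumed.
    On exhaustion, truth.expected_counts / realized_counts / class_counts /
    samples are populated; the conservation invariant (reads generated ==
    sum of class counts) holds per sample.
    """
    if not samples:
        raise ValueError("empty sample list")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    # child 0 is reserved for annotation/study assembly; samples use 1..n
    children = np.random.SeedSequence(seed).spawn(len(samples) + 1)[1:]
    ids = list(truth.pirnas.index)
    expected = {}
    realized = {}
    classes = {}
    rows = []
    for sample, child in zip(samples, children):
        rng = np.random.default_rng(child)
        reads, exp, cnt, cls = generate_sample_reads(
            annotation, truth, sample, depth, noise, rng, count_noise
        )
        if len(reads) != sum(cls.values()):
            raise AssertionError("class counts do not conserve the read total")
        expected[sample.sample_id] = exp
        realized[sample.sample_id] = cnt
        classes[sample.sample_id] = cls
        rows.append({
            "sample_id": sample.sample_id, "tissue": sample.tissue,
            **{f"frac_{k}": v for k, v in noise.to_dict().items() if k.startswith("frac")},
        })
        yield sample, reads
    truth.expected_counts = pd.DataFrame(expected, index=ids)
    truth.realized_counts = pd.DataFrame(realized, index=ids)
    truth.class_counts = pd.DataFrame(classes).T.loc[[s.sample_id for s in samples]]
    truth.samples = pd.DataFrame(rows).set_index("sample_id")


def generate_reads(
    annotation: dict,
    truth: TruthTable,
    samples: list[SampleMetadata],
    depth: float,
    noise: NoiseModel,
    seed: int,
    outdir: str | Path,
    count_noise: str = "poisson",
) -> TruthTable:
    """Write one FASTQ per sample under ``outdir`` and complete the truth."""
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, reads in iter_sample_reads(
        annotation, truth, samples, depth, noise, seed, count_noise
    ):
        pio.write_fastq(reads, outdir / f"{sample.sample_id}.fastq")
    return truth


# ---------------------------------------------------------------------------
# Study-level scenario


@dataclass
class StudyParams:
    """The planted study design; defaults are the full desk-scale scenario."""

    n_focus_samples: int = 30
    n_reference_samples: int = 3
    other_tissues: tuple[str, ...] = ("adrenal_gland", "brain", "kidney", "liver", "lung")
    n_other_samples: int = 3
    focus: str = "placenta"
    reference: str = "testis"

    n_single: int = 151
    n_oligo: int = 116
    n_mid: int = 0
    n_high: int = 30
    oligo_loci_total: int = 485  # 95 piRNAs x 4 loci + 21 x 5 -> 636 loci below 10x

    n_node: int = 16              # 15 imprinted single-locus + 1 multi-locus
    n_imprinted_single: int = 15
    n_mito_expressed: int = 19
    n_exclusive: int = 11
    n_ubiquitous: int = 53
    n_focus_biased: int = 22
    n_reference_biased: int = 95

    n_background: int = 80
    n_background_mito: int = 23   # 42 annotated chrM piRNAs in total
    n_background_cluster: int = 10

    depth: float = 200_000.0
    count_noise: str = "poisson"

    @property
    def n_expressed(self) -> int:
        return self.n_single + self.n_oligo + self.n_mid + self.n_high

    @property
    def tissues(self) -> list[str]:
        return [self.focus, self.reference, *self.other_tissues]


# unscaled per-tissue mean expression by planted class, in the tissue order
# [focus, reference, adrenal_gland, brain, kidney, liver, lung]
CLASS_PROFILES = {
    "node": {"placenta": 800, "adrenal_gland": 15, "brain": 15},
    "exclusive": {"placenta": 20},
    "ubiquitous": {t: 150 for t in
                   ("placenta", "testis", "adrenal_gland", "brain", "kidney", "liver", "lung")},
    "focus_biased": {"placenta": 500, "testis": 50, "adrenal_gland": 150,
                     "brain": 150, "kidney": 150, "lung": 150},
    "reference_biased": {"placenta": 30, "testis": 400, "adrenal_gland": 100,
                         "brain": 100, "kidney": 100, "lung": 100},
    "broad": {"placenta": 100, "testis": 100, "kidney": 100, "lung": 100},
}


@dataclass
class SimulatedStudy:
    annotation: dict
    truth: TruthTable
    samples: list[SampleMetadata]
    genome: GenomeModel
    config: FilterConfig
    noise: NoiseModel
    params: StudyParams
    seed: int

    def iter_reads(self):
        return iter_sample_reads(
            self.annotation, self.truth, self.samples, self.params.depth,
            self.noise, self.seed, self.params.count_noise,
        )


def simulate_study(
    seed: int,
    params: StudyParams | None = None,
    genome: GenomeModel | None = None,
    config: FilterConfig | None = None,
    noise: NoiseModel | None = None,
) -> SimulatedStudy:
    """Assemble the full planted study: annotation, truth table and samples.

    Read libraries are produced lazily by ``SimulatedStudy.iter_reads`` (or
    written with :func:`generate_reads`), so a study can be streamed through
    the pipeline one sample at a time.
    """
    params = params or StudyParams()
    genome = genome or default_genome()
    config = config or FilterConfig()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    p = params
    class_sizes = {
        "node": p.n_node, "exclusive": p.n_exclusive, "ubiquitous": p.n_ubiquitous,
        "focus_biased": p.n_focus_biased, "reference_biased": p.n_reference_biased,
    }
    n_broad = p.n_expressed - sum(class_sizes.values())
    if n_broad < 0:
        raise ValueError("specificity class sizes exceed the expressed set")
    class_sizes["broad"] = n_broad
    if p.n_imprinted_single >= p.n_node and p.n_node > 0:
        raise ValueError("the node needs at least one multi-locus member")

    # oligo locus counts hitting the planted distinct-locus total
    base = p.oligo_loci_total // p.n_oligo if p.n_oligo else 0
    extra = p.oligo_loci_total - base * p.n_oligo
    oligo_counts = [base + 1] * extra + [base] * (p.n_oligo - extra)

    annotation, pir_truth = generate_annotation(
        p.n_expressed,
        {"single": p.n_single, "oligo": p.n_oligo, "mid": p.n_mid, "high": p.n_high},
        genome,
        n_imprinted_single_locus=p.n_imprinted_single,
        n_mito=p.n_mito_expressed,
        n_in_clusters=0,
        seed=rng,
        config=config,
        oligo_locus_counts=oligo_counts,
        id_prefix="piR-syn",
        id_start=1,
    )
    pir_truth["expressed"] = True

    bg_single = p.n_background - p.n_background // 2
    bg_annotation, bg_truth = generate_annotation(
        p.n_background,
        {"single": bg_single, "oligo": p.n_background - bg_single, "mid": 0, "high": 0},
        genome,
        n_imprinted_single_locus=0,
        n_mito=p.n_background_mito,
        n_in_clusters=p.n_background_cluster,
        seed=rng,
        config=config,
        id_prefix="piR-bg",
        id_start=1,
    )
    bg_truth["expressed"] = False
    annotation.update(bg_annotation)
    truth_df = pd.concat([pir_truth, bg_truth])

    # expression classes over the expressed set: imprinted singles + the first
    # non-designated oligo form the node; mito piRNAs are folded into the
    # ubiquitous group; remaining classes fill deterministically.
    ids = list(pir_truth.index)
    cls = pd.Series("", index=truth_df.index, name="expression_class")
    node_ids = [i for i in ids if truth_df.loc[i, "imprinted"]]
    extra_node = [i for i in ids if truth_df.loc[i, "bin"] == "oligo"][: p.n_node - len(node_ids)]
    node_ids += extra_node
    cls[node_ids] = "node"
    mito_ids = [i for i in ids if truth_df.loc[i, "mitochondrial"]]
    if len(mito_ids) > class_sizes["ubiquitous"]:
        raise ValueError("mitochondrial piRNAs must fit in the ubiquitous class")
    cls[mito_ids] = "ubiquitous"
    remaining = [i for i in ids if not cls[i]]
    fill = (
        ["exclusive"] * class_sizes["exclusive"]
        + ["ubiquitous"] * (class_sizes["ubiquitous"] - len(mito_ids))
        + ["focus_biased"] * class_sizes["focus_biased"]
        + ["reference_biased"] * class_sizes["reference_biased"]
        + ["broad"] * class_sizes["broad"]
    )
    if len(fill) != len(remaining):
        raise ValueError("class sizes inconsistent with the expressed set")
    cls[remaining] = fill
    cls[bg_truth.index] = "background"
    truth_df["expression_class"] = cls
    truth_df["node_member"] = truth_df["expression_class"] == "node"

    # per-tissue unscaled means
    tissues = p.tissues
    means = pd.DataFrame(0.0, index=truth_df.index, columns=tissues)
    for pid in ids:
        profile = CLASS_PROFILES[truth_df.loc[pid, "expression_class"]]
        for t, v in profile.items():
            if t == "placenta":
                means.loc[pid, p.focus] = v
            elif t == "testis":
                means.loc[pid, p.reference] = v
            elif t in means.columns:
                means.loc[pid, t] = v

    # samples
    samples = [
        SampleMetadata(f"{p.focus}_{i + 1:02d}", p.focus) for i in range(p.n_focus_samples)
    ] + [
        SampleMetadata(f"{p.reference}_{i + 1:02d}", p.reference)
        for i in range(p.n_reference_samples)
    ]
    for t in p.other_tissues:
        samples += [SampleMetadata(f"{t}_{i + 1:02d}", t) for i in range(p.n_other_samples)]

    # background piRNAs: sporadic expression private to 2 random samples each
    sample_ids = [s.sample_id for s in samples]
    private = pd.DataFrame(0.0, index=truth_df.index, columns=sample_ids)
    for pid in bg_truth.index:
        picks = rng.choice(len(sample_ids), size=2, replace=False)
        for j in picks:
            private.iloc[private.index.get_loc(pid), j] = 6.0

    truth = TruthTable(pirnas=truth_df, tissue_means=means, private_means=private)
    logger.info(
        "simulated study: %d piRNAs (%d expressed), %d samples, depth %g",
        len(annotation), len(ids), len(samples), p.depth,
    )
    return SimulatedStudy(annotation, truth, samples, genome, config, noise, params, seed)
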