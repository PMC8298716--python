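"""End-to-end study execution: reads -> QC -> counts -> RPM -> reports.

Samples are processed one library at a time (reads are never all held in
memory), then the matrix-level stages run: the consistency filter is
applied over the focus-tissue cohort, and the kept set feeds multiplicity,
membership, specificity, clustering/node and embedding analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import compare as cmp
from . import multiplicity as mult
from .core import FilterConfig, PiRNARecord, ReadRecord, RegionSet, SampleMetadata, logger
from .preprocess import QCReport, preprocess_reads
from .quantify import (
    CountsMatrix,
    ExpressionMatrix,
    SubstringIndex,
    assign_sample,
    consistent_expression_filter,
    detected_ids,
    min_sample_threshold,
    rpm_normalize,
)


@dataclass
class StudyResult:
    """Everything the pipeline computes for one study."""

    config: FilterConfig
    metadata: list[SampleMetadata]
    counts: CountsMatrix
    rpm: ExpressionMatrix
    qc_reports: dict[str, QCReport]
    detected: list[str]
    kept: list[str]
    filter_diagnostics: pd.DataFrame
    filter_cohort: list[str]
    multiplicity: mult.MultiplicityReport
    membership: mult.MembershipReport
    detection: pd.DataFrame
    specificity: pd.Series
    fold: pd.DataFrame
    dendrogram: cmp.Dendrogram | None
    node: cmp.DendrogramNode | None
    node_summary: tuple[int, int, int]
    node_detail: pd.DataFrame
    embedding: cmp.Embedding | None
    focus_silhouette: float
    focus: str
    reference: str

    def summary(self) -> dict:
        spec_counts = self.specificity.value_counts()
        fold_counts = self.fold["fold_class"].value_counts()
        m = self.multiplicity
        return {
            "n_samples": len(self.metadata),
            "n_annotated": len(self.counts.counts.index),
            "n_detected": len(self.detected),
            "n_consistent": len(self.kept),
            "min_samples_required": min_sample_threshold(
                len(self.filter_cohort), self.config.min_sample_frac
            ),
            "n_single_locus": m.bin_totals["single"],
            "n_loci_2_9": m.bin_totals["oligo"],
            "n_loci_10_100": m.bin_totals["mid"],
            "n_loci_over_100": m.bin_totals["high"],
            "n_low_multiplicity_pirnas": m.bin_totals["single"] + m.bin_totals["oligo"],
            "n_distinct_loci_low_multiplicity": m.n_distinct_loci_low,
            "n_in_clusters": self.membership.totals.get("in_piRNA_clusters", 0),
            "n_mitochondrial": self.membership.totals.get("mitochondrial", 0),
            "pct_mitochondrial_of_known": self.membership.percent_of_reference.get(
                "mitochondrial", 0
            ),
            "n_exclusive": int(spec_counts.get("exclusive_to_focus", 0)),
            "n_ubiquitous": int(spec_counts.get("ubiquitous", 0)),
            "n_focus_biased": int(fold_counts.get("focus_biased", 0)),
            "n_reference_biased": int(fold_counts.get("reference_biased", 0)),
            "n_not_detected_in_reference": int(
                fold_counts.get("not_detected_in_reference", 0)
            ),
            "n_detected_in_reference": int(
                self.detection[self.reference].loc[self.kept].sum()
            )
            if self.reference in self.detection.columns
            else 0,
            "node_n_members": self.node_summary[0],
            "node_n_single_locus": self.node_summary[1],
            "node_n_in_region": self.node_summary[2],
            "focus_silhouette": self.focus_silhouette,
        }


def quantify_samples(
    sample_reads: Iterable[tuple[SampleMetadata, list[ReadRecord]]],
    annotation: dict[str, PiRNARecord],
    adapter: str | None,
    config: FilterConfig,
) -> tuple[CountsMatrix, dict[str, QCReport], list[SampleMetadata]]:
    """Stream samples through read QC and assignment into a CountsMatrix.

    The RPM denominator for each sample is its piRNA-candidate read total
    (QC-retained, >= pirna_min_len).
    """
    index = SubstringIndex(annotation, config.pirna_min_len)
    pirna_ids = sorted(annotation)
    row = {pid: i for i, pid in enumerate(pirna_ids)}
    columns = {}
    libs = {}
    unassigned = {}
    qc_reports = {}
    metadata = []
    for sample, reads in sample_reads:
        candidates, qc = preprocess_reads(reads, adapter, config)
        counts, n_un = assign_sample(candidates, index)
        col = np.zeros(len(pirna_ids), dtype=np.int64)
        for pid, c in counts.items():
            col[row[pid]] = c
        columns[sample.sample_id] = col
        libs[sample.sample_id] = len(candidates)
        unassigned[sample.sample_id] = n_un
        qc_reports[sample.sample_id] = qc
        metadata.append(sample)
        logger.info(
            "sample %s: %d reads in, %d candidates, %d unassigned",
            sample.sample_id, qc.n_input, qc.retained, n_un,
        )
    if not columns:
        raise ValueError("no samples provided")
    counts_matrix = CountsMatrix(
        pd.DataFrame(columns, index=pirna_ids),
        pd.Series(libs, dtype=np.int64),
        pd.Series(unassigned, dtype=np.int64),
    )
    return counts_matrix, qc_reports, metadata


def run_study(
    sample_reads: Iterable[tuple[SampleMetadata, list[ReadRecord]]],
    annotation: dict[str, PiRNARecord],
    clusters: RegionSet,
    imprinted: RegionSet,
    adapter: str | None,
    config: FilterConfig,
    focus: str,
    reference: str,
    tsne_seed: int = 0,
    tsne_perplexity: float = 10.0,
    node_factor: float = 100.0,
    node_pseudocount: float = 10.0,
) -> StudyResult:
    """Run the whole analysis on streamed sample read libraries.

    The consistency filter is computed over the focus-tissue cohort (the
    discovery samples); all downstream stages analyse the kept set across
    every sample.
    """
    config.log_effective()
    counts, qc_reports, metadata = quantify_samples(
        sample_reads, annotation, adapter, config
    )
    rpm = rpm_normalize(counts)

    detected = detected_ids(counts)
    cohort = [s.sample_id for s in metadata if s.tissue == focus]
    if not cohort:
        raise ValueError(f"no samples with focus tissue {focus!r}")
    kept, diag = consistent_expression_filter(
        counts.subset_samples(cohort), rpm.subset_samples(cohort), config
    )

    kept_annotation = {pid: annotation[pid] for pid in kept}
    n_known_mito = sum(1 for rec in annotation.values() if rec.is_mitochondrial)
    multiplicity = mult.multiplicity_report(kept_annotation, config)
    membership = mult.membership_report(
        kept_annotation,
        [clusters, imprinted],
        reference_sizes={"mitochondrial": n_known_mito} if n_known_mito else None,
    )

    kept_counts = CountsMatrix(
        counts.counts.loc[kept], counts.library_sizes, counts.unassigned
    )
    kept_rpm = ExpressionMatrix(rpm.rpm.loc[kept], rpm.library_sizes)
    detection = cmp.detection_vector(kept_counts, kept_rpm, metadata, config)
    specificity = cmp.exclusivity_classes(detection, focus)
    fold = cmp.fold_bias(kept_counts, kept_rpm, metadata, focus, reference, config)

    dendrogram = node = None
    node_summary = (0, 0, 0)
    node_detail = pd.DataFrame(columns=["locus_count", "single_locus", "in_region"])
    if len(kept) >= 2:
        dendrogram = cmp.hierarchical_cluster(kept_rpm.rpm)
        node = cmp.extract_enriched_node(
            dendrogram, kept_rpm.rpm, metadata, focus,
            factor=node_factor, pseudocount=node_pseudocount,
        )
        if node is not None:
            node_summary, node_detail = cmp.node_region_report(
                list(node.members), annotation, imprinted
            )

    embedding = None
    silhouette = float("nan")
    n_samples = len(metadata)
    if kept and n_samples > 3 * tsne_perplexity:
        embedding = cmp.tsne_embed(
            kept_rpm.rpm, dims=3, perplexity=tsne_perplexity, seed=tsne_seed
        )
        silhouette = cmp.focus_silhouette(embedding, metadata, focus)

    return StudyResult(
        config=config,
        metadata=metadata,
        counts=counts,
        rpm=rpm,
        qc_reports=qc_reports,
        detected=detected,
        kept=kept,
        filter_diagnostics=diag,
        filter_cohort=cohort,
        multiplicity=multiplicity,
        membership=membership,
        detection=detection,
        specificity=specificity,
        fold=fold,
        dendrogram=dendrogram,
        node=node,
        node_summary=node_summary,
        node_detail=node_detail,
        embedding=embedding,
        focus_silhouette=silhouette,
        focus=focus,
        reference=reference,
    )


def run_simulated_study(sim, tsne_seed: int | None = None) -> StudyResult:
    """Convenience wrapper: stream a SimulatedStudy through run_study."""
    return run_study(
        sim.iter_reads(),
        sim.annotation,
        sim.genome.cluster_regions,
        sim.genome.imprinted_region_set(),
        adapter=sim.noise.adapter,
        config=sim.config,
        focus=sim.params.focus,
        reference=sim.params.reference,
        tsne_seed=sim.seed if tsne_seed is None else tsne_seed,
    )
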