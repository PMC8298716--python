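"""Cross-tissue comparison of a focus-tissue piRNA set.

Covers: per-tissue detection calls (the consistency criteria applied within
each tissue's samples), exclusive/ubiquitous specificity classes, median
fold-bias calls between a focus and a reference tissue, unsupervised
hierarchical clustering of piRNAs with predicate-based node extraction, and
a 3-D t-SNE embedding of samples.

Expression values are transformed log2(RPM + 1) before distance computation
(clustering and t-SNE); raw mode is available via ``log_transform=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_samples

from .core import FilterConfig, PiRNARecord, RegionSet, SampleMetadata, logger
from .multiplicity import RegionIndex, classify_multiplicity, locus_count
from .quantify import CountsMatrix, ExpressionMatrix, min_sample_threshold

FOLD_CLASSES = ("focus_biased", "reference_biased", "neither", "not_detected_in_reference")
SPECIFICITY_CLASSES = ("exclusive_to_focus", "ubiquitous", "other")


def samples_by_tissue(metadata: list[SampleMetadata]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for s in metadata:
        out.setdefault(s.tissue, []).append(s.sample_id)
    return out


def detection_vector(
    counts: CountsMatrix,
    rpm: ExpressionMatrix,
    metadata: list[SampleMetadata],
    config: FilterConfig,
) -> pd.DataFrame:
    """Per-tissue detection calls (piRNA x tissue booleans).

    A piRNA is detected in a tissue iff, restricted to that tissue's
    samples, it satisfies the consistency criteria: summed count >=
    min_total_reads and RPM >= min_rpm in >= min_sample_threshold of them.
    A tissue of n=3 samples therefore needs >= 10 reads and >= 1 RPM in a
    single sample, matching the small-cohort rule.
    """
    tissues = samples_by_tissue(metadata)
    for tissue, sids in tissues.items():
        if not sids:
            raise ValueError(f"tissue {tissue!r} has no samples")
        missing = set(sids) - set(counts.counts.columns)
        if missing:
            raise ValueError(f"samples missing from matrix: {sorted(missing)}")
    cols = {}
    for tissue, sids in tissues.items():
        sub_counts = counts.counts[sids]
        sub_rpm = rpm.rpm[sids]
        need = min_sample_threshold(len(sids), config.min_sample_frac)
        cols[tissue] = (sub_counts.sum(axis=1) >= config.min_total_reads) & (
            (sub_rpm >= config.min_rpm).sum(axis=1) >= need
        )
    return pd.DataFrame(cols)


def exclusivity_classes(detection: pd.DataFrame, focus: str) -> pd.Series:
    """Classify each piRNA as exclusive_to_focus / ubiquitous / other.

    exclusive_to_focus: detected in the focus tissue and nowhere else.
    ubiquitous: detected in every tissue.  Everything else (including
    piRNAs not detected in the focus tissue) is "other".
    """
    if focus not in detection.columns:
        raise ValueError(f"focus tissue {focus!r} not in detection table")
    if detection.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    others = detection.drop(columns=[focus])
    exclusive = detection[focus] & ~others.any(axis=1)
    ubiquitous = detection.all(axis=1)
    out = pd.Series("other", index=detection.index, name="specificity_class")
    out[ubiquitous] = "ubiquitous"
    out[exclusive] = "exclusive_to_focus"
    return out


def fold_bias(
    counts: CountsMatrix,
    rpm: ExpressionMatrix,
    metadata: list[SampleMetadata],
    focus: str,
    reference: str,
    config: FilterConfig,
    pirna_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Median-RPM fold-bias calls between focus and reference tissues.

    With all reference-tissue counts zero the piRNA is routed to
    not_detected_in_reference before any division.  Otherwise
    r = (focus median + pseudocount) / (reference median + pseudocount);
    r >= fold_threshold -> focus_biased, 1/r >= fold_threshold ->
    reference_biased, else neither.  A zero reference median with nonzero
    counts and pseudocount 0 yields an infinite ratio (focus_biased); both
    medians zero yields "neither".
    """
    tissues = samples_by_tissue(metadata)
    for t in (focus, reference):
        if t not in tissues:
            raise ValueError(f"undefined tissue label {t!r}")
    ids = list(pirna_ids) if pirna_ids is not None else list(rpm.rpm.index)
    f_med = rpm.rpm.loc[ids, tissues[focus]].median(axis=1)
    r_med = rpm.rpm.loc[ids, tissues[reference]].median(axis=1)
    r_counts = counts.counts.loc[ids, tissues[reference]]
    ref_absent = (r_counts.sum(axis=1) == 0) & (r_med == 0)
    pc = config.pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (f_med + pc) / (r_med + pc)
    classes = []
    for pid in ids:
        if ref_absent.loc[pid]:
            classes.append("not_detected_in_reference")
            continue
        r = ratio.loc[pid]
        if np.isnan(r):  # both medians zero with pseudocount 0
            classes.append("neither")
        elif r >= config.fold_threshold:
            classes.append("focus_biased")
        elif r > 0 and 1.0 / r >= config.fold_threshold:
            classes.append("reference_biased")
        elif r == 0:
            classes.append("reference_biased")
        else:
            classes.append("neither")
    return pd.DataFrame(
        {
            "focus_median_rpm": f_med,
            "reference_median_rpm": r_med,
            "fold_ratio": ratio,
            "fold_class": pd.Series(classes, index=ids),
        }
    )


@dataclass
class DendrogramNode:
    """One node of the binary dendrogram; leaves carry a single piRNA."""

    node_id: int
    height: float
    members: tuple[str, ...]
    children: tuple[int, int] | None
    parent: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class Dendrogram:
    """Full hierarchical-clustering result over piRNA rows."""

    linkage: np.ndarray
    leaf_ids: list[str]
    nodes: dict[int, DendrogramNode]
    method: str
    metric: str

    @property
    def root(self) -> DendrogramNode:
        return self.nodes[max(self.nodes)]

    def internal_nodes(self) -> list[DendrogramNode]:
        return [n for n in self.nodes.values() if not n.is_leaf]

    def to_newick(self) -> str:
        def rec(node: DendrogramNode, parent_height: float) -> str:
            length = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{node.members[0]}:{length:.6g}"
            a, b = (self.nodes[c] for c in node.children)
            return f"({rec(a, node.height)},{rec(b, node.height)}):{length:.6g}"

        root = self.root
        a, b = (self.nodes[c] for c in root.children)
        return f"({rec(a, root.height)},{rec(b, root.height)});"


def log2_rpm(rpm_df: pd.DataFrame) -> pd.DataFrame:
    return np.log2(rpm_df + 1.0)


def hierarchical_cluster(
    rpm_df: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
    log_transform: bool = True,
) -> Dendrogram:
    """Cluster piRNA rows of an RPM (sub)matrix into a full binary dendrogram.

    Values are log2(RPM+1)-transformed by default.  Correlation distance on
    a constant row is undefined and raises with a suggestion to use
    Euclidean distance.
    """
    if rpm_df.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    X = log2_rpm(rpm_df) if log_transform else rpm_df
    vals = X.to_numpy(dtype=float)
    if metric == "correlation" and (vals.std(axis=1) == 0).any():
        raise ValueError(
            "correlation distance undefined for constant rows; use metric='euclidean'"
        )
    Z = sch.linkage(vals, method=method, metric=metric)
    n = len(X.index)
    leaf_ids = list(X.index)
    nodes: dict[int, DendrogramNode] = {
        i: DendrogramNode(i, 0.0, (leaf_ids[i],), None) for i in range(n)
    }
    for k, (a, b, height, _) in enumerate(Z):
        a, b = int(a), int(b)
        nid = n + k
        nodes[nid] = DendrogramNode(
            nid, float(height), nodes[a].members + nodes[b].members, (a, b)
        )
        nodes[a].parent = nid
        nodes[b].parent = nid
    return Dendrogram(Z, leaf_ids, nodes, method, metric)


def enrichment_ratio(
    values: pd.DataFrame,
    focus_samples: list[str],
    other_samples: list[str],
    pseudocount: float,
) -> float:
    """(median over focus cells + pc) / (median over non-focus cells + pc)."""
    f = float(np.median(values[focus_samples].to_numpy()))
    o = float(np.median(values[other_samples].to_numpy()))
    return (f + pseudocount) / (o + pseudocount)


def extract_node(
    dendrogram: Dendrogram,
    node_predicate,
    required_leaves: set[str] | None = None,
) -> DendrogramNode | None:
    """Smallest node satisfying the predicate (ties: smaller node id).

    When ``required_leaves`` is given, only nodes containing all of them are
    considered; an empty requirement set, or no satisfying node, yields None
    (not an error).
    """
    if required_leaves is not None and not required_leaves:
        return None
    best = None
    for node in sorted(dendrogram.nodes.values(), key=lambda n: (len(n.members), n.node_id)):
        if required_leaves is not None and not required_leaves <= set(node.members):
            continue
        if node_predicate(node):
            best = node
            break
    return best


def extract_enriched_node(
    dendrogram: Dendrogram,
    rpm_df: pd.DataFrame,
    metadata: list[SampleMetadata],
    focus: str,
    factor: float = 100.0,
    pseudocount: float = 10.0,
) -> DendrogramNode | None:
    """Extract the focus-tissue high/near-exclusive expression node.

    Operationalisation of "highly and nearly exclusively expressed": a leaf
    qualifies when its own focus-vs-rest pooled-median RPM ratio (with the
    stabilising pseudocount) reaches ``factor``; the extracted node is the
    smallest one that contains every qualifying leaf and whose pooled member
    values also reach ``factor``.  None when no leaf qualifies.
    """
    tissues = samples_by_tissue(metadata)
    if focus not in tissues:
        raise ValueError(f"undefined focus tissue {focus!r}")
    focus_s = [s for s in tissues[focus] if s in rpm_df.columns]
    other_s = [c for c in rpm_df.columns if c not in set(focus_s)]
    if not focus_s or not other_s:
        raise ValueError("need samples in both focus and non-focus groups")

    qualifying = {
        pid
        for pid in dendrogram.leaf_ids
        if enrichment_ratio(rpm_df.loc[[pid]], focus_s, other_s, pseudocount) >= factor
    }
    if not qualifying:
        return None

    def node_ok(node: DendrogramNode) -> bool:
        sub = rpm_df.loc[list(node.members)]
        return enrichment_ratio(sub, focus_s, other_s, pseudocount) >= factor

    return extract_node(dendrogram, node_ok, required_leaves=qualifying)


def node_region_report(
    members: list[str] | tuple[str, ...],
    annotation: dict[str, PiRNARecord],
    region: RegionSet,
) -> tuple[tuple[int, int, int], pd.DataFrame]:
    """(n_members, n_single_locus, n_with_a_locus_in_region) for a node.

    A member with several loci counts in the region total when any locus
    overlaps, but never in the single-locus total.
    """
    missing = [m for m in members if m not in annotation]
    if missing:
        raise ValueError(f"node members missing from annotation: {missing}")
    idx = RegionIndex(region)
    rows = []
    for pid in members:
        rec = annotation[pid]
        rows.append(
            {
                "pirna_id": pid,
                "locus_count": locus_count(rec),
                "single_locus": locus_count(rec) == 1,
                "in_region": any(idx.overlaps(l) for l in rec.loci),
            }
        )
    detail = (
        pd.DataFrame(rows).set_index("pirna_id")
        if rows
        else pd.DataFrame(columns=["locus_count", "single_locus", "in_region"])
    )
    summary = (
        len(rows),
        int(detail["single_locus"].sum()) if rows else 0,
        int(detail["in_region"].sum()) if rows else 0,
    )
    return summary, detail


@dataclass
class Embedding:
    """Sample coordinates from t-SNE plus the parameters that produced them."""

    coords: pd.DataFrame
    params: dict

    def to_dict(self) -> dict:
        return {"params": self.params, "coords": self.coords.to_dict(orient="index")}


def tsne_embed(
    rpm_df: pd.DataFrame,
    dims: int = 3,
    perplexity: float = 10.0,
    seed: int = 0,
    n_iter: int = 1000,
    log_transform: bool = True,
) -> Embedding:
    """Embed samples (columns of the piRNA x sample matrix) with t-SNE.

    Deterministic for a fixed seed; rows of the result follow the input
    sample order.  Requires n_samples > 3 * perplexity.
    """
    n = rpm_df.shape[1]
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large: need n_samples > {3 * perplexity:g}, got {n}"
        )
    X = (log2_rpm(rpm_df) if log_transform else rpm_df).to_numpy(dtype=float).T
    model = TSNE(
        n_components=dims,
        perplexity=perplexity,
        random_state=seed,
        max_iter=n_iter,
        init="pca",
    )
    coords = model.fit_transform(X)
    df = pd.DataFrame(
        coords, index=list(rpm_df.columns), columns=[f"dim{i + 1}" for i in range(dims)]
    )
    if not np.isfinite(coords).all():
        raise ValueError("non-finite embedding coordinates")
    return Embedding(
        df,
        {"dims": dims, "perplexity": perplexity, "seed": seed, "n_iter": n_iter,
         "log_transform": log_transform},
    )


def focus_silhouette(
    embedding: Embedding, metadata: list[SampleMetadata], focus: str
) -> float:
    """Mean silhouette of focus-tissue samples against all others (focus vs rest)."""
    tissue = {s.sample_id: s.tissue for s in metadata}
    labels = np.array(
        [1 if tissue.get(s) == focus else 0 for s in embedding.coords.index]
    )
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("focus group must be a proper subset of samples")
    sil = silhouette_samples(embedding.coords.to_numpy(), labels)
    return float(sil[labels == 1].mean())
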