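"""Tissue comparison: detection, exclusivity, fold bias, clustering, t-SNE."""

import io as _io

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from pirnakit import FilterConfig, GenomicInterval, PiRNARecord, RegionSet
from pirnakit.core import SampleMetadata
from pirnakit.compare import (
    detection_vector,
    exclusivity_classes,
    extract_enriched_node,
    extract_node,
    focus_silhouette,
    fold_bias,
    hierarchical_cluster,
    node_region_report,
    tsne_embed,
)
from pirnakit.quantify import CountsMatrix, ExpressionMatrix, rpm_normalize

SEQ = "ACGTACGTACGTACGTACGTACGTA"


def study(counts_by_tissue: dict[str, dict[str, list[int]]], lib=1_000_000):
    """Build counts/rpm/metadata from tissue -> pirna -> per-sample counts."""
    metadata, cols = [], {}
    for tissue, rows in counts_by_tissue.items():
        n = len(next(iter(rows.values())))
        for j in range(n):
            sid = f"{tissue}_{j}"
            metadata.append(SampleMetadata(sid, tissue))
            cols[sid] = [rows[p][j] for p in rows]
    index = list(next(iter(counts_by_tissue.values())))
    df = pd.DataFrame(cols, index=index)
    libs = pd.Series(lib, index=df.columns)
    cm = CountsMatrix(df, libs)
    return cm, rpm_normalize(cm), metadata


class TestDetection:
    def test_zero_in_reference_not_detected(self, config):
        cm, em, md = study(
            {
                "placenta": {"p": [20] * 5},
                "testis": {"p": [0, 0, 0]},
            }
        )
        det = detection_vector(cm, em, md, config)
        assert bool(det.loc["p", "placenta"]) is True
        assert bool(det.loc["p", "testis"]) is False

    def test_small_cohort_single_sample_rule(self, config):
        # >= 10 reads and RPM >= 1 in 1 of 3 testis samples -> detected
        cm, em, md = study({"placenta": {"p": [5] * 5}, "testis": {"p": [12, 0, 0]}})
        det = detection_vector(cm, em, md, config)
        assert bool(det.loc["p", "testis"]) is True

    def test_all_zero_matrix(self, config):
        cm, em, md = study({"a": {"p": [0, 0]}, "b": {"p": [0, 0]}})
        assert not detection_vector(cm, em, md, config).any().any()


class TestExclusivity:
    def make(self):
        det = pd.DataFrame(
            {
                "placenta": [True, True, True, False],
                "testis": [False, True, False, True],
                "brain": [False, True, True, True],
            },
            index=["excl", "ubiq", "other", "absent"],
        )
        return det

    def test_classes(self):
        cls = exclusivity_classes(self.make(), "placenta")
        assert cls.loc["excl"] == "exclusive_to_focus"
        assert cls.loc["ubiq"] == "ubiquitous"
        assert cls.loc["other"] == "other"
        assert cls.loc["absent"] == "other"

    def test_partition(self):
        cls = exclusivity_classes(self.make(), "placenta")
        assert cls.value_counts().sum() == 4

    def test_needs_two_tissues(self):
        with pytest.raises(ValueError):
            exclusivity_classes(pd.DataFrame({"placenta": [True]}), "placenta")


class TestFoldBias:
    def test_boundary_inclusive_five_fold(self, config):
        cm, em, md = study(
            {"placenta": {"p": [10, 10, 10]}, "testis": {"p": [2, 2, 2]}}
        )
        fb = fold_bias(cm, em, md, "placenta", "testis", config)
        assert fb.loc["p", "fold_class"] == "focus_biased"
        assert fb.loc["p", "fold_ratio"] == pytest.approx(5.0)

    def test_equal_medians_neither(self, config):
        cm, em, md = study({"placenta": {"p": [7, 7]}, "testis": {"p": [7, 7]}})
        assert (
            fold_bias(cm, em, md, "placenta", "testis", config).loc["p", "fold_class"]
            == "neither"
        )

    def test_reference_all_zero(self, config):
        cm, em, md = study({"placenta": {"p": [50, 50]}, "testis": {"p": [0, 0, 0]}})
        assert (
            fold_bias(cm, em, md, "placenta", "testis", config).loc["p", "fold_class"]
            == "not_detected_in_reference"
        )

    def test_undefined_tissue_error(self, config):
        cm, em, md = study({"placenta": {"p": [1, 1]}, "testis": {"p": [1, 1]}})
        with pytest.raises(ValueError, match="undefined tissue"):
            fold_bias(cm, em, md, "placenta", "spleen", config)

    def test_antisymmetry(self, config, rng):
        for _ in range(20):
            a = rng.integers(1, 200, size=(8, 4))
            b = rng.integers(1, 200, size=(8, 3))
            cm, em, md = study(
                {
                    "placenta": {f"p{i}": list(a[i]) for i in range(8)},
                    "testis": {f"p{i}": list(b[i]) for i in range(8)},
                }
            )
            fwd = fold_bias(cm, em, md, "placenta", "testis", config)["fold_class"]
            rev = fold_bias(cm, em, md, "testis", "placenta", config)["fold_class"]
            assert ((fwd == "focus_biased") == (rev == "reference_biased")).all()
            assert ((fwd == "reference_biased") == (rev == "focus_biased")).all()


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]] * 2, index=["a", "b"], columns=["s1", "s2", "s3"])
        d = hierarchical_cluster(df, log_transform=False)
        assert d.root.height == pytest.approx(0.0)
        assert set(d.root.members) == {"a", "b"}

    def test_single_linkage_hand_worked(self):
        # leaves at x = 0, 1, 3: pairwise distances 1, 2, 3.
        # single linkage merges (a,b) at 1, then joins c at min(2,3) = 2.
        df = pd.DataFrame([[0.0], [1.0], [3.0]], index=["a", "b", "c"], columns=["s"])
        d = hierarchical_cluster(df, method="single", log_transform=False)
        first = d.nodes[3]
        assert set(first.members) == {"a", "b"} and first.height == pytest.approx(1.0)
        assert d.root.height == pytest.approx(2.0)

    def test_heights_monotone(self, rng):
        for method in ("single", "complete", "average"):
            df = pd.DataFrame(
                rng.random((12, 6)), index=[f"p{i}" for i in range(12)]
            )
            d = hierarchical_cluster(df, method=method, log_transform=False)
            for node in d.internal_nodes():
                for c in node.children:
                    assert d.nodes[c].height <= node.height + 1e-12

    def test_constant_row_correlation_error(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="euclidean"):
            hierarchical_cluster(df, metric="correlation", log_transform=False)

    def test_newick_is_parseable(self):
        df = pd.DataFrame(
            np.arange(12.0).reshape(4, 3), index=["a", "b", "c", "d"]
        )
        d = hierarchical_cluster(df, log_transform=False)
        tree = Phylo.read(_io.StringIO(d.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c", "d"]


def block_study():
    """2 high-in-focus piRNAs, 3 flat ones, 4 focus + 4 other samples."""
    rows = {}
    for pid in ("hi1", "hi2"):
        rows[pid] = [5000.0] * 4 + [0.0] * 4
    for pid in ("f1", "f2", "f3"):
        rows[pid] = [50.0] * 8
    rpm = pd.DataFrame(
        rows, index=[f"s{j}" for j in range(8)]
    ).T
    md = [SampleMetadata(f"s{j}", "placenta" if j < 4 else "brain") for j in range(8)]
    return rpm, md


class TestNodeExtraction:
    def test_planted_block_recovered(self):
        rpm, md = block_study()
        d = hierarchical_cluster(rpm)
        node = extract_enriched_node(d, rpm, md, "placenta", factor=100, pseudocount=10)
        assert node is not None and set(node.members) == {"hi1", "hi2"}

    def test_threshold_above_any_node_is_empty(self):
        rpm, md = block_study()
        d = hierarchical_cluster(rpm)
        assert extract_enriched_node(d, rpm, md, "placenta", factor=1e9) is None

    def test_minimality_when_everything_satisfies(self):
        rpm, md = block_study()
        d = hierarchical_cluster(rpm)
        # a trivially true predicate: the smallest node (a leaf) wins, not root
        node = extract_node(d, lambda n: True)
        assert node is not None and len(node.members) == 1

    def test_node_region_report(self):
        region = RegionSet("MEG8", [GenomicInterval("chr14", 1000, 2000)])
        ann = {
            "in1": PiRNARecord("in1", SEQ, [GenomicInterval("chr14", 1100, 1130)]),
            "in2": PiRNARecord("in2", SEQ, [GenomicInterval("chr14", 1500, 1530)]),
            "multi": PiRNARecord(
                "multi",
                SEQ,
                [GenomicInterval("chr14", 1200, 1230), GenomicInterval("chr2", 0, 30)],
            ),
            "out": PiRNARecord("out", SEQ, [GenomicInterval("chr5", 0, 30)]),
        }
        summary, detail = node_region_report(["in1", "in2", "multi", "out"], ann, region)
        assert summary == (4, 3, 3)
        assert bool(detail.loc["multi", "in_region"]) is True
        assert bool(detail.loc["multi", "single_locus"]) is False

    def test_empty_node(self):
        region = RegionSet("MEG8", [GenomicInterval("chr14", 1000, 2000)])
        assert node_region_report([], {}, region)[0] == (0, 0, 0)


class TestTsne:
    def two_groups(self, rng, n_per=12):
        a = rng.normal(0, 1, size=(20, n_per))
        b = rng.normal(8, 1, size=(20, n_per))
        rpm = pd.DataFrame(
            np.abs(np.hstack([a, b])),
            index=[f"p{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(2 * n_per)],
        )
        md = [
            SampleMetadata(f"s{j}", "placenta" if j < n_per else "brain")
            for j in range(2 * n_per)
        ]
        return rpm, md

    def test_deterministic_for_fixed_seed(self, rng):
        rpm, _ = self.two_groups(rng)
        e1 = tsne_embed(rpm, perplexity=5, seed=7)
        e2 = tsne_embed(rpm, perplexity=5, seed=7)
        np.testing.assert_array_equal(e1.coords.to_numpy(), e2.coords.to_numpy())
        assert list(e1.coords.index) == list(rpm.columns)

    def test_perplexity_bound_error(self, rng):
        rpm, _ = self.two_groups(rng)
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(rpm.iloc[:, :5], perplexity=30)

    def test_groups_separate(self, rng):
        rpm, md = self.two_groups(rng)
        for seed in range(5):
            emb = tsne_embed(rpm, perplexity=5, seed=seed, log_transform=False)
            X = emb.coords.to_numpy()
            labels = np.array([0] * 12 + [1] * 12)
            intra, inter = [], []
            for i in range(24):
                for j in range(i + 1, 24):
                    d = np.linalg.norm(X[i] - X[j])
                    (intra if labels[i] == labels[j] else inter).append(d)
            assert np.mean(inter) > np.mean(intra)
            assert focus_silhouette(emb, md, "placenta") > 0
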