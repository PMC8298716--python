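"""Synthetic study generator: planted structure, determinism, noise classes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pirnakit import FilterConfig
from pirnakit.core import GenomicInterval, SampleMetadata
from pirnakit.io import write_annotation
from pirnakit.multiplicity import RegionIndex
from pirnakit.preprocess import preprocess_reads
from pirnakit.quantify import SubstringIndex, assign_sample
from pirnakit.simulate import (
    GenomeModel,
    NoiseModel,
    StudyParams,
    TruthTable,
    default_genome,
    generate_annotation,
    generate_reads,
    generate_sample_reads,
    iter_sample_reads,
    simulate_study,
)

from conftest import small_params


class TestGenomeModel:
    def test_default_is_valid(self):
        g = default_genome()
        assert "chrM" in g.chromosomes
        assert len(g.cluster_regions) == 20

    def test_cluster_overlapping_imprinted_rejected(self):
        with pytest.raises(ValueError, match="overlaps the imprinted region"):
            GenomeModel(
                chromosomes={"chr14": 1_000_000, "chrM": 16_569},
                imprinted_region=GenomicInterval("chr14", 1000, 2000),
                cluster_regions=__import__("pirnakit").RegionSet(
                    "c", [GenomicInterval("chr14", 1500, 3000)]
                ),
            )


class TestGenerateAnnotation:
    MIX = {"single": 151, "oligo": 116, "mid": 0, "high": 30}

    def test_exact_bin_counts(self, config):
        ann, truth = generate_annotation(
            297, self.MIX, default_genome(), 15, 19, 0, seed=1, config=config
        )
        assert truth["bin"].value_counts().to_dict() == {
            "single": 151, "oligo": 116, "high": 30
        }
        assert len(ann) == 297

    def test_designated_roles_placed(self, config):
        genome = default_genome()
        ann, truth = generate_annotation(
            60, {"single": 40, "oligo": 20, "mid": 0, "high": 0},
            genome, 5, 7, 4, seed=2, config=config,
        )
        imp = RegionIndex(genome.imprinted_region_set())
        clus = RegionIndex(genome.cluster_regions)
        for pid in truth.index[truth["imprinted"]]:
            rec = ann[pid]
            assert rec.locus_count == 1
            assert all(imp.overlaps(l) for l in rec.loci)
        assert truth["mitochondrial"].sum() == 7
        for pid in truth.index[truth["mitochondrial"]]:
            assert ann[pid].is_mitochondrial
        assert truth["in_cluster"].sum() == 4
        for pid in truth.index[truth["in_cluster"]]:
            assert any(clus.overlaps(l) for l in ann[pid].loci)
        # non-designated piRNAs stay clear of clusters and the imprinted region
        for pid in truth.index[~(truth["in_cluster"] | truth["imprinted"])]:
            assert not any(clus.overlaps(l) or imp.overlaps(l) for l in ann[pid].loci)

    def test_single_pirna(self, config):
        ann, truth = generate_annotation(
            1, {"single": 1, "oligo": 0, "mid": 0, "high": 0},
            default_genome(), 0, 0, 0, seed=3, config=config,
        )
        (rec,) = ann.values()
        assert rec.locus_count == 1

    def test_deterministic(self, config, tmp_path):
        outs = []
        for run in range(2):
            ann, _ = generate_annotation(
                50, {"single": 30, "oligo": 20, "mid": 0, "high": 0},
                default_genome(), 3, 3, 2, seed=11, config=config,
            )
            p = tmp_path / f"a{run}.tsv"
            write_annotation(ann, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_sequences_mutually_non_substring(self, config):
        ann, _ = generate_annotation(
            80, {"single": 80, "oligo": 0, "mid": 0, "high": 0},
            default_genome(), 0, 0, 0, seed=4, config=config,
        )
        seqs = [r.sequence for r in ann.values()]
        for i, s in enumerate(seqs):
            assert not any(s in t for j, t in enumerate(seqs) if j != i)

    def test_region_too_small_error(self, config):
        genome = GenomeModel(
            chromosomes={"chr14": 1_000_000, "chrM": 16_569},
            imprinted_region=GenomicInterval("chr14", 1000, 1050),
        )
        with pytest.raises(ValueError, match="too small"):
            generate_annotation(
                10, {"single": 10, "oligo": 0, "mid": 0, "high": 0},
                genome, 10, 0, 0, seed=5, config=config,
            )


def one_pirna_truth(config, mean, tissue="placenta"):
    ann, truth_df = generate_annotation(
        1, {"single": 1, "oligo": 0, "mid": 0, "high": 0},
        default_genome(), 0, 0, 0, seed=9, config=config,
    )
    truth_df["expressed"] = True
    means = pd.DataFrame({tissue: [mean]}, index=truth_df.index)
    return ann, TruthTable(pirnas=truth_df, tissue_means=means)


class TestGenerateReads:
    def test_depth_zero_empty(self, config, tmp_path):
        ann, truth = one_pirna_truth(config, 100.0)
        samples = [SampleMetadata("s1", "placenta")]
        generate_reads(ann, truth, samples, 0.0, NoiseModel(), 1, tmp_path)
        assert (tmp_path / "s1.fastq").read_text() == ""
        assert truth.realized_counts.to_numpy().sum() == 0

    def test_empty_sample_list_error(self, config):
        ann, truth = one_pirna_truth(config, 100.0)
        with pytest.raises(ValueError, match="empty sample list"):
            list(iter_sample_reads(ann, truth, [], 100.0, NoiseModel(), 1))

    def test_poisson_counts_near_mean(self, config):
        # oracle: P(|X - 100| <= 40) for X ~ Poisson(100) exceeds 99.9%
        lo, hi = 60, 140
        bound = stats.poisson.cdf(hi, 100) - stats.poisson.cdf(lo - 1, 100)
        assert bound > 0.999
        ann, truth = one_pirna_truth(config, 100.0)
        noise = NoiseModel(frac_mirna=0, frac_low_quality=0, frac_adapter=0,
                           frac_random=0, adapter_tag_frac=0)
        sample = SampleMetadata("s1", "placenta")
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            _, _, counts, _ = generate_sample_reads(ann, truth, sample, 100.0, noise, rng)
            hits += int(lo <= counts[0] <= hi)
        assert hits / n_seeds >= 0.99

    def test_low_quality_fraction_binomial(self, config):
        # half the library planted low-quality -> ~half fails the Phred filter
        noise = NoiseModel(frac_mirna=0, frac_low_quality=0.5, frac_adapter=0,
                           frac_random=0, adapter_tag_frac=0)
        ann, truth = one_pirna_truth(config, 100.0)
        rng = np.random.default_rng(3)
        reads, _, _, cls = generate_sample_reads(
            ann, truth, SampleMetadata("s1", "placenta"), 8000.0, noise, rng
        )
        _, report = preprocess_reads(reads, noise.adapter, config)
        n = report.n_input
        p_hat = report.low_quality / n
        assert abs(p_hat - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_class_counts_conserve_and_map_to_qc(self, config):
        noise = NoiseModel()
        ann, truth = one_pirna_truth(config, 500.0)
        rng = np.random.default_rng(4)
        reads, _, counts, cls = generate_sample_reads(
            ann, truth, SampleMetadata("s1", "placenta"), 20_000.0, noise, rng
        )
        assert len(reads) == sum(cls.values())
        _, report = preprocess_reads(reads, noise.adapter, config)
        assert report.mirna_length == cls["mirna_length"]
        assert report.low_quality == cls["low_quality"]
        assert report.adapter_only == cls["adapter_artifact"]
        assert report.retained == cls["pirna"] + cls["random_fragment"]

    def test_byte_identical_for_same_seed(self, config, tmp_path):
        params = small_params(depth=2000.0)
        outs = []
        for run in range(2):
            sim = simulate_study(21, params=params)
            out = tmp_path / f"run{run}"
            generate_reads(
                sim.annotation, sim.truth, sim.samples, params.depth, sim.noise, 21, out
            )
            outs.append(b"".join(sorted(p.read_bytes() for p in out.glob("*.fastq"))))
        assert outs[0] == outs[1]


class TestStudyRecovery:
    def test_assigned_counts_equal_realized_truth(self, config):
        """With exact sequence copies, assignment reproduces the drawn counts."""
        params = small_params(depth=5000.0)
        sim = simulate_study(31, params=params)
        index = SubstringIndex(sim.annotation, config.pirna_min_len)
        assigned = {}
        for sample, reads in sim.iter_reads():
            candidates, _ = preprocess_reads(reads, sim.noise.adapter, config)
            counts, _ = assign_sample(candidates, index)
            assigned[sample.sample_id] = counts
        for sid, counts in assigned.items():  # truth completed after the loop
            truth_col = sim.truth.realized_counts[sid]
            for pid in sim.annotation:
                assert counts.get(pid, 0) == truth_col.loc[pid]

    def test_planted_structure_summary(self):
        params = small_params()
        sim = simulate_study(41, params=params)
        truth = sim.truth.pirnas
        assert truth["expressed"].sum() == params.n_expressed
        assert truth.loc[truth["expressed"], "bin"].value_counts().to_dict() == {
            "single": params.n_single, "oligo": params.n_oligo,
            "mid": params.n_mid, "high": params.n_high,
        }
        assert truth["node_member"].sum() == params.n_node
        assert (truth["expressed"] & truth["mitochondrial"]).sum() == params.n_mito_expressed
        assert (truth["expressed"] & truth["in_cluster"]).sum() == 0
        cls = truth.loc[truth["expressed"], "expression_class"].value_counts()
        assert cls["exclusive"] == params.n_exclusive
        assert cls["ubiquitous"] == params.n_ubiquitous
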