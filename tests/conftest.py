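import numpy as np
import pytest
from hypothesis import settings

from pirnakit import FilterConfig, GenomicInterval, PiRNARecord
from pirnakit.simulate import StudyParams

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def config():
    return FilterConfig()


@pytest.fixture
def tiny_annotation():
    """Three piRNAs: one single-locus, one with 3 loci, one mitochondrial."""
    return {
        "piR-a": PiRNARecord(
            "piR-a", "ACGTACGTACGTACGTACGTACG", [GenomicInterval("chr1", 100, 123)]
        ),
        "piR-b": PiRNARecord(
            "piR-b",
            "TTTTGGGGCCCCAAAATTTTGGGGCC",
            [
                GenomicInterval("chr2", 10, 36),
                GenomicInterval("chr3", 500, 526),
                GenomicInterval("chr4", 900, 926),
            ],
        ),
        "piR-m": PiRNARecord(
            "piR-m", "GACTGACTGACTGACTGACTGACT", [GenomicInterval("chrM", 40, 64)]
        ),
    }


def small_params(**overrides) -> StudyParams:
    """Down-scaled planted study for fast generator/pipeline tests."""
    defaults = dict(
        n_focus_samples=6,
        n_reference_samples=3,
        n_other_samples=2,
        n_single=30,
        n_oligo=20,
        n_mid=2,
        n_high=3,
        oligo_loci_total=80,
        n_node=5,
        n_imprinted_single=4,
        n_mito_expressed=6,
        n_exclusive=3,
        n_ubiquitous=10,
        n_focus_biased=4,
        n_reference_biased=6,
        n_background=12,
        n_background_mito=4,
        n_background_cluster=3,
        depth=20_000.0,
    )
    defaults.update(overrides)
    return StudyParams(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
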