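import numpy as np
import pytest

from pathgwas.model import (
    GeneRecord,
    GeneSet,
    GeneSetCollection,
    GenotypeStudy,
    PipelineConfig,
    SnpRecord,
)


@pytest.fixture
def tiny_study() -> GenotypeStudy:
    """3 samples x 2 SNPs, hand-written."""
    snps = [SnpRecord("rs1", "1", 100), SnpRecord("rs2", "1", 500)]
    geno = np.array([[0, 1], [1, 2], [2, -1]], dtype=np.int8)
    return GenotypeStudy(snps, ["s1", "s2", "s3"], [1, 1, 0], geno)


@pytest.fixture
def null_study() -> GenotypeStudy:
    """60 samples x 40 SNPs with no genotype-phenotype association."""
    rng = np.random.default_rng(11)
    snps = [SnpRecord(f"rs{j}", "1", 1000 * (j + 1)) for j in range(40)]
    geno = rng.binomial(2, 0.3, size=(60, 40)).astype(np.int8)
    return GenotypeStudy(snps, [f"s{i}" for i in range(60)], [1] * 30 + [0] * 30, geno)


@pytest.fixture
def small_annotation() -> list[GeneRecord]:
    return [
        GeneRecord("GA", "1", 100_000, 120_000),
        GeneRecord("GB", "1", 200_000, 260_000),
        GeneRecord("GC", "2", 100_000, 150_000),
    ]


@pytest.fixture
def small_collection() -> GeneSetCollection:
    return GeneSetCollection(
        [
            GeneSet("SET_AB", frozenset({"GA", "GB"})),
            GeneSet("SET_C", frozenset({"GC"})),
            GeneSet("SET_ALL", frozenset({"GA", "GB", "GC"})),
        ]
    )


@pytest.fixture
def default_config() -> PipelineConfig:
    return PipelineConfig()
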