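"""Core domain types for case-control GWAS pathway analysis.

Conventions used throughout the package:

* Genotypes are stored as counts of the *minor* allele (0, 1, 2), with -1
  marking a missing call.  Minor/major assignment is made once, on the
  control group of the discovery cohort, and reused unchanged for any
  replication cohort so that directions of allele-frequency differences
  stay comparable across cohorts.
* Genomic coordinates are 1-based, fully closed intervals (NCBI
  convention): a gene spanning [start, end] contains both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

MISSING = -1  # sentinel genotype value


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP: identifier, map position and allele labels."""

    snp_id: str
    chromosome: str
    position: int
    minor_allele: str = "A"
    major_allele: str = "B"

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"SNP {self.snp_id}: position must be positive")
        if self.minor_allele == self.major_allele:
            raise ValueError(f"SNP {self.snp_id}: minor and major allele identical")


@dataclass(frozen=True)
class GeneRecord:
    """A gene locus: symbol plus 1-based closed genomic interval."""

    symbol: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.symbol}: start > end")


@dataclass(frozen=True)
class GeneSet:
    """A named pathway: a set of gene symbols with a source database tag."""

    name: str
    genes: frozenset[str]
    source: str = "other"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name}: empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


class GenotypeStudy:
    """One case-control cohort: SNP metadata, samples, phenotype, genotypes.

    Parameters
    ----------
    snps
        Ordered SNP records; order matches genotype matrix columns.
    samples
        Ordered sample identifiers; order matches matrix rows.
    phenotype
        Per-sample 1 (case) / 0 (control) labels.
    genotypes
        samples x snps int8 matrix of minor-allele counts; -1 = missing.
    """

    def __init__(
        self,
        snps: Sequence[SnpRecord],
        samples: Sequence[str],
        phenotype: Iterable[int],
        genotypes: np.ndarray,
    ) -> None:
        self.snps = list(snps)
        self.samples = list(samples)
        self.phenotype = np.asarray(list(phenotype), dtype=np.int8)
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self._validate()

    def _validate(self) -> None:
        n_samples, n_snps = self.genotypes.shape
        if n_samples != len(self.samples) or n_snps != len(self.snps):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in study")
        if not set(np.unique(self.genotypes)) <= {MISSING, 0, 1, 2}:
            bad = sorted(set(np.unique(self.genotypes)) - {MISSING, 0, 1, 2})
            raise ValueError(f"invalid genotype codes: {bad}")
        n_case = int(self.phenotype.sum())
        if n_case == 0 or n_case == len(self.phenotype):
            raise ValueError("study needs at least one case and one control")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return self.n_samples - self.n_cases

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype == 1

    def subset(self, snp_mask: np.ndarray | None = None, sample_mask: np.ndarray | None = None) -> "GenotypeStudy":
        """Return a new study restricted to masked SNPs / samples."""
        snp_mask = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask, bool)
        sample_mask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        return GenotypeStudy(
            [s for s, keep in zip(self.snps, snp_mask) if keep],
            [s for s, keep in zip(self.samples, sample_mask) if keep],
            self.phenotype[sample_mask],
            self.genotypes[np.ix_(sample_mask, snp_mask)],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeStudy):
            return NotImplemented
        return (
            self.snps == other.snps
            and self.samples == other.samples
            and np.array_equal(self.phenotype, other.phenotype)
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeStudy({self.n_samples} samples: {self.n_cases} cases / "
            f"{self.n_controls} controls, {self.n_snps} snps)"
        )


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the study's defaults.

    Defaults mirror the analysis protocol: pathways restricted to 10-100
    genes, SNPs assigned to genes within +/-20 kb of gene boundaries, SNP QC
    at MAF >= 0.01, call rate >= 95% and control HWE p >= 1e-4, 1000
    phenotype permutations, Aligator gene significance at SNP p < 0.01 with
    5000 replicate gene lists and 1000 correction repeats, and nominal
    significance at p < 0.05 everywhere else.
    """

    min_set_genes: int = 10
    max_set_genes: int = 100
    flank_bp: int = 20_000
    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-4
    n_permutations: int = 1000
    aligator_snp_p: float = 0.01
    aligator_replicates: int = 5000
    aligator_correction_reps: int = 1000
    srt_snp_p: float = 0.05
    pathway_sig_p: float = 0.05
    validation_p: float = 0.05
    gengen_weight: float = 1.0
    rng_seed: int = 0
    # count pathway size on raw GMT membership (True) or only on genes
    # present in the annotation (False)
    filter_on_raw_size: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_set_genes <= self.max_set_genes):
            raise ValueError("need 0 < min_set_genes <= max_set_genes")
        for name in ("maf_min", "call_rate_min", "hwe_p_min", "aligator_snp_p",
                     "srt_snp_p", "pathway_sig_p", "validation_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("flank_bp",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_permutations", "aligator_replicates", "aligator_correction_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
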