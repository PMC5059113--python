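"""Synthetic case-control genotype studies with planted pathway effects.

The generator emulates the structure the pipeline assumes: biallelic SNPs
in Hardy-Weinberg equilibrium within each phenotype group, SNPs placed
inside or within the flanking window of synthetic genes, genes organised
into pathways of bounded size, and a disease model expressed directly on
the allelic scale.  For an effect SNP with control minor-allele frequency
p and allelic odds ratio OR, the case-group frequency is

    p' = OR * p / (1 - p + OR * p)

and case genotypes are drawn in HWE at p'.  Because the analysis statistic
is the allelic test, the planted OR is directly recoverable from the scan.

Every SNP of an effect gene carries the gene's odds ratio.  SNPs are
independent by default; an optional within-gene correlation mode exists so
permutation nulls can be exercised under LD.  Pathways partition the gene
pool disjointly, keeping null pathways free of planted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    MISSING,
    GeneRecord,
    GeneSet,
    GeneSetCollection,
    GenotypeStudy,
    SnpRecord,
)

#: spacing that keeps neighbouring genes' 20 kb windows disjoint
_GENE_PITCH = 200_000
_GENE_LENGTH = 50_000


@dataclass
class SimulationDesign:
    """Study-shape and effect parameters for the generator.

    Defaults mirror a bladder-cancer discovery cohort (969 cases, 957
    controls) with a desk-scale SNP panel: 300 genes in 50 disjoint
    pathways of 10-30 genes, 1-5 SNPs per gene, common variants only.
    ``effect_pathways`` plants effects: each entry is (pathway name,
    fraction of its genes made causal, allelic odds ratio).
    """

    n_cases: int = 969
    n_controls: int = 957
    n_genes: int = 300
    snps_per_gene: tuple[int, int] = (1, 5)
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 30)
    effect_pathways: list[tuple[str, float, float]] = field(default_factory=list)
    missing_rate: float = 0.002
    ld_rho: float = 0.0  # within-gene genotype correlation; 0 = independent
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_genes, self.n_pathways) <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        smin, smax = self.pathway_size_range
        if smin < 1 or smin > smax:
            raise ValueError("invalid pathway_size_range")
        if smax * self.n_pathways > self.n_genes:
            # sizes are drawn in [smin, smax]; require worst-case feasibility
            raise ValueError(
                "n_genes too small for n_pathways disjoint pathways of the "
                "requested size range"
            )
        for name, frac, odds in self.effect_pathways:
            if not (0 < frac <= 1):
                raise ValueError(f"effect fraction for {name} must lie in (0, 1]")
            if odds <= 0:
                raise ValueError(f"odds ratio for {name} must be positive")


@dataclass
class SimulatedTruth:
    """Ground truth of the planted effects, for recovery tests."""

    effect_snps: list[str]
    effect_genes: list[str]
    effect_pathways: list[str]
    snp_or: dict[str, float]


def case_frequency(p: float, odds_ratio: float) -> float:
    """Case-group minor-allele frequency under a per-allele odds ratio."""
    return odds_ratio * p / (1 - p + odds_ratio * p)


@dataclass
class _Panel:
    """The fixed part of a design: SNPs, genes, pathways, planted effects."""

    snps: list[SnpRecord]
    genes: list[GeneRecord]
    collection: GeneSetCollection
    maf: np.ndarray
    snp_gene: list[int]  # gene index per SNP
    truth: SimulatedTruth


def _build_panel(design: SimulationDesign, rng: np.random.Generator) -> _Panel:
    genes = []
    for i in range(design.n_genes):
        chrom = str(1 + i % 22)
        slot = i // 22
        start = 1 + _GENE_PITCH * slot + _GENE_PITCH // 4
        genes.append(GeneRecord(f"G{i:04d}", chrom, start, start + _GENE_LENGTH))

    lo, hi = design.snps_per_gene
    snps, snp_gene = [], []
    counter = 0
    for gi, gene in enumerate(genes):
        for _ in range(int(rng.integers(lo, hi + 1))):
            pos = int(rng.integers(gene.start - 20_000, gene.end + 20_000 + 1))
            snps.append(SnpRecord(f"rs{counter:06d}", gene.chromosome, max(pos, 1), "A", "B"))
            snp_gene.append(gi)
            counter += 1
    maf = rng.uniform(*design.maf_range, size=len(snps))

    sizes = rng.integers(
        design.pathway_size_range[0], design.pathway_size_range[1] + 1,
        size=design.n_pathways,
    )
    pool = rng.permutation(design.n_genes)
    sets, cursor = [], 0
    for i, size in enumerate(sizes):
        members = frozenset(genes[g].symbol for g in pool[cursor:cursor + int(size)])
        cursor += int(size)
        sets.append(GeneSet(f"PATHWAY_{i:03d}", members))
    collection = GeneSetCollection(sets)

    symbol_to_gi = {g.symbol: i for i, g in enumerate(genes)}
    snp_or: dict[str, float] = {}
    effect_genes: list[str] = []
    effect_paths: list[str] = []
    for name, frac, odds in design.effect_pathways:
        gene_set = collection[name]
        members = sorted(gene_set.genes)
        n_effect = max(1, round(frac * len(members)))
        chosen = list(rng.choice(members, size=n_effect, replace=False))
        effect_paths.append(name)
        effect_genes.extend(chosen)
        chosen_gi = {symbol_to_gi[s] for s in chosen}
        for snp, gi in zip(snps, snp_gene):
            if gi in chosen_gi:
                snp_or[snp.snp_id] = odds
    truth = SimulatedTruth(
        effect_snps=sorted(snp_or),
        effect_genes=sorted(set(effect_genes)),
        effect_pathways=effect_paths,
        snp_or=snp_or,
    )
    return _Panel(snps=snps, genes=genes, collection=collection, maf=maf,
                  snp_gene=snp_gene, truth=truth)


def _draw_genotypes(
    panel: _Panel, freqs: np.ndarray, n: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """(n x n_snps) HWE genotypes at the given per-SNP frequencies.

    With rho > 0, SNPs within a gene copy an anchor SNP's genotype with
    probability rho per sample, producing within-gene correlation of about
    rho while preserving each SNP's marginal frequency (all SNPs of a gene
    then share the anchor's frequency).
    """
    n_snps = len(panel.snps)
    if rho == 0:
        return rng.binomial(2, freqs[None, :], size=(n, n_snps)).astype(np.int8)
    geno = np.empty((n, n_snps), dtype=np.int8)
    snp_gene = np.asarray(panel.snp_gene)
    for gi in np.unique(snp_gene):
        cols = np.where(snp_gene == gi)[0]
        f = freqs[cols[0]]  # shared within-gene frequency under LD mode
        anchor = rng.binomial(2, f, size=n).astype(np.int8)
        for c in cols:
            independent = rng.binomial(2, f, size=n).astype(np.int8)
            copy = rng.random(n) < rho
            geno[:, c] = np.where(copy, anchor, independent)
    return geno


def _simulate_from_panel(
    design: SimulationDesign, panel: _Panel, n_cases: int, n_controls: int,
    rng: np.random.Generator,
) -> GenotypeStudy:
    control_f = panel.maf.copy()
    if design.ld_rho > 0:
        # LD mode shares one frequency per gene (anchor's)
        snp_gene = np.asarray(panel.snp_gene)
        for gi in np.unique(snp_gene):
            cols = np.where(snp_gene == gi)[0]
            control_f[cols] = control_f[cols[0]]
    case_f = control_f.copy()
    for j, snp in enumerate(panel.snps):
        odds = panel.truth.snp_or.get(snp.snp_id)
        if odds is not None:
            case_f[j] = case_frequency(control_f[j], odds)

    g_ctl = _draw_genotypes(panel, control_f, n_controls, design.ld_rho, rng)
    g_case = _draw_genotypes(panel, case_f, n_cases, design.ld_rho, rng)
    geno = np.vstack([g_case, g_ctl])
    if design.missing_rate > 0:
        mask = rng.random(geno.shape) < design.missing_rate
        geno[mask] = MISSING
    samples = [f"case{i:05d}" for i in range(n_cases)] + [
        f"ctl{i:05d}" for i in range(n_controls)
    ]
    phenotype = [1] * n_cases + [0] * n_controls
    return GenotypeStudy(panel.snps, samples, phenotype, geno)


def simulate_study(
    design: SimulationDesign,
) -> tuple[GenotypeStudy, list[GeneRecord], GeneSetCollection, SimulatedTruth]:
    """Generate one cohort plus its annotation, pathways and ground truth."""
    ss = np.random.SeedSequence(design.seed)
    panel_rng, geno_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    panel = _build_panel(design, panel_rng)
    study = _simulate_from_panel(design, panel, design.n_cases, design.n_controls, geno_rng)
    return study, panel.genes, panel.collection, panel.truth


def simulate_two_cohorts(
    design: SimulationDesign, replication_scale: float = 1.0
) -> tuple[GenotypeStudy, GenotypeStudy, list[GeneRecord], GeneSetCollection, SimulatedTruth]:
    """Discovery and replication cohorts sharing panel, MAFs and effects.

    The cohorts use independent genotype streams; replication sample sizes
    are the discovery sizes scaled by ``replication_scale``.
    """
    if replication_scale <= 0:
        raise ValueError("replication_scale must be positive")
    ss = np.random.SeedSequence(design.seed)
    panel_rng, disc_rng, rep_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    panel = _build_panel(design, panel_rng)
    discovery = _simulate_from_panel(
        design, panel, design.n_cases, design.n_controls, disc_rng
    )
    replication = _simulate_from_panel(
        design,
        panel,
        max(1, round(design.n_cases * replication_scale)),
        max(1, round(design.n_controls * replication_scale)),
        rep_rng,
    )
    return discovery, replication, panel.genes, panel.collection, panel.truth
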