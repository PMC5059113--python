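"""Aligator pathway enrichment: significant-gene counting with SNP-sampled
replicate gene lists.

A gene is significant when at least one of its mapped SNPs has association
p below a preset threshold (default 0.01, strict <).  With K significant
genes study-wide, the null for "how many significant genes fall in pathway
S" is built by drawing replicate gene lists of size exactly K: SNPs are
drawn uniformly with replacement from all mapped SNPs and each drawn SNP's
gene(s) join the list if not already present, until the list reaches K.
Sampling SNPs rather than genes reproduces the key property of the method:
genes covered by many SNPs enter replicate lists proportionally more often,
which cancels the gene-size bias of the observed significant-gene list.

The per-pathway p is the fraction of replicates whose member count reaches
the observed count.  The multiple-testing correction treats one replicate
list as pseudo-observed data against a bootstrap resample of the replicate
pool, repeated many times, to judge whether the study shows an excess of
significant gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import PathwaySnpIndex, SnpGeneMap


@dataclass
class AligatorCorrection:
    """Study-wide excess-of-significant-sets summary."""

    observed_significant_sets: int
    null_counts: np.ndarray  # significant-set counts per bootstrap round
    percentile: float  # fraction of rounds with count < observed
    excess_p: float  # fraction of rounds with count >= observed

    def to_dict(self) -> dict:
        return {
            "observed_significant_sets": self.observed_significant_sets,
            "null_count_mean": float(self.null_counts.mean()),
            "null_count_q95": float(np.quantile(self.null_counts, 0.95)),
            "percentile": self.percentile,
            "excess_p": self.excess_p,
        }


def significant_genes(
    assoc: pd.DataFrame, snp_gene_map: SnpGeneMap, threshold: float = 0.01
) -> set[str]:
    """Genes with at least one mapped SNP at association p < threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    sig_snps = set(assoc.loc[assoc["p"] < threshold, "snp_id"])
    return {
        gene
        for gene, snps in snp_gene_map.gene_to_snps.items()
        if any(s in sig_snps for s in snps)
    }


def replicate_gene_list(
    snp_gene_map: SnpGeneMap, all_snps: list[str], k: int, rng: np.random.Generator
) -> list[str]:
    """One replicate gene list of size exactly ``k`` by SNP sampling.

    SNPs are drawn uniformly with replacement; a drawn SNP appends its
    mapped gene(s), in position order, skipping genes already present.  If
    a multi-gene SNP pushes the list past k it is truncated at exactly k.
    """
    reachable = {g for s in all_snps for g in snp_gene_map.snp_to_genes.get(s, ())}
    if k > len(reachable):
        raise ValueError(f"k={k} exceeds the {len(reachable)} genes reachable by SNP sampling")
    if k == 0:
        return []
    chosen: list[str] = []
    seen: set[str] = set()
    n = len(all_snps)
    while len(chosen) < k:
        for idx in rng.integers(0, n, size=128):
            for gene in snp_gene_map.snp_to_genes.get(all_snps[idx], ()):
                if gene not in seen:
                    seen.add(gene)
                    chosen.append(gene)
            if len(chosen) >= k:
                break
    return chosen[:k]


def aligator_p(observed_count: int, replicate_counts: np.ndarray) -> float:
    """Fraction of replicates with at least the observed member count.

    observed_count = 0 gives p = 1 (every replicate count is >= 0).
    """
    replicate_counts = np.asarray(replicate_counts)
    if replicate_counts.size == 0:
        raise ValueError("no replicate counts")
    return float((replicate_counts >= observed_count).mean())


@dataclass
class AligatorScan:
    """Full Aligator result: per-pathway table plus the replicate machinery
    needed by the multiple-testing correction."""

    table: pd.DataFrame
    replicate_counts: np.ndarray  # (n_replicates x n_pathways)
    pathway_names: list[str]
    k: int
    significant: set[str] = field(default_factory=set)


def aligator_scan(
    assoc: pd.DataFrame,
    snp_gene_map: SnpGeneMap,
    index: PathwaySnpIndex,
    threshold: float = 0.01,
    n_replicates: int = 5000,
    rng: np.random.Generator | None = None,
) -> AligatorScan:
    """Observed significant-gene counts and replicate null per pathway."""
    rng = np.random.default_rng() if rng is None else rng
    sig = significant_genes(assoc, snp_gene_map, threshold)
    k = len(sig)
    entries = index.usable
    names = [e.name for e in entries]
    member_sets = [set(e.genes) for e in entries]
    observed = np.array([len(m & sig) for m in member_sets])

    all_snps = list(assoc["snp_id"])
    gene_pathways: dict[str, list[int]] = {}
    for i, m in enumerate(member_sets):
        for g in m:
            gene_pathways.setdefault(g, []).append(i)

    counts = np.zeros((n_replicates, len(names)), dtype=np.int32)
    if k > 0:
        for rep in range(n_replicates):
            for gene in replicate_gene_list(snp_gene_map, all_snps, k, rng):
                for i in gene_pathways.get(gene, ()):
                    counts[rep, i] += 1
    p = np.array([aligator_p(int(o), counts[:, i]) for i, o in enumerate(observed)])
    table = pd.DataFrame(
        {
            "pathway": names,
            "observed_count": observed,
            "p_aligator": p,
            "n_replicates": n_replicates,
        }
    )
    return AligatorScan(table=table, replicate_counts=counts, pathway_names=names,
                        k=k, significant=sig)


def aligator_correction(
    scan: AligatorScan,
    n_reps: int = 1000,
    set_sig_p: float = 0.05,
    rng: np.random.Generator | None = None,
) -> AligatorCorrection:
    """Excess-of-significant-sets test by bootstrap over replicate lists.

    Each round promotes one replicate gene list to pseudo-observed data,
    resamples the replicate pool with replacement as its null, recomputes
    every pathway's p, and counts pathways with p < ``set_sig_p``.  The
    observed count of significant pathways is then located within the
    bootstrap distribution of those counts.
    """
    rng = np.random.default_rng() if rng is None else rng
    counts = scan.replicate_counts
    n_rep = counts.shape[0]
    observed_sig = int((scan.table["p_aligator"] < set_sig_p).sum())
    null_counts = np.zeros(n_reps, dtype=np.int32)
    for r in range(n_reps):
        obs_idx = int(rng.integers(n_rep))
        pool = rng.integers(0, n_rep, size=n_rep)
        # p per pathway: fraction of resampled lists with count >= pseudo-observed
        p = (counts[pool] >= counts[obs_idx]).mean(axis=0)
        null_counts[r] = int((p < set_sig_p).sum())
    percentile = float((null_counts < observed_sig).mean())
    excess_p = float((null_counts >= observed_sig).mean())
    return AligatorCorrection(
        observed_significant_sets=observed_sig,
        null_counts=null_counts,
        percentile=percentile,
        excess_p=excess_p,
    )
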