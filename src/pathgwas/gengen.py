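"""Gen-Gen pathway enrichment: weighted KS running-sum on gene statistics.

Each gene is represented by the largest allelic chi-square among its mapped
SNPs.  Genes are ranked by this statistic, descending, and a weighted
Kolmogorov-Smirnov-like running sum measures how concentrated a pathway's
genes are at the top of the ranking:

    ES(S) = max_{1<=j<=N} [ sum_{hits <= j} |r|^w / N_R  -  sum_{misses <= j} 1/(N - N_H) ]

with N_R = sum over the pathway's genes of |r|^w.  The weight exponent w
(default 1) is applied in both the numerator increments and N_R, following
the original GSEA convention; ES is the signed maximum of the running
deviation, not the maximum absolute deviation.

The null distribution comes from full phenotype permutations: for every
permutation the association scan, gene statistics, ranking and ES are
recomputed, which preserves LD between SNPs.  NES standardises ES against
the permutation mean and SD, and the empirical p is the fraction of
permutations with ES at least as large as observed (p = s/N, so a pathway
beating every permutation reports p = 0, printed as "< 1/N").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import chi2_to_p, permutation_chi2, PermutationEnsemble
from .mapping import SnpGeneMap
from .model import GeneSetCollection, GenotypeStudy


@dataclass
class GeneStatistic:
    gene: str
    r: float
    source_snp: str


@dataclass
class GenGenResult:
    pathway: str
    es: float
    nes: float  # NaN when the permutation SD is zero
    p_gengen: float
    n_permutations: int


def gene_statistics(assoc: pd.DataFrame, snp_gene_map: SnpGeneMap) -> list[GeneStatistic]:
    """Max-SNP chi-square per gene; genes without mapped SNPs are absent.

    ``source_snp`` is the SNP attaining the maximum (first in the gene's
    mapped order on ties).
    """
    chi2 = dict(zip(assoc["snp_id"], assoc["chi2"]))
    out = []
    for gene, snp_ids in snp_gene_map.gene_to_snps.items():
        best_snp, best = None, -np.inf
        for s in snp_ids:
            if s in chi2 and chi2[s] > best:
                best, best_snp = chi2[s], s
        if best_snp is not None:
            out.append(GeneStatistic(gene, float(best), best_snp))
    return out


def enrichment_score(
    r_sorted: np.ndarray, is_member_sorted: np.ndarray, weight: float = 1.0
) -> float:
    """ES for one pathway given rank-ordered gene statistics and membership.

    ``r_sorted`` must be sorted descending; ``is_member_sorted`` is the
    boolean pathway membership in the same order.  Degenerate sets (no
    member, or all genes members) are an error.
    """
    r_sorted = np.asarray(r_sorted, dtype=float)
    member = np.asarray(is_member_sorted, dtype=bool)
    n = r_sorted.size
    n_h = int(member.sum())
    if n_h == 0 or n_h == n:
        raise ValueError("degenerate gene set: no member or no non-member genes")
    w = np.abs(r_sorted) ** weight
    n_r = w[member].sum()
    if n_r == 0:
        # all member statistics zero: hit increments are uniform
        hit = np.cumsum(member) / n_h
    else:
        hit = np.cumsum(np.where(member, w, 0.0)) / n_r
    miss = np.cumsum(~member) / (n - n_h)
    return float(np.max(hit - miss))


def rank_genes(stats: list[GeneStatistic]) -> tuple[np.ndarray, list[str]]:
    """Sort gene statistics descending; ties broken by gene symbol.

    Returns (r values sorted, gene symbols in rank order).  The
    deterministic tie rule matters because the permutation null recomputes
    the ranking thousands of times.
    """
    ordered = sorted(stats, key=lambda g: (-g.r, g.gene))
    return np.array([g.r for g in ordered]), [g.gene for g in ordered]


class _PermutedGeneStats:
    """Vectorised per-permutation gene statistics and rankings.

    Precomputes, for the gene universe (genes with >=1 mapped SNP present
    in the study), segment boundaries so the per-gene max over SNP
    chi-squares is one ``maximum.reduceat`` per permutation batch.  Genes
    are held in lexicographic order so a stable argsort of -r reproduces
    the symbol tie-break.
    """

    def __init__(self, study: GenotypeStudy, snp_gene_map: SnpGeneMap):
        snp_pos = {sid: j for j, sid in enumerate(study.snp_ids)}
        genes, col_idx, boundaries = [], [], []
        for gene in sorted(snp_gene_map.gene_to_snps):
            cols = [snp_pos[s] for s in snp_gene_map.gene_to_snps[gene] if s in snp_pos]
            if cols:
                boundaries.append(len(col_idx))
                col_idx.extend(cols)
                genes.append(gene)
        self.genes = genes  # lexicographic order
        self._col_idx = np.array(col_idx, dtype=np.intp)
        self._boundaries = np.array(boundaries, dtype=np.intp)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_stats(self, chi2_matrix: np.ndarray) -> np.ndarray:
        """(n_rows x n_genes) per-gene max chi2 from (n_rows x n_snps) chi2."""
        return np.maximum.reduceat(chi2_matrix[:, self._col_idx], self._boundaries, axis=1)


def _es_matrix(
    r: np.ndarray, member: np.ndarray, weight: float
) -> np.ndarray:
    """ES per row for one pathway; ``r`` is (rows x genes), unsorted."""
    order = np.argsort(-r, axis=1, kind="stable")
    r_sorted = np.take_along_axis(r, order, axis=1)
    member_sorted = member[order]
    n = r.shape[1]
    n_h = int(member.sum())
    w = np.abs(r_sorted) ** weight
    w_hit = np.where(member_sorted, w, 0.0)
    n_r = w_hit.sum(axis=1, keepdims=True)
    uniform = np.cumsum(member_sorted, axis=1) / n_h
    with np.errstate(invalid="ignore", divide="ignore"):
        weighted = np.cumsum(w_hit, axis=1) / n_r
    hit = np.where(n_r > 0, weighted, uniform)
    miss = np.cumsum(~member_sorted, axis=1) / (n - n_h)
    return (hit - miss).max(axis=1)


def gengen_scan(
    study: GenotypeStudy,
    snp_gene_map: SnpGeneMap,
    collection: GeneSetCollection,
    ensemble: PermutationEnsemble,
    weight: float = 1.0,
    observed_chi2: np.ndarray | None = None,
    permuted_chi2: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gen-Gen ES/NES and permutation p for every pathway.

    ``observed_chi2`` / ``permuted_chi2`` (per-SNP chi-square for the
    observed labels and the ensemble) may be passed in when already
    computed, e.g. to share one permutation scan with the SNP Ratio Test.

    Returns a frame with columns pathway, es, nes, p_gengen, n_permutations;
    pathways degenerate in the gene universe are skipped.  NES is NaN where
    the permutation ES spread is zero.
    """
    from .association import association_scan

    pgs = _PermutedGeneStats(study, snp_gene_map)
    if pgs.n_genes == 0:
        raise ValueError("no genes with mapped SNPs in study")
    if observed_chi2 is None:
        observed_chi2 = association_scan(study)["chi2"].to_numpy()
    if permuted_chi2 is None:
        permuted_chi2 = permutation_chi2(study, ensemble)
    r_obs = pgs.gene_stats(observed_chi2[None, :])
    r_perm = pgs.gene_stats(permuted_chi2)

    gene_index = {g: i for i, g in enumerate(pgs.genes)}
    n = pgs.n_genes
    rows = []
    for gene_set in collection:
        idx = [gene_index[g] for g in (s.upper() for s in gene_set.genes) if g in gene_index]
        member = np.zeros(n, dtype=bool)
        member[idx] = True
        n_h = member.sum()
        if n_h == 0 or n_h == n:
            continue
        es_obs = float(_es_matrix(r_obs, member, weight)[0])
        es_perm = _es_matrix(r_perm, member, weight)
        sd = float(es_perm.std(ddof=0))
        nes = (es_obs - float(es_perm.mean())) / sd if sd > 0 else np.nan
        p = float((es_perm >= es_obs).mean())
        rows.append(
            {"pathway": gene_set.name, "es": es_obs, "nes": nes,
             "p_gengen": p, "n_permutations": ensemble.n_permutations}
        )
    return pd.DataFrame(rows, columns=["pathway", "es", "nes", "p_gengen", "n_permutations"])


def chi2_p_values(chi2_matrix: np.ndarray) -> np.ndarray:
    """Convenience re-export: p-values for a chi-square matrix."""
    return chi2_to_p(chi2_matrix)
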