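"""SNP Ratio Test: pathway significance via the fraction of significant SNPs.

For pathway W the statistic is the SNP ratio

    r_w = (# significant SNPs in W) / (# SNPs in W)

with SNP significance at p below a preset threshold (default 0.05).  The
null recomputes every SNP's association p under phenotype permutations and
the empirical pathway p uses the add-one rule

    P = (s + 1) / (N + 1)

where s counts permuted datasets whose ratio is greater than or equal to
the observed one.  P therefore never reaches 0 (minimum 1/(N+1)), unlike
the Gen-Gen s/N convention.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

from .association import chi2_to_p, permutation_chi2, PermutationEnsemble
from .mapping import PathwaySnpIndex
from .model import GenotypeStudy

SRT_COLUMNS = [
    "pathway", "n_snps", "n_significant", "ratio", "s", "n_permutations", "p_srt",
]


def snp_ratio(assoc: pd.DataFrame, pathway_snps: list[str], threshold: float = 0.05) -> float:
    """Fraction of the pathway's distinct SNPs with association p < threshold."""
    if not pathway_snps:
        raise ValueError("pathway has no SNPs")
    distinct = list(dict.fromkeys(pathway_snps))
    p = assoc.set_index("snp_id")["p"]
    sig = sum(1 for s in distinct if s in p.index and p[s] < threshold)
    return sig / len(distinct)


def srt_empirical_p(s: int, n: int) -> float:
    """Add-one empirical p-value (s + 1) / (N + 1), computed exactly."""
    if n < 1:
        raise ValueError("need at least one permutation")
    if not (0 <= s <= n):
        raise ValueError(f"s={s} outside [0, {n}]")
    return float(Fraction(s + 1, n + 1))


def srt_scan(
    study: GenotypeStudy,
    index: PathwaySnpIndex,
    ensemble: PermutationEnsemble,
    threshold: float = 0.05,
    observed_p: np.ndarray | None = None,
    permuted_chi2: np.ndarray | None = None,
) -> pd.DataFrame:
    """Observed SNP ratios and permutation p for every usable pathway.

    Shares the permutation chi-square matrix with Gen-Gen when passed in.
    Pathways without mapped SNPs are skipped.  Ties (permuted ratio equal
    to observed) count toward s.
    """
    from .association import association_scan

    if observed_p is None:
        observed_p = association_scan(study)["p"].to_numpy()
    if permuted_chi2 is None:
        permuted_chi2 = permutation_chi2(study, ensemble)
    perm_p = chi2_to_p(permuted_chi2)
    n_perm = perm_p.shape[0]

    snp_pos = {sid: j for j, sid in enumerate(study.snp_ids)}
    sig_obs = observed_p < threshold
    sig_perm = perm_p < threshold

    rows = []
    for entry in index.usable:
        cols = np.array([snp_pos[s] for s in entry.snp_ids if s in snp_pos], dtype=np.intp)
        if cols.size == 0:
            continue
        n_snps = cols.size
        n_sig = int(sig_obs[cols].sum())
        ratio = n_sig / n_snps
        perm_ratio = sig_perm[:, cols].mean(axis=1)
        s = int((perm_ratio >= ratio).sum())
        rows.append(
            {
                "pathway": entry.name,
                "n_snps": n_snps,
                "n_significant": n_sig,
                "ratio": ratio,
                "s": s,
                "n_permutations": n_perm,
                "p_srt": srt_empirical_p(s, n_perm),
            }
        )
    return pd.DataFrame(rows, columns=SRT_COLUMNS)
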