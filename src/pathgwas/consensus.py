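"""Consensus pathway calling, candidate SNP selection, two-cohort
validation and stratified meta-analysis.

A pathway is a *consensus* finding when all three enrichment methods
(Gen-Gen, Aligator, SNP Ratio Test) give p < alpha (default 0.05); the
most promising ("top") pathways additionally reach p <= 0.001 in at least
one method.  Candidate SNPs from consensus pathways are validated in an
independent cohort: a SNP validates when both cohorts are significant at
p < alpha AND the allele-frequency difference points the same way in both.
The meta-analysis is a Cochran-Mantel-Haenszel 1-d.f. test over the two
study-stratified 2x2 allele-count tables, with pooled MAFs from summed
counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import StratifiedTable

from .mapping import PathwaySnpIndex
from .model import GeneSet

logger = logging.getLogger(__name__)

CONSENSUS_COLUMNS = [
    "pathway", "p_gengen", "rank_gengen", "p_aligator", "rank_aligator",
    "p_srt", "rank_srt", "top_flag",
]


def _competition_rank(p: pd.Series) -> pd.Series:
    """1224-style rank: ties share the smallest rank, as in league tables."""
    return p.rank(method="min").astype(int)


def consensus_pathways(
    gengen: pd.DataFrame,
    aligator: pd.DataFrame,
    srt: pd.DataFrame,
    alpha: float = 0.05,
    top_p: float = 0.001,
) -> pd.DataFrame:
    """Pathways with p < alpha under all three methods simultaneously.

    Ranks are competition ranks within each method over its full pathway
    list (computed before intersecting).  ``top_flag`` marks pathways with
    p <= ``top_p`` in any method.  Output is sorted by Gen-Gen p then
    pathway name.  Pathways missing from any method are excluded with a
    warning.
    """
    g = gengen[["pathway", "p_gengen"]].copy()
    a = aligator[["pathway", "p_aligator"]].copy()
    s = srt[["pathway", "p_srt"]].copy()
    g["rank_gengen"] = _competition_rank(g["p_gengen"])
    a["rank_aligator"] = _competition_rank(a["p_aligator"])
    s["rank_srt"] = _competition_rank(s["p_srt"])

    all_names = set(g.pathway) | set(a.pathway) | set(s.pathway)
    common = set(g.pathway) & set(a.pathway) & set(s.pathway)
    if all_names - common:
        logger.warning(
            "%d pathways missing from at least one method were excluded",
            len(all_names - common),
        )
    merged = g.merge(a, on="pathway").merge(s, on="pathway")
    keep = (
        (merged["p_gengen"] < alpha)
        & (merged["p_aligator"] < alpha)
        & (merged["p_srt"] < alpha)
    )
    out = merged[keep].copy()
    out["top_flag"] = (
        (out["p_gengen"] <= top_p) | (out["p_aligator"] <= top_p) | (out["p_srt"] <= top_p)
    )
    out = out.sort_values(["p_gengen", "pathway"], kind="stable").reset_index(drop=True)
    return out.reindex(columns=CONSENSUS_COLUMNS)


def overlap_genes(a: GeneSet, b: GeneSet) -> set[str]:
    """Exact symbol intersection of two gene sets."""
    return set(a.genes) & set(b.genes)


def select_candidate_snps(
    consensus: pd.DataFrame,
    index: PathwaySnpIndex,
    assoc: pd.DataFrame,
    alpha: float = 0.05,
    top_only: bool = False,
) -> pd.DataFrame:
    """Distinct SNPs in consensus pathways with discovery p < alpha.

    Each SNP appears once, annotated with every consensus pathway it
    belongs to (comma-joined, pathway order of the consensus table).  With
    ``top_only`` the selection is restricted to top-flagged pathways.
    """
    rows = consensus[consensus["top_flag"]] if top_only else consensus
    p = assoc.set_index("snp_id")["p"]
    membership: dict[str, list[str]] = {}
    for name in rows["pathway"]:
        if name not in index.entries:
            continue
        for sid in index[name].snp_ids:
            if sid in p.index and p[sid] < alpha:
                membership.setdefault(sid, []).append(name)
    out = pd.DataFrame(
        {
            "snp_id": list(membership),
            "pathways": [",".join(v) for v in membership.values()],
            "p_discovery": [float(p[sid]) for sid in membership],
        }
    )
    return out.sort_values("p_discovery", kind="stable").reset_index(drop=True) if len(out) else out


def meta_analysis(
    discovery: pd.Series | dict, replication: pd.Series | dict
) -> tuple[float, float, float]:
    """CMH meta-analysis of two cohorts' allele-count tables.

    Inputs are association rows with fields case_minor_count,
    case_total_alleles, control_minor_count, control_total_alleles (same
    minor-allele orientation in both cohorts).  Returns (meta_p,
    pooled_maf_case, pooled_maf_control).  A stratum with a zero group
    total is dropped with a warning; with no usable stratum the p is NaN.
    """
    strata = []
    for row in (discovery, replication):
        a = float(row["case_minor_count"])
        at = float(row["case_total_alleles"])
        c = float(row["control_minor_count"])
        ct = float(row["control_total_alleles"])
        if at == 0 or ct == 0:
            logger.warning("meta-analysis: dropping stratum with empty group")
            continue
        strata.append(np.array([[a, at - a], [c, ct - c]], dtype=float))

    num_case = sum(float(r["case_minor_count"]) for r in (discovery, replication))
    den_case = sum(float(r["case_total_alleles"]) for r in (discovery, replication))
    num_ctl = sum(float(r["control_minor_count"]) for r in (discovery, replication))
    den_ctl = sum(float(r["control_total_alleles"]) for r in (discovery, replication))
    pooled_case = num_case / den_case if den_case else float("nan")
    pooled_ctl = num_ctl / den_ctl if den_ctl else float("nan")

    if not strata:
        return float("nan"), pooled_case, pooled_ctl
    if len(strata) == 1:
        from .association import allelic_test

        t = strata[0]
        _, p = allelic_test(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
        return p, pooled_case, pooled_ctl
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = StratifiedTable(strata).test_null_odds(correction=False)
    return float(res.pvalue), pooled_case, pooled_ctl


@dataclass
class ValidationSummary:
    records: pd.DataFrame
    n_candidates: int
    n_validated: int


def validate_snps(
    candidates: pd.DataFrame,
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
) -> ValidationSummary:
    """Two-cohort validation of candidate SNPs with meta-analysis.

    A SNP validates iff discovery p < alpha, replication p < alpha and the
    sign of (case MAF - control MAF) agrees in the two cohorts (strict <
    at the boundary).  SNPs absent from the replication table are kept with
    validated = False and NaN replication fields.
    """
    disc = discovery.set_index("snp_id")
    rep = replication.set_index("snp_id")
    rows = []
    for cand in candidates.itertuples():
        sid = cand.snp_id
        d = disc.loc[sid]
        present = sid in rep.index
        r = rep.loc[sid] if present else None
        direction_ok = False
        validated = False
        meta_p = pooled_case = pooled_ctl = float("nan")
        if present:
            d_dir = np.sign(d["maf_case"] - d["maf_control"])
            r_dir = np.sign(r["maf_case"] - r["maf_control"])
            direction_ok = bool(d_dir == r_dir and d_dir != 0)
            validated = bool(d["p"] < alpha and r["p"] < alpha and direction_ok)
            meta_p, pooled_case, pooled_ctl = meta_analysis(d, r)
        rows.append(
            {
                "snp_id": sid,
                "pathways": getattr(cand, "pathways", ""),
                "maf_case_discovery": d["maf_case"],
                "maf_control_discovery": d["maf_control"],
                "p_discovery": d["p"],
                "maf_case_replication": r["maf_case"] if present else np.nan,
                "maf_control_replication": r["maf_control"] if present else np.nan,
                "p_replication": r["p"] if present else np.nan,
                "direction_consistent": direction_ok,
                "validated": validated,
                "maf_case_pooled": pooled_case,
                "maf_control_pooled": pooled_ctl,
                "p_meta": meta_p,
            }
        )
    records = pd.DataFrame(rows)
    return ValidationSummary(
        records=records,
        n_candidates=len(records),
        n_validated=int(records["validated"].sum()) if len(records) else 0,
    )
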