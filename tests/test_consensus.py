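import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathgwas.association import allelic_test
from pathgwas.consensus import (
    consensus_pathways,
    meta_analysis,
    overlap_genes,
    select_candidate_snps,
    validate_snps,
)
from pathgwas.datasets import (
    load_pathway_pvalues,
    load_significant_pathway_sets,
    load_validated_snps,
)
from pathgwas.mapping import PathwayEntry, PathwaySnpIndex
from pathgwas.model import GeneSet


def cmh_oracle(tables):
    """Independent Cochran-Mantel-Haenszel 1-d.f. statistic (no correction)."""
    num = var = 0.0
    for t in tables:
        a, b = t[0]
        c, d = t[1]
        n = a + b + c + d
        num += a - (a + b) * (a + c) / n
        var += (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
    from scipy import stats

    chi2 = num**2 / var
    return chi2, float(stats.chi2.sf(chi2, 1))


def _three_tables(ps):
    """Per-method frames from {pathway: (p_gengen, p_aligator, p_srt)}."""
    names = list(ps)
    g = pd.DataFrame({"pathway": names, "p_gengen": [ps[n][0] for n in names]})
    a = pd.DataFrame({"pathway": names, "p_aligator": [ps[n][1] for n in names]})
    s = pd.DataFrame({"pathway": names, "p_srt": [ps[n][2] for n in names]})
    return g, a, s


class TestConsensusPathways:
    def test_all_null_gives_empty(self):
        g, a, s = _three_tables({"A": (0.5, 0.5, 0.5), "B": (0.5, 0.5, 0.5)})
        assert len(consensus_pathways(g, a, s)) == 0

    def test_requires_all_three_methods(self):
        g, a, s = _three_tables({"A": (0.01, 0.01, 0.2), "B": (0.01, 0.01, 0.01)})
        out = consensus_pathways(g, a, s)
        assert list(out["pathway"]) == ["B"]

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(89)
        ps = {f"P{i}": tuple(rng.uniform(size=3)) for i in range(40)}
        g, a, s = _three_tables(ps)
        small = set(consensus_pathways(g, a, s, alpha=0.2)["pathway"])
        large = set(consensus_pathways(g, a, s, alpha=0.6)["pathway"])
        assert small <= large

    def test_published_table_under_stated_rule(self):
        # The published list contains one pathway (NDKDYNAMIN, SRT p 0.08991)
        # that fails its own all-three-p<0.05 rule, so the strict rule keeps
        # 17 of the 18 published rows; the five top pathways are unaffected.
        t = load_pathway_pvalues()
        out = consensus_pathways(
            t[["pathway", "p_gengen"]], t[["pathway", "p_aligator"]],
            t[["pathway", "p_srt"]],
        )
        assert "BIOCARTA_NDKDYNAMIN_PATHWAY" not in set(out["pathway"])
        assert len(out) == 17
        top = set(out.loc[out["top_flag"], "pathway"])
        assert top == {
            "REACTOME_SIGNALING_BY_PDGF",
            "REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH",
            "BIOCARTA_RACCYCD_PATHWAY",
            "BIOCARTA_SKP2E2F_PATHWAY",
            "REACTOME_UNFOLDED_PROTEIN_RESPONSE",
        }


class TestOverlapGenes:
    def test_published_cell_cycle_overlap(self):
        sets = load_significant_pathway_sets()
        got = overlap_genes(sets["BIOCARTA_RACCYCD_PATHWAY"],
                            sets["BIOCARTA_SKP2E2F_PATHWAY"])
        assert got == {"E2F1", "TFDP1", "CDK2", "RB1", "CCNE1"}

    def test_published_growth_factor_overlap(self):
        sets = load_significant_pathway_sets()
        got = overlap_genes(
            sets["REACTOME_SIGNALING_BY_PDGF"],
            sets["REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH"],
        )
        assert len(got) == 31

    def test_disjoint_and_symmetry_idempotence(self):
        a = GeneSet("A", frozenset({"G1", "G2"}))
        b = GeneSet("B", frozenset({"G3"}))
        assert overlap_genes(a, b) == set()
        assert overlap_genes(a, a) == set(a.genes)
        c = GeneSet("C", frozenset({"G2", "G3"}))
        assert overlap_genes(a, c) == overlap_genes(c, a)


class TestSelectCandidates:
    def _fixture(self):
        idx = PathwaySnpIndex()
        idx.entries["P1"] = PathwayEntry("P1", ["GA"], ["rs1", "rs2"])
        idx.entries["P2"] = PathwayEntry("P2", ["GB"], ["rs2", "rs3"])
        consensus = pd.DataFrame({"pathway": ["P1", "P2"], "top_flag": [True, False]})
        assoc = pd.DataFrame({"snp_id": ["rs1", "rs2", "rs3"], "p": [0.01, 0.02, 0.5]})
        return consensus, idx, assoc

    def test_shared_snp_deduplicated_with_both_annotations(self):
        consensus, idx, assoc = self._fixture()
        out = select_candidate_snps(consensus, idx, assoc, 0.05)
        row = out[out.snp_id == "rs2"].iloc[0]
        assert row["pathways"] == "P1,P2"
        assert len(out) == 2  # rs1 and rs2; rs3 above alpha

    def test_no_snp_below_alpha(self):
        consensus, idx, assoc = self._fixture()
        out = select_candidate_snps(consensus, idx, assoc, 0.001)
        assert len(out) == 0

    def test_top_only_restricts(self):
        consensus, idx, assoc = self._fixture()
        out = select_candidate_snps(consensus, idx, assoc, 0.05, top_only=True)
        assert set(out["snp_id"]) == {"rs1", "rs2"}
        assert all("P2" not in p.split(",")[0] for p in out["pathways"])

    def test_matches_brute_force_union(self):
        rng = np.random.default_rng(97)
        idx = PathwaySnpIndex()
        snp_pool = [f"rs{i}" for i in range(60)]
        for k in range(8):
            snps = list(rng.choice(snp_pool, 12, replace=False))
            idx.entries[f"P{k}"] = PathwayEntry(f"P{k}", [], snps)
        consensus = pd.DataFrame({"pathway": [f"P{k}" for k in range(8)],
                                  "top_flag": [False] * 8})
        assoc = pd.DataFrame({"snp_id": snp_pool, "p": rng.uniform(size=60)})
        out = select_candidate_snps(consensus, idx, assoc, 0.3)
        p = assoc.set_index("snp_id")["p"]
        expected = {s for k in range(8) for s in idx[f"P{k}"].snp_ids if p[s] < 0.3}
        assert set(out["snp_id"]) == expected


def _assoc_row(case_minor, case_total, control_minor, control_total):
    _, p = allelic_test(case_minor, case_total - case_minor,
                        control_minor, control_total - control_minor)
    return pd.Series({
        "case_minor_count": case_minor, "case_total_alleles": case_total,
        "control_minor_count": control_minor, "control_total_alleles": control_total,
        "maf_case": case_minor / case_total, "maf_control": control_minor / control_total,
        "p": p,
    })


class TestMetaAnalysis:
    def test_matches_independent_cmh(self):
        rng = np.random.default_rng(101)
        for _ in range(50):
            d = _assoc_row(*(int(x) for x in rng.integers(50, 400, 2)),
                           *(int(x) for x in rng.integers(50, 400, 2)))
            r = _assoc_row(*(int(x) for x in rng.integers(50, 400, 2)),
                           *(int(x) for x in rng.integers(50, 400, 2)))
            if d["maf_case"] >= 1 or r["maf_case"] >= 1:
                continue
            p, _, _ = meta_analysis(d, r)
            tables = []
            for row in (d, r):
                a = row["case_minor_count"]; at = row["case_total_alleles"]
                c = row["control_minor_count"]; ct = row["control_total_alleles"]
                tables.append(np.array([[a, at - a], [c, ct - c]], float))
            _, p_oracle = cmh_oracle(tables)
            assert p == pytest.approx(p_oracle, rel=1e-6)

    def test_opposite_strata_cancel(self):
        d = _assoc_row(150, 400, 100, 400)
        r = _assoc_row(100, 400, 150, 400)
        p, pooled_case, pooled_ctl = meta_analysis(d, r)
        assert p > 0.9
        assert pooled_case == pytest.approx(pooled_ctl)

    def test_meta_p_between_per_study_ps_when_one_stratum_null(self):
        d = _assoc_row(100, 400, 100, 400)   # chi2 = 0, p = 1
        r = _assoc_row(160, 400, 100, 400)   # strong signal
        p, _, _ = meta_analysis(d, r)
        assert r["p"] < p < d["p"]

    def test_pooled_maf_is_count_weighted_mean(self):
        d = _assoc_row(100, 400, 120, 400)
        r = _assoc_row(300, 800, 310, 800)
        _, pooled_case, pooled_ctl = meta_analysis(d, r)
        assert pooled_case == pytest.approx(400 / 1200)
        assert min(d["maf_case"], r["maf_case"]) <= pooled_case <= max(d["maf_case"], r["maf_case"])
        assert min(d["maf_control"], r["maf_control"]) <= pooled_ctl <= max(d["maf_control"], r["maf_control"])


class TestValidateSnps:
    def _tables(self):
        discovery = pd.DataFrame([
            {"snp_id": "rsA", "maf_case": 0.42, "maf_control": 0.46, "p": 0.0089,
             "case_minor_count": 814, "case_total_alleles": 1938,
             "control_minor_count": 880, "control_total_alleles": 1914},
            {"snp_id": "rsB", "maf_case": 0.30, "maf_control": 0.25, "p": 0.01,
             "case_minor_count": 581, "case_total_alleles": 1938,
             "control_minor_count": 478, "control_total_alleles": 1914},
            {"snp_id": "rsC", "maf_case": 0.30, "maf_control": 0.25, "p": 0.01,
             "case_minor_count": 581, "case_total_alleles": 1938,
             "control_minor_count": 478, "control_total_alleles": 1914},
        ])
        replication = pd.DataFrame([
            {"snp_id": "rsA", "maf_case": 0.43, "maf_control": 0.46, "p": 0.0004,
             "case_minor_count": 3037, "case_total_alleles": 7064,
             "control_minor_count": 4710, "control_total_alleles": 10240},
            {"snp_id": "rsB", "maf_case": 0.24, "maf_control": 0.28, "p": 0.01,
             "case_minor_count": 1695, "case_total_alleles": 7064,
             "control_minor_count": 2867, "control_total_alleles": 10240},
            {"snp_id": "rsC", "maf_case": 0.30, "maf_control": 0.25, "p": 0.05,
             "case_minor_count": 2119, "case_total_alleles": 7064,
             "control_minor_count": 2560, "control_total_alleles": 10240},
        ])
        candidates = pd.DataFrame({"snp_id": ["rsA", "rsB", "rsC"],
                                   "pathways": ["P", "P", "P"],
                                   "p_discovery": [0.0089, 0.01, 0.01]})
        return candidates, discovery, replication

    def test_same_direction_both_significant_validates(self):
        cands, disc, rep = self._tables()
        out = validate_snps(cands, disc, rep).records.set_index("snp_id")
        assert bool(out.loc["rsA", "validated"])
        assert bool(out.loc["rsA", "direction_consistent"])

    def test_opposite_direction_fails(self):
        cands, disc, rep = self._tables()
        out = validate_snps(cands, disc, rep).records.set_index("snp_id")
        assert not bool(out.loc["rsB", "validated"])
        assert not bool(out.loc["rsB", "direction_consistent"])

    def test_boundary_p_is_strict(self):
        cands, disc, rep = self._tables()
        out = validate_snps(cands, disc, rep, alpha=0.05).records.set_index("snp_id")
        assert not bool(out.loc["rsC", "validated"])  # replication p == alpha

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_validated_implies_both_significant(self, data):
        rng_vals = data.draw(st.lists(
            st.tuples(st.floats(0.001, 0.99), st.floats(0.001, 0.99),
                      st.floats(0.1, 0.45), st.floats(0.1, 0.45)),
            min_size=1, max_size=6))
        disc_rows, rep_rows, cand = [], [], []
        for i, (pd_, pr_, fd, fr) in enumerate(rng_vals):
            sid = f"rs{i}"
            disc_rows.append({"snp_id": sid, "maf_case": fd, "maf_control": 0.3, "p": pd_,
                              "case_minor_count": int(fd * 1000), "case_total_alleles": 1000,
                              "control_minor_count": 300, "control_total_alleles": 1000})
            rep_rows.append({"snp_id": sid, "maf_case": fr, "maf_control": 0.3, "p": pr_,
                             "case_minor_count": int(fr * 1000), "case_total_alleles": 1000,
                             "control_minor_count": 300, "control_total_alleles": 1000})
            cand.append({"snp_id": sid, "pathways": "P", "p_discovery": pd_})
        out = validate_snps(pd.DataFrame(cand), pd.DataFrame(disc_rows),
                            pd.DataFrame(rep_rows)).records
        for _, row in out.iterrows():
            if row["validated"]:
                assert row["p_discovery"] < 0.05 and row["p_replication"] < 0.05
                assert row["direction_consistent"]

    def test_absent_replication_snp_reported_unvalidated(self):
        cands, disc, rep = self._tables()
        out = validate_snps(cands, disc, rep.iloc[:1]).records.set_index("snp_id")
        assert not bool(out.loc["rsB", "validated"])
        assert np.isnan(out.loc["rsB", "p_replication"])

    def test_published_validated_snp_table_dedup(self):
        snps = load_validated_snps()
        sign_d = np.sign(snps["maf_case_discovery"] - snps["maf_control_discovery"])
        sign_r = np.sign(snps["maf_case_replication"] - snps["maf_control_replication"])
        ok = (snps["p_discovery"] < 0.05) & (snps["p_replication"] < 0.05) & (sign_d == sign_r)
        assert ok.all()  # every published row satisfies the validation rule
        assert snps.loc[ok, "snp_id"].nunique() == 17
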