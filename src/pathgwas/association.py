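"""Quality control, allelic association scan and phenotype permutations.

The association statistic throughout is the allelic 1-d.f. test: a Pearson
chi-square (no continuity correction) on the 2x2 table of minor/major
allele counts in cases versus controls.  Missing genotypes simply drop out
of a SNP's allele counts.

The permutation engine shuffles case/control labels while preserving the
observed case and control totals; per-permutation chi-square statistics for
every SNP are computed in one matrix product, which is what makes the
permutation-based enrichment methods tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MISSING, GenotypeStudy, PipelineConfig

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1DF_MEDIAN = float(stats.chi2.median(1))  # 0.45493642...


@dataclass
class QcReport:
    """Tally of SNPs/samples removed by each filter, in application order."""

    samples_removed_callrate: int = 0
    snps_removed_maf: int = 0
    snps_removed_callrate: int = 0
    snps_removed_hwe: int = 0
    snps_retained: int = 0

    @property
    def snps_removed(self) -> int:
        return self.snps_removed_maf + self.snps_removed_callrate + self.snps_removed_hwe

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PermutationEnsemble:
    """n phenotype relabelings preserving the case/control split.

    ``labels`` is an (n_permutations x n_samples) boolean matrix, True where
    the sample is a case under that permutation.  Each permutation's row is
    drawn from an independent counter-derived substream of the master seed,
    so the ensemble is reproducible permutation by permutation.
    """

    labels: np.ndarray
    seed: int

    @property
    def n_permutations(self) -> int:
        return self.labels.shape[0]


def permute_phenotypes(study: GenotypeStudy, n: int, seed: int) -> PermutationEnsemble:
    """Draw ``n`` label permutations of the study's case/control status."""
    if n < 1:
        raise ValueError("need at least one permutation")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n)
    n_cases = study.n_cases
    labels = np.zeros((n, study.n_samples), dtype=bool)
    for i, child in enumerate(streams):
        rng = np.random.default_rng(child)
        idx = rng.permutation(study.n_samples)[:n_cases]
        labels[i, idx] = True
    return PermutationEnsemble(labels=labels, seed=seed)


# ---------------------------------------------------------------------------
# single-table tests
# ---------------------------------------------------------------------------

def _pearson_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square of the 2x2 table [[a, b], [c, d]], no correction."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def allelic_test(
    case_minor: int, case_major: int, control_minor: int, control_major: int
) -> tuple[float, float]:
    """Allelic 1-d.f. chi-square and two-sided p for one SNP's allele counts.

    Returns (chi2, p).  A table with a zero marginal (monomorphic in both
    groups, or an empty group) yields chi2 = 0, p = 1 by convention.
    """
    if case_minor + case_major <= 0 or control_minor + control_major <= 0:
        raise ValueError("each group needs a positive allele total")
    chi2 = _pearson_2x2(case_minor, case_major, control_minor, control_major)
    p = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return chi2, p


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value from genotype counts.

    1-d.f. Pearson chi-square of the observed genotype counts against the
    HWE expectations p^2, 2pq, q^2 computed from the observed allele
    frequency.  Monomorphic input returns p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    p_allele = (2 * n_AA + n_Aa) / (2 * n)
    if p_allele in (0.0, 1.0):
        return 1.0
    q = 1 - p_allele
    expected = np.array([n * p_allele**2, 2 * n * p_allele * q, n * q**2])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def apply_qc(study: GenotypeStudy, config: PipelineConfig) -> tuple[GenotypeStudy, QcReport]:
    """Sample call-rate filter, then per-SNP MAF / call-rate / HWE filters.

    Each SNP is tallied once, at the first filter it fails, in the order
    MAF -> call rate -> control HWE.  SNP statistics are computed after
    low-call-rate samples are dropped.
    """
    report = QcReport()
    G = study.genotypes
    called = G != MISSING

    sample_ok = called.mean(axis=1) >= config.call_rate_min
    report.samples_removed_callrate = int((~sample_ok).sum())
    if not sample_ok.all():
        study = study.subset(sample_mask=sample_ok)
        G = study.genotypes
        called = G != MISSING

    n_samples = study.n_samples
    minor = np.where(called, G, 0)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = minor.sum(axis=0) / (2 * n_called)
    maf = np.where(n_called > 0, maf, 0.0)
    maf = np.minimum(maf, 1 - maf)  # frequency of the rarer allele

    fail_maf = (maf < config.maf_min) | (n_called == 0)
    fail_call = n_called / n_samples < config.call_rate_min

    controls = ~study.is_case
    Gc = G[controls]
    called_c = Gc != MISSING
    hwe_p = np.ones(study.n_snps)
    for j in range(study.n_snps):
        if fail_maf[j] or fail_call[j]:
            continue  # earlier filter already claims this SNP
        g = Gc[called_c[:, j], j]
        if g.size:
            hwe_p[j] = hwe_test(int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum()))
    fail_hwe = hwe_p < config.hwe_p_min

    report.snps_removed_maf = int(fail_maf.sum())
    report.snps_removed_callrate = int((fail_call & ~fail_maf).sum())
    report.snps_removed_hwe = int((fail_hwe & ~fail_maf & ~fail_call).sum())
    keep = ~(fail_maf | fail_call | fail_hwe)
    report.snps_retained = int(keep.sum())
    if report.snps_retained == 0:
        raise ValueError("empty study after QC")
    return study.subset(snp_mask=keep), report


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

def _allele_counts(study: GenotypeStudy, case_labels: np.ndarray) -> tuple[np.ndarray, ...]:
    """Minor counts and allele totals per SNP for arbitrary label matrices.

    ``case_labels``: (n_label_sets x n_samples) boolean.  Returns four
    (n_label_sets x n_snps) arrays: case minor, case total, control minor,
    control total (totals are 2 x called genotypes).
    """
    G = study.genotypes
    called = (G != MISSING).astype(np.float64)
    minor = np.where(G == MISSING, 0, G).astype(np.float64)
    L = case_labels.astype(np.float64)
    case_minor = L @ minor
    case_total = 2.0 * (L @ called)
    all_minor = minor.sum(axis=0)
    all_total = 2.0 * called.sum(axis=0)
    return case_minor, case_total, all_minor - case_minor, all_total - case_total


def _chi2_from_counts(
    case_minor: np.ndarray, case_total: np.ndarray,
    control_minor: np.ndarray, control_total: np.ndarray,
) -> np.ndarray:
    """Vectorised allelic chi-square from allele counts (zero-safe)."""
    a, c = case_minor, control_minor
    b, d = case_total - case_minor, control_total - control_minor
    n = case_total + control_total
    denom = case_total * control_total * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    return np.where(denom > 0, chi2, 0.0)


def association_scan(study: GenotypeStudy) -> pd.DataFrame:
    """Allelic 1-d.f. test for every SNP against the observed phenotype.

    Returns an association table with one row per SNP: allele counts,
    group MAFs, chi2, p and the sign of (case MAF - control MAF).
    """
    labels = study.is_case[None, :]
    a, at, c, ct = (x[0] for x in _allele_counts(study, labels))
    chi2 = _chi2_from_counts(a, at, c, ct)
    p = np.where(chi2 > 0, stats.chi2.sf(chi2, 1), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf_case = np.where(at > 0, a / at, np.nan)
        maf_control = np.where(ct > 0, c / ct, np.nan)
    return pd.DataFrame(
        {
            "snp_id": study.snp_ids,
            "case_minor_count": a.astype(int),
            "case_total_alleles": at.astype(int),
            "control_minor_count": c.astype(int),
            "control_total_alleles": ct.astype(int),
            "maf_case": maf_case,
            "maf_control": maf_control,
            "chi2": chi2,
            "p": p,
            "direction": np.sign(np.nan_to_num(maf_case - maf_control)).astype(int),
        }
    )


def permutation_chi2(study: GenotypeStudy, ensemble: PermutationEnsemble) -> np.ndarray:
    """(n_permutations x n_snps) allelic chi-square under each relabeling."""
    a, at, c, ct = _allele_counts(study, ensemble.labels)
    return _chi2_from_counts(a, at, c, ct)


def chi2_to_p(chi2: np.ndarray) -> np.ndarray:
    """Two-sided p for 1-d.f. chi-square values (chi2 = 0 -> p = 1)."""
    return np.where(np.asarray(chi2) > 0, stats.chi2.sf(chi2, 1), 1.0)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def genomic_inflation(chi2_values: np.ndarray) -> float:
    """Genomic-control inflation factor: median chi2 / null 1-d.f. median."""
    chi2_values = np.asarray(chi2_values, dtype=float)
    if chi2_values.size == 0:
        raise ValueError("no chi-square values")
    return float(np.median(chi2_values) / CHI2_1DF_MEDIAN)


def qq_data(p_values: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p pairs for a Q-Q plot.

    Observed p's are sorted ascending and paired with uniform quantiles
    i/(n+1).
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    expected = np.arange(1, p.size + 1) / (p.size + 1)
    return pd.DataFrame(
        {"expected_neglog10_p": -np.log10(expected), "observed_neglog10_p": -np.log10(p)}
    )


def ld_r2(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> float:
    """Composite-genotype LD: squared Pearson correlation of allele counts.

    Computed over samples non-missing at both SNPs.  This phase-free
    estimator is a deterministic approximation to haplotype-based r2,
    adequate for reporting strong LD (r2 > 0.7).
    """
    a = np.asarray(genotypes_a, dtype=float)
    b = np.asarray(genotypes_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("fewer than 2 complete genotype pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("undefined r2: monomorphic SNP")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.corrcoef(a, b)[0, 1]
    return float(r**2)
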