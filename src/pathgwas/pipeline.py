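"""End-to-end orchestration: QC -> scan -> map -> three enrichment engines
-> consensus -> two-cohort validation, with a reproducibility manifest.

One permutation ensemble drives both Gen-Gen and the SNP Ratio Test, and
the expensive per-permutation association scan is computed exactly once
and shared; Aligator's null is SNP sampling, not permutation, and draws
from its own seeded substream.  All orderings are explicit sorts, so a
fixed seed reproduces results bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aligator import AligatorCorrection, aligator_correction, aligator_scan
from .association import (
    association_scan,
    genomic_inflation,
    permutation_chi2,
    permute_phenotypes,
    apply_qc,
    QcReport,
)
from .consensus import (
    consensus_pathways,
    select_candidate_snps,
    validate_snps,
    ValidationSummary,
)
from .gengen import gengen_scan
from .io import filter_gene_sets, read_config
from .mapping import build_pathway_index, map_snps_to_genes
from .model import GeneRecord, GeneSetCollection, GenotypeStudy, PipelineConfig
from .srt import srt_scan

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Funnel counts and provenance of one pipeline run."""

    seed: int
    config: dict
    version: str = __version__
    input_digests: dict = field(default_factory=dict)
    samples_in: int = 0
    snps_in: int = 0
    snps_after_qc: int = 0
    genes_mapped: int = 0
    pathways_in: int = 0
    pathways_after_size_filter: int = 0
    pathways_tested: int = 0
    inflation_factor: float = float("nan")
    consensus_count: int = 0
    candidate_snps: int = 0
    validated_snps: int = 0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


@dataclass
class CohortAnalysis:
    """All per-cohort results of the enrichment stage."""

    study: GenotypeStudy
    qc: QcReport
    assoc: pd.DataFrame
    gengen: pd.DataFrame
    aligator: pd.DataFrame
    srt: pd.DataFrame
    consensus: pd.DataFrame
    index: "object"
    inflation: float
    aligator_correction: AligatorCorrection | None = None


@dataclass
class PipelineResult:
    discovery: CohortAnalysis
    candidates: pd.DataFrame
    validation: ValidationSummary | None
    manifest: RunManifest


def analyze_cohort(
    study: GenotypeStudy,
    genes: list[GeneRecord],
    collection: GeneSetCollection,
    config: PipelineConfig,
    run_correction: bool = False,
) -> CohortAnalysis:
    """QC, association scan and the three enrichment methods on one cohort."""
    study, qc = apply_qc(study, config)
    logger.info("QC: %d SNPs retained (%s)", qc.snps_retained, qc.to_dict())
    assoc = association_scan(study)
    inflation = genomic_inflation(assoc["chi2"].to_numpy())

    sized = filter_gene_sets(collection, config.min_set_genes, config.max_set_genes)
    snp_gene_map = map_snps_to_genes(study.snps, genes, config.flank_bp)
    index = build_pathway_index(snp_gene_map, sized)

    ensemble = permute_phenotypes(study, config.n_permutations, config.rng_seed)
    perm_chi2 = permutation_chi2(study, ensemble)
    observed_chi2 = assoc["chi2"].to_numpy()

    gengen = gengen_scan(
        study, snp_gene_map, sized, ensemble, config.gengen_weight,
        observed_chi2=observed_chi2, permuted_chi2=perm_chi2,
    )
    ali_rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(1)[0])
    ali = aligator_scan(
        assoc, snp_gene_map, index, config.aligator_snp_p,
        config.aligator_replicates, ali_rng,
    )
    correction = None
    if run_correction:
        correction = aligator_correction(
            ali, config.aligator_correction_reps, config.pathway_sig_p, ali_rng
        )
    srt = srt_scan(
        study, index, ensemble, config.srt_snp_p,
        observed_p=assoc["p"].to_numpy(), permuted_chi2=perm_chi2,
    )
    consensus = consensus_pathways(gengen, ali.table, srt, config.pathway_sig_p)
    return CohortAnalysis(
        study=study, qc=qc, assoc=assoc, gengen=gengen, aligator=ali.table,
        srt=srt, consensus=consensus, index=index, inflation=inflation,
        aligator_correction=correction,
    )


def run_pipeline(
    study: GenotypeStudy,
    genes: list[GeneRecord],
    collection: GeneSetCollection,
    config: PipelineConfig,
    replication: GenotypeStudy | None = None,
    top_only: bool = False,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Full discovery analysis plus optional replication-cohort validation.

    With ``out_dir`` set, result TSVs and the JSON manifest are written
    there (created if needed).
    """
    manifest = RunManifest(
        seed=config.rng_seed,
        config={k: getattr(config, k) for k in PipelineConfig.__dataclass_fields__},
        samples_in=study.n_samples,
        snps_in=study.n_snps,
        pathways_in=len(collection),
    )
    disc = analyze_cohort(study, genes, collection, config)
    manifest.snps_after_qc = disc.qc.snps_retained
    manifest.genes_mapped = sum(1 for e in disc.index.usable for _ in [0])
    manifest.genes_mapped = len({g for e in disc.index.usable for g in e.genes})
    manifest.pathways_after_size_filter = len(
        filter_gene_sets(collection, config.min_set_genes, config.max_set_genes)
    )
    manifest.pathways_tested = len(disc.gengen)
    manifest.inflation_factor = disc.inflation
    manifest.consensus_count = len(disc.consensus)

    candidates = select_candidate_snps(
        disc.consensus, disc.index, disc.assoc, config.pathway_sig_p, top_only
    )
    manifest.candidate_snps = len(candidates)

    validation = None
    if replication is not None and len(candidates):
        rep_assoc = association_scan(replication)
        validation = validate_snps(candidates, disc.assoc, rep_assoc, config.validation_p)
        manifest.validated_snps = validation.n_validated

    result = PipelineResult(
        discovery=disc, candidates=candidates, validation=validation, manifest=manifest
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    from .io import write_results

    out_dir.mkdir(parents=True, exist_ok=True)
    disc = result.discovery
    write_results(disc.assoc, out_dir / "association.tsv")
    write_results(disc.gengen, out_dir / "gengen.tsv")
    write_results(disc.aligator, out_dir / "aligator.tsv")
    write_results(disc.srt, out_dir / "srt.tsv")
    write_results(disc.consensus, out_dir / "consensus.tsv")
    if len(result.candidates):
        write_results(result.candidates, out_dir / "candidates.tsv")
    if result.validation is not None:
        write_results(result.validation.records, out_dir / "validation.tsv")
    (out_dir / "qc_report.json").write_text(json.dumps(disc.qc.to_dict(), indent=2))
    (out_dir / "manifest.json").write_text(result.manifest.to_json())


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for manifest provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# worked examples on the bundled published tables
# ---------------------------------------------------------------------------

def run_worked_examples() -> dict:
    """Recompute the checkable numbers from the bundled summary tables.

    Returns a machine-readable report; each entry carries the computed
    value, the published value and a pass flag.  The consensus-count check
    is expected to disagree with the published total of 18 because one
    published row (BIOCARTA_NDKDYNAMIN_PATHWAY, SRT p = 0.08991) fails the
    stated all-three-methods p < 0.05 rule; see docs/methods.md.
    """
    from .consensus import overlap_genes
    from .datasets import (
        load_pathway_pvalues,
        load_significant_pathway_sets,
        load_validated_snps,
    )
    from .srt import srt_empirical_p

    report: dict[str, dict] = {}

    def check(name: str, value, published, ok=None) -> None:
        report[name] = {
            "computed": value,
            "published": published,
            "pass": bool(value == published) if ok is None else bool(ok),
        }

    check("srt_p_s0_n1000", round(srt_empirical_p(0, 1000), 6), 0.000999)
    check("srt_p_s1_n1000", round(srt_empirical_p(1, 1000), 6), 0.001998)

    sets = load_significant_pathway_sets()
    cc = overlap_genes(sets["BIOCARTA_RACCYCD_PATHWAY"], sets["BIOCARTA_SKP2E2F_PATHWAY"])
    check("cell_cycle_overlap_genes", len(cc), 5)
    gf = overlap_genes(
        sets["REACTOME_SIGNALING_BY_PDGF"],
        sets["REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH"],
    )
    check("growth_factor_overlap_genes", len(gf), 31)
    check("ncam_set_size", len(sets["REACTOME_NCAM_SIGNALING_FOR_NEURITE_OUT_GROWTH"]), 69)
    check("pdgf_set_size", len(sets["REACTOME_SIGNALING_BY_PDGF"]), 64)

    table = load_pathway_pvalues()
    cons = consensus_pathways(
        table[["pathway", "p_gengen"]],
        table[["pathway", "p_aligator"]],
        table[["pathway", "p_srt"]],
        alpha=0.05,
    )
    check("consensus_pathways", len(cons), 18)
    check("top_pathways", int(cons["top_flag"].sum()), 5)

    snps = load_validated_snps()
    validated = snps[
        (snps["p_discovery"] < 0.05)
        & (snps["p_replication"] < 0.05)
        & (
            np.sign(snps["maf_case_discovery"] - snps["maf_control_discovery"])
            == np.sign(snps["maf_case_replication"] - snps["maf_control_replication"])
        )
    ]
    check("validated_distinct_snps", validated["snp_id"].nunique(), 17)
    return report


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Thin re-export so callers can stay within this module."""
    return read_config(path)
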