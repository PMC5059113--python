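"""Readers and writers for the plain-text formats the pipeline consumes.

Supported formats
-----------------
* Genotype TSV (sample-major): header ``sample_id<TAB>phenotype<TAB><snp ids...>``,
  one row per sample, genotype cells in {0, 1, 2, NA}.  SNP metadata
  (chromosome, position, alleles) travels in an optional sidecar file
  ``<stem>.snps.tsv``; without it placeholder metadata is synthesized.
* PLINK text pedigrees (.ped/.map pair).  Minor/major alleles are assigned
  from control-group frequencies at load time.
* GMT gene sets (set name, description, member symbols; tab-separated).
* BED-like gene annotation TSV (symbol, chromosome, start, end) using
  1-based fully closed coordinates.
* Results TSVs for pathway enrichment and SNP validation tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    MISSING,
    GeneRecord,
    GeneSet,
    GeneSetCollection,
    GenotypeStudy,
    PipelineConfig,
    SnpRecord,
)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

_GENO_CODES = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "": MISSING, ".": MISSING}


def _snp_sidecar(path: Path) -> Path:
    return path.with_suffix(".snps.tsv") if path.suffix != ".snps" else path


def read_genotypes(path: str | Path, dialect: str = "tsv") -> GenotypeStudy:
    """Read a genotype study from ``tsv`` or ``plink_text`` files.

    For ``plink_text`` pass the path of either the .ped or the .map file.
    """
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "plink_text":
        return _read_plink_text(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path) -> GenotypeStudy:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "phenotype":
            raise ParseError(f"{path}:1: expected header 'sample_id<TAB>phenotype<TAB>snp ids...'")
        snp_ids = header[2:]
        if len(set(snp_ids)) != len(snp_ids):
            raise ParseError(f"{path}:1: duplicate SNP ids in header")
        samples, phenos, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, found {len(parts)}"
                )
            samples.append(parts[0])
            if parts[1] not in ("0", "1"):
                raise ParseError(f"{path}:{lineno}: phenotype must be 0 or 1, got {parts[1]!r}")
            phenos.append(int(parts[1]))
            try:
                rows.append([_GENO_CODES[c] for c in parts[2:]])
            except KeyError as exc:
                raise ParseError(
                    f"{path}:{lineno}: invalid genotype code {exc.args[0]!r} "
                    "(expected 0, 1, 2 or NA)"
                ) from None
    snps = _read_snp_sidecar(_snp_sidecar(path), snp_ids)
    return GenotypeStudy(snps, samples, phenos, np.array(rows, dtype=np.int8))


def _read_snp_sidecar(path: Path, snp_ids: list[str]) -> list[SnpRecord]:
    if not path.exists():
        # placeholder metadata: one synthetic chromosome, positions by column
        return [SnpRecord(sid, "1", i + 1, "A", "B") for i, sid in enumerate(snp_ids)]
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"snp_id", "chromosome", "position", "minor_allele", "major_allele"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: sidecar must have columns {sorted(required)}")
    by_id = {
        r.snp_id: SnpRecord(r.snp_id, r.chromosome, int(r.position), r.minor_allele, r.major_allele)
        for r in df.itertuples()
    }
    missing = [sid for sid in snp_ids if sid not in by_id]
    if missing:
        raise ParseError(f"{path}: sidecar lacks metadata for SNPs {missing[:5]}")
    return [by_id[sid] for sid in snp_ids]


def write_genotypes(study: GenotypeStudy, path: str | Path) -> None:
    """Write a study as genotype TSV plus its SNP-metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\tphenotype\t" + "\t".join(study.snp_ids) + "\n")
        for i, sample in enumerate(study.samples):
            cells = ["NA" if g == MISSING else str(g) for g in study.genotypes[i]]
            fh.write(f"{sample}\t{study.phenotype[i]}\t" + "\t".join(cells) + "\n")
    meta = pd.DataFrame(
        {
            "snp_id": study.snp_ids,
            "chromosome": [s.chromosome for s in study.snps],
            "position": [s.position for s in study.snps],
            "minor_allele": [s.minor_allele for s in study.snps],
            "major_allele": [s.major_allele for s in study.snps],
        }
    )
    meta.to_csv(_snp_sidecar(path), sep="\t", index=False)


def _read_plink_text(path: Path) -> GenotypeStudy:
    """Read a .ped/.map pair; minor allele assigned on control frequency."""
    stem = path.with_suffix("")
    ped, map_ = stem.with_suffix(".ped"), stem.with_suffix(".map")
    for f in (ped, map_):
        if not f.exists():
            raise ParseError(f"missing PLINK text file {f}")
    snp_meta = []
    with open(map_) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_}:{lineno}: expected 4 columns (chrom, id, cM, bp)")
            snp_meta.append((parts[0], parts[1], int(parts[3])))
    n_snps = len(snp_meta)

    samples, phenos, allele_rows = [], [], []
    with open(ped) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped}:{lineno}: expected {6 + 2 * n_snps} fields, found {len(parts)}"
                )
            samples.append(parts[1])
            if parts[5] not in ("1", "2"):
                raise ParseError(f"{ped}:{lineno}: phenotype must be 1 (control) or 2 (case)")
            phenos.append(int(parts[5]) - 1)
            allele_rows.append(parts[6:])

    alleles = np.array(allele_rows).reshape(len(samples), n_snps, 2)
    controls = np.array(phenos) == 0
    snps, geno_cols = [], []
    for j, (chrom, sid, pos) in enumerate(snp_meta):
        col = alleles[:, j, :]
        observed = sorted({a for a in col.ravel() if a != "0"})
        if len(observed) > 2:
            raise ParseError(f"{ped}: SNP {sid} has >2 alleles: {observed}")
        if len(observed) == 0:
            observed = ["A", "B"]  # fully missing column
        if len(observed) == 1:
            observed = observed + ["A" if observed[0] != "A" else "B"]
        # control-frequency minor assignment; ties broken alphabetically
        ctl = col[controls]
        counts = {a: int((ctl == a).sum()) for a in observed}
        minor = min(observed, key=lambda a: (counts[a], a))
        major = observed[1] if observed[0] == minor else observed[0]
        missing_pair = (col == "0").any(axis=1)
        g = (col == minor).sum(axis=1).astype(np.int8)
        g[missing_pair] = MISSING
        geno_cols.append(g)
        snps.append(SnpRecord(sid, chrom, pos, minor, major))
    return GenotypeStudy(snps, samples, phenos, np.column_stack(geno_cols))


# ---------------------------------------------------------------------------
# gene sets / annotation
# ---------------------------------------------------------------------------

_SOURCE_PREFIXES = {"KEGG": "KEGG", "BIOCARTA": "Biocarta", "REACTOME": "Reactome"}


def _infer_source(name: str) -> str:
    for prefix, source in _SOURCE_PREFIXES.items():
        if name.upper().startswith(prefix):
            return source
    return "other"


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB genes...``.

    Duplicate gene symbols within a line are collapsed; duplicate set names
    are an error.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name, genes, _infer_source(name)))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write(s.name + "\t" + s.source + "\t" + "\t".join(sorted(s.genes)) + "\n")


def filter_gene_sets(
    collection: GeneSetCollection, min_set_genes: int = 10, max_set_genes: int = 100
) -> GeneSetCollection:
    """Keep sets whose size lies in [min_set_genes, max_set_genes], inclusive.

    Size is counted on the raw symbol membership, before any SNP mapping;
    order is preserved and the operation is idempotent.
    """
    if min_set_genes > max_set_genes:
        raise ValueError("min_set_genes > max_set_genes")
    return GeneSetCollection(
        [s for s in collection if min_set_genes <= len(s.genes) <= max_set_genes]
    )


def read_gene_annotation(path: str | Path) -> list[GeneRecord]:
    """Read a gene annotation TSV (symbol, chromosome, start, end).

    Coordinates are 1-based and fully closed.  A header line starting with
    'symbol' is skipped.
    """
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if lineno == 1 and parts[0].lower() == "symbol":
                continue
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected symbol, chromosome, start, end")
            symbol = parts[0].strip().upper()
            if symbol in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene symbol {symbol}")
            seen.add(symbol)
            try:
                rec = GeneRecord(symbol, parts[1], int(parts[2]), int(parts[3]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


def write_gene_annotation(genes: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\tchromosome\tstart\tend\n")
        for g in genes:
            fh.write(f"{g.symbol}\t{g.chromosome}\t{g.start}\t{g.end}\n")


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

PATHWAY_RESULT_COLUMNS = [
    "pathway", "p_gengen", "rank_gengen", "p_aligator", "rank_aligator",
    "p_srt", "rank_srt",
]

VALIDATION_COLUMNS = [
    "snp_id", "gene", "pathways",
    "maf_case_discovery", "maf_control_discovery", "p_discovery",
    "maf_case_replication", "maf_control_replication", "p_replication",
    "direction_consistent", "validated",
    "maf_case_pooled", "maf_control_pooled", "p_meta",
]


def write_results(results: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> None:
    """Write a results table as TSV with a stable column order.

    ``columns`` defaults to the frame's own order; floats keep 6 significant
    digits so write/read round-trips preserve values at reporting precision.
    """
    df = results if columns is None else results.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from YAML or JSON; unknown keys are an error."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    raw = raw or {}
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    data = {k: getattr(config, k) for k in PipelineConfig.__dataclass_fields__}
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh)
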