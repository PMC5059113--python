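"""SNP-to-gene assignment and pathway SNP indexing.

A SNP is assigned to every gene whose body, extended by a symmetric
flanking window (default +/-20 kb, both boundaries inclusive), contains the
SNP's position on the same chromosome.  Strand is ignored: the window
extends in both directions regardless of gene orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .model import GeneRecord, GeneSetCollection, SnpRecord

logger = logging.getLogger(__name__)


@dataclass
class SnpGeneMap:
    """Mutually inverse gene->SNPs and SNP->genes mappings."""

    gene_to_snps: dict[str, list[str]] = field(default_factory=dict)
    snp_to_genes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.gene_to_snps)

    @property
    def n_mapped_snps(self) -> int:
        return len(self.snp_to_genes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"snp_id": s, "gene": g}
            for g, snps in self.gene_to_snps.items()
            for s in snps
        ]
        return pd.DataFrame(rows, columns=["snp_id", "gene"])


@dataclass
class PathwayEntry:
    """One pathway's mapped content: member genes with SNPs, distinct SNPs."""

    name: str
    genes: list[str]
    snp_ids: list[str]
    flagged: bool = False  # True when no member gene has a mapped SNP

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class PathwaySnpIndex:
    """Per-pathway mapped genes and distinct SNP lists."""

    entries: dict[str, PathwayEntry] = field(default_factory=dict)

    def __getitem__(self, name: str) -> PathwayEntry:
        return self.entries[name]

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def usable(self) -> list[PathwayEntry]:
        """Entries with at least one mapped SNP (flagged ones excluded)."""
        return [e for e in self.entries.values() if not e.flagged]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"pathway": e.name, "n_genes": e.n_genes, "n_snps": e.n_snps,
                 "flagged": e.flagged}
                for e in self.entries.values()
            ]
        )


def map_snps_to_genes(
    snps: list[SnpRecord], genes: list[GeneRecord], flank_bp: int = 20_000
) -> SnpGeneMap:
    """Assign each SNP to all genes within the flanked gene interval.

    Closed-interval rule: SNP s maps to gene g iff they share a chromosome
    and g.start - flank_bp <= s.position <= g.end + flank_bp.  A SNP may map
    to several overlapping genes.  Orders are preserved: gene lists follow
    annotation order, SNP lists follow study order.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    # bucket by chromosome, then sweep sorted intervals per chromosome
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append((g.start - flank_bp, g.end + flank_bp, g.symbol))
    for intervals in by_chrom.values():
        intervals.sort()

    gene_to_snps: dict[str, list[str]] = {}
    snp_to_genes: dict[str, list[str]] = {}
    import bisect

    for snp in snps:
        intervals = by_chrom.get(snp.chromosome, [])
        hits = []
        # intervals overlap at most a few genes; linear scan from first
        # candidate keeps this near O(log n) per SNP for sparse layouts
        i = bisect.bisect_right(intervals, (snp.position, float("inf"), ""))
        for lo, hi, sym in intervals[:i][::-1]:
            if hi >= snp.position:
                hits.append(sym)
            elif snp.position - lo > _max_span(intervals):
                break
        for sym in sorted(hits):
            gene_to_snps.setdefault(sym, []).append(snp.snp_id)
            snp_to_genes.setdefault(snp.snp_id, []).append(sym)
    # restore annotation order for gene keys
    ordered = {g.symbol: gene_to_snps[g.symbol] for g in genes if g.symbol in gene_to_snps}
    return SnpGeneMap(gene_to_snps=ordered, snp_to_genes=snp_to_genes)


def _max_span(intervals: list[tuple[int, int, str]]) -> int:
    # cached on the list object to avoid recomputation per SNP
    span = getattr(intervals, "_span", None)
    if span is None:
        span = max((hi - lo for lo, hi, _ in intervals), default=0)
        try:
            intervals._span = span  # type: ignore[attr-defined]
        except AttributeError:
            pass
    return span


def build_pathway_index(
    snp_gene_map: SnpGeneMap, collection: GeneSetCollection
) -> PathwaySnpIndex:
    """Restrict each pathway to genes with mapped SNPs; count distinct SNPs.

    A SNP shared by two member genes is counted once.  Pathways with no
    mapped gene are retained but flagged (downstream methods skip them).
    Gene symbols are matched after uppercasing both sides; unmatched
    pathway genes are dropped from the index and logged.
    """
    index = PathwaySnpIndex()
    for gene_set in collection:
        members = sorted(g.upper() for g in gene_set.genes)
        mapped = [g for g in members if g in snp_gene_map.gene_to_snps]
        dropped = len(members) - len(mapped)
        if dropped:
            logger.debug("pathway %s: %d genes without mapped SNPs", gene_set.name, dropped)
        seen: set[str] = set()
        snp_ids: list[str] = []
        for g in mapped:
            for s in snp_gene_map.gene_to_snps[g]:
                if s not in seen:
                    seen.add(s)
                    snp_ids.append(s)
        index.entries[gene_set.name] = PathwayEntry(
            name=gene_set.name, genes=mapped, snp_ids=snp_ids, flagged=not mapped
        )
    return index
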