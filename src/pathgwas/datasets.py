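"""Bundled worked-example tables from a published bladder-cancer GWAS
pathway analysis (969 cases / 957 controls discovery cohort, independent
replication cohort of 3,532 cases / 5,120 controls).

Three small text files ship with the package:

* ``pathway_pvalues.tsv`` — the 18 pathways reported significant, with the
  published Gen-Gen / Aligator / SNP Ratio Test p-values and ranks.
  p-values published only as a bound ("<0.001") are kept as strings; the
  loader converts them to a float just below the bound so threshold
  comparisons (p < 0.05, p <= 0.001) behave as the bound implies.
* ``significant_pathways.gmt`` — gene membership of the five top pathways.
* ``validated_snps.tsv`` — the validated-SNP table: per-cohort minor
  allele frequencies and allelic-test p-values plus the pooled analysis,
  one row per SNP-pathway pair (SNPs shared by two pathways appear twice).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_gene_sets
from .model import GeneSetCollection

_P_COLUMNS = ["p_gengen", "p_aligator", "p_srt"]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pathgwas").joinpath("data", name)))


def parse_p_label(value: str | float) -> float:
    """Convert a printed p-value, possibly a bound like '<0.001', to float.

    A bound maps to the largest float strictly below it, so strict
    comparisons against thresholds at or above the bound hold.
    """
    if isinstance(value, str) and value.startswith("<"):
        return float(np.nextafter(float(value[1:]), 0.0))
    return float(value)


def load_pathway_pvalues() -> pd.DataFrame:
    """The published per-pathway p/rank table for the three methods."""
    df = pd.read_csv(_data_path("pathway_pvalues.tsv"), sep="\t", dtype={c: str for c in _P_COLUMNS})
    for c in _P_COLUMNS:
        df[c] = df[c].map(parse_p_label)
    return df


def load_significant_pathway_sets() -> GeneSetCollection:
    """Gene membership of the five top pathways."""
    return read_gene_sets(_data_path("significant_pathways.gmt"))


def load_validated_snps() -> pd.DataFrame:
    """The published validated-SNP table (one row per SNP-pathway pair)."""
    return pd.read_csv(_data_path("validated_snps.tsv"), sep="\t")
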