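"""Three pathway-enrichment methods and consensus calling on one cohort.

Simulates a cohort with one enriched pathway (half its genes carry allelic
OR 1.8), then runs Gen-Gen (weighted KS running sum over per-gene max
chi-square, phenotype-permutation null), Aligator (significant-gene counts
against SNP-sampled replicate gene lists) and the SNP Ratio Test
(significant-SNP fraction, add-one permutation p).  A pathway significant
at p < 0.05 in all three methods is a consensus finding.
"""

from pathgwas import PipelineConfig, SimulationDesign, simulate_study
from pathgwas.pipeline import analyze_cohort

design = SimulationDesign(
    n_cases=600, n_controls=600, n_genes=300, n_pathways=15,
    pathway_size_range=(10, 20), snps_per_gene=(2, 4),
    effect_pathways=[("PATHWAY_007", 0.5, 1.8)], seed=2,
)
study, genes, pathways, truth = simulate_study(design)
config = PipelineConfig(n_permutations=200, aligator_replicates=2000, rng_seed=2)

result = analyze_cohort(study, genes, pathways, config)

print("per-method p for the planted pathway PATHWAY_007:")
for table, col in ((result.gengen, "p_gengen"), (result.aligator, "p_aligator"),
                   (result.srt, "p_srt")):
    row = table[table["pathway"] == "PATHWAY_007"].iloc[0]
    print(f"  {col:11s} = {row[col]:.4f}")

print("\nconsensus pathways (p < 0.05 in all three methods):")
print(result.consensus[["pathway", "p_gengen", "p_aligator", "p_srt", "top_flag"]]
      .to_string(index=False))
print("\na Gen-Gen p of 0.0000 means the observed enrichment score beat all "
      f"{config.n_permutations} permutations (reported as < 1/{config.n_permutations}).")
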