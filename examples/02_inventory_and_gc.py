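"""Gene inventory and codon-position GC analysis of a parsed cohort.

Builds the copy-number matrix, clade summaries, and the classic comparison
between the conserved psbB-psbT-psbN-psbH cluster and the non-conserved psb
genes (psbA, psbI, psbK, psbL), which differ strongly in GC content.
"""

from pathlib import Path
from tempfile import mkdtemp

from plastomics import (build_copy_matrix, clade_summaries,
                        compare_gene_groups, gene_gc_table, read_cohort)
from plastomics.panel import CONSERVED_PSB, NONCONSERVED_PSB
from plastomics.synth import CohortConfig, generate_cohort

outdir = Path(mkdtemp(prefix="plastome_cohort_"))
generate_cohort(CohortConfig(n_genomes=8, seed=7), outdir)
cohort = read_cohort(outdir, outdir / "taxonomy.tsv")

matrix = build_copy_matrix(cohort)
print(f"copy-number matrix: {matrix.shape[0]} genomes x "
      f"{matrix.shape[1]} genes; "
      f"ndhB copies per genome: {sorted(set(matrix['ndhB']))} "
      "(2 = duplicated in the inverted repeats)")

summary = clade_summaries(cohort)
print("\nper-clade genome sizes (kb) and mean distinct gene counts:")
print(summary[["major_clade", "n_genomes", "mean_size_kb",
               "mean_genes_distinct"]].to_string(index=False))

gc = gene_gc_table(cohort)
comp = compare_gene_groups(gc, CONSERVED_PSB, NONCONSERVED_PSB,
                           "conserved psb", "non-conserved psb")
print(f"\nGC123 of conserved psb cluster: {100 * comp.mean_a:.2f}% vs "
      f"non-conserved psb genes: {100 * comp.mean_b:.2f}% "
      f"(t = {comp.t:.1f}, p = {comp.p:.2e} {comp.stars})")
print("higher GC in the conserved cluster mirrors the pattern seen in "
      "real plastomes")
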