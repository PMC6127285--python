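"""Run the full diagnostic pipeline on the packaged 29-family cohort.

Screens each family's candidate variants (DP/FS QC, MAF < 0.015 across
population databases), evaluates splice-predictor scores, searches for a
second hit in the gene of the known monoallelic variant (falling back to
other loci), and prints the cohort summary.
"""

import secondhit as sh

cohort = sh.load_cohort_fixture()
results = sh.run_cohort(cohort)
summary = sh.summarize(results, cohort)

print(summary.to_text())
print()
for gene, row in summary.second_hit_rate.items():
    print(
        f"prior {gene} carriers: {row['carriers']}, "
        f"second hit found in the same gene: {row['solved_same_gene']}"
    )
# The yield line is the fraction of families receiving a molecular
# diagnosis; the per-gene lines show how often whole-gene sequencing
# actually delivered the missing second allele.
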