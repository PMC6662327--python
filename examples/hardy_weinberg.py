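"""Hardy-Weinberg genotype frequencies, one locus and many.

Random mating turns allele frequencies into genotype frequencies in a
single generation: p_i^2 homozygotes and 2 p_i p_j heterozygotes.
"""

from popgenlab import AlleleFrequencySet, hw_genotype_frequencies
from popgenlab.hwfreq import genotype_label, multilocus_distribution

alleles = AlleleFrequencySet((0.5, 0.3, 0.2))
table = hw_genotype_frequencies(alleles)
for pair in sorted(table):
    print(f"  {genotype_label(pair)}: {table[pair]:.3f}")
het = sum(v for (i, j), v in table.items() if i != j)
print(f"total heterozygosity: {het:.2f}")  # 1 - sum(p_i^2) = 0.62

counts, probs = multilocus_distribution([0.5] * 4)
print("total '+' count over 4 loci (Binomial(8, 0.5)):")
print("  " + ", ".join(f"{int(c)}: {p:.4f}" for c, p in zip(counts, probs)))
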