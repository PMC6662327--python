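"""Genetic drift: fixation probability, heterozygosity loss, bottlenecks.

A neutral allele fixes with probability equal to its initial frequency,
and drift erodes heterozygosity by a factor (1 - 1/2N) per generation -
dramatically so through a bottleneck.
"""

from popgenlab import FounderParams, WFParams, founder_event, wf_drift

out = wf_drift(WFParams(N=10, p0=0.3, ngen=200, nrep=2000, seed=42))
print(f"N=10, p0=0.3, 2000 replicates after 200 generations:")
print(f"  fraction fixed for A: {out.fraction_fixed:.3f}   (theory: 0.300)")
h10 = out.heterozygosity(10)
theory = 2 * 0.3 * 0.7 * (1 - 1 / 20) ** 10
print(f"  heterozygosity at t=10: {h10:.4f}   (theory: {theory:.4f})")

fp = FounderParams(N0=1000, Nf=2, start=1, duration=5, p0=0.5,
                   ngen=6, nrep=2000, seed=7)
fo = founder_event(fp)
print(f"bottleneck to Nf=2 for 5 generations:")
print(f"  heterozygosity after the bottleneck: {fo.heterozygosity(5):.4f} "
      f"(theory: {0.5 * 0.75**5:.4f})")
# five generations at two founders destroy ~76% of the variation
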