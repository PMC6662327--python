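"""Polygenic trait under truncation selection: R = h2 S, then range escape.

Ten additive loci at p=0.5 with unit effects and unit environmental noise.
Keeping the top half of phenotypes each generation gives a first-generation
response close to the breeder's equation; sustained selection fixes every
"+" allele, pushing the mean to the maximal genetic value of 20 - far
beyond the founding population's range.
"""

from popgenlab import PolygenicModel, normal_approximation, phenotype_selection_run

model = PolygenicModel(nloci=10, p=0.5, effect=1.0, env_sd=1.0)
mean, var = normal_approximation(model)
h2 = (var - model.env_sd**2) / var
print(f"model: mean {mean}, variance {var}, heritability h2 = {h2:.3f}")

run = phenotype_selection_run(model, n=2000, keep_fraction=0.5, ngen=1, seed=1)
S = run.selection_differential[0]
R = run.mean_phenotype[1] - run.mean_phenotype[0]
print(f"one generation, keep top 50%: S = {S:.3f}, response R = {R:.3f}, "
      f"h2*S = {h2 * S:.3f}")

long = phenotype_selection_run(model, n=1000, keep_fraction=0.2, ngen=150, seed=2)
print(f"150 generations, keep top 20%: mean phenotype "
      f"{long.mean_phenotype[0]:.2f} -> {long.mean_phenotype[-1]:.2f}")
print(f"  final '+' allele frequencies: {long.allele_freqs[-1]}")
# all loci fixed: the ceiling 2 * nloci * effect = 20 is reached without mutation
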