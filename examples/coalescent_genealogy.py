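"""Forward-time Wright-Fisher genealogy: coalescence of sampled gene copies.

Tracing a sample back through the pedigree, lineages merge at rate ~1/n per
pair per generation, so two copies find their common ancestor after about
n generations on average.  The genealogy exports to Newick.
"""

import numpy as np

from popgenlab import (
    genealogy_to_newick,
    mrca_generation,
    simulate_genealogy,
    trace_lineages,
)

G = simulate_genealogy(n=10, ngen=100, seed=5)
trace = trace_lineages(G, sample=range(10))
print(f"n=10 copies, 100 generations; sample = entire final generation")
print(f"  distinct lineages going back: {[int(c) for c in trace.lineage_count[:8]]} ...")
mrca = mrca_generation(G, range(10))
print(f"  MRCA generation: {mrca} (TMRCA = {G.ngen - mrca} generations)")
print(f"  Newick: {genealogy_to_newick(G, range(10))[:60]}...")

times = []
for seed in range(500):
    g = simulate_genealogy(20, 200, seed=seed)
    m = mrca_generation(g, {0, 1})
    if m is not None:
        times.append(g.ngen - m)
print(f"mean pairwise TMRCA over 500 runs (n=20): {np.mean(times):.1f} "
      "(theory: 20)")
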