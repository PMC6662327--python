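"""Deterministic one-locus selection: trajectories, equilibria, mutation balance.

Overdominance (heterozygote advantage) maintains both alleles at a stable
interior frequency; recurrent mutation balances selection against a
recessive lethal at q ~ sqrt(mu).
"""

from popgenlab import (
    FitnessScheme,
    equilibria,
    mutation_selection_equilibrium,
    selection_trajectory,
)

w = FitnessScheme(wAA=0.8, wAa=1.0, waa=0.9)
traj = selection_trajectory(p0=0.05, w=w, ngen=500)
print(f"overdominant scheme {w}")
print(f"  p after 500 generations from p0=0.05: {traj.p[-1]:.6f}")
print(f"  mean fitness rose from {traj.wbar[0]:.4f} to {traj.wbar[-1]:.4f}")

report = equilibria(w)
for eq in report:
    print(f"  equilibrium p = {eq.p_hat:.4f} ({eq.stability})")
# the interior point 1/3 is the stable polymorphism; 0 and 1 are repelling

p_hat = mutation_selection_equilibrium(FitnessScheme(1, 1, 0), mu=1e-4)
print(f"recessive lethal, mu=1e-4: balance frequency q = {1 - p_hat:.6f}")
# ~0.01 = sqrt(mu): mutation re-supplies what selection removes
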