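"""Hawk-dove game: the ESS is a mixture, and it does not maximise mean payoff.

With resource value v=2 and fight cost c=4 the evolutionarily stable hawk
frequency is v/c = 0.5, yet an all-dove population would enjoy a higher
average payoff - natural selection does not maximise group benefit.
"""

from popgenlab import PayoffMatrix, hawkdove_trajectory, mean_payoff
from popgenlab.games import hawkdove_equilibrium

M = PayoffMatrix.classic(v=2.0, c=4.0, baseline=2.0)
traj = hawkdove_trajectory(p0=0.01, M=M, ngen=2000)
print(f"hawk frequency from p0=0.01 after 2000 generations: {traj.p[-1]:.6f}")

report = hawkdove_equilibrium(M)
print(f"interior equilibrium p* = {report.interior.p_hat:.3f} "
      f"({report.interior.stability})  [v/c = 0.5]")

print(f"mean payoff, all dove: {mean_payoff(0.0, M):.3f}")
print(f"mean payoff, at ESS  : {mean_payoff(0.5, M):.3f}")
# doves do better collectively, but a dove population is invasible by hawks
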