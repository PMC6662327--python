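# Methods

This note records the models implemented by `popgenlab`, the assumptions and
defaults behind them, and the numerical and design choices that were
genuinely open.

## Deterministic selection (`popgenlab.detsel`)

The core is the textbook discrete-generation viability model at one
biallelic autosomal locus in an effectively infinite, randomly mating
population: genotypes form at Hardy–Weinberg proportions, survive in
proportion to their relative fitnesses, and the surviving allele frequency
is

    p' = (p^2 wAA + p q wAa) / wbar(p),   wbar = p^2 wAA + 2pq wAa + q^2 waa.

Only fitness ratios matter (scale invariance is enforced by a property
test), the boundaries p ∈ {0, 1} are exact fixed points, and mean fitness
is non-decreasing along trajectories — the adaptive-landscape picture.
When all three fitnesses are equal the step returns `p` unchanged rather
than evaluating the ratio; this keeps exact neutrality bit-stable, which
the stochastic simulators rely on (a last-ulp perturbation would
desynchronise their binomial streams).

Interior equilibria exist exactly under over- or underdominance and are
taken from the closed form (wAa − waa)/((wAa − wAA) + (wAa − waa)), cross-
checked in tests against bisection on Δp.  Stability is classified from the
numerical derivative of the map at the fixed point (central difference,
step 1e−6): |dp'/dp| < 1 stable, > 1 unstable, within 1e−6 of 1
semistable.  Boundary stability is read from the sign of Δp one part in
10⁶ inside the boundary.

**Frequency-dependent selection** uses the one-parameter family
wAA = waa = 1, wAa = 1 − 2spq, re-evaluated at the current frequency.  This
family was chosen because its equilibrium structure is fully analysable:
s < 0 gives heterozygote advantage and a stable polymorphism at 1/2; s > 0
an unstable point at 1/2.  It is a canonical stand-in, not a claim about
any other implementation of frequency dependence.

**Mutation–selection balance** applies one-way mutation A → a at rate μ
*after* selection: p'' = p'(1 − μ).  The order is fixed and documented
because it defines the equilibrium: for a recessive lethal (w = (1, 1, 0))
the exact fixed point of this composition is q̂ = √μ, consistent with the
classical q̂ ≈ √(μ/s) approximation.  Fixed-point iteration stops when the
absolute per-step change falls below 1e−12 (cap 10⁷ iterations).

**Sex-ratio evolution** follows competing haploid brood-sex-ratio
strategies under Shaw–Mohler fitness, w_i = r_i/R̄ + (1 − r_i)/(1 − R̄),
the canonical formalisation of Fisher's sex-ratio principle.  Mean fitness
is identically 2, which the tests assert to 1e−12, and the population mean
ratio converges to 1/2.  Convergence of the strategy *mixture* is
algebraic (the fitness differential vanishes as R̄ → 1/2), so tests assert
monotone approach rather than exponential convergence.  Diploid sex-linked
genetics is out of scope; the strategies are asexual lineages.

## Hawk–dove game (`popgenlab.games`)

Discrete-time replicator dynamics on a 2×2 payoff matrix with an additive
baseline turning payoffs into positive fitnesses.  A discrete map (rather
than the continuous-time replicator ODE) keeps the game on the same
generation-by-generation contract as every other module.  The baseline
defaults to twice the largest payoff magnitude; baselines change the speed
but not the fixed points, which is tested.  The classic parameterisation
(v = 2, c = 4, hence ESS at hawk frequency 1/2) is the default because the
payoff entries are otherwise arbitrary.

## Wright–Fisher simulation (`popgenlab.wfsim`)

Diploid bookkeeping: N individuals carry 2N gene copies and the next
generation's allele count is Binomial(2N, p).  No individual genotypes are
tracked — binomial counts are sufficient for every frequency-level
quantity the package reports.  The diploid convention is declared, not
inferred from any other source.

Event order in the two-deme model is migration → selection → drift, with
migration computed from both demes' pre-migration frequencies
simultaneously (avoiding deme-order asymmetry); `m12` is the fraction of
deme 2's gene pool arriving from deme 1 (donor → recipient).  Bottlenecks
replace N with Nf for generations start … start+duration−1.

Replicates draw from independent child streams spawned from the master
seed (`numpy.random.SeedSequence.spawn`), so replicate r's trajectory is
invariant to nrep, and the two-deme model spawns one stream per deme per
replicate, so zero migration decouples bit-for-bit into single-deme runs.
Absorbed trajectories are filled forward to keep matrices rectangular.

## Forward-time genealogies (`popgenlab.coalescent`)

Haploid bookkeeping (n gene copies), matching the gene-copy picture of
coalescence: each copy picks its parent uniformly at random, giving
pairwise coalescence probability 1/n per generation and E[T₂] = n.  The
whole parent matrix is drawn in a single RNG call (rows are iid), which is
deterministic given the seed.  Samples that fail to coalesce in-window are
reported as `None` / counted, not errors — except in Newick export, where
a single root is required.  The plotting layout stably sorts each
generation by (parent's drawn position, own index) from past to present;
this guarantees siblings are adjacent and the result is deterministic, but
it is one readable layout among many, not a crossing-minimisation claim.

## Polygenic traits and the CLT (`popgenlab.quantgen`)

The "simplifying assumptions" of the analytic phenotype distribution are:
independent loci (linkage equilibrium), Hardy–Weinberg proportions at each
locus, purely additive and equal allelic effects, and additive independent
Gaussian environmental noise.  The exact genetic-value distribution is the
convolution of per-locus count tables (q², 2pq, p²) — a single kernel
shared with the multilocus Hardy–Weinberg table — and the matching normal
approximation has mean `effect·Σ2p` and variance `effect²·Σ2pq + env_sd²`.
Every assumption is testable against the individual-based simulator.

Directional selection is truncation on phenotype (keep the top
`keep_fraction`), not fitness-proportional reproduction: truncation makes
the selection differential S observable, the breeder's-equation check
R ≈ h²S well-defined, and the escape beyond the founding range sharp.
Mating is random pairs among survivors with replacement across offspring,
selfing excluded; each offspring locus receives one allele per parent with
probability count/2 (free recombination); no mutation.  Under sustained
truncation all "+" alleles fix and the mean reaches 2·nloci·effect.

The CLT sampler draws sums or means of iid uniform(0,1), exponential(1) or
Bernoulli(π) variables and reports sample mean/variance/skewness next to
the analytic moments; skewness decays as 1/√n.

## Visualisation (`popgenlab.viz`)

The tested surface is geometry, not pixels: cobweb staircases are returned
as exact segment lists satisfying y_k = map(x_k) and x_{k+1} = y_k;
genealogy drawings reuse the layout module's segments; images are checked
for existence, format validity and frame counts only, because pixel output
is toolkit-dependent.  GIF assembly is native (imageio) from in-memory
frames.  The Agg backend is forced at import since the package only
renders to files.

## Command-line interface (`popgenlab.cli`)

One subcommand per model, argparse-based, with a YAML config file whose
values are overridden by explicit flags (precedence is tested).  Validation
runs before any computation, so a failed run writes no numeric output; each
successful run writes a JSON manifest (parameters, seed, file list) that
reproduces it bit-for-bit.  Tables are always written; plots and GIFs are
opt-in (`--plot`, `--animate`) to keep batch runs fast.  Distribution-only
subcommands (e.g. `hardy-weinberg`) accept `--ngen` for interface
uniformity but do not use it.

## Problem sizes and tolerances

Deterministic fixed points are iterated to 1e−12; acceptance-level
convergence claims use 1e−6.  Stochastic checks run at desk scale chosen to
put 3–4 Monte-Carlo standard errors inside the stated bands: 2000
replicates for neutral fixation/heterozygosity (N = 10), 5000 for the
drift variance law, 2000 seeded pedigrees for pairwise TMRCA (n = 20,
window 200 generations, leaving < 0.01 % truncation bias), 50 seeds ×
2000 individuals for the breeder's-equation ratio, and 20 000 draws for
CLT moments.

## Known limitations

Two-locus selection, continuous-time dynamics, explicit sex chromosomes,
mutation inside the drift simulators, more than two demes, overlapping
generations, dominance/epistasis in the polygenic model, and backward-time
coalescent sampling with exponential waiting times are all out of scope.
The synthetic nature of every input means the tests validate internal
consistency with classical theory, not fit to any empirical data set.
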