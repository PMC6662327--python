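"""Polygenic quantitative genetics and the central limit theorem.

The polygenic model: ``nloci`` independent biallelic loci in Hardy-Weinberg
and linkage equilibrium, purely additive with a shared per-allele effect.
An individual's genetic value is ``effect`` times its total count of "+"
alleles; phenotype adds an independent Normal(0, env_sd) environmental
deviate.  The exact genetic-value distribution is the convolution of the
per-locus Hardy-Weinberg count tables (shared with
:func:`popgenlab.hwfreq.multilocus_distribution`), and for many loci it is
well approximated by a normal distribution — the same central-limit effect
demonstrated directly by :func:`clt_sample`.

Directional selection is modelled as truncation: each generation the top
``keep_fraction`` of phenotypes become parents, offspring are formed by free
recombination (one allele per locus per parent, drawn Bernoulli(count/2)),
and no mutation occurs.  The first-generation response follows the
breeder's equation R = h^2 S, and sustained truncation drives every "+"
allele to fixation, carrying the mean far beyond the founding range.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .errors import DomainError, SelectionTooStrongError
from .hwfreq import multilocus_distribution

__all__ = [
    "PolygenicModel",
    "IndividualPopulation",
    "CLTSpec",
    "CLTSample",
    "SelectionRun",
    "polygenic_distribution",
    "normal_approximation",
    "simulate_population",
    "phenotype_selection_run",
    "clt_sample",
]


@dataclass(frozen=True)
class PolygenicModel:
    """Additive polygenic trait architecture.

    ``p`` may be a scalar (shared by all loci) or one frequency per locus;
    ``effect`` is the trait increment per "+" allele and ``env_sd`` the
    standard deviation of the environmental deviate (same trait units).
    """

    nloci: int
    p: Union[float, Tuple[float, ...]] = 0.5
    effect: float = 1.0
    env_sd: float = 0.0

    def __post_init__(self):
        if self.nloci < 1 or self.nloci != int(self.nloci):
            raise DomainError("nloci must be a positive integer")
        p = self.p
        if np.isscalar(p):
            p = (float(p),) * self.nloci
        else:
            p = tuple(float(x) for x in p)
        if len(p) != self.nloci:
            raise DomainError(f"need {self.nloci} per-locus frequencies, got {len(p)}")
        for x in p:
            if not (0.0 <= x <= 1.0) or math.isnan(x):
                raise DomainError(f"locus frequency {x!r} must lie in [0, 1]")
        object.__setattr__(self, "p", p)
        if not math.isfinite(self.effect):
            raise DomainError("effect must be finite")
        if self.env_sd < 0 or not math.isfinite(self.env_sd):
            raise DomainError("env_sd must be finite and >= 0")


def polygenic_distribution(model: PolygenicModel) -> Tuple[np.ndarray, np.ndarray]:
    """Exact genetic-phenotype distribution ``(values, probabilities)``.

    Values are the possible genetic phenotypes 0, effect, ..., 2*nloci*effect;
    probabilities come from exact convolution of the per-locus
    Hardy-Weinberg count tables and sum to 1.
    """
    counts, probs = multilocus_distribution(model.p)
    return counts * model.effect, probs


def normal_approximation(model: PolygenicModel) -> Tuple[float, float]:
    """Normal (mean, variance) matching the phenotype distribution.

    mean = effect * sum(2 p_l); variance = additive genetic variance
    effect^2 * sum(2 p_l (1 - p_l)) plus env_sd^2.
    """
    mean = model.effect * sum(2.0 * p for p in model.p)
    var_g = model.effect ** 2 * sum(2.0 * p * (1.0 - p) for p in model.p)
    return mean, var_g + model.env_sd ** 2


@dataclass
class IndividualPopulation:
    """Individuals as rows of per-locus "+" allele counts plus phenotypes."""

    genotypes: np.ndarray  # (n, nloci), entries in {0, 1, 2}
    phenotypes: np.ndarray  # (n,)
    model: PolygenicModel

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def allele_freqs(self) -> np.ndarray:
        """Per-locus "+" allele frequency, column mean / 2."""
        return self.genotypes.mean(axis=0) / 2.0


def _draw_genotypes(model: PolygenicModel, n: int, rng) -> np.ndarray:
    return rng.binomial(2, np.asarray(model.p), size=(n, model.nloci))


def _phenotypes(model: PolygenicModel, genotypes: np.ndarray, rng) -> np.ndarray:
    genetic = model.effect * genotypes.sum(axis=1)
    if model.env_sd > 0:
        return genetic + rng.normal(0.0, model.env_sd, size=genotypes.shape[0])
    return genetic.astype(float)


def simulate_population(model: PolygenicModel, n: int, seed) -> IndividualPopulation:
    """Draw n individuals at Hardy-Weinberg/linkage equilibrium; seeded."""
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    genotypes = _draw_genotypes(model, n, rng)
    phenotypes = _phenotypes(model, genotypes, rng)
    return IndividualPopulation(genotypes=genotypes, phenotypes=phenotypes, model=model)


@dataclass
class SelectionRun:
    """Per-generation summaries of a truncation-selection experiment."""

    mean_phenotype: np.ndarray         # (ngen + 1,)
    var_phenotype: np.ndarray          # (ngen + 1,)
    allele_freqs: np.ndarray           # (ngen + 1, nloci)
    selection_differential: np.ndarray  # (ngen,): mean(kept) - mean(all)
    model: PolygenicModel

    @property
    def mean_p(self) -> np.ndarray:
        return self.allele_freqs.mean(axis=1)

    def to_csv(self, path, delimiter: str = ",") -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(["generation", "mean_phenotype", "var_phenotype", "mean_p"])
            for t in range(self.mean_phenotype.size):
                writer.writerow([t,
                                 repr(float(self.mean_phenotype[t])),
                                 repr(float(self.var_phenotype[t])),
                                 repr(float(self.mean_p[t]))])


def phenotype_selection_run(model: PolygenicModel, n: int, keep_fraction: float,
                            ngen: int, seed) -> SelectionRun:
    """Individual-based directional selection by phenotypic truncation.

    Each generation the top ``keep_fraction`` of phenotypes survive; each of
    the n offspring draws two distinct parents uniformly (with replacement
    across offspring, selfing excluded) and one freely recombining allele
    per locus per parent.  No mutation, so the response is fuelled entirely
    by standing variation.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if not (0.0 < keep_fraction <= 1.0):
        raise DomainError("keep_fraction must lie in (0, 1]")
    if ngen < 0:
        raise DomainError("ngen must be >= 0")
    nkeep = int(round(keep_fraction * n))
    if nkeep < 2:
        raise SelectionTooStrongError(
            f"keep_fraction={keep_fraction} of n={n} leaves {nkeep} (< 2) parents"
        )
    rng = np.random.default_rng(seed)
    genotypes = _draw_genotypes(model, n, rng)
    phenotypes = _phenotypes(model, genotypes, rng)

    L = model.nloci
    mean_ph = np.empty(ngen + 1)
    var_ph = np.empty(ngen + 1)
    freqs = np.empty((ngen + 1, L))
    sdiff = np.empty(ngen)
    mean_ph[0] = phenotypes.mean()
    var_ph[0] = phenotypes.var()
    freqs[0] = genotypes.mean(axis=0) / 2.0

    for t in range(1, ngen + 1):
        order = np.argsort(phenotypes)[::-1]
        kept = genotypes[order[:nkeep]]
        sdiff[t - 1] = phenotypes[order[:nkeep]].mean() - phenotypes.mean()
        # two distinct parents per offspring, uniform over survivors
        a = rng.integers(nkeep, size=n)
        b = rng.integers(nkeep - 1, size=n)
        b[b >= a] += 1
        # one gamete allele per locus per parent: Bernoulli(count / 2)
        gam_a = (rng.random((n, L)) < kept[a] / 2.0).astype(np.int64)
        gam_b = (rng.random((n, L)) < kept[b] / 2.0).astype(np.int64)
        genotypes = gam_a + gam_b
        phenotypes = _phenotypes(model, genotypes, rng)
        mean_ph[t] = phenotypes.mean()
        var_ph[t] = phenotypes.var()
        freqs[t] = genotypes.mean(axis=0) / 2.0

    return SelectionRun(mean_phenotype=mean_ph, var_phenotype=var_ph,
                        allele_freqs=freqs, selection_differential=sdiff,
                        model=model)


# ---------------------------------------------------------------------------
# central limit theorem demonstration

_FAMILIES = ("uniform", "exponential", "bernoulli")


@dataclass(frozen=True)
class CLTSpec:
    """Specification for a central-limit-theorem sampling demonstration.

    ``family`` is the parent distribution of the addends — uniform(0, 1),
    exponential(1), or bernoulli(pi) — and each of the ``n_sums`` draws is
    the sum (or mean) of ``n_per_sum`` iid variables.
    """

    family: str
    n_per_sum: int
    n_sums: int
    mode: str = "sum"
    seed: int = 0
    pi: float = 0.5

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise DomainError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        if self.n_per_sum < 1 or self.n_sums < 1:
            raise DomainError("n_per_sum and n_sums must be >= 1")
        if self.mode not in ("sum", "mean"):
            raise DomainError("mode must be 'sum' or 'mean'")
        if not (0.0 <= self.pi <= 1.0):
            raise DomainError("bernoulli pi must lie in [0, 1]")

    def parent_moments(self) -> Tuple[float, float]:
        if self.family == "uniform":
            return 0.5, 1.0 / 12.0
        if self.family == "exponential":
            return 1.0, 1.0
        return self.pi, self.pi * (1.0 - self.pi)


@dataclass
class CLTSample:
    samples: np.ndarray
    sample_mean: float
    sample_var: float
    sample_skewness: float
    analytic_mean: float
    analytic_var: float
    spec: CLTSpec

    def to_csv(self, path, delimiter: str = ",") -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(["draw", "value"])
            for i, v in enumerate(self.samples):
                writer.writerow([i, repr(float(v))])


def clt_sample(spec: CLTSpec) -> CLTSample:
    """Draw sums (or means) of iid variables and summarise their shape.

    Skewness of the sum decays as 1/sqrt(n_per_sum), so raising
    ``n_per_sum`` visibly normalises even a strongly skewed parent such as
    the exponential.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_sums, spec.n_per_sum)
    if spec.family == "uniform":
        draws = rng.random(shape)
    elif spec.family == "exponential":
        draws = rng.exponential(1.0, size=shape)
    else:
        draws = rng.binomial(1, spec.pi, size=shape).astype(float)
    agg = draws.sum(axis=1) if spec.mode == "sum" else draws.mean(axis=1)
    mu, var = spec.parent_moments()
    n = spec.n_per_sum
    analytic_mean = n * mu if spec.mode == "sum" else mu
    analytic_var = n * var if spec.mode == "sum" else var / n
    return CLTSample(
        samples=agg,
        sample_mean=float(agg.mean()),
        sample_var=float(agg.var(ddof=1)),
        sample_skewness=float(stats.skew(agg)),
        analytic_mean=analytic_mean,
        analytic_var=analytic_var,
        spec=spec,
    )
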