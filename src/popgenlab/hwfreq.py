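"""Hardy-Weinberg genotype frequencies.

Single-locus genotype frequencies for an arbitrary number of alleles
(p_i^2 homozygotes, 2 p_i p_j heterozygotes), and the exact distribution of
the total count of a focal ("+") allele summed over many independent
biallelic loci, computed by convolving the per-locus Hardy-Weinberg count
distributions.  The same convolution kernel powers the polygenic phenotype
distribution in :mod:`popgenlab.quantgen`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .errors import DomainError

__all__ = [
    "AlleleFrequencySet",
    "hw_genotype_frequencies",
    "genotype_label",
    "multilocus_distribution",
    "genotype_frequencies_to_csv",
    "count_distribution_to_csv",
]


@dataclass(frozen=True)
class AlleleFrequencySet:
    """Frequencies of k >= 2 alleles at one locus; must sum to 1."""

    freqs: Tuple[float, ...]

    def __init__(self, freqs: Sequence[float]):
        object.__setattr__(self, "freqs", tuple(float(f) for f in freqs))
        if len(self.freqs) < 2:
            raise DomainError("need at least two alleles")
        for f in self.freqs:
            if not (0.0 <= f <= 1.0) or math.isnan(f):
                raise DomainError(f"allele frequency {f!r} must lie in [0, 1]")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise DomainError(f"allele frequencies sum to {sum(self.freqs)}, not 1")

    @property
    def k(self) -> int:
        return len(self.freqs)


def hw_genotype_frequencies(alleles: AlleleFrequencySet) -> Dict[Tuple[int, int], float]:
    """Hardy-Weinberg genotype frequencies keyed by ordered allele pairs (i <= j).

    Homozygote (i, i) has frequency p_i^2 and heterozygote (i, j) has
    2 p_i p_j; the k(k+1)/2 entries sum to 1.
    """
    p = alleles.freqs
    out: Dict[Tuple[int, int], float] = {}
    for i in range(alleles.k):
        for j in range(i, alleles.k):
            out[(i, j)] = p[i] * p[i] if i == j else 2.0 * p[i] * p[j]
    return out


def genotype_label(pair: Tuple[int, int]) -> str:
    """Display label for an ordered allele-index pair, e.g. (0, 1) -> 'A1A2'."""
    i, j = pair
    return f"A{i + 1}A{j + 1}"


def multilocus_distribution(p_per_locus: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the total "+" allele count over independent loci.

    Each locus contributes a Hardy-Weinberg genotype count (0, 1 or 2 "+"
    alleles with probabilities q^2, 2pq, p^2); the per-locus tables are
    convolved exactly.  Returns ``(counts 0..2L, probabilities)``.
    """
    ps = [float(p) for p in p_per_locus]
    if not ps:
        raise DomainError("need at least one locus")
    for p in ps:
        if not (0.0 <= p <= 1.0) or math.isnan(p):
            raise DomainError(f"locus frequency {p!r} must lie in [0, 1]")
    dist = np.array([1.0])
    for p in ps:
        q = 1.0 - p
        dist = np.convolve(dist, np.array([q * q, 2.0 * p * q, p * p]))
    dist = np.clip(dist, 0.0, None)
    dist /= dist.sum()
    return np.arange(dist.size), dist


def genotype_frequencies_to_csv(freqs: Dict[Tuple[int, int], float], path,
                                delimiter: str = ",") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["genotype", "frequency"])
        for pair in sorted(freqs):
            writer.writerow([genotype_label(pair), repr(float(freqs[pair]))])


def count_distribution_to_csv(counts: np.ndarray, probs: np.ndarray, path,
                              delimiter: str = ",", value_header: str = "count") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([value_header, "probability"])
        for c, pr in zip(counts, probs):
            writer.writerow([repr(float(c)) if isinstance(c, float) else int(c),
                             repr(float(pr))])
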