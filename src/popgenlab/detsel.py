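"""Deterministic one-locus selection models.

Numerical analysis of viability selection at a biallelic locus, plus three
classic extensions built on the same recursion: frequency-dependent
selection, one-way mutation opposing selection (mutation-selection balance),
and Fisherian sex-ratio evolution under Shaw-Mohler fitness.

The core recursion is the standard discrete-generation viability model:
with genotype fitnesses ``wAA, wAa, waa`` and allele frequency ``p``
(``q = 1 - p``),

    wbar(p) = p^2 wAA + 2 p q wAa + q^2 waa
    p'      = (p^2 wAA + p q wAa) / wbar(p)

Fixation boundaries ``p in {0, 1}`` are exact fixed points, trajectories are
invariant to rescaling all three fitnesses by a positive constant, and under
frequency-independent selection mean fitness never decreases along a
trajectory (the adaptive-landscape property).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import AllOneSexError, DegenerateModelError, DomainError

__all__ = [
    "FitnessScheme",
    "Trajectory",
    "Equilibrium",
    "EquilibriumReport",
    "SexRatioModel",
    "mean_fitness",
    "selection_step",
    "delta_p",
    "selection_trajectory",
    "equilibria",
    "freqdep_step",
    "freqdep_trajectory",
    "mutation_selection_step",
    "mutation_selection_trajectory",
    "mutation_selection_equilibrium",
    "sexratio_step",
    "sexratio_trajectory",
]

#: absolute tolerance for fixed-point iteration convergence
FIXED_POINT_TOL = 1e-12
#: iteration cap for fixed-point searches
FIXED_POINT_MAX_ITER = 10**7
#: finite-difference step for stability classification
STABILITY_STEP = 1e-6


def _check_freq(p: float, name: str = "p") -> float:
    p = float(p)
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise DomainError(f"{name}={p!r} is not a frequency in [0, 1]")
    return p


@dataclass(frozen=True)
class FitnessScheme:
    """Relative viabilities of the AA, Aa and aa genotypes.

    All three values must be finite, non-negative, and not all zero.  Only
    fitness ratios matter: multiplying every value by a positive constant
    leaves every trajectory unchanged.
    """

    wAA: float
    wAa: float
    waa: float

    def __post_init__(self):
        vals = (self.wAA, self.wAa, self.waa)
        for name, v in zip(("wAA", "wAa", "waa"), vals):
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"fitness {name}={v!r} must be finite and >= 0")
        if max(vals) == 0:
            raise DomainError("at least one genotype fitness must be positive")

    @property
    def is_neutral(self) -> bool:
        return self.wAA == self.wAa == self.waa

    @property
    def is_overdominant(self) -> bool:
        return self.wAa > max(self.wAA, self.waa)

    @property
    def is_underdominant(self) -> bool:
        return self.wAa < min(self.wAA, self.waa)

    def scaled(self, c: float) -> "FitnessScheme":
        if c <= 0:
            raise DomainError("scaling constant must be positive")
        return FitnessScheme(c * self.wAA, c * self.wAa, c * self.waa)


@dataclass
class Trajectory:
    """Per-generation allele-frequency record of a deterministic model run.

    ``p[t]`` is the frequency of the focal allele at generation ``t``
    (``t = 0 .. ngen``); ``wbar``, when present, is the matching
    mean-fitness (or mean-payoff) series.
    """

    p: np.ndarray
    wbar: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1 or self.p.size < 1:
            raise DomainError("trajectory needs a 1-D frequency series")
        if self.wbar is not None:
            self.wbar = np.asarray(self.wbar, dtype=float)
            if self.wbar.shape != self.p.shape:
                raise DomainError("wbar series must match p in length")

    @property
    def generations(self) -> int:
        return self.p.size - 1

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    def to_csv(self, path, delimiter: str = ",") -> None:
        """Write ``generation,p,q,wbar`` rows (wbar blank if absent)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(["generation", "p", "q", "wbar"])
            for t, p in enumerate(self.p):
                wb = "" if self.wbar is None else repr(float(self.wbar[t]))
                writer.writerow([t, repr(float(p)), repr(float(1.0 - p)), wb])


@dataclass(frozen=True)
class Equilibrium:
    p_hat: float
    stability: str  # "stable" | "unstable" | "semistable"


@dataclass
class EquilibriumReport:
    """All fixed points of a one-dimensional frequency map with stabilities."""

    equilibria: tuple

    @property
    def interior(self) -> Optional[Equilibrium]:
        for eq in self.equilibria:
            if 0.0 < eq.p_hat < 1.0:
                return eq
        return None

    def __iter__(self):
        return iter(self.equilibria)

    def to_csv(self, path, delimiter: str = ",") -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(["p_hat", "stability"])
            for eq in self.equilibria:
                writer.writerow([repr(eq.p_hat), eq.stability])


def mean_fitness(p: float, w: FitnessScheme) -> float:
    """Population mean fitness wbar(p) = p^2 wAA + 2pq wAa + q^2 waa."""
    p = _check_freq(p)
    q = 1.0 - p
    return p * p * w.wAA + 2.0 * p * q * w.wAa + q * q * w.waa


def selection_step(p: float, w: FitnessScheme) -> float:
    """One generation of viability selection: p' = (p^2 wAA + pq wAa) / wbar.

    The boundaries 0 and 1 are exact fixed points, as is any ``p`` under a
    flat fitness scheme.  Raises :class:`DegenerateModelError` when the mean
    fitness vanishes at an interior frequency.
    """
    p = _check_freq(p)
    if p == 0.0 or p == 1.0 or w.is_neutral:
        return p
    q = 1.0 - p
    wbar = p * p * w.wAA + 2.0 * p * q * w.wAa + q * q * w.waa
    if wbar <= 0.0:
        raise DegenerateModelError(
            f"mean fitness is zero at p={p}; the recursion is undefined"
        )
    p_next = (p * p * w.wAA + p * q * w.wAa) / wbar
    return min(1.0, max(0.0, p_next))


def delta_p(p: float, w: FitnessScheme) -> float:
    """Per-generation change in allele frequency, selection_step(p) - p."""
    return selection_step(p, w) - p


def selection_trajectory(p0: float, w: FitnessScheme, ngen: int,
                         label: str = "selection") -> Trajectory:
    """Iterate the selection recursion ``ngen`` times from ``p0``.

    Records both the allele frequency and the mean fitness each generation.
    """
    p0 = _check_freq(p0, "p0")
    if ngen < 0:
        raise DomainError("ngen must be >= 0")
    p = np.empty(ngen + 1)
    wb = np.empty(ngen + 1)
    p[0] = p0
    wb[0] = mean_fitness(p0, w)
    for t in range(1, ngen + 1):
        p[t] = selection_step(p[t - 1], w)
        wb[t] = mean_fitness(p[t], w)
    return Trajectory(p=p, wbar=wb, label=label)


def _classify_interior(step: Callable[[float], float], p_hat: float) -> str:
    # |map derivative| at the fixed point: <1 attracting, >1 repelling
    h = STABILITY_STEP
    lo, hi = max(0.0, p_hat - h), min(1.0, p_hat + h)
    d = (step(hi) - step(lo)) / (hi - lo)
    if abs(abs(d) - 1.0) < STABILITY_STEP:
        return "semistable"
    return "stable" if abs(d) < 1.0 else "unstable"


def _classify_boundary(step: Callable[[float], float], boundary: float) -> str:
    # sign of delta-p just inside the boundary decides attraction
    eps = 1e-6
    p = eps if boundary == 0.0 else 1.0 - eps
    d = step(p) - p
    if d == 0.0:
        return "semistable"
    moving_in = (d < 0) if boundary == 0.0 else (d > 0)
    return "stable" if moving_in else "unstable"


def equilibria(w: FitnessScheme, tolerance: float = 1e-9) -> EquilibriumReport:
    """All equilibria of the selection map with stability classification.

    The boundaries 0 and 1 are always fixed points.  An interior
    polymorphic equilibrium exists exactly when the heterozygote fitness
    lies outside the homozygote range: overdominance gives a stable interior
    point, underdominance an unstable one, at

        p_hat = (wAa - waa) / ((wAa - wAA) + (wAa - waa)).
    """
    step = lambda p: selection_step(p, w)
    eqs = [Equilibrium(0.0, _classify_boundary(step, 0.0))]
    if w.is_overdominant or w.is_underdominant:
        p_hat = (w.wAa - w.waa) / ((w.wAa - w.wAA) + (w.wAa - w.waa))
        if tolerance < p_hat < 1.0 - tolerance:
            if abs(delta_p(p_hat, w)) >= tolerance:  # pragma: no cover - sanity
                raise DegenerateModelError("closed-form equilibrium failed residual check")
            eqs.append(Equilibrium(p_hat, _classify_interior(step, p_hat)))
    eqs.append(Equilibrium(1.0, _classify_boundary(step, 1.0)))
    return EquilibriumReport(equilibria=tuple(eqs))


# ---------------------------------------------------------------------------
# frequency-dependent selection

def _freqdep_scheme(p: float, s: float) -> FitnessScheme:
    return FitnessScheme(1.0, 1.0 - s * 2.0 * p * (1.0 - p), 1.0)


def freqdep_step(p: float, s: float) -> float:
    """One generation of frequency-dependent selection.

    The genotype fitnesses are re-evaluated at the current frequency as
    ``wAA = waa = 1`` and ``wAa = 1 - 2 s p q``: for ``s < 0`` heterozygotes
    are favoured when common and p = 1/2 is a stable polymorphism; for
    ``s > 0`` the same point is an unstable equilibrium.
    """
    p = _check_freq(p)
    s = float(s)
    if not -1.0 <= s <= 1.0:
        raise DomainError("frequency-dependence coefficient s must lie in [-1, 1]")
    return selection_step(p, _freqdep_scheme(p, s))


def freqdep_trajectory(p0: float, s: float, ngen: int) -> Trajectory:
    """Iterate :func:`freqdep_step`; wbar is mean fitness at each generation."""
    p0 = _check_freq(p0, "p0")
    if ngen < 0:
        raise DomainError("ngen must be >= 0")
    p = np.empty(ngen + 1)
    wb = np.empty(ngen + 1)
    p[0] = p0
    wb[0] = mean_fitness(p0, _freqdep_scheme(p0, s))
    for t in range(1, ngen + 1):
        p[t] = freqdep_step(p[t - 1], s)
        wb[t] = mean_fitness(p[t], _freqdep_scheme(p[t], s))
    return Trajectory(p=p, wbar=wb, label="freqdep")


# ---------------------------------------------------------------------------
# mutation-selection balance

def mutation_selection_step(p: float, w: FitnessScheme, mu: float) -> float:
    """Selection followed by one-way mutation A -> a at rate ``mu``."""
    mu = float(mu)
    if not 0.0 <= mu < 1.0:
        raise DomainError("mutation rate mu must lie in [0, 1)")
    return selection_step(p, w) * (1.0 - mu)


def mutation_selection_trajectory(p0: float, w: FitnessScheme, mu: float,
                                  ngen: int) -> Trajectory:
    p0 = _check_freq(p0, "p0")
    if ngen < 0:
        raise DomainError("ngen must be >= 0")
    p = np.empty(ngen + 1)
    wb = np.empty(ngen + 1)
    p[0] = p0
    wb[0] = mean_fitness(p0, w)
    for t in range(1, ngen + 1):
        p[t] = mutation_selection_step(p[t - 1], w, mu)
        wb[t] = mean_fitness(p[t], w)
    return Trajectory(p=p, wbar=wb, label="mutation-selection")


def mutation_selection_equilibrium(w: FitnessScheme, mu: float,
                                   p0: float = 0.999,
                                   tol: float = FIXED_POINT_TOL,
                                   max_iter: int = FIXED_POINT_MAX_ITER) -> float:
    """Fixed point of the mutation-selection map found by direct iteration.

    For a recessive deleterious allele (w = (1, 1, 1 - s)) the balance
    frequency of the deleterious allele is approximately sqrt(mu / s).
    """
    p = _check_freq(p0, "p0")
    for _ in range(max_iter):
        p_next = mutation_selection_step(p, w, mu)
        if abs(p_next - p) < tol:
            return p_next
        p = p_next
    raise DegenerateModelError("fixed-point iteration did not converge")


# ---------------------------------------------------------------------------
# Fisherian sex-ratio evolution

@dataclass
class SexRatioModel:
    """Competing sex-allocation strategies in an infinite population.

    ``ratios[i]`` is strategy i's brood sex ratio (proportion of sons) and
    ``freqs[i]`` its current frequency.  Strategy fitness follows the
    Shaw-Mohler principle: reproductive value flows equally through sons and
    daughters, so w_i = r_i / R + (1 - r_i) / (1 - R) with R the population
    mean sex ratio, and the replicator map drives R toward 1/2.
    """

    ratios: Sequence[float]
    freqs: Sequence[float]

    def __post_init__(self):
        self.ratios = tuple(float(r) for r in self.ratios)
        self.freqs = tuple(float(f) for f in self.freqs)
        if len(self.ratios) == 0 or len(self.ratios) != len(self.freqs):
            raise DomainError("need matching, non-empty ratios and freqs")
        for r in self.ratios:
            if not 0.0 <= r <= 1.0:
                raise DomainError(f"brood sex ratio {r} must lie in [0, 1]")
        if any(f < 0 for f in self.freqs):
            raise DomainError("strategy frequencies must be non-negative")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise DomainError("strategy frequencies must sum to 1")

    @property
    def mean_ratio(self) -> float:
        """Population mean proportion of sons, R = sum_i f_i r_i."""
        return float(sum(f * r for f, r in zip(self.freqs, self.ratios)))


def sexratio_step(model: SexRatioModel) -> SexRatioModel:
    """One replicator generation under Shaw-Mohler sex-allocation fitness.

    Mean fitness sum_i f_i w_i equals 2 identically, so the map normalises
    by 2.  Raises :class:`AllOneSexError` when the population produces only
    one sex (R in {0, 1}), where fitness is undefined.
    """
    R = model.mean_ratio
    if R <= 0.0 or R >= 1.0:
        raise AllOneSexError(f"population mean sex ratio R={R} leaves one sex absent")
    w = [r / R + (1.0 - r) / (1.0 - R) for r in model.ratios]
    fw = [f * wi for f, wi in zip(model.freqs, w)]
    total = sum(fw)  # identically 2 under Shaw-Mohler
    new_freqs = [x / total for x in fw]
    return SexRatioModel(ratios=model.ratios, freqs=new_freqs)


@dataclass
class SexRatioTrajectory:
    ratios: tuple
    freqs: np.ndarray          # shape (ngen + 1, nstrategies)
    mean_ratio: np.ndarray     # shape (ngen + 1,)

    def to_csv(self, path, delimiter: str = ",") -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            header = ["generation", "mean_ratio"] + [
                f"freq_r{r}" for r in self.ratios
            ]
            writer.writerow(header)
            for t in range(self.freqs.shape[0]):
                writer.writerow(
                    [t, repr(float(self.mean_ratio[t]))]
                    + [repr(float(x)) for x in self.freqs[t]]
                )


def sexratio_trajectory(model: SexRatioModel, ngen: int) -> SexRatioTrajectory:
    """Iterate :func:`sexratio_step`, recording frequencies and mean ratio."""
    if ngen < 0:
        raise DomainError("ngen must be >= 0")
    k = len(model.ratios)
    freqs = np.empty((ngen + 1, k))
    mean = np.empty(ngen + 1)
    freqs[0] = model.freqs
    mean[0] = model.mean_ratio
    cur = model
    for t in range(1, ngen + 1):
        cur = sexratio_step(cur)
        freqs[t] = cur.freqs
        mean[t] = cur.mean_ratio
    return SexRatioTrajectory(ratios=model.ratios, freqs=freqs, mean_ratio=mean)
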