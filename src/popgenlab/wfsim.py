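"""Stochastic Wright-Fisher simulation.

Non-overlapping generations in a diploid population of ``N`` individuals
(2N gene copies): each generation the allele count of the next generation is
drawn Binomial(2N, p), optionally after deterministic viability selection
and/or migration have adjusted ``p``.  Includes pure drift, drift with
selection, a two-deme migration-selection-drift model, and founder
events / bottlenecks with a time-varying population size.

Replicates are simulated from independent child streams spawned from the
master seed, so the first replicate's trajectory does not change when more
replicates are requested.  Absorbed trajectories (p in {0, 1}) are filled
forward so that output matrices stay rectangular.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .detsel import FitnessScheme, selection_step
from .errors import DomainError

__all__ = [
    "WFParams",
    "MSDParams",
    "FounderParams",
    "ReplicateTrajectories",
    "wf_drift",
    "drift_selection",
    "msd",
    "founder_event",
    "replicate_seed_sequences",
]

SeedLike = Union[int, np.random.SeedSequence, Sequence[np.random.SeedSequence]]


def replicate_seed_sequences(seed: SeedLike, nrep: int) -> List[np.random.SeedSequence]:
    """Spawn one independent child seed sequence per replicate.

    ``seed`` may be an integer, a SeedSequence, or an explicit list of
    ``nrep`` SeedSequences (used to couple runs bit-for-bit across models).
    """
    if isinstance(seed, (list, tuple)):
        if len(seed) != nrep:
            raise DomainError(f"need {nrep} seed sequences, got {len(seed)}")
        return list(seed)
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(int(seed))
    return seed.spawn(nrep)


def _check_positive_int(value, name: str) -> int:
    if value != int(value) or int(value) < 1:
        raise DomainError(f"{name}={value!r} must be a positive integer")
    return int(value)


@dataclass(frozen=True)
class WFParams:
    """Parameters of a single-deme Wright-Fisher run.

    N diploid individuals (2N gene copies), initial frequency ``p0``,
    ``ngen`` generations, ``nrep`` independent replicate populations.
    """

    N: int
    p0: float
    ngen: int
    nrep: int = 1
    seed: int = 0

    def __post_init__(self):
        _check_positive_int(self.N, "N")
        _check_positive_int(self.nrep, "nrep")
        if self.ngen < 0 or self.ngen != int(self.ngen):
            raise DomainError(f"ngen={self.ngen!r} must be a non-negative integer")
        if not (0.0 <= self.p0 <= 1.0):
            raise DomainError(f"p0={self.p0!r} must lie in [0, 1]")


@dataclass
class ReplicateTrajectories:
    """Per-replicate allele-frequency matrix with absorption bookkeeping.

    ``p`` has shape (nrep, ngen + 1); ``absorbed_at[r]`` is the generation
    at which replicate r hit 0 or 1 (or -1 if segregating at the end).
    """

    p: np.ndarray
    absorbed_at: np.ndarray
    sizes: Optional[np.ndarray] = None  # per-generation N, for bottleneck runs

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.absorbed_at = np.asarray(self.absorbed_at, dtype=int)

    @property
    def nrep(self) -> int:
        return self.p.shape[0]

    @property
    def ngen(self) -> int:
        return self.p.shape[1] - 1

    @property
    def fixed(self) -> np.ndarray:
        """Replicates that ended fixed for the focal allele (p == 1)."""
        return self.p[:, -1] == 1.0

    @property
    def lost(self) -> np.ndarray:
        return self.p[:, -1] == 0.0

    @property
    def fraction_fixed(self) -> float:
        return float(np.mean(self.fixed))

    @property
    def fraction_lost(self) -> float:
        return float(np.mean(self.lost))

    def heterozygosity(self, t: Optional[int] = None) -> np.ndarray:
        """Mean expected heterozygosity 2p(1-p) across replicates.

        Returns the full per-generation series, or a scalar at generation t.
        """
        h = 2.0 * self.p * (1.0 - self.p)
        series = h.mean(axis=0)
        return float(series[t]) if t is not None else series

    def to_csv(self, path, delimiter: str = ",", deme: Optional[int] = None) -> None:
        """Long format ``replicate,generation,p`` (+ ``deme`` / ``N`` columns)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            header = ["replicate", "generation", "p"]
            if deme is not None:
                header.append("deme")
            if self.sizes is not None:
                header.append("N")
            writer.writerow(header)
            for r in range(self.nrep):
                for t in range(self.ngen + 1):
                    row = [r, t, repr(float(self.p[r, t]))]
                    if deme is not None:
                        row.append(deme)
                    if self.sizes is not None:
                        row.append(int(self.sizes[t]))
                    writer.writerow(row)


def _run_replicates(
    nrep: int,
    ngen: int,
    p0: float,
    seeds: List[np.random.SeedSequence],
    size_at: Callable[[int], int],
    det_step: Optional[Callable[[float], float]] = None,
) -> ReplicateTrajectories:
    """Shared drift engine: deterministic step (optional), then binomial sampling."""
    P = np.empty((nrep, ngen + 1))
    absorbed = np.full(nrep, -1, dtype=int)
    P[:, 0] = p0
    if p0 == 0.0 or p0 == 1.0:
        absorbed[:] = 0
        P[:] = p0
        return ReplicateTrajectories(p=P, absorbed_at=absorbed)
    for r in range(nrep):
        rng = np.random.default_rng(seeds[r])
        p = p0
        for t in range(1, ngen + 1):
            if det_step is not None:
                p = det_step(p)
            if p == 0.0 or p == 1.0:
                P[r, t:] = p
                absorbed[r] = t
                break
            two_n = 2 * size_at(t)
            p = rng.binomial(two_n, p) / two_n
            P[r, t] = p
            if p == 0.0 or p == 1.0:
                P[r, t:] = p
                absorbed[r] = t
                break
    return ReplicateTrajectories(p=P, absorbed_at=absorbed)


def wf_drift(params: WFParams, seed: Optional[SeedLike] = None) -> ReplicateTrajectories:
    """Pure genetic drift: allele counts resampled Binomial(2N, p) each generation.

    Deterministic given the seed.  A neutral allele fixes with probability
    equal to its initial frequency, and expected heterozygosity decays by
    (1 - 1/(2N)) per generation.
    """
    seeds = replicate_seed_sequences(params.seed if seed is None else seed, params.nrep)
    return _run_replicates(params.nrep, params.ngen, params.p0, seeds,
                           size_at=lambda t: params.N)


def drift_selection(params: WFParams, w: FitnessScheme,
                    seed: Optional[SeedLike] = None) -> ReplicateTrajectories:
    """Viability selection followed by binomial drift each generation.

    With a flat fitness scheme this reduces exactly to :func:`wf_drift`
    (same seed, same trajectories).
    """
    seeds = replicate_seed_sequences(params.seed if seed is None else seed, params.nrep)
    return _run_replicates(params.nrep, params.ngen, params.p0, seeds,
                           size_at=lambda t: params.N,
                           det_step=lambda p: selection_step(p, w))


@dataclass(frozen=True)
class MSDParams:
    """Two-deme migration-selection-drift parameters.

    ``m12`` is the fraction of deme 2's gene pool arriving from deme 1 each
    generation (donor -> recipient), and symmetrically for ``m21``.  Each
    generation the order of events is migration (computed from both demes'
    pre-migration frequencies simultaneously), then selection with the
    deme's own fitness scheme, then binomial drift.
    """

    N1: int
    N2: int
    p01: float
    p02: float
    w1: FitnessScheme
    w2: FitnessScheme
    m12: float
    m21: float
    ngen: int
    nrep: int = 1
    seed: int = 0

    def __post_init__(self):
        _check_positive_int(self.N1, "N1")
        _check_positive_int(self.N2, "N2")
        _check_positive_int(self.nrep, "nrep")
        if self.ngen < 0:
            raise DomainError("ngen must be >= 0")
        for name in ("p01", "p02", "m12", "m21"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name}={v!r} must lie in [0, 1]")


def msd(params: MSDParams,
        seed: Optional[SeedLike] = None) -> Tuple[ReplicateTrajectories, ReplicateTrajectories]:
    """Two-deme migration-selection-drift; returns one trajectory set per deme.

    Each replicate spawns one child stream per deme, so with zero migration
    the run decouples into two independent single-deme
    :func:`drift_selection` runs with those per-deme seeds.
    """
    rep_seeds = replicate_seed_sequences(params.seed if seed is None else seed,
                                         params.nrep)
    nrep, ngen = params.nrep, params.ngen
    P1 = np.empty((nrep, ngen + 1))
    P2 = np.empty((nrep, ngen + 1))
    abs1 = np.full(nrep, -1, dtype=int)
    abs2 = np.full(nrep, -1, dtype=int)
    P1[:, 0], P2[:, 0] = params.p01, params.p02
    for r in range(nrep):
        s1, s2 = rep_seeds[r].spawn(2)
        rng1, rng2 = np.random.default_rng(s1), np.random.default_rng(s2)
        p1, p2 = params.p01, params.p02
        for t in range(1, ngen + 1):
            # migration from both demes' pre-migration frequencies
            p1m = (1.0 - params.m21) * p1 + params.m21 * p2
            p2m = (1.0 - params.m12) * p2 + params.m12 * p1
            p1s = selection_step(p1m, params.w1)
            p2s = selection_step(p2m, params.w2)
            if 0.0 < p1s < 1.0:
                p1 = rng1.binomial(2 * params.N1, p1s) / (2 * params.N1)
            else:
                p1 = p1s
            if 0.0 < p2s < 1.0:
                p2 = rng2.binomial(2 * params.N2, p2s) / (2 * params.N2)
            else:
                p2 = p2s
            P1[r, t], P2[r, t] = p1, p2
        abs1[r] = _first_absorption(P1[r])
        abs2[r] = _first_absorption(P2[r])
    return (ReplicateTrajectories(p=P1, absorbed_at=abs1),
            ReplicateTrajectories(p=P2, absorbed_at=abs2))


def _first_absorption(row: np.ndarray) -> int:
    hits = np.nonzero((row == 0.0) | (row == 1.0))[0]
    return int(hits[0]) if hits.size else -1


@dataclass(frozen=True)
class FounderParams:
    """Founder event / bottleneck: population of size N0 drops to Nf.

    The bottleneck occupies generations ``start .. start + duration - 1``;
    generation t is sampled at size Nf inside that window and N0 outside.
    Heterozygosity decays by (1 - 1/(2 Nf)) per bottleneck generation.
    """

    N0: int
    Nf: int
    start: int
    duration: int
    p0: float
    ngen: int
    nrep: int = 1
    seed: int = 0

    def __post_init__(self):
        _check_positive_int(self.N0, "N0")
        _check_positive_int(self.Nf, "Nf")
        _check_positive_int(self.nrep, "nrep")
        if self.Nf > self.N0:
            raise DomainError("bottleneck size Nf must not exceed N0")
        if self.ngen < 0:
            raise DomainError("ngen must be >= 0")
        if self.start < 0 or self.duration < 0 or self.start + self.duration > self.ngen + 1:
            raise DomainError("bottleneck window must lie within [0, ngen]")
        if not (0.0 <= self.p0 <= 1.0):
            raise DomainError(f"p0={self.p0!r} must lie in [0, 1]")

    def size_track(self) -> np.ndarray:
        sizes = np.full(self.ngen + 1, self.N0, dtype=int)
        sizes[self.start:self.start + self.duration] = self.Nf
        return sizes


def founder_event(params: FounderParams,
                  seed: Optional[SeedLike] = None) -> ReplicateTrajectories:
    """Drift with a time-varying population size; the size track is attached."""
    seeds = replicate_seed_sequences(params.seed if seed is None else seed, params.nrep)
    sizes = params.size_track()
    out = _run_replicates(params.nrep, params.ngen, params.p0, seeds,
                          size_at=lambda t: int(sizes[t]))
    out.sizes = sizes
    return out
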