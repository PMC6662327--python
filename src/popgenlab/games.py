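"""Hawk-dove game under discrete-time replicator dynamics.

Two behavioural strategies, "hawk" (escalate) and "dove" (display/share),
meet at random in an infinite population.  With resource value ``v`` and
fight cost ``c`` the classic payoff matrix is

    HH = (v - c) / 2      HD = v
    DH = 0                DD = v / 2

Payoffs become fitnesses after adding a positive ``baseline`` offset, and
the hawk frequency evolves by the discrete replicator map

    p' = p wH / (p wH + (1 - p) wD).

For ``c > v > 0`` the unique evolutionarily stable strategy is the mixture
with hawk frequency v / c, even though population mean payoff is maximised
by an all-dove population.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .detsel import EquilibriumReport, Equilibrium, Trajectory, _check_freq
from .errors import DomainError, InvalidBaselineError

__all__ = [
    "PayoffMatrix",
    "strategy_fitness",
    "mean_payoff",
    "hawkdove_step",
    "hawkdove_trajectory",
    "hawkdove_equilibrium",
    "hawkdove_to_csv",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """2x2 hawk-dove payoffs plus a baseline fitness offset.

    Entry ``XY`` is the payoff to a strategy-X individual meeting a
    strategy-Y opponent.  ``baseline + min(payoffs)`` must be positive so
    the replicator map is always defined.
    """

    HH: float
    HD: float
    DH: float
    DD: float
    baseline: float = 0.0

    def __post_init__(self):
        for name in ("HH", "HD", "DH", "DD", "baseline"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"payoff entry {name}={v!r} must be finite")
        if self.baseline < 0:
            raise DomainError("baseline must be non-negative")
        if self.baseline + min(self.HH, self.HD, self.DH, self.DD) <= 0:
            raise InvalidBaselineError(
                "baseline + min(payoff) must be > 0 for positive fitnesses"
            )

    @classmethod
    def classic(cls, v: float = 2.0, c: float = 4.0,
                baseline: Optional[float] = None) -> "PayoffMatrix":
        """Classic value/cost parameterisation.

        Default baseline is twice the largest payoff magnitude, which keeps
        every fitness strictly positive for any v, c > 0.
        """
        entries = ((v - c) / 2.0, v, 0.0, v / 2.0)
        if baseline is None:
            baseline = 2.0 * max(abs(x) for x in entries)
        return cls(*entries, baseline=baseline)


def strategy_fitness(p: float, M: PayoffMatrix) -> Tuple[float, float]:
    """Expected fitness of hawk and dove at hawk frequency ``p``.

    Opponents are met in proportion to their population frequency, so
    wH = baseline + p HH + (1-p) HD and wD = baseline + p DH + (1-p) DD.
    """
    p = _check_freq(p)
    wH = M.baseline + p * M.HH + (1.0 - p) * M.HD
    wD = M.baseline + p * M.DH + (1.0 - p) * M.DD
    return wH, wD


def mean_payoff(p: float, M: PayoffMatrix) -> float:
    """Population mean payoff (baseline excluded) at hawk frequency ``p``."""
    p = _check_freq(p)
    q = 1.0 - p
    return (p * (p * M.HH + q * M.HD)) + (q * (p * M.DH + q * M.DD))


def hawkdove_step(p: float, M: PayoffMatrix) -> float:
    """One generation of the discrete replicator map."""
    wH, wD = strategy_fitness(p, M)
    if (p > 0 and wH <= 0) or (p < 1 and wD <= 0):
        raise InvalidBaselineError("non-positive strategy fitness; raise the baseline")
    denom = p * wH + (1.0 - p) * wD
    return min(1.0, max(0.0, p * wH / denom))


def hawkdove_trajectory(p0: float, M: PayoffMatrix, ngen: int) -> Trajectory:
    """Iterate the replicator map, recording hawk frequency and mean payoff."""
    p0 = _check_freq(p0, "p0")
    if ngen < 0:
        raise DomainError("ngen must be >= 0")
    p = np.empty(ngen + 1)
    payoff = np.empty(ngen + 1)
    p[0] = p0
    payoff[0] = mean_payoff(p0, M)
    for t in range(1, ngen + 1):
        p[t] = hawkdove_step(p[t - 1], M)
        payoff[t] = mean_payoff(p[t], M)
    return Trajectory(p=p, wbar=payoff, label="hawk-dove")


def hawkdove_equilibrium(M: PayoffMatrix) -> EquilibriumReport:
    """Fixed points of the replicator map with stability classification.

    The interior candidate p* = (DD - HD) / (HH - HD - DH + DD) is reported
    when it lies strictly inside (0, 1); a vanishing denominator simply
    means no interior equilibrium.  Stability is read off the numerical
    derivative of the map; in a fully degenerate game (all payoffs equal)
    every frequency is neutral and the boundaries are reported semistable.
    """
    step = lambda p: hawkdove_step(p, M)
    eqs = [Equilibrium(0.0, _boundary_stability(step, 0.0))]
    denom = M.HH - M.HD - M.DH + M.DD
    if denom != 0.0:
        p_star = (M.DD - M.HD) / denom
        if 0.0 < p_star < 1.0:
            eqs.append(Equilibrium(p_star, _interior_stability(step, p_star)))
    eqs.append(Equilibrium(1.0, _boundary_stability(step, 1.0)))
    return EquilibriumReport(equilibria=tuple(eqs))


def _interior_stability(step, p_star: float) -> str:
    h = 1e-6
    lo, hi = p_star - h, p_star + h
    d = (step(hi) - step(lo)) / (hi - lo)
    if abs(abs(d) - 1.0) < 1e-6:
        return "semistable"
    return "stable" if abs(d) < 1.0 else "unstable"


def _boundary_stability(step, boundary: float) -> str:
    eps = 1e-6
    p = eps if boundary == 0.0 else 1.0 - eps
    d = step(p) - p
    if abs(d) < 1e-15:
        return "semistable"
    moving_in = (d < 0) if boundary == 0.0 else (d > 0)
    return "stable" if moving_in else "unstable"


def hawkdove_to_csv(traj: Trajectory, path, delimiter: str = ",") -> None:
    """Write ``generation,p_hawk,p_dove,mean_payoff`` rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["generation", "p_hawk", "p_dove", "mean_payoff"])
        for t, p in enumerate(traj.p):
            writer.writerow(
                [t, repr(float(p)), repr(float(1.0 - p)),
                 repr(float(traj.wbar[t])) if traj.wbar is not None else ""]
            )
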