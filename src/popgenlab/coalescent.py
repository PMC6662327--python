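"""Forward-time Wright-Fisher genealogies and coalescence statistics.

Simulates the full parent-offspring pedigree of ``n`` haploid gene copies
over ``ngen`` discrete generations: every copy picks its parent uniformly at
random from the previous generation.  Tracing sampled copies back through
the pedigree exposes coalescence (lineage merging): for a pair of copies
the per-generation coalescence probability is 1/n, so the expected pairwise
time to the most recent common ancestor (TMRCA) is n generations.

Genealogies export to Newick (branch lengths in generations, ultrametric)
and to a plotting layout in which sibling copies are placed adjacently.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Optional, Tuple

import numpy as np

from .errors import DomainError, NotCoalescedError

__all__ = [
    "GenealogyMatrix",
    "LineageTrace",
    "GenealogyLayout",
    "simulate_genealogy",
    "trace_lineages",
    "mrca_generation",
    "genealogy_to_newick",
    "layout_genealogy",
]


@dataclass
class GenealogyMatrix:
    """Parent assignments for n gene copies over ngen generations.

    ``parent[t, i]`` is the index (in 0..n-1) of the parent, living in
    generation t, of copy i in generation t + 1.  Generations are numbered
    0 (founding) through ngen (present); generation 0 has no parents, so
    the matrix has ``ngen`` rows.
    """

    parent: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        if self.parent.ndim != 2:
            raise DomainError("parent matrix must be 2-D (ngen x n)")
        n = self.parent.shape[1]
        if n < 1:
            raise DomainError("need at least one gene copy")
        if self.parent.size and (self.parent.min() < 0 or self.parent.max() >= n):
            raise DomainError("parent indices must lie in [0, n-1]")

    @property
    def n(self) -> int:
        return self.parent.shape[1]

    @property
    def ngen(self) -> int:
        return self.parent.shape[0]

    def to_csv(self, path, delimiter: str = ",") -> None:
        """Edge list ``generation,child,parent`` (generation of the child)."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(["generation", "child", "parent"])
            for t in range(self.ngen):
                for child in range(self.n):
                    writer.writerow([t + 1, child, int(self.parent[t, child])])


def simulate_genealogy(n: int, ngen: int, seed) -> GenealogyMatrix:
    """Simulate the Wright-Fisher pedigree of ``n`` copies over ``ngen`` generations.

    Each copy draws its parent independently and uniformly; deterministic
    given the seed.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if ngen < 1:
        raise DomainError("ngen must be >= 1")
    rng = np.random.default_rng(seed)
    parent = rng.integers(0, n, size=(ngen, n))
    return GenealogyMatrix(parent=parent,
                           seed=seed if isinstance(seed, int) else None)


@dataclass
class LineageTrace:
    """Ancestor sets of a sample, traced back generation by generation.

    ``ancestors[k]`` is the set of ancestor indices at generation
    ``ngen - k`` (k = 0 is the sample itself); ``lineage_count`` is the
    matching number of distinct lineages, non-increasing back in time.
    """

    sample: FrozenSet[int]
    ancestors: List[FrozenSet[int]]
    lineage_count: np.ndarray
    ngen: int

    def ancestors_at(self, generation: int) -> FrozenSet[int]:
        return self.ancestors[self.ngen - generation]


def _check_sample(G: GenealogyMatrix, sample: Iterable[int]) -> List[int]:
    s = sorted(set(int(i) for i in sample))
    if not s:
        raise DomainError("sample must be non-empty")
    if s[0] < 0 or s[-1] >= G.n:
        raise DomainError(f"sample indices must lie in [0, {G.n - 1}]")
    return s


def trace_lineages(G: GenealogyMatrix, sample: Iterable[int]) -> LineageTrace:
    """Trace the sampled copies of the final generation back to generation 0."""
    s = _check_sample(G, sample)
    cur = frozenset(s)
    ancestors = [cur]
    for t in range(G.ngen, 0, -1):
        row = G.parent[t - 1]
        cur = frozenset(int(row[i]) for i in cur)
        ancestors.append(cur)
    counts = np.array([len(a) for a in ancestors], dtype=int)
    return LineageTrace(sample=frozenset(s), ancestors=ancestors,
                        lineage_count=counts, ngen=G.ngen)


def mrca_generation(G: GenealogyMatrix, sample: Iterable[int]) -> Optional[int]:
    """Most recent generation at which the sample has a single ancestor.

    Returns None when the sample never coalesces within the simulated
    window.  A singleton sample trivially coalesces in the final generation.
    """
    trace = trace_lineages(G, sample)
    for k, count in enumerate(trace.lineage_count):
        if count == 1:
            return G.ngen - k
    return None


def genealogy_to_newick(G: GenealogyMatrix, sample: Iterable[int]) -> str:
    """Rooted ultrametric Newick tree of the sample, branch lengths in generations.

    Tip labels are the sampled copy indices; every root-to-tip path length
    equals (final generation - MRCA generation).  Raises
    :class:`NotCoalescedError` when the sample has no in-window MRCA.
    """
    s = _check_sample(G, sample)
    # nodes: ancestor index -> (newick fragment, branch length accumulated so far)
    nodes = {i: (str(i), 0) for i in s}
    gen = G.ngen
    while len(nodes) > 1 and gen > 0:
        row = G.parent[gen - 1]
        groups: dict = {}
        for idx in sorted(nodes):
            frag, blen = nodes[idx]
            groups.setdefault(int(row[idx]), []).append((frag, blen + 1))
        nodes = {}
        for par, members in groups.items():
            if len(members) == 1:
                nodes[par] = members[0]
            else:
                frag = "(" + ",".join(f"{f}:{b}" for f, b in members) + ")"
                nodes[par] = (frag, 0)
        gen -= 1
    if len(nodes) > 1:
        raise NotCoalescedError(
            f"sample has {len(nodes)} surviving lineages at generation 0; no MRCA"
        )
    (frag, blen), = nodes.values()
    if not frag.startswith("("):  # singleton sample: make a valid one-tip tree
        return f"({frag}:{blen});" if blen else f"({frag}:0);"
    return frag + ";"


@dataclass
class GenealogyLayout:
    """Horizontal plotting positions plus child-parent line segments.

    ``positions[t, i]`` is the column at which copy i of generation t is
    drawn; each row is a permutation of 0..n-1.  ``segments`` holds one
    ((x_child, t), (x_parent, t - 1)) pair per child copy.
    """

    positions: np.ndarray
    segments: List[Tuple[Tuple[float, int], Tuple[float, int]]]


def layout_genealogy(G: GenealogyMatrix) -> GenealogyLayout:
    """Order copies so siblings sit together and parent order is preserved.

    Generation 0 keeps its natural order; every later generation is stably
    sorted by (parent's drawn position, own index), working from past to
    present.  The result is deterministic and keeps lineages readable.
    """
    n, ngen = G.n, G.ngen
    positions = np.empty((ngen + 1, n), dtype=int)
    positions[0] = np.arange(n)
    for t in range(1, ngen + 1):
        parents = G.parent[t - 1]
        order = sorted(range(n), key=lambda i: (positions[t - 1][parents[i]], i))
        for rank, copy in enumerate(order):
            positions[t][copy] = rank
    segments = []
    for t in range(1, ngen + 1):
        for i in range(n):
            segments.append(
                ((float(positions[t][i]), t),
                 (float(positions[t - 1][G.parent[t - 1, i]]), t - 1))
            )
    return GenealogyLayout(positions=positions, segments=segments)
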