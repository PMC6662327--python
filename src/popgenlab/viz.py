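"""Static and animated visualisation of model outputs.

Renders the standard plots (frequency trajectories, the mean-fitness
landscape, cobweb diagrams of the one-dimensional frequency map, and
Wright-Fisher genealogies) to PNG/SVG, and assembles frame sequences into
animated GIFs.  The testable surface is the geometry — cobweb segment
lists, layout line segments, frame counts — not pixels.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple, Union

import matplotlib

matplotlib.use("Agg")

import imageio.v3 as iio
import matplotlib.pyplot as plt
import numpy as np

from .coalescent import GenealogyLayout, GenealogyMatrix, layout_genealogy
from .detsel import FitnessScheme, Trajectory, mean_fitness
from .errors import DomainError, FrameMismatchError
from .wfsim import ReplicateTrajectories

__all__ = [
    "CobwebDiagram",
    "render_cobweb",
    "render_trajectory",
    "landscape_curve",
    "render_landscape",
    "render_genealogy",
    "export_animation",
    "figure_to_frame",
    "trajectory_frames",
]

Segment = Tuple[Tuple[float, float], Tuple[float, float]]


@dataclass
class CobwebDiagram:
    """Staircase geometry of graphical iteration of a 1-D map.

    ``segments`` alternates vertical ((x, y_prev) -> (x, y)) and horizontal
    ((x, y) -> (y, y)) pieces: exactly two per iteration, starting from
    (p0, p0) on the identity diagonal.
    """

    p0: float
    segments: List[Segment]
    path: Optional[str] = None

    @property
    def endpoint(self) -> float:
        return self.segments[-1][1][1] if self.segments else self.p0


def render_cobweb(step_map: Callable[[float], float], p0: float, nsteps: int,
                  path=None, ngrid: int = 201, title: str = "") -> CobwebDiagram:
    """Cobweb plot of ``step_map``: curve, identity diagonal, staircase.

    Returns the exact staircase segment list; writes an image when ``path``
    is given.  Raises :class:`DomainError` if the map leaves [0, 1].
    """
    if nsteps < 1:
        raise DomainError("nsteps must be >= 1")
    if not (0.0 <= p0 <= 1.0):
        raise DomainError("p0 must lie in [0, 1]")
    segments: List[Segment] = []
    x, y_prev = p0, p0
    for _ in range(nsteps):
        y = step_map(x)
        if not (0.0 <= y <= 1.0) or math.isnan(y):
            raise DomainError(f"map value {y!r} at p={x!r} leaves [0, 1]")
        segments.append(((x, y_prev), (x, y)))   # vertical: up/down to the curve
        segments.append(((x, y), (y, y)))        # horizontal: across to the diagonal
        x, y_prev = y, y
    if path is not None:
        grid = np.linspace(0.0, 1.0, ngrid)
        curve = np.array([step_map(g) for g in grid])
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(grid, curve, lw=1.5, label=r"$p_{t+1}$")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        xs = [s for seg in segments for s in (seg[0], seg[1])]
        ax.plot([pt[0] for pt in xs], [pt[1] for pt in xs], color="C3", lw=0.9)
        ax.set_xlabel(r"$p_t$")
        ax.set_ylabel(r"$p_{t+1}$")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        if title:
            ax.set_title(title)
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return CobwebDiagram(p0=p0, segments=segments,
                         path=str(path) if path is not None else None)


def render_trajectory(traj: Union[Trajectory, ReplicateTrajectories], path,
                      title: str = "", ylabel: str = "allele frequency (p)") -> str:
    """Plot one line per series (replicate) of generation vs frequency."""
    if isinstance(traj, Trajectory):
        series = traj.p[np.newaxis, :]
    else:
        series = traj.p
    fig, ax = plt.subplots(figsize=(6, 4))
    gens = np.arange(series.shape[1])
    for row in series:
        ax.plot(gens, row, lw=0.8 if series.shape[0] > 1 else 1.6)
    ax.set_xlabel("generation")
    ax.set_ylabel(ylabel)
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return str(path)


def landscape_curve(w: FitnessScheme, ngrid: int = 201) -> Tuple[np.ndarray, np.ndarray]:
    """The (p, mean fitness) curve drawn by :func:`render_landscape`."""
    if ngrid < 201:
        ngrid = 201
    grid = np.linspace(0.0, 1.0, ngrid)
    return grid, np.array([mean_fitness(p, w) for p in grid])


def render_landscape(w: FitnessScheme, path, ngrid: int = 201) -> str:
    """Adaptive landscape: mean fitness as a function of allele frequency."""
    grid, wbar = landscape_curve(w, ngrid)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(grid, wbar, lw=1.6)
    ax.set_xlabel("allele frequency (p)")
    ax.set_ylabel(r"mean fitness ($\bar{w}$)")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return str(path)


def render_genealogy(G: GenealogyMatrix, path,
                     layout: Optional[GenealogyLayout] = None) -> str:
    """Draw the pedigree: copies on a grid, one segment per child-parent link.

    Generation 0 (founders) is at the top; n*(ngen+1) points and n*ngen
    segments in total.
    """
    if layout is None:
        layout = layout_genealogy(G)
    fig, ax = plt.subplots(figsize=(6, 6))
    for (x1, t1), (x0, t0) in layout.segments:
        ax.plot([x1, x0], [t1, t0], color="0.5", lw=0.7, zorder=1)
    for t in range(G.ngen + 1):
        ax.scatter(layout.positions[t], np.full(G.n, t), s=14, color="C0", zorder=2)
    ax.set_xlabel("gene copy")
    ax.set_ylabel("generation")
    ax.invert_yaxis()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return str(path)


def figure_to_frame(fig) -> np.ndarray:
    """Rasterise a matplotlib figure to an RGB array (one animation frame)."""
    buf = io.BytesIO()
    fig.savefig(buf, format="png")
    buf.seek(0)
    return iio.imread(buf.getvalue(), extension=".png")[..., :3]


def trajectory_frames(traj: Trajectory, step: int = 1, dpi: int = 60) -> List[np.ndarray]:
    """Cumulative-line frames of a trajectory for GIF assembly."""
    frames = []
    gens = np.arange(traj.p.size)
    for end in range(1, traj.p.size + 1, max(1, step)):
        fig, ax = plt.subplots(figsize=(5, 3.5), dpi=dpi)
        ax.plot(gens[:end], traj.p[:end], lw=1.6)
        ax.set_xlim(0, max(1, traj.generations))
        ax.set_ylim(-0.02, 1.02)
        ax.set_xlabel("generation")
        ax.set_ylabel("p")
        frames.append(figure_to_frame(fig))
        plt.close(fig)
    return frames


def export_animation(frames: Sequence[Union[np.ndarray, str]], delay_ms: float,
                     path) -> str:
    """Assemble equally-sized frames into an animated GIF.

    ``frames`` may be RGB arrays or image file paths; all must share
    identical dimensions.  ``delay_ms`` is the per-frame display time.
    """
    if len(frames) < 1:
        raise DomainError("need at least one frame")
    arrays = []
    for f in frames:
        arr = f if isinstance(f, np.ndarray) else iio.imread(f)
        arrays.append(np.asarray(arr))
    shape = arrays[0].shape
    for i, arr in enumerate(arrays):
        if arr.shape != shape:
            raise FrameMismatchError(
                f"frame {i} has shape {arr.shape}, expected {shape}"
            )
    iio.imwrite(path, np.stack(arrays), extension=".gif",
                duration=delay_ms, loop=0)
    return str(path)
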