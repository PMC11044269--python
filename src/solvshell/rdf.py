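"""Solute-solvent radial distribution functions and shell-separation diagnostics.

The RDF is the single-solute (infinite-dilution) pair distribution: the
histogram of solute-site distances, normalized per frame by the
ideal-gas expectation ``rho * V_shell`` with ``rho`` the mean solvent
site number density.  A shell-segmented variant splits each pair's
contribution according to whether the solvent molecule belongs to the
first shell in that frame; the two segments sum bin-wise to the total.

The quality of a shell definition is diagnosed by where the first-shell
and remainder segments cross (an estimate of the shell boundary) and by
the trapezoidal area under ``min(g_first, g_remainder)`` (zero for a
sharp radial cutoff, positive whenever the definition lets first-shell
ligands sit beyond remainder ligands or vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .shells import ShellSeries
from .trajectory import Topology, Trajectory, minimum_image

__all__ = [
    "RDFResult",
    "ShellSeparation",
    "FirstMinimum",
    "RDFError",
    "compute_rdf",
    "find_first_minimum",
    "segment_rdf",
    "separation_diagnostics",
]

DEFAULT_BIN_WIDTH = 0.05  # Angstrom
#: fraction of the smallest box edge used as the default r_max
DEFAULT_RMAX_FRACTION = 0.49


class RDFError(ValueError):
    """RDF computation or feature detection failed."""


@dataclass
class RDFResult:
    """Binned g(r) with normalization metadata."""

    r: np.ndarray  # bin centers, Angstrom
    g: np.ndarray
    segment: str = "total"  # total | first_shell | remainder
    n_frames: int = 0
    density: float = 0.0  # mean solvent site density, A^-3
    bin_width: float = DEFAULT_BIN_WIDTH


@dataclass
class ShellSeparation:
    """Crossing distance and overlap area of the two RDF segments."""

    intersection_distance: float  # Angstrom
    overlap_area: float  # dimensionless (integral of min(g1, g2) dr)


@dataclass
class FirstMinimum:
    """First RDF minimum: smoothed location (``r``) and raw-bin location."""

    r: float
    r_raw: float


def _distance_histogram(
    trajectory: Trajectory,
    topology: Topology,
    edges: np.ndarray,
    shells: ShellSeries | None = None,
):
    """Histogram solute-site distances; optionally split by shell membership."""
    mols = topology.solvent_molecules
    total = np.zeros(len(edges) - 1)
    first = np.zeros(len(edges) - 1)
    dens = 0.0
    for fi, frame in enumerate(trajectory):
        sites = np.array([frame.coords[topology.solvent_sites[m]] for m in mols])
        rel = minimum_image(sites - frame.coords[topology.solute_site], frame.box)
        r = np.linalg.norm(rel, axis=1)
        total += np.histogram(r, bins=edges)[0]
        if shells is not None:
            inside = np.array([m in shells.members[fi] for m in mols], dtype=bool)
            first += np.histogram(r[inside], bins=edges)[0]
        dens += len(mols) / float(np.prod(frame.box))
    return total, first, dens / trajectory.n_frames


def _normalize(counts: np.ndarray, edges: np.ndarray, n_frames: int, density: float) -> np.ndarray:
    vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    return counts / (n_frames * density * vol)


def _check_geometry(trajectory: Trajectory, r_max: float | None) -> float:
    min_edge = min(float(f.box.min()) for f in trajectory)
    if r_max is None:
        return DEFAULT_RMAX_FRACTION * min_edge
    if r_max > 0.5 * min_edge:
        raise RDFError(
            f"r_max = {r_max} exceeds half the smallest box edge ({0.5 * min_edge:.3f} A)"
        )
    return r_max


def compute_rdf(
    trajectory: Trajectory,
    topology: Topology,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float | None = None,
) -> RDFResult:
    """Single-solute RDF of solute-site pairs, normalized to 1 in the bulk."""
    r_max = _check_geometry(trajectory, r_max)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, _, density = _distance_histogram(trajectory, topology, edges)
    g = _normalize(counts, edges, trajectory.n_frames, density)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(r=centers, g=g, segment="total", n_frames=trajectory.n_frames,
                     density=density, bin_width=bin_width)


def segment_rdf(
    trajectory: Trajectory,
    topology: Topology,
    shells: ShellSeries,
    bin_width: float = DEFAULT_BIN_WIDTH,
    r_max: float | None = None,
) -> tuple[RDFResult, RDFResult, RDFResult]:
    """Total, first-shell and remainder RDFs sharing one bin grid.

    A pair contributes to the first-shell segment iff the solvent
    molecule is a member of that frame's shell set; segments sum to the
    total bin-wise.
    """
    if shells.n_frames != trajectory.n_frames:
        raise RDFError(
            f"shell series has {shells.n_frames} frames, trajectory has {trajectory.n_frames}"
        )
    r_max = _check_geometry(trajectory, r_max)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, counts_first, density = _distance_histogram(trajectory, topology, edges, shells)
    centers = 0.5 * (edges[1:] + edges[:-1])
    nf = trajectory.n_frames

    def mk(c, seg):
        return RDFResult(r=centers, g=_normalize(c, edges, nf, density), segment=seg,
                         n_frames=nf, density=density, bin_width=bin_width)

    return mk(counts, "total"), mk(counts_first, "first_shell"), mk(counts - counts_first, "remainder")


def _moving_average(y: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(y, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def find_first_minimum(
    rdf: RDFResult,
    window: tuple[float, float],
    smooth_width: int = 5,
) -> FirstMinimum:
    """Locate the minimum between the first and second RDF peaks.

    A ``smooth_width``-point moving average is applied before locating
    the first local maximum inside ``window`` and the lowest smoothed bin
    after it; the raw-bin minimum over the same span is reported
    alongside.  Raises :class:`RDFError` when no interior first peak or
    minimum exists (monotone or flat g).
    """
    lo, hi = window
    sm = _moving_average(rdf.g, smooth_width)
    sel = np.nonzero((rdf.r >= lo) & (rdf.r <= hi))[0]
    if len(sel) < 5:
        raise RDFError("search window contains too few bins")
    w = sm[sel]
    # first strict local maximum inside the window
    peak = None
    for i in range(1, len(w) - 1):
        if w[i] > w[i - 1] and w[i] >= w[i + 1]:
            peak = i
            break
    if peak is None:
        raise RDFError("no resolved first peak inside the search window")
    tail = w[peak:]
    v = int(np.argmin(tail)) + peak
    if v == peak or v >= len(w) - 1:
        raise RDFError("no interior minimum found after the first peak")
    raw = rdf.g[sel]
    v_raw = int(np.argmin(raw[peak:])) + peak
    return FirstMinimum(r=float(rdf.r[sel[v]]), r_raw=float(rdf.r[sel[v_raw]]))


def separation_diagnostics(first_shell: RDFResult, remainder: RDFResult) -> ShellSeparation:
    """Crossing distance and trapezoidal overlap area of the two segments.

    The crossing is the first point after the first-shell peak where the
    remainder segment reaches the first-shell segment, located by linear
    interpolation between the bracketing bins.  The overlap area
    ``integral of min(g_first, g_remainder) dr`` is symmetric in the two
    segments and zero for a sharp radial cutoff.
    """
    if first_shell.r.shape != remainder.r.shape or not np.allclose(first_shell.r, remainder.r):
        raise RDFError("segments must share identical bins")
    g1, g2, r = first_shell.g, remainder.g, first_shell.r
    peak = int(np.argmax(g1))
    diff = g2 - g1
    cross = None
    for i in range(peak, len(r)):
        if diff[i] >= 0.0:
            cross = i
            break
    if cross is None:
        raise RDFError("segments never cross after the first-shell peak")
    if cross == peak or diff[cross] == 0.0 or diff[cross - 1] == diff[cross]:
        x = float(r[cross])
    else:
        # linear interpolation on the sign change of (g_remainder - g_first)
        f = -diff[cross - 1] / (diff[cross] - diff[cross - 1])
        x = float(r[cross - 1] + f * (r[cross] - r[cross - 1]))
    area = float(np.trapezoid(np.minimum(g1, g2), r))
    return ShellSeparation(intersection_distance=x, overlap_area=area)
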