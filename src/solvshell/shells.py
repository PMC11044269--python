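"""First-solvation-shell ligand assignment.

Four nearest-neighbor criteria are implemented:

GC
    radial cutoff at the first RDF minimum r_m: every solvent site within
    r_m of the solute belongs to the first shell (boundary inclusive).
RAD / RAD_open
    relative angular distance.  Candidates are scanned outward from the
    solute i; candidate j is blocked by an already accepted closer ligand
    k when ``1/r_ij^2 <= cos(theta_jik)/r_ik^2``.  The closed variant
    stops scanning at the first blocked candidate; the open variant
    continues past rejections.
MV
    modified Voronoi.  j is a direct neighbor of i when its pair vector
    pierces the shared Voronoi face, equivalent to the pair-distance
    inequality ``r_ik^2 + r_jk^2 > f_c * r_ij^2`` holding for every other
    site k.  f_c = 1 reproduces the geometric direct-neighbor definition;
    lower values loosen the criterion.

Assignment is per molecule via its representative site, per frame, with
no temporal smoothing.  All positions are first reduced to the
solute-centered minimum-image copy, so every pair distance used by the
criteria is consistent with one local, unwrapped picture of the shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory import Frame, Topology, Trajectory, minimum_image

__all__ = [
    "GCParams",
    "MVParams",
    "ShellSeries",
    "assign_gc",
    "assign_rad",
    "assign_mv",
    "assign_series",
    "gc_members",
    "rad_members",
    "mv_members",
]


@dataclass
class GCParams:
    """Radial-cutoff parameters: ``r_m`` in Angstrom (> 0)."""

    r_m: float

    def __post_init__(self) -> None:
        if self.r_m <= 0:
            raise ValueError("GC cutoff r_m must be positive")


@dataclass
class MVParams:
    """Modified-Voronoi parameters: ``f_c`` in (0, 1], default 1.0."""

    f_c: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.f_c <= 1.0:
            raise ValueError("f_c must lie in (0, 1]")


@dataclass
class ShellSeries:
    """Per-frame first-shell membership for one method.

    ``members[f]`` is the frozenset of solvent molecule ids in the first
    shell at frame f; ``cn`` is the corresponding coordination-number
    series.
    """

    method: str
    members: list[frozenset[int]]
    times: np.ndarray
    dt: float

    @property
    def cn(self) -> np.ndarray:
        return np.array([len(s) for s in self.members], dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.members)

    def all_molecules(self) -> set[int]:
        out: set[int] = set()
        for s in self.members:
            out |= s
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (frame, time_ps, method, molecule_id), one row per membership."""
        rows = [
            (f, self.times[f], self.method, m)
            for f in range(self.n_frames)
            for m in sorted(self.members[f])
        ]
        return pd.DataFrame(rows, columns=["frame", "time_ps", "method", "molecule_id"])


# ---------------------------------------------------------------------------
# core criteria on solute-centered site positions
# ---------------------------------------------------------------------------

def _centered_sites(frame: Frame, topology: Topology) -> tuple[np.ndarray, list[int]]:
    """Minimum-image positions of all solvent representative sites relative to the solute."""
    mols = topology.solvent_molecules
    if not mols:
        return np.empty((0, 3)), []
    sites = np.array([frame.coords[topology.solvent_sites[m]] for m in mols])
    rel = minimum_image(sites - frame.coords[topology.solute_site], frame.box)
    return rel, mols


def gc_members(rel: np.ndarray, r_m: float) -> list[int]:
    """Indices of sites within the cutoff (inclusive boundary)."""
    if len(rel) == 0:
        return []
    r = np.linalg.norm(rel, axis=1)
    return list(np.nonzero(r <= r_m)[0])


def rad_members(rel: np.ndarray, open_variant: bool = False, order: Sequence[int] | None = None) -> list[int]:
    """RAD shell membership for sites at positions ``rel`` around the origin.

    ``order`` optionally fixes the tie-break order of equidistant sites
    (defaults to index-ascending, i.e. molecule id when called through
    :func:`assign_rad`).
    """
    n = len(rel)
    if n == 0:
        return []
    r = np.linalg.norm(rel, axis=1)
    if np.any(r == 0.0):
        raise ValueError("degenerate zero solute-solvent distance in RAD assignment")
    if order is None:
        order = np.lexsort((np.arange(n), r))  # distance, then index ascending
    accepted: list[int] = []
    for j in order:
        blocked = False
        for k in accepted:
            cos_t = np.dot(rel[j], rel[k]) / (r[j] * r[k])
            # Eq.-style RAD inequality: blocked when 1/r_ij^2 <= cos(theta)/r_ik^2
            if 1.0 / r[j] ** 2 <= cos_t / r[k] ** 2:
                blocked = True
                break
        if blocked:
            if not open_variant:
                break
            continue
        accepted.append(int(j))
    return accepted


def mv_members(rel: np.ndarray, f_c: float = 1.0) -> list[int]:
    """Modified-Voronoi direct neighbors of the origin among sites ``rel``."""
    n = len(rel)
    if n == 0:
        return []
    r2 = np.einsum("ij,ij->i", rel, rel)
    if np.any(r2 == 0.0):
        raise ValueError("degenerate coincident site in MV assignment")
    out: list[int] = []
    for j in range(n):
        d2 = np.einsum("ij,ij->i", rel - rel[j], rel - rel[j])  # r_jk^2 for all k
        lhs = r2 + d2  # r_ik^2 + r_jk^2
        lhs[j] = np.inf
        if np.all(lhs > f_c * r2[j]):
            out.append(j)
    return out


# ---------------------------------------------------------------------------
# frame-level assignment
# ---------------------------------------------------------------------------

def assign_gc(frame: Frame, topology: Topology, params: GCParams) -> frozenset[int]:
    """Solvent molecules whose representative site lies within r_m of the solute."""
    rel, mols = _centered_sites(frame, topology)
    return frozenset(mols[i] for i in gc_members(rel, params.r_m))


def assign_rad(frame: Frame, topology: Topology, open_variant: bool = False) -> frozenset[int]:
    """RAD (closed) or RAD_open first-shell molecules."""
    rel, mols = _centered_sites(frame, topology)
    return frozenset(mols[i] for i in rad_members(rel, open_variant=open_variant))


def assign_mv(frame: Frame, topology: Topology, params: MVParams | None = None) -> frozenset[int]:
    """Modified-Voronoi direct-neighbor molecules of the solute."""
    params = params or MVParams()
    rel, mols = _centered_sites(frame, topology)
    return frozenset(mols[i] for i in mv_members(rel, f_c=params.f_c))


METHODS = ("GC", "RAD", "RAD_open", "MV")


def assign_series(
    trajectory: Trajectory,
    topology: Topology,
    method: str,
    params: GCParams | MVParams | None = None,
) -> ShellSeries:
    """Assign the first shell on every frame with one method.

    ``method`` is one of ``GC``, ``RAD``, ``RAD_open``, ``MV``.  GC
    requires :class:`GCParams`; MV accepts optional :class:`MVParams`.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    members: list[frozenset[int]] = []
    for frame in trajectory:
        if method == "GC":
            if not isinstance(params, GCParams):
                raise ValueError("GC assignment requires GCParams(r_m=...)")
            members.append(assign_gc(frame, topology, params))
        elif method == "RAD":
            members.append(assign_rad(frame, topology, open_variant=False))
        elif method == "RAD_open":
            members.append(assign_rad(frame, topology, open_variant=True))
        else:
            mv = params if isinstance(params, MVParams) else MVParams()
            members.append(assign_mv(frame, topology, mv))
    times = np.array([f.time for f in trajectory])
    dt = trajectory.dt if trajectory.n_frames > 1 else 0.0
    return ShellSeries(method=method, members=members, times=times, dt=dt)
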