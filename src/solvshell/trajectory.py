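"""Periodic trajectory data model, extended-XYZ I/O, and minimum-image geometry.

Coordinates are stored exactly as read; no wrapping is ever applied
destructively.  All pair geometry goes through the minimum-image
convention for an orthorhombic cell, which is the only cell shape
supported (triclinic lattices are rejected on input).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Frame",
    "Topology",
    "Trajectory",
    "TrajectoryError",
    "read_extxyz",
    "write_extxyz",
    "minimum_image",
    "min_image_distance",
    "angle_at",
]

#: relative tolerance used when checking frame-time uniformity
DT_RTOL = 1e-6


class TrajectoryError(ValueError):
    """Malformed trajectory input or inconsistent frame data."""


@dataclass
class Frame:
    """One stored configuration of a periodic system.

    Parameters
    ----------
    index:
        Position of the frame in the trajectory (>= 0).
    time:
        Frame time in ps; must be nondecreasing along a trajectory.
    box:
        Orthorhombic edge lengths (a, b, c) in Angstrom, all > 0.
    coords:
        ``(n_atoms, 3)`` Cartesian coordinates in Angstrom, unwrapped.
    species:
        Per-atom element labels, length ``n_atoms``.
    """

    index: int
    time: float
    box: np.ndarray
    coords: np.ndarray
    species: list[str]

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if np.any(self.box <= 0):
            raise TrajectoryError(f"frame {self.index}: box edges must be positive, got {self.box}")
        if len(self.species) != len(self.coords):
            raise TrajectoryError(
                f"frame {self.index}: {len(self.coords)} coordinates but "
                f"{len(self.species)} species labels"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass
class Topology:
    """Partition of atoms into molecules plus the analysis sites.

    ``molecules`` assigns every atom index to exactly one molecule.  One
    molecule is the solute; each solvent molecule is represented by a
    single site (e.g. the O of H2O, the C of DCM) picked by
    ``solvent_site_selector`` — an element label, or a callable mapping
    ``(molecule_atom_indices, species)`` to one atom index.
    """

    molecules: Sequence[Sequence[int]]
    solute_site: int
    solvent_site_selector: str | Callable[[Sequence[int], list[str]], int] = "O"
    #: filled by :meth:`bind`; molecule id -> representative atom index
    solvent_sites: dict[int, int] = field(default_factory=dict)
    solute_molecule: int = -1

    def bind(self, species: list[str]) -> "Topology":
        """Resolve representative sites against a species list; validates the partition."""
        seen: set[int] = set()
        n_atoms = len(species)
        for mol in self.molecules:
            for a in mol:
                if a in seen:
                    raise TrajectoryError(f"atom {a} assigned to more than one molecule")
                seen.add(a)
        if seen != set(range(n_atoms)):
            missing = sorted(set(range(n_atoms)) - seen)[:5]
            raise TrajectoryError(f"molecule partition does not cover all atoms (missing {missing}...)")

        self.solute_molecule = -1
        for m, mol in enumerate(self.molecules):
            if self.solute_site in mol:
                self.solute_molecule = m
                break
        if self.solute_molecule < 0:
            raise TrajectoryError(f"solute site {self.solute_site} not found in any molecule")

        self.solvent_sites = {}
        for m, mol in enumerate(self.molecules):
            if m == self.solute_molecule:
                continue
            if callable(self.solvent_site_selector):
                idx = self.solvent_site_selector(mol, species)
            else:
                matches = [a for a in mol if species[a] == self.solvent_site_selector]
                if not matches:
                    raise TrajectoryError(
                        f"molecule {m} has no atom of element {self.solvent_site_selector!r}"
                    )
                idx = matches[0]
            self.solvent_sites[m] = idx
        return self

    @property
    def solvent_molecules(self) -> list[int]:
        return sorted(self.solvent_sites)


@dataclass
class Trajectory:
    """Ordered frames with uniform time spacing."""

    frames: list[Frame]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("trajectory must contain at least one frame")
        n0 = self.frames[0].n_atoms
        for f in self.frames:
            if f.n_atoms != n0:
                raise TrajectoryError(
                    f"inconsistent atom count: frame {f.index} has {f.n_atoms}, expected {n0}"
                )
        times = np.array([f.time for f in self.frames])
        if np.any(np.diff(times) < 0):
            raise TrajectoryError("frame times must be nondecreasing")
        if len(times) >= 3:
            steps = np.diff(times)
            if steps[0] > 0 and np.any(np.abs(steps - steps[0]) > DT_RTOL * max(steps[0], 1.0)):
                raise TrajectoryError("nonuniform frame spacing; dynamic analyses assume uniform dt")

    @property
    def dt(self) -> float:
        """Spacing between stored frames in ps (inferred from the first two frames)."""
        if len(self.frames) < 2:
            raise TrajectoryError("dt undefined for a single-frame trajectory")
        return self.frames[1].time - self.frames[0].time

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def t_sim(self) -> float:
        """Total simulated (observed) time span in ps."""
        return self.frames[-1].time - self.frames[0].time

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# minimum-image geometry
# ---------------------------------------------------------------------------

def minimum_image(dvec: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Reduce displacement vector(s) component-wise into the minimum image.

    Works on a single 3-vector or an ``(n, 3)`` array.
    """
    dvec = np.asarray(dvec, dtype=float)
    box = np.asarray(box, dtype=float)
    return dvec - box * np.round(dvec / box)


def min_image_displacement(frame: Frame, a: int, b: int) -> np.ndarray:
    """Minimum-image displacement vector from atom ``a`` to atom ``b``."""
    return minimum_image(frame.coords[b] - frame.coords[a], frame.box)


def min_image_distance(frame: Frame, a: int, b: int) -> float:
    """Minimum-image distance between atoms ``a`` and ``b`` in Angstrom."""
    return float(np.linalg.norm(min_image_displacement(frame, a, b)))


def angle_at(frame: Frame, i: int, j: int, k: int) -> float:
    """Angle theta_jik at vertex ``i`` between atoms ``j`` and ``k``, in radians.

    Both arms use minimum-image displacement vectors from ``i``.
    """
    u = min_image_displacement(frame, i, j)
    v = min_image_displacement(frame, i, k)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise TrajectoryError("zero-length displacement in angle computation")
    c = np.dot(u, v) / (nu * nv)
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# extended-XYZ I/O
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice\s*=\s*"([^"]+)"', re.IGNORECASE)
_TIME_RE = re.compile(r'\bTime\s*=\s*"?([-+0-9.eE]+)"?', re.IGNORECASE)


def _parse_comment(comment: str, frame_no: int, box_override) -> tuple[np.ndarray, float | None]:
    m = _LATTICE_RE.search(comment)
    if m:
        vals = np.array([float(x) for x in m.group(1).split()])
        if vals.size != 9:
            raise TrajectoryError(f"frame {frame_no}: Lattice must have 9 components")
        cell = vals.reshape(3, 3)
        off = cell - np.diag(np.diag(cell))
        if np.any(np.abs(off) > 1e-10):
            raise TrajectoryError(
                f"frame {frame_no}: non-orthorhombic lattice not supported "
                f"(off-diagonal components present)"
            )
        box = np.diag(cell).copy()
    elif box_override is not None:
        box = np.asarray(box_override, dtype=float).reshape(3)
    else:
        raise TrajectoryError(
            f"frame {frame_no}: no Lattice in comment line and no box_override given"
        )
    t = _TIME_RE.search(comment)
    return box, (float(t.group(1)) if t else None)


def read_extxyz(path: str | Path, box_override: Sequence[float] | None = None) -> Trajectory:
    """Read an extended-XYZ trajectory.

    Each frame: an atom count line, a comment line carrying
    ``Lattice="ax 0 0 0 by 0 0 0 cz"`` and optionally ``Time=<ps>``, then
    one ``element x y z`` line per atom.  If no frame carries a lattice,
    ``box_override`` must supply the edge lengths.  Frames lacking a time
    are numbered at 1 ps spacing.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    n_expected: int | None = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise TrajectoryError(
                f"malformed frame header at line {pos + 1}: {lines[pos]!r}"
            ) from exc
        if pos + 1 + n >= len(lines) + 1 and pos + 1 + n > len(lines):
            raise TrajectoryError(f"truncated frame starting at line {pos + 1}")
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise TrajectoryError(
                f"inconsistent atom count across frames: {n} != {n_expected}"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        box, t = _parse_comment(comment, len(frames), box_override)
        species: list[str] = []
        coords = np.empty((n, 3))
        for a in range(n):
            parts = lines[pos + 2 + a].split()
            if len(parts) < 4:
                raise TrajectoryError(f"malformed atom line {pos + 3 + a}: {lines[pos + 2 + a]!r}")
            species.append(parts[0])
            coords[a] = [float(x) for x in parts[1:4]]
        if t is None:
            t = float(len(frames))
        frames.append(Frame(index=len(frames), time=t, box=box, coords=coords, species=species))
        pos += 2 + n
    if not frames:
        raise TrajectoryError(f"no frames found in {path}")
    return Trajectory(frames=frames, metadata={"source": str(path)})


def write_extxyz(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory in extended-XYZ with per-frame lattice and time."""
    with open(path, "w") as fh:
        for f in trajectory:
            a, b, c = f.box
            fh.write(f"{f.n_atoms}\n")
            fh.write(
                f'Lattice="{a:.10g} 0 0 0 {b:.10g} 0 0 0 {c:.10g}" '
                f'Properties=species:S:1:pos:R:3 Time={f.time:.10g}\n'
            )
            for sp, (x, y, z) in zip(f.species, f.coords):
                fh.write(f"{sp} {x:.10f} {y:.10f} {z:.10f}\n")
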