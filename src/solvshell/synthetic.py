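"""Synthetic fixtures with exact ground truth for every analysis stage.

Three generators are provided:

* :func:`make_static_geometry` — fixed, exactly symmetric coordination
  geometries (octahedron, tetrahedron, simple-cubic lattice, particle
  pair) for pinning down the neighbor criteria;
* :func:`simulate_exchange` — a counting-process model of shell
  exchange: each ligand slot alternates bound and unbound states with
  exponential holding times, optionally perturbed by sub-``t*``
  flickers, and is placed at a shell or bulk radius along a fixed
  direction so that a radial cutoff midway between the radii recovers
  the intended membership exactly.  The ground truth is recorded, not
  inferred;
* :func:`make_ideal_gas` — uniform solvent around a fixed solute, the
  null model for RDF normalization.

The exchange generator is deliberately not a physical liquid: membership
intervals are the model, so every event count is exactly recomputable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Frame, Topology, Trajectory

__all__ = [
    "ExchangeSimParams",
    "GroundTruthLog",
    "make_static_geometry",
    "simulate_exchange",
    "make_ideal_gas",
    "fibonacci_sphere",
]


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` nearly uniformly spread unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def _single_atom_topology(n_atoms: int, solvent_element: str = "O") -> Topology:
    return Topology(
        molecules=[[i] for i in range(n_atoms)],
        solute_site=0,
        solvent_site_selector=solvent_element,
    )


# ---------------------------------------------------------------------------
# static coordination fixtures
# ---------------------------------------------------------------------------

_STATIC_KINDS = ("octahedron", "tetrahedron", "cubic_lattice", "two_particle")


def make_static_geometry(
    kind: str,
    distance: float,
    n_frames: int = 1,
    dt: float = 0.1,
    box: float | None = None,
) -> tuple[Trajectory, Topology]:
    """Exact symmetric solute + solvent-site geometry, repeated over frames.

    ``kind`` is one of octahedron (6 sites), tetrahedron (4),
    cubic_lattice (3x3x3 minus the central solute: 6 at d, 12 at
    d*sqrt(2), 8 at d*sqrt(3)) or two_particle (1 site).  The box is
    large enough that no periodic image comes into play.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if kind == "octahedron":
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        sites = distance * dirs
    elif kind == "tetrahedron":
        dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float) / np.sqrt(3.0)
        sites = distance * dirs
    elif kind == "cubic_lattice":
        offsets = [
            np.array([i, j, k], float)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        sites = distance * np.array(offsets)
    elif kind == "two_particle":
        sites = distance * np.array([[1.0, 0.0, 0.0]])
    else:
        raise ValueError(f"unknown geometry kind {kind!r}; expected one of {_STATIC_KINDS}")

    edge = box if box is not None else max(10.0 * distance, 20.0)
    center = np.full(3, edge / 2.0)
    coords = np.vstack(([center], sites + center))
    species = ["K"] + ["O"] * len(sites)
    frames = [
        Frame(index=f, time=f * dt, box=np.full(3, edge), coords=coords.copy(), species=list(species))
        for f in range(n_frames)
    ]
    topo = _single_atom_topology(len(coords)).bind(species)
    return Trajectory(frames=frames), topo


# ---------------------------------------------------------------------------
# stochastic shell-exchange process
# ---------------------------------------------------------------------------

@dataclass
class ExchangeSimParams:
    """Conditions for the stochastic exchange generator.

    ``tau_true`` is the mean bound (in-shell) holding time in ps — the
    residence time the direct method should recover.  ``tau_unbound`` is
    the mean bulk holding time; its default of 50 ps mimics an ionic
    shell in a dilute bath (a ligand spends far longer in the bulk than
    bound, and the stationary CN is n_slots * tau_true /
    (tau_true + tau_unbound) ~ 4.5 for the defaults).  Flickers are brief
    departures injected into bound intervals at ``flicker_rate`` per ps
    of bound time, with mean duration ``flicker_mean`` intended to stay
    below the minimum excursion time t*.
    """

    n_ligand_slots: int = 50
    tau_true: float = 5.0  # ps, mean bound holding time
    tau_unbound: float = 50.0  # ps, mean unbound holding time
    flicker_rate: float = 0.0  # ps^-1 of bound time
    flicker_mean: float = 0.1  # ps
    dt: float = 0.1  # ps between stored frames
    t_total: float = 500.0  # ps
    seed: int = 0
    shell_radius: float = 2.8  # Angstrom
    bulk_radius: float = 8.0  # Angstrom
    jitter: float = 0.1  # Angstrom, radial; never crosses the midpoint cutoff

    def __post_init__(self) -> None:
        if self.shell_radius >= self.bulk_radius:
            raise ValueError("shell_radius must be smaller than bulk_radius")
        if self.tau_true <= self.dt:
            raise ValueError("tau_true must exceed the frame spacing dt")
        if self.jitter >= 0.5 * (self.bulk_radius - self.shell_radius):
            raise ValueError("jitter must not reach the midpoint cutoff")

    @property
    def gc_cutoff(self) -> float:
        """Radial cutoff midway between the shell and bulk radii."""
        return 0.5 * (self.shell_radius + self.bulk_radius)

    @property
    def n_frames(self) -> int:
        return int(round(self.t_total / self.dt)) + 1


@dataclass
class GroundTruthLog:
    """Exact membership record of the exchange generator.

    ``states`` is the (n_slots, n_frames) boolean membership matrix the
    coordinates encode; counts for any ``t*`` are recomputed from it with
    the same frame-interval persistence convention the analysis uses
    (per-run persistence; the final run credited only with its observed
    duration).  ``bound_durations``
    collects the completed bound holding times drawn by the process
    (before flicker injection), for checking the exponential-holding
    assumption itself.
    """

    states: np.ndarray
    dt: float
    molecule_ids: list[int]
    bound_durations: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]

    @property
    def t_sim(self) -> float:
        return (self.n_frames - 1) * self.dt

    @property
    def cn_series(self) -> np.ndarray:
        return self.states.sum(axis=0).astype(float)

    def counts(self, t_star: float) -> tuple[int, int]:
        """(total departures, sustained departures) at a given t*."""
        n0 = 0
        n_sust = 0
        for row in self.states:
            change = np.nonzero(np.diff(row))[0] + 1
            starts = np.concatenate(([0], change))
            lengths = np.concatenate((np.diff(starts), [len(row) - starts[-1]]))
            for i in range(1, len(starts)):
                state = bool(row[starts[i]])
                final = i == len(starts) - 1
                persistence = (lengths[i] - 1) * self.dt if final else lengths[i] * self.dt
                if not state:  # departure from the shell
                    n0 += 1
                    n_sust += int(persistence >= t_star)
        return n0, n_sust

    def direct_mrt(self, t_star: float) -> float:
        """Ground-truth direct-method MRT implied by the membership matrix."""
        _, n_sust = self.counts(t_star)
        if n_sust == 0:
            raise ValueError("no sustained exchange in ground truth")
        return float(self.cn_series.mean()) * self.t_sim / n_sust

    def intervals(self) -> pd.DataFrame:
        """Tidy per-ligand membership intervals (molecule, state, t_start, t_end)."""
        rows = []
        for mol, row in zip(self.molecule_ids, self.states):
            change = np.nonzero(np.diff(row))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(row)]))
            for s, e in zip(starts, ends):
                rows.append(
                    {"molecule": mol, "state": "bound" if row[s] else "unbound",
                     "t_start": s * self.dt, "t_end": (e - 1) * self.dt}
                )
        return pd.DataFrame(rows)


def _holding_intervals(rng, params: ExchangeSimParams):
    """Alternating bound/unbound intervals for one slot, stationary start."""
    p_bound = params.tau_true / (params.tau_true + params.tau_unbound)
    state = bool(rng.random() < p_bound)
    t = 0.0
    intervals = []  # (state, start, end)
    completed_bound = []
    while t < params.t_total:
        mean = params.tau_true if state else params.tau_unbound
        dur = rng.exponential(mean)
        end = min(t + dur, params.t_total)
        intervals.append((state, t, end))
        if state and t + dur <= params.t_total:
            completed_bound.append(dur)
        t += dur
        state = not state
    return intervals, completed_bound


def simulate_exchange(params: ExchangeSimParams) -> tuple[Trajectory, Topology, GroundTruthLog]:
    """Generate a trajectory of stochastic shell exchange with exact truth.

    Each ligand slot keeps a fixed direction (golden-spiral lattice) and
    sits at ``shell_radius`` when bound and ``bulk_radius`` when unbound,
    with a small radial jitter.  A GC cutoff at the midpoint
    (:attr:`ExchangeSimParams.gc_cutoff`) reproduces the intended
    membership exactly; the :class:`GroundTruthLog` records it.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_ligand_slots
    n_frames = params.n_frames
    times = np.arange(n_frames) * params.dt

    states = np.zeros((n, n_frames), dtype=bool)
    all_bound: list[float] = []
    for s in range(n):
        intervals, completed = _holding_intervals(rng, params)
        all_bound.extend(completed)
        # half-open intervals [start, end): frame f belongs to the interval
        # whose end lies strictly beyond its time
        ends = np.array([t1 for _, _, t1 in intervals])
        ivl_state = np.array([st for st, _, _ in intervals], dtype=bool)
        idx = np.minimum(np.searchsorted(ends, times, side="right"), len(intervals) - 1)
        states[s] = ivl_state[idx]
        # flickers: brief departures injected into bound intervals
        if params.flicker_rate > 0.0:
            for st, t0, t1 in intervals:
                if not st:
                    continue
                span = t1 - t0
                for _ in range(rng.poisson(params.flicker_rate * span)):
                    fs = t0 + rng.random() * span
                    fe = min(fs + rng.exponential(params.flicker_mean), t1)
                    flo = int(np.ceil(fs / params.dt - 1e-9))
                    fhi = int(np.ceil(fe / params.dt - 1e-9))  # exclusive
                    if fhi > flo:
                        states[s, flo : min(fhi, n_frames)] = False

    dirs = fibonacci_sphere(n)
    edge = 2.0 * (params.bulk_radius + 2.0)
    center = np.full(3, edge / 2.0)
    radii = np.where(states, params.shell_radius, params.bulk_radius)
    radii = radii + rng.uniform(-params.jitter, params.jitter, size=radii.shape)

    species = ["K"] + ["O"] * n
    frames = []
    for f in range(n_frames):
        coords = np.vstack(([center], center + radii[:, f, None] * dirs))
        frames.append(
            Frame(index=f, time=times[f], box=np.full(3, edge), coords=coords, species=list(species))
        )
    topo = _single_atom_topology(n + 1).bind(species)
    log = GroundTruthLog(
        states=states, dt=params.dt, molecule_ids=topo.solvent_molecules,
        bound_durations=np.array(all_bound),
    )
    return Trajectory(frames=frames, metadata={"generator": "simulate_exchange", "seed": params.seed}), topo, log


# ---------------------------------------------------------------------------
# ideal-gas solvent bath
# ---------------------------------------------------------------------------

def make_ideal_gas(
    n_solvent: int,
    density: float,
    n_frames: int,
    seed: int,
    dt: float = 0.1,
) -> tuple[Trajectory, Topology]:
    """Uniform solvent sites around a fixed central solute.

    The cubic box edge is set by ``(n_solvent / density)**(1/3)``; solvent
    positions are redrawn uniformly each frame, so g(r) = 1 at every
    distance up to counting noise.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    edge = (n_solvent / density) ** (1.0 / 3.0)
    center = np.full(3, edge / 2.0)
    species = ["K"] + ["O"] * n_solvent
    frames = []
    for f in range(n_frames):
        solvent = rng.uniform(0.0, edge, size=(n_solvent, 3))
        coords = np.vstack(([center], solvent))
        frames.append(
            Frame(index=f, time=f * dt, box=np.full(3, edge), coords=coords, species=list(species))
        )
    topo = _single_atom_topology(n_solvent + 1).bind(species)
    return Trajectory(frames=frames, metadata={"generator": "make_ideal_gas", "seed": seed}), topo
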