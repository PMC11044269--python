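"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the 27-image
distance scan, direct numeric evaluation of the neighbor inequalities,
and a full Voronoi tessellation with an explicit pair-vector/face
intersection test.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Voronoi


def brute_min_image_distance(coords_a, coords_b, box) -> float:
    """Minimum distance over all 27 periodic images of b."""
    box = np.asarray(box, float)
    # pre-wrap both points into the primary cell, then scan the 27 images
    a = np.mod(coords_a, box)
    b = np.mod(coords_b, box)
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = np.array([i, j, k]) * box
                best = min(best, float(np.linalg.norm(b + shift - a)))
    return best


def brute_min_image_displacement(coords_a, coords_b, box) -> np.ndarray:
    box = np.asarray(box, float)
    a = np.mod(coords_a, box)
    b = np.mod(coords_b, box)
    best, best_d = None, np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                d = b + np.array([i, j, k]) * box - a
                n = float(np.linalg.norm(d))
                if n < best_d:
                    best, best_d = d, n
    return best


def rad_blocked(rel_j: np.ndarray, rel_k: np.ndarray) -> bool:
    """Direct numeric evaluation of the RAD inequality for one blocker."""
    rj = np.linalg.norm(rel_j)
    rk = np.linalg.norm(rel_k)
    cos_t = float(np.dot(rel_j, rel_k) / (rj * rk))
    return (1.0 / rj**2) <= cos_t / rk**2


def _inside_convex_polygon(poly: np.ndarray, point: np.ndarray, normal: np.ndarray) -> bool:
    """Containment of a point in a planar convex polygon embedded in 3D."""
    n = normal / np.linalg.norm(normal)
    # in-plane orthonormal basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, n)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    p2 = np.column_stack((poly @ u, poly @ v))
    q = np.array([point @ u, point @ v])
    c = p2.mean(axis=0)
    order = np.argsort(np.arctan2(p2[:, 1] - c[1], p2[:, 0] - c[0]))
    p2 = p2[order]
    signs = []
    for i in range(len(p2)):
        e = p2[(i + 1) % len(p2)] - p2[i]
        w = q - p2[i]
        signs.append(np.sign(e[0] * w[1] - e[1] * w[0]))
    signs = [s for s in signs if s != 0]
    return bool(signs) and all(s == signs[0] for s in signs)


def voronoi_direct_neighbors(rel_sites: np.ndarray) -> list[int]:
    """Direct neighbors of the origin via full tessellation.

    A site is a direct neighbor when the origin-site pair vector pierces
    the shared Voronoi face; the pair vector crosses the bisecting plane
    at the segment midpoint, so the test is containment of the midpoint
    in the shared face polygon.  Distant dummy points bound the diagram.
    """
    pts = np.vstack((np.zeros(3), rel_sites))
    r_far = 100.0 * (np.abs(pts).max() + 1.0)
    dummies = r_far * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
    )
    vor = Voronoi(np.vstack((pts, dummies)))
    n_real = len(pts)
    out = []
    for (a, b), rv in zip(vor.ridge_points, vor.ridge_vertices):
        if 0 not in (a, b):
            continue
        other = int(b if a == 0 else a)
        if other >= n_real or -1 in rv:
            continue
        poly = vor.vertices[rv]
        midpoint = 0.5 * pts[other]
        if _inside_convex_polygon(poly, midpoint, normal=pts[other]):
            out.append(other - 1)
    return sorted(out)


def count_exchange_events(membership: np.ndarray, dt: float, t_star: float):
    """Exhaustive enumeration of departures on one ligand's boolean series.

    Returns (departures, sustained departures) with per-run persistence:
    interior runs persist for length*dt, the final run for
    (length-1)*dt.
    """
    n0 = 0
    n_sust = 0
    i = 1
    runs = []
    start = 0
    for i in range(1, len(membership)):
        if membership[i] != membership[i - 1]:
            runs.append((bool(membership[start]), start, i - start))
            start = i
    runs.append((bool(membership[start]), start, len(membership) - start))
    for idx in range(1, len(runs)):
        state, _, length = runs[idx]
        persistence = (length - 1) * dt if idx == len(runs) - 1 else length * dt
        if not state:
            n0 += 1
            if persistence >= t_star:
                n_sust += 1
    return n0, n_sust


def midrank_spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman via explicit mid-ranking + Pearson on the ranks."""

    def midranks(x):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(len(x), float)
        i = 0
        sx = np.asarray(x, float)[order]
        while i < len(x):
            j = i
            while j + 1 < len(x) and sx[j + 1] == sx[i]:
                j += 1
            ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
            i = j + 1
        return ranks

    ra, rb = midranks(a), midranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float(np.dot(ra, rb) / np.sqrt(np.dot(ra, ra) * np.dot(rb, rb)))
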