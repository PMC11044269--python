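"""RDF computation, first-minimum detection and shell-separation diagnostics."""

import numpy as np
import pytest

from solvshell import (
    GCParams,
    RDFError,
    RDFResult,
    assign_series,
    compute_rdf,
    find_first_minimum,
    make_ideal_gas,
    segment_rdf,
    separation_diagnostics,
)
from solvshell.shells import ShellSeries
from solvshell.trajectory import Frame, Topology, Trajectory


def _system(site_positions, box=20.0, times=None):
    """Solute at the center plus one single-atom solvent molecule per site, per frame."""
    frames = []
    center = np.full(3, box / 2.0)
    n = len(site_positions[0])
    species = ["K"] + ["O"] * n
    for i, sites in enumerate(site_positions):
        coords = np.vstack(([center], np.asarray(sites, float) + center))
        t = times[i] if times is not None else 0.1 * i
        frames.append(Frame(index=i, time=t, box=np.full(3, box), coords=coords, species=species))
    topo = Topology(molecules=[[i] for i in range(n + 1)], solute_site=0).bind(species)
    return Trajectory(frames=frames), topo


class TestComputeRDF:
    def test_ideal_gas_is_flat(self):
        traj, topo = make_ideal_gas(n_solvent=400, density=0.0334, n_frames=80, seed=7)
        res = compute_rdf(traj, topo, bin_width=0.2)
        sel = res.r > 1.0
        counts_expected = res.n_frames * res.density * (4 / 3) * np.pi * (
            (res.r[sel] + 0.1) ** 3 - (res.r[sel] - 0.1) ** 3)
        sigma = 1.0 / np.sqrt(counts_expected)  # Poisson noise on g = 1
        assert np.all(np.abs(res.g[sel] - 1.0) < 3.5 * sigma + 0.02)

    def test_ideal_gas_neighbor_count_integral(self):
        # integral of rho g(r) dV up to r must match the Poisson expectation
        traj, topo = make_ideal_gas(n_solvent=400, density=0.0334, n_frames=80, seed=11)
        res = compute_rdf(traj, topo, bin_width=0.2)
        vol = (4 / 3) * np.pi * ((res.r + 0.1) ** 3 - (res.r - 0.1) ** 3)
        cum = np.cumsum(res.g * res.density * vol)
        for r_test in (2.0, 3.5, 5.0):
            i = np.argmin(np.abs(res.r + 0.1 - r_test))
            expected = res.density * (4 / 3) * np.pi * r_test**3
            sigma = np.sqrt(expected / res.n_frames)
            assert abs(cum[i] - expected) < 3 * sigma + 1e-6

    def test_single_site_single_bin(self):
        traj, topo = _system([[[3.12, 0.0, 0.0]]])
        res = compute_rdf(traj, topo, bin_width=0.1, r_max=5.0)
        nz = np.nonzero(res.g)[0]
        assert len(nz) == 1
        assert res.r[nz[0]] == pytest.approx(3.15)  # bin [3.1, 3.2)

    def test_hand_counted_fixture(self):
        # 2 frames x 4 sites at known distances; brute-force histogram + normalization
        d_frames = [[2.1, 2.1, 3.3, 4.7], [2.1, 3.3, 3.3, 4.7]]
        sites = [[[d, 0, 0] for d in ds] for ds in d_frames]
        traj, topo = _system(sites, box=20.0)
        bw = 0.2
        res = compute_rdf(traj, topo, bin_width=bw, r_max=6.0)
        density = 4 / 20.0**3
        edges = np.arange(0.0, 6.0 + bw, bw)
        for lo, hi, count in [(2.0, 2.2, 3), (3.2, 3.4, 3), (4.6, 4.8, 2)]:
            b = int(np.searchsorted(edges, lo + 1e-9)) - 0
            shell = (4 / 3) * np.pi * (hi**3 - lo**3)
            expected = count / (2 * density * shell)
            idx = np.nonzero(np.isclose(res.r, (lo + hi) / 2))[0][0]
            assert res.g[idx] == pytest.approx(expected, rel=1e-10)
        assert res.g.sum() * 0 == 0  # finite everywhere

    def test_r_max_beyond_half_box_rejected(self):
        traj, topo = _system([[[2.0, 0, 0]]], box=10.0)
        with pytest.raises(RDFError, match="half the smallest box edge"):
            compute_rdf(traj, topo, r_max=6.0)


class TestFirstMinimum:
    @staticmethod
    def _gaussian_rdf(valley=3.4):
        r = np.arange(0.025, 8.0, 0.05)
        g = (2.2 * np.exp(-((r - 2.6) ** 2) / 0.08)
             + 1.1 * np.exp(-((r - 4.2) ** 2) / 0.18))
        return RDFResult(r=r, g=g, bin_width=0.05), valley

    def test_two_gaussian_valley_located(self):
        rdf, _ = self._gaussian_rdf()
        found = find_first_minimum(rdf, window=(2.0, 5.0))
        # analytic valley of this two-Gaussian profile: lowest point between peaks
        mid = (rdf.r > 2.6) & (rdf.r < 4.2)
        expected = rdf.r[mid][np.argmin(rdf.g[mid])]
        assert abs(found.r - expected) <= 2 * rdf.bin_width
        assert abs(found.r_raw - expected) <= rdf.bin_width

    def test_monotone_decreasing_errors(self):
        r = np.arange(0.05, 6.0, 0.05)
        rdf = RDFResult(r=r, g=np.exp(-r))
        with pytest.raises(RDFError):
            find_first_minimum(rdf, window=(1.0, 5.0))

    def test_flat_rdf_errors(self):
        r = np.arange(0.05, 6.0, 0.05)
        rdf = RDFResult(r=r, g=np.ones_like(r))
        with pytest.raises(RDFError):
            find_first_minimum(rdf, window=(1.0, 5.0))


def _gc_shells(traj, topo, r_m):
    return assign_series(traj, topo, "GC", GCParams(r_m))


class TestSegmentation:
    @staticmethod
    def _fluid(seed=3, n=60, frames=40):
        rng = np.random.default_rng(seed)
        sites = []
        for _ in range(frames):
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            sites.append(v * rng.uniform(2.0, 9.0, size=(n, 1)))
        return _system(sites, box=20.0)

    def test_segments_sum_to_total(self):
        traj, topo = self._fluid()
        shells = _gc_shells(traj, topo, 3.4)
        total, first, rem = segment_rdf(traj, topo, shells, bin_width=0.1, r_max=9.0)
        np.testing.assert_allclose(first.g + rem.g, total.g, rtol=1e-10, atol=1e-12)

    def test_gc_segmentation_is_step_function(self):
        traj, topo = self._fluid(seed=5)
        r_m = 3.4
        shells = _gc_shells(traj, topo, r_m)
        _, first, rem = segment_rdf(traj, topo, shells, bin_width=0.1, r_max=9.0)
        assert np.all(first.g[first.r > r_m + 0.05] == 0.0)
        assert np.all(rem.g[rem.r < r_m - 0.05] == 0.0)

    def test_all_empty_shells(self):
        traj, topo = self._fluid(seed=6)
        empty = ShellSeries(method="GC",
                            members=[frozenset()] * traj.n_frames,
                            times=np.array([f.time for f in traj]), dt=traj.dt)
        total, first, rem = segment_rdf(traj, topo, empty, bin_width=0.1, r_max=9.0)
        assert np.all(first.g == 0.0)
        np.testing.assert_allclose(rem.g, total.g)

    def test_out_of_cutoff_member_leaks_past_rm(self):
        # one molecule held in the shell set despite sitting at 4.5 A:
        # first-shell density must appear beyond the 3.4 A cutoff
        sites = [[[2.5, 0, 0], [4.5, 0, 0], [7.0, 0, 0]]] * 4
        traj, topo = _system(sites)
        members = [frozenset({1, 2})] * 4
        shells = ShellSeries(method="RAD", members=members,
                             times=np.array([f.time for f in traj]), dt=traj.dt)
        _, first, _ = segment_rdf(traj, topo, shells, bin_width=0.1, r_max=9.0)
        assert first.g[np.argmin(np.abs(first.r - 4.55))] > 0.0

    def test_misaligned_series_rejected(self):
        traj, topo = self._fluid(seed=8)
        short = ShellSeries(method="GC", members=[frozenset()] * (traj.n_frames - 1),
                            times=np.array([f.time for f in traj][:-1]), dt=traj.dt)
        with pytest.raises(RDFError, match="frames"):
            segment_rdf(traj, topo, short, bin_width=0.1, r_max=9.0)


class TestSeparationDiagnostics:
    def test_gc_crossing_at_cutoff_zero_overlap(self):
        traj, topo = TestSegmentation._fluid(seed=9, n=80, frames=60)
        r_m = 3.4
        shells = _gc_shells(traj, topo, r_m)
        _, first, rem = segment_rdf(traj, topo, shells, bin_width=0.05, r_max=9.0)
        sep = separation_diagnostics(first, rem)
        assert sep.overlap_area == pytest.approx(0.0, abs=1e-12)
        assert abs(sep.intersection_distance - r_m) <= 0.1

    def test_analytic_triangles_exact(self):
        # triangle A peaks at r=2 (height 2, base [1,3]); triangle B peaks at
        # r=4 (height 2, base [3,5]) shifted to overlap on [2.5, 3.5]
        r = np.arange(0.0, 6.0, 0.01)
        g1 = np.clip(2.0 - np.abs(r - 2.0) * (2.0 / 1.5), 0.0, None)  # base [0.5, 3.5]
        g2 = np.clip(2.0 - np.abs(r - 4.0) * (2.0 / 1.5), 0.0, None)  # base [2.5, 5.5]
        sep = separation_diagnostics(RDFResult(r=r, g=g1), RDFResult(r=r, g=g2))
        # symmetric triangles cross midway at r = 3, height 2 - (4/3)
        assert sep.intersection_distance == pytest.approx(3.0, abs=1e-9)
        # overlap: two congruent right triangles, area = height^2 * 1.5 / 2 each
        h = 2.0 - (2.0 / 1.5)
        expected = h * (3.5 - 2.5) / 2.0
        assert sep.overlap_area == pytest.approx(expected, rel=1e-3)

    def test_overlap_symmetric_under_label_exchange(self):
        r = np.arange(0.0, 6.0, 0.01)
        g1 = np.clip(2.0 - np.abs(r - 2.0), 0.0, None)
        g2 = np.clip(1.5 - np.abs(r - 3.0), 0.0, None)
        a = separation_diagnostics(RDFResult(r=r, g=g1), RDFResult(r=r, g=g2))
        b_area = float(np.trapezoid(np.minimum(g2, g1), r))
        assert a.overlap_area == pytest.approx(b_area, rel=1e-12)

    def test_disjoint_segments_zero_area(self):
        r = np.arange(0.0, 8.0, 0.01)
        g1 = np.clip(1.0 - np.abs(r - 2.0), 0.0, None)  # support [1, 3]
        g2 = np.clip(1.0 - np.abs(r - 6.0), 0.0, None)  # support [5, 7]
        sep = separation_diagnostics(RDFResult(r=r, g=g1), RDFResult(r=r, g=g2))
        assert sep.overlap_area == 0.0

    def test_mismatched_bins_rejected(self):
        r1 = np.arange(0.0, 5.0, 0.05)
        r2 = np.arange(0.0, 5.0, 0.1)
        with pytest.raises(RDFError, match="identical bins"):
            separation_diagnostics(RDFResult(r=r1, g=np.ones_like(r1)),
                                   RDFResult(r=r2, g=np.ones_like(r2)))
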