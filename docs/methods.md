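# Methods

This note documents the models and conventions implemented in
`solvshell`, the choices made where several defensible conventions
exist, and what the synthetic test fixtures do and do not demonstrate.

## Scope and data model

The package analyzes trajectories of a single solute in explicit
solvent: periodic orthorhombic cells, uniform frame spacing `dt` (ps),
coordinates in Å.  Coordinates are never rewrapped; every distance and
angle is evaluated under the minimum-image convention.  Analysis
operates on one *representative site* per solvent molecule (the O of
H2O, the C of DCM) and on one solute site; whole-molecule centers of
mass are out of scope.  Membership decisions apply to the molecule as a
whole via its site.

Triclinic cells are rejected at input.  Frame times must be uniform:
the exchange and autocorrelation estimators assume equal sampling
intervals, and silently accepting irregular spacing would corrupt the
event persistence bookkeeping.

## Shell definitions

Before any neighbor criterion is applied, all solvent sites are reduced
to the solute-centered minimum-image copy; every pair distance used by
the criteria below refers to that single local picture.  This is exact
whenever the coordination environment is small compared to the cell,
which holds for every intended use (one solute, cell edges ≳ 18 Å).

**GC (radial cutoff).**  A molecule is a first-shell member when its
site lies within `r_m` of the solute, boundary inclusive (`≤`).  The
boundary convention is a measure-zero choice, fixed for
reproducibility.  `r_m` is conventionally the first minimum of the
solute–site RDF (see below).

**RAD (relative angular distance).**  Candidates are sorted by distance
from the solute `i` (ties broken by ascending molecule id, so output is
deterministic).  A candidate `j` is *blocked* by an already accepted
closer ligand `k` when

    1 / r_ij^2  ≤  cos(θ_jik) / r_ik^2 ,

with `θ_jik` the angle at the solute between the two ligands.  A
blocker behind the solute (`cos θ < 0`) can never block.  The closed
variant stops scanning at the first blocked candidate; RAD_open
continues through the sorted list, so RAD_open ⊇ RAD on every frame.
Blockers are drawn from accepted ligands only; since the algorithm
runs outward, every ligand closer than a candidate has already been
classified when the candidate is tested.  The criterion is asymmetric
between particles: the test suite constructs a three-particle
configuration where `j` is in `i`'s shell while `i` is not in `j`'s.

**MV (modified Voronoi).**  `j` is a *direct neighbor* of `i` when the
pair vector pierces the shared Voronoi face, which reduces to the pair
inequality

    r_ik^2 + r_jk^2  >  f_c · r_ij^2   for every other site k,

at `f_c = 1`.  (The pair vector crosses the bisecting plane at the
segment midpoint, and the midpoint lies on the shared face exactly when
the angle at every third particle `k` subtending the pair is acute.)
Lowering `f_c` weakens the right-hand side and can only add members.
Equality is treated as blocking, so in a simple-cubic environment the
twelve next-nearest sites — whose midpoints fall exactly on a cell
edge — are excluded and the shell is the six face-sharing neighbors.
The equivalence with an explicit tessellation (scipy Voronoi diagram
plus midpoint-in-face test) is asserted on 50 random configurations in
the test suite.

## Direct-method exchange accounting

Given the per-frame membership series of each molecule, every change of
status between consecutive frames is a *migration*.  A migration is
*sustained* when the new status persists at least the minimum excursion
time `t*`; the recommended and default value is `t* = 0.5 ps`.
Persistence is measured in whole frame intervals: an interior run of
`L` frames persists `L·dt` (the time between the two crossings that
bracket it); the final run of a trajectory has only `(L−1)·dt` of
observed duration and is credited with exactly that, so no unobserved
persistence is ever fabricated (the resulting end bias is O(t*/t_sim)).
Whether "persists for more than t*" is strict or inclusive is a
one-frame question; the inclusive reading (`≥ t*`) is used.

The mean residence time is

    MRT = CN_av · t_sim / N_ex^{t*} ,

with `CN_av` the mean instantaneous coordination number and `t_sim` the
observed time span.  `N_ex^{t*}` counts **departures** from the shell
whose subsequent absence is sustained, i.e. residence-period
terminations.  The numerator is the total ligand-residence time
observed, so dividing by the number of completed stays gives an
(asymptotically) unbiased estimator of the mean residence time; this is
verified against the stochastic generator's ground truth.  Counting
arrivals *in addition to* departures would bracket every residence
period twice and halve the estimate, so arrivals are detected, flagged,
and reported in the summary but excluded from `N_ex`.  Two consequences
follow directly:

* `t* = 0` reduces MRT to `CN_av · t_sim / N_ex^{0.0}` exactly;
* increasing `t*` can only discard events, so `N_ex^{t*}` is
  nonincreasing and MRT nondecreasing in `t*`.

A flicker — an excursion shorter than `t*` — is registered as a
migration but terminates nothing: the surrounding residence period
continues.  This makes MRT insensitive to boundary recrossings while
the rate coefficient

    R_ex = N_ex^{0.0} / N_ex^{t*}

grows with them; `R_ex` is the mean number of departures needed for one
sustained exchange and equals 1 when every departure persists.  When no
sustained exchange is observed, MRT is undefined; the summary reports
`CN_av · t_sim` as a lower bound with an explicit flag rather than a
number that looks like an estimate.

Residual biases of the estimator are inherent to the `t*` filter: a
genuine absence shorter than `t*` (probability `1 − exp(−t*/τ_bulk)`
for exponential bulk times) merges two stays into one.  For the default
generator conditions this is a ~1% effect.

## RDF and shell-separation diagnostics

The RDF is normalized for a single reference particle (infinite
dilution): counts per bin are divided by `n_frames · ρ · V_shell` with
`ρ` the mean solvent-site number density, so `g → 1` in a homogeneous
bath.  Defaults: bin width 0.05 Å, `r_max = 0.49 ×` smallest box edge.

The first-minimum locator smooths `g` with a 5-point moving average,
finds the first interior local maximum inside the search window, and
returns the lowest smoothed bin after it (the raw-bin minimum is
reported alongside).  Monotone or flat profiles raise an error rather
than returning a spurious cutoff.

Segmented RDFs split each pair contribution by the molecule's shell
membership in that frame; first-shell and remainder segments sum
bin-wise to the total by construction.  Shell quality is summarized by
(i) the crossing distance where the remainder segment overtakes the
first-shell segment after its peak, located by linear interpolation
between the bracketing bins, and (ii) the trapezoidal integral of
`min(g_first, g_remainder)`.  A sharp radial cutoff yields a step
segmentation: crossing at `r_m`, overlap area exactly zero.  The area
is symmetric under exchanging the segment labels.

## CN autocorrelation

`C_CN(t)` is the autocorrelation of `δN(t) = N(t) − ⟨N⟩`, estimated
with the biased (divide-by-N) autocovariance — guaranteeing a positive
semidefinite sequence — and normalized to `C(0) = 1`.  The integral
relaxation time `τ_CN` is the trapezoidal integral of `C` up to an
upper limit; since no canonical limit exists, the default is the first
zero crossing of the estimated `C`, capped at 10 ps, and both the value
and the limit actually used are reported.

For well-averaged curves a double-exponential decay

    C(t) = a·exp(−t/τ_s) + (1−a)·exp(−t/τ_l),   0 ≤ a ≤ 1,

is fitted by bounded least squares over a window (default 0–5 ps,
uniform weights), with amplitudes constrained nonnegative and summing
to `C(0)`.  The effective decay constant is the amplitude-weighted mean
`τ_eff = a·τ_s + (1−a)·τ_l`, which always lies between `τ_s` and
`τ_l`.  Fits with nearly equal decay constants are flagged degenerate
(effectively single-exponential); decay constants below the sampling
interval are flagged unresolved rather than reported as physical.

## Cross-method diagnostics

CN distributions are plain normalized histograms (percent).  Method
agreement uses Pearson correlation on the per-frame CN values and
Spearman rank correlation with mid-rank tie averaging, computed on the
same trajectory.  No significance testing is attached: the series are
strongly autocorrelated, so naive p-values would be meaningless.

## Synthetic generators

**Static geometries** (octahedron, tetrahedron, simple-cubic 3×3×3,
particle pair) pin down the neighbor criteria with exactly known
answers and no statistical tolerance.

**Stochastic exchange process.**  Each of `n_ligand_slots` ligands
alternates bound and unbound states with exponential holding times —
mean `tau_true` (default 5 ps) bound and `tau_unbound` (default 50 ps)
unbound — starting from the stationary state.  The defaults emulate an
ionic shell in a dilute bath: on average `50·5/55 ≈ 4.5` ligands bound,
and bulk excursions long enough (`t*/τ_bulk = 0.01`) that the `t*`
filter discards almost nothing it shouldn't.  Optional flickers — brief
departures with mean duration 0.1 ps, injected at a chosen rate per ps
of bound time — stress the excursion filter.  Ligand directions are
fixed per slot on a golden-spiral lattice rather than re-randomized per
frame, so angular relationships persist between frames as they do in a
liquid.  Bound ligands sit at `shell_radius` (2.8 Å), unbound at
`bulk_radius` (8 Å), with ±0.1 Å radial jitter that cannot reach the
midpoint cutoff at 5.4 Å, so a GC assignment at the midpoint recovers
the generated membership *exactly* and every event count is
recomputable from the recorded ground truth.

What passing these tests shows: the estimator pipeline (assignment →
event detection → MRT/R_ex) is correct and unbiased under its own
assumptions.  What it does not show: correctness on real liquids, where
membership is not two-radius, residence times are not exponential, and
solvent structure produces correlated, gradual boundary crossings.  The
generator makes no attempt at physical forces; exactness of the ground
truth was chosen over realism.

One geometric caveat: with the sparse ion-like defaults (~4.5 of 50
directions occupied), the cutoff-free RAD and MV criteria legitimately
admit an occasional unblocked bulk ligand at 8 Å — open space carries
no second shell to block the view.  Cross-method comparisons are
therefore exercised on a dense variant (`tau_unbound = tau_true`,
~25 ligands bound) in which blocking is complete; there the MRTs from
GC, RAD and MV agree within 10% despite different CN_av, while the
sparse configuration is reserved for the GC-based recovery tests it was
designed for.

**Ideal gas** solvent (uniform redraw each frame around a fixed solute)
provides the exact `g ≡ 1` null for RDF normalization and Poisson
neighbor counts.

## Numerical and degenerate-input conventions

* Distance ties in RAD sorting break by molecule id; outputs are fully
  deterministic, and all generators take a mandatory seed.
* Zero solute–site distance or coincident sites raise errors in
  RAD/MV rather than propagating NaN.
* A zero-variance CN series makes autocorrelation and correlation
  undefined; both raise.
* Segment pairs must share identical bins; frame-misaligned shell
  series are rejected.
* The RAD/MV equality cases (`cos θ` exactly at the bound, midpoint
  exactly on a face edge) are classified as blocked; this is the only
  convention under which the simple-cubic lattice yields the geometric
  answer.

## Problem sizes used in the shipped checks

The recovery and stability checks run the generator at 50 slots,
500 ps, `dt = 0.1 ps` (5001 frames) over 10 seeds, and the ideal-gas
RDF at 400 sites × 80 frames — sizes chosen so every statistical
tolerance (3 SE bands, 3σ counting noise) is meaningfully tight while
the whole suite completes in well under a minute.

## Known limitations

* Orthorhombic cells only; no triclinic support.
* One solute per analysis; solvent–solvent shell analysis requires
  re-running with each molecule as the solute.
* MV under periodic boundaries uses the solute-centered copy, which is
  exact only while the shell is small against the cell.
* The double-exponential fit assumes a positive, decaying ACF over the
  window; oscillatory ACFs (strongly anticorrelated CN) should be
  interpreted via `τ_CN` with an explicit limit instead.
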