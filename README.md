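# solvshell

Solvation-shell definition and ligand-exchange dynamics from molecular
dynamics trajectories of a solute in explicit solvent.

How long does a water molecule stay coordinated to an ion?  The answer
depends on an apparently innocuous choice: what counts as "coordinated".
`solvshell` implements four first-shell definitions side by side and
couples each to the *direct method* for exchange dynamics, so that
coordination numbers, residence times and their sensitivity to the
shell definition can be compared on the same trajectory.  It is aimed
at simulators analyzing QM/MM, semiempirical or classical MD of ions
and small molecular solutes in solution.

## Shell definitions

* **GC** — radial cutoff at the first minimum `r_m` of the
  solute–solvent RDF: member iff `r ≤ r_m`.
* **RAD** — relative angular distance: scanning ligands outward,
  candidate *j* is blocked by an accepted closer ligand *k* when
  `1/r_ij² ≤ cos(θ_jik)/r_ik²`; the closed variant stops at the first
  blocked candidate, **RAD_open** keeps scanning.
* **MV** — modified Voronoi: *j* is a direct neighbor iff its pair
  vector pierces the shared Voronoi face, equivalently
  `r_ik² + r_jk² > f_c·r_ij²` for every third site *k* (`f_c = 1` by
  default; smaller values loosen the criterion).

## Exchange analysis

With the per-frame shell series in hand, every membership change is a
migration, and a migration persisting at least the minimum excursion
time `t*` (default 0.5 ps) is a sustained exchange.  The mean residence
time and rate coefficient follow the direct method:

    MRT  = CN_av · t_sim / N_ex^{t*}        R_ex = N_ex^{0.0} / N_ex^{t*}

where `N_ex^{t*}` counts sustained departures from the shell (see
`docs/methods.md` for the exact counting and end-of-trajectory
conventions).  Also provided: shell-segmented RDFs with
intersection-distance and overlap-area diagnostics, CN distributions,
Pearson/Spearman cross-method correlation, and the CN autocorrelation
`C_CN(t)` with its integral relaxation time `τ_CN` and double-exponential
decay constants.

Synthetic generators (static coordination geometries, a stochastic
exchange process with exact ground truth, an ideal-gas bath) back every
estimator with known answers.

## Worked example

Generate a stochastic exchange trajectory whose true mean residence
time is 5 ps (50 ligand slots, 500 ps, sub-`t*` flickers injected at
0.2 ps⁻¹), then assign shells with the radial cutoff and run the direct
method:

```python
import solvshell as sv

params = sv.ExchangeSimParams(seed=7, tau_true=5.0, n_ligand_slots=50,
                              t_total=500.0, flicker_rate=0.2)
traj, topo, truth = sv.simulate_exchange(params)

shells = sv.assign_series(traj, topo, "GC", sv.GCParams(params.gc_cutoff))
s = sv.summarize(traj, shells, sv.ExchangeParams(t_star=0.5))
print(f"CN_av={s.cn_av:.2f}  N0={s.n_ex_0}  N05={s.n_ex_tstar}  "
      f"MRT={s.mrt:.2f} ps  R_ex={s.r_ex:.2f}")
print(f"ground truth MRT: {truth.direct_mrt(0.5):.2f} ps")
```

prints

```
CN_av=4.36  N0=719  N05=445  MRT=4.90 ps  R_ex=1.62
ground truth MRT: 4.90 ps
```

On average 4.36 of the 50 ligands are bound; 719 departures were
registered, of which 445 persisted beyond 0.5 ps, so each sustained
exchange took 1.62 boundary crossings (`R_ex`) — the flickers inflate
`N^0.0` but not the residence time, and the recovered MRT of 4.90 ps
matches the generator's ground truth and its 5 ps design value.

The same formula applied at the desk reproduces published residence
times; e.g. a weakly exchanging cation with `CN_av = 4.1` and a
sustained exchange rate of 0.18 ps⁻¹:

```python
>>> sv.mrt_from_rate(4.1, 0.18)
22.777...   # ≈ 23 ps
```

## Command line

```sh
solvshell simulate --kind exchange --seed 1 --out traj.xyz
solvshell assign  --config run.yaml --out shells.csv
solvshell analyze --config run.yaml --shells shells.csv --outdir results/
solvshell rdf     --config run.yaml --shells shells.csv --outdir results/
```

`run.yaml` names the trajectory, topology rules (solute site, solvent
element), method parameters (`r_m`, `f_c`), `t_star`, and RDF/ACF
settings.  Trajectories are extended-XYZ with per-frame
`Lattice="..."`/`Time=` comments; all outputs are delimited text.

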