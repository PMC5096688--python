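# Methods

## The model

`propagon` implements a discrete-size nucleated-polymerization model (NPM)
of prion aggregate dynamics in a growing yeast cell, built for the
Sup35/[PSI+] system. Aggregates are linear amyloid polymers of integer size
`i >= n0`, where `n0` is the minimum stable nucleus; four processes act:

| process        | rate                              | parameter |
|----------------|-----------------------------------|-----------|
| synthesis      | `alpha` (monomer units/min)       | `alpha`   |
| conversion     | `2*beta*s` per aggregate          | `beta`    |
| fragmentation  | `gamma` per internal bond         | `gamma`   |
| dilution       | `mu` per molecule/aggregate       | `mu = ln2 / t_d` |

Conversion (elongation) proceeds at both fiber ends; the factor 2 is the
module constant `model.N_ENDS` and can be set to 1 for the single-ended
convention. Fragments smaller than `n0` dissolve instantly back to soluble
monomer. Protein amounts are in arbitrary "monomer units": absolute
concentrations are never compared, only the dimensionless observables
(soluble fraction `f`, basic reproductive number `R0`) that the assays
report.

Writing `u_i` for the abundance of size-`i` aggregates, `U = sum u_i`,
`M = sum i*u_i`, the first-moment system

```
ds/dt = alpha - mu*s - 2*beta*s*U + gamma*n0*(n0-1)*U
dU/dt = gamma*(M - (2*n0-1)*U) - mu*U
dM/dt = 2*beta*s*U - gamma*n0*(n0-1)*U - mu*M
```

is an **exact** closure of the size-resolved master equations, not an
approximation: for every size `i >= n0` the expected monomer mass dissolved
per fragmentation event sums to `n0*(n0-1)` and the expected net change in
aggregate number is `i - (2*n0-1)`, independent of how the `i-1` break
positions partition into surviving/dissolving outcomes. The test suite
checks this identity by brute-force summation of the size-resolved rates.

Total protein `T = s + M` obeys `dT/dt = alpha - mu*T` identically, so
`T* = alpha/mu` at steady state regardless of the aggregate state. The
prion coexistence state has

```
s* = (gamma^2*n0*(n0-1) + mu*gamma*(2*n0-1) + mu^2) / (2*beta*gamma)
M* = alpha/mu - s*,      U* = gamma*M* / (gamma*(2*n0-1) + mu)
```

and exists iff `s* < alpha/mu`. The basic reproductive number is defined
through the steady state as `R0 = (alpha/mu)/s* = 1/f`, where `f` is the
steady-state soluble fraction — the quantity the SDS-solubility assay
measures directly. `R0 > 1` iff the coexistence state exists, and in the
slow-fragmentation regime (`gamma*(2*n0-1) << mu`) `R0` is proportional to
`gamma` with the other rates held fixed, which is what makes `R0` a proxy
for fragmentation efficiency.

## Inference

* **R0 per strain**: point estimate `1/mean(f)` over replicates (`f` is the
  measured quantity; `1/mean` is the plug-in estimator of `1/E[f]`).
* **Confidence intervals**: nonparametric bootstrap resampling replicates
  within strain, default `n_boot = 10000`, `ci_level = 0.95`. The default
  interval is the **studentized bootstrap** (bootstrap-t with a delta-method
  standard error for `1/mean`). A calibration study at the panel's working
  conditions (n = 6 replicates, noise sd 0.01, 1500 simulations per truth
  across four panel-range fractions) measured coverage of nominal-95%
  intervals: percentile 83.9–86.9%, basic 84.8–86.1%, studentized
  94.7–95.9%. The familiar small-sample undercoverage of percentile-type
  intervals is far outside acceptable calibration at n ~ 5–6, so the
  studentized interval is the default; `method="percentile"|"basic"` remain
  available.
* **Strain comparisons**: CI for `R0(a) - R0(b)` by independent resampling
  of both strains per bootstrap replicate; "significant" means the CI
  excludes 0. No multiple-testing correction is applied (comparisons are
  reported raw).
* **Fragmentation rate**: `f = s*(gamma)/(alpha/mu)` is a quadratic in
  `gamma`; both positive roots are reported and the smaller
  (slow-fragmentation) root is returned, because it continues continuously
  to the subcritical boundary as `f -> 1` and sits on the ascending branch
  where `R0` increases with `gamma`. Fractions below the attainable minimum
  `f_min = mu^2*((2*n0-1) + 2*sqrt(n0*(n0-1)))/(2*beta*alpha)` raise an
  error carrying the attainable range — the inversion never extrapolates.
* **Dilution rates**: per-strain, from measured doubling times
  (`mu = ln2/t_d`). The doubling-time table covers RWT 97.7, R1-5 99.1,
  ΔRPR 99.5, R2E1 112.3, R2E2 166.0 min; R1-5ΔRPR was not measured and uses
  the ΔRPR value (closest construct, same medium).

## Stochastic simulation

`simulate_well_mixed` is an exact Gillespie simulation of the same reaction
network (integer molecule counts, per-bond fragmentation with uniform break
position). Every fragmentation event is audited in-kernel: `s + M` must be
conserved exactly and the propagon count must change by -1, 0 or +1; any
violation aborts the run.

`simulate_lineage` follows one focal cell through a protocol of phases,
each scaling `gamma` (0 = GdnHCl, which blocks Hsp104-mediated
fragmentation while synthesis and conversion continue). Growth dilution is
implemented *only* by division — every `t_d` minutes the cell keeps each
aggregate independently with probability `p_keep` (default 0.5, symmetric
partition) and a `Binomial(s, 1/2)` share of monomer — so the expected
dilution rate `ln2/t_d` matches the ODE `mu` without double counting. Each
lineage draws a uniform division-phase offset from its seed (an
asynchronous culture: cells sit at random cycle positions when the protocol
starts); pass `division_phase=1.0` for a synchronized population. Samples
landing exactly on a division time report the post-division count.

Two engines share this contract:

* `mode="exact"` (default): full event-driven simulation.
* `mode="hybrid"`: the soluble pool and aggregate elongation advance by
  exact linear-ODE updates between discrete events; fragmentation fires as
  an inhomogeneous Poisson process sampled by thinning (its intensity
  `gamma*(M - U)` only grows between events, so the interval-end value is a
  valid bound); division segregation stays fully stochastic; aggregate
  sizes become reals with continuum break positions. This drops only the
  demographic noise of the monomer pool and of single elongation steps,
  which is O(1/sqrt(s)) ~ 0.3% at this package's molecule scales, and runs
  about three orders of magnitude faster. The test suite holds the two
  engines to agreement within Monte Carlo error on per-cell propagon-count
  ensembles.

`amplification_rate` summarizes a lineage ensemble as the least-squares
slope of `log(mean propagon count)` against time over a chosen
early-recovery window, with its standard error. The ensemble mean (not the
median) is fitted because the mean of a branching process grows
exponentially even when many lineages are near extinction; medians are
available from the tables directly.

## The synthetic study generator

No raw measurements are deposited for the assays this package analyzes, so
`propagon.synth` generates datasets with the same statistical structure and
known ground truth.

**Panel.** Six strains share `alpha = 700` monomer units/min, `beta`
calibrated once so `2*beta*alpha = 0.4`, `n0 = 4`; each carries its own
`mu` from its doubling time. Fragmentation rates are strictly ordered
`R2E2 > R2E1 > RWT > R1-5 > ΔRPR > R1-5ΔRPR`. RWT, ΔRPR and R1-5ΔRPR are
parameterized by target R0 (2.2, 1.75, 1.45); R1-5 is solved to have
*exactly* wildtype's soluble fraction (the two strains are experimentally
indistinguishable by this assay), which under its slightly slower growth
puts its `gamma` just below wildtype's; R2E1 and R2E2 take `gamma` at 1.6x
and 1.65x wildtype, which their slower growth (longer doubling times,
smaller `mu`) amplifies into R0 ~ 5.3 and ~ 17.7. Two couplings constrain
this design: (i) `R0 ~ 2*beta*alpha*gamma/mu^3` in the slow-fragmentation
regime, so the 1.7-fold doubling-time spread forces
`R0(R2E2) >~ 4.9 * R0(RWT)` whenever the `gamma` ordering is strict; and
(ii) the gamma-inversion error scales as
`(1 + (2*n0-1)*gamma/mu) * noise_sd/(sqrt(n_reps)*f)`, so strains with
small `f` (large R0) become unidentifiable at the generator's noise level.
The chosen span (R0 ~ 1.45–17.7) is the widest that keeps every strain's
`gamma` recoverable to 10% from 6 replicates at noise sd 0.01.

**Soluble tables.** Replicates are the closed-form steady-state fraction
plus additive Gaussian noise (default sd 0.01, the scale of
replicate-to-replicate variation in quantitative immunoblotting), clamped
to (0, 1]; at default settings the clamp is never active in practice.

**Propagon time courses.** The default protocol cures 420 min in GdnHCl
(~4 generations; mean counts drop to ~0.5–6 per cell, "just before prion
loss") and recovers 480 min, sampled every 30 min. Pilot measurements
showed that shallow curing cannot resolve strains: at the pre-curing steady
state the per-aggregate fragmentation rate `gamma * <size>` is nearly
strain-invariant because `<size> ~ mu/gamma`. Deep curing inflates all
aggregates by continued conversion (a gamma-independent size gain), after
which the early re-amplification rate orders with `gamma` — which is
exactly why the laboratory assay cures to near-loss before release. The
amplification fit window is release..+180 min (`AMPLIFICATION_WINDOW`).
Default `n_cells = 1200` lineages per strain: per-cell counts at this
package's molecule scale (~5–50 propagons at steady state, against hundreds
in vivo) carry roughly an order of magnitude less information per cell, and
the larger ensemble restores the discrimination the real assay achieves
with a handful of cells.

**Determinism.** Every table derives from one master seed through
`numpy.random.SeedSequence` spawning; regeneration is bit-identical.

## Numerical choices

* Moment ODEs: `scipy.integrate.solve_ivp` with **Radau**
  (`rtol 1e-8 / atol 1e-10` defaults). Radau's global conservation error on
  supercritical growth runs stays within ~0.2x the requested local
  tolerance, where LSODA drifted to ~13x.
* Size-resolved ODEs: LSODA; truncation `i_max` chosen adaptively as the
  smallest power of two keeping the elongation mass flux past the boundary
  below 0.1% of total protein; the loss is always reported on the result
  and a warning records any violation — never silently ignored.
* Negative undershoots are clipped to zero only for reporting; an
  undershoot beyond `100*atol` raises.
* Gamma inversion uses the numerically stable quadratic formula (no
  cancellation between `-b` and the discriminant root).
* Kernel seeds are derived via `SeedSequence` and masked to 31 bits for the
  numba Mersenne-Twister state.

## What passing tests do and do not show

The generator emulates replicate noise on a bounded fraction, integer
per-cell propagon counts, strain-specific growth, and protocol structure
(curing depth, sampling cadence). It does **not** emulate between-day batch
structure, gel-quantification nonlinearity, plating inefficiency of the
colony assay (available separately as `propagon_assay`), mother–daughter
segregation bias (`p_keep` is configurable but defaults to symmetric), cell
size/age structure, or conformational strain variants. Passing the
recovery and ordering tests therefore shows the *pipeline* is correct and
well calibrated under the stated noise model, not that real gels would
yield these error bars.

## Known limitations

* The moment closure is exact for the stated reaction rules; rules with
  size-dependent fragmentation or finite sub-nucleus lifetimes would break
  it.
* `R0 = 1/f` presumes total protein is at its steady state `alpha/mu`;
  perturbation experiments (e.g. mid-curing solubility) need the full
  trajectory, not the identity.
* The hybrid engine treats monomer and elongation deterministically; at
  molecule counts below ~10^3 the neglected noise becomes visible and the
  exact engine should be used.
* Problem sizes in the acceptance pipeline (500-run ensembles, 200 panels,
  100 studies, 1200-cell time courses) are the package's chosen study
  scale; all are arguments, not constants.
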