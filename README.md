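# propagon

Nucleated-polymerization modeling of yeast prion propagation: infer the
basic reproductive number of amyloid aggregates from steady-state soluble
protein, invert it for the fragmentation rate, and simulate propagon
segregation through GdnHCl curing/recovery protocols.

## The problem

The yeast prion [PSI+] is a heritable amyloid state of the translation
release factor Sup35. Its propagation cycle has two kinetic steps:
**conversion** (soluble Sup35 adds onto fiber ends at rate `2βs` per
aggregate) and **fragmentation** (the chaperone machinery severs each
internal bond at rate `γ`, creating new heritable templates — propagons).
Cell growth dilutes everything at `μ = ln2/t_d`, new protein is made at
`α`, and fragments below the nucleus size `n0` dissolve. Sequence elements
of the Sup35 prion domain (the oligopeptide repeats and the
repeat-proximal region, RPR) tune the fragmentation step; this package
provides the quantitative machinery to measure that tuning from two assays:

1. **SDS-solubility**: the fraction `f` of Sup35 that is soluble at
   steady state. The first two moments of the aggregate size distribution
   (`U` = aggregate number, `M` = aggregated mass) close exactly:

   ```
   ds/dt = α − μs − 2βsU + γ·n0(n0−1)·U
   dU/dt = γ(M − (2n0−1)U) − μU
   dM/dt = 2βsU − γ·n0(n0−1)·U − μM
   ```

   Total protein is `α/μ` at steady state, so the basic reproductive
   number of an aggregate — descendants per aggregate lifetime — is
   simply **`R0 = 1/f`**, and the steady-state relation inverts in closed
   form for `γ` given (`α`, `β`, `μ`, `n0`). Prions persist iff `R0 > 1`,
   and `R0 ∝ γ` when fragmentation is slow relative to dilution.

2. **Propagon counting**: cells are grown in GdnHCl (Hsp104 inhibited,
   `γ = 0`) so propagons dilute two-fold per generation, then released;
   the per-cell count re-amplifies at a rate that reads out `γ`. The
   package simulates single-cell lineages through such protocols with an
   exact Gillespie kernel (and a validated accelerated hybrid engine), and
   fits the re-amplification rate from count time courses.

A synthetic-data module generates six-strain study panels (RWT, R1-5,
ΔRPR, R1-5ΔRPR, R2E1, R2E2) with strain-specific doubling times, strictly
ordered fragmentation rates and known ground truth, for end-to-end
validation of the whole pipeline. See `docs/methods.md` for the model,
estimators and design choices.

## Worked example

```python
>>> from propagon import (ModelParams, steady_state_coexistence,
...                       r0_from_params, soluble_fraction_from_params)
>>> p = ModelParams(alpha=100, beta=2e-4, gamma=1e-3, mu=7e-3, n0=4)
>>> ss = steady_state_coexistence(p)
>>> round(ss.s, 1), round(ss.U, 1), round(ss.M, 1)
(275.0, 1000.8, 14010.7)
>>> round(r0_from_params(p), 3), round(1 / soluble_fraction_from_params(p), 3)
(51.948, 51.948)
```

Soluble protein is kinetically buffered at `s* = 275` monomer units while
total protein is 14286, so only 1.9% of the protein is soluble and each
aggregate produces ~52 descendants per lifetime.

Running `python examples/infer_r0_from_solubility.py` (bootstrap R0 from
replicate solubility measurements of the default panel) prints:

```
strain      n  mean f    R0 [95% CI]
RWT         6  0.4555    2.20 [ 2.18,  2.22]
R1-5        6  0.4571    2.19 [ 2.16,  2.27]
ΔRPR        6  0.5710    1.75 [ 1.71,  1.80]
R1-5ΔRPR    6  0.6874    1.45 [ 1.42,  1.49]
R2E1        6  0.1871    5.34 [ 5.01,  5.67]
R2E2        6  0.0552   18.12 [15.39, 21.67]

comparisons (delta = R0_a - R0_b; significant iff CI excludes 0):
  R2E2       vs RWT   : delta = +15.93 [+13.19, +19.49]  significant
  R1-5       vs RWT   : delta =  -0.01 [ -0.04,  +0.05]  not significant
  R1-5ΔRPR   vs ΔRPR  : delta =  -0.30 [ -0.35,  -0.25]  significant
```

The repeat expansions amplify fastest (highest R0), deleting the RPR or a
repeat slows amplification, and R1-5 is statistically indistinguishable
from wildtype — each estimate with a studentized-bootstrap CI. The other
examples cover fragmentation-rate fitting (`fit_fragmentation_rate.py`),
the curing/recovery simulation (`curing_recovery_simulation.py`) and the
end-to-end synthetic pipeline (`synthetic_study_pipeline.py`). A thin CLI
wraps the same calls:

```sh
propagon --seed 17 synth --out study/         # materialize a synthetic study
propagon infer-r0 study/soluble.tsv --out r0.json
propagon fit-gamma study/soluble.tsv --out gamma.json
```

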