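"""End-to-end pipeline: generate a synthetic study, re-infer the kinetics.

A study materializes replicate soluble fractions for all six strains plus
propagon time courses for the curing/recovery panel strains, all from one
master seed.  The inference layer then recovers the per-strain fragmentation
rate and R0, which this script compares against the generator's ground truth.
"""

from propagon import gamma_from_soluble_fraction, generate_study, ground_truth

study = generate_study(master_seed=1, include_propagons=False)
truth = ground_truth(study.panel).set_index("strain")

print("strain      gamma truth   gamma hat    rel err    R0 truth  R0 hat")
for meas in study.soluble_tables:
    spec = next(s for s in study.panel if s.label == meas.strain)
    fit = gamma_from_soluble_fraction(
        meas.mean, spec.params.alpha, spec.params.beta,
        spec.params.mu, spec.params.n0,
    )
    g_true = truth.loc[meas.strain, "gamma"]
    print(
        f"{meas.strain:10s}  {g_true:.4e}  {fit.gamma:.4e}  "
        f"{fit.gamma / g_true - 1:+8.2%}   {truth.loc[meas.strain, 'r0']:7.3f}  "
        f"{1.0 / meas.mean:6.3f}"
    )

print(
    "\nWith six replicates at noise sd 0.01 the fragmentation rate is "
    "typically\nrecovered to within a few percent; regenerate with the same "
    "master seed and\nevery number reproduces bit-for-bit."
)
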