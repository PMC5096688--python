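"""Estimate R0 per strain from replicate soluble-fraction measurements.

Generates a synthetic solubility table for the default six-strain panel
(replicates of the fraction of protein that is SDS-soluble at 53 degC),
then computes bootstrap R0 estimates and two strain comparisons.
"""

from propagon import bootstrap_r0, compare_r0, default_panel, generate_soluble_table

panel = default_panel(0)
tables = {s.label: generate_soluble_table(s, seed=i) for i, s in enumerate(panel)}

print("strain      n  mean f    R0 [95% CI]")
for label, meas in tables.items():
    est = bootstrap_r0(meas, n_boot=10_000, seed=1)
    print(
        f"{label:10s} {meas.n:2d}  {meas.mean:.4f}   "
        f"{est.point:5.2f} [{est.ci_low:5.2f}, {est.ci_high:5.2f}]"
    )

print("\ncomparisons (delta = R0_a - R0_b; significant iff CI excludes 0):")
for a, b in (("R2E2", "RWT"), ("R1-5", "RWT"), ("R1-5ΔRPR", "ΔRPR")):
    c = compare_r0(tables[a], tables[b], n_boot=10_000, seed=2)
    flag = "significant" if c.significant else "not significant"
    print(
        f"  {a:10s} vs {b:6s}: delta = {c.delta:+6.2f} "
        f"[{c.ci_low:+6.2f}, {c.ci_high:+6.2f}]  {flag}"
    )
print(
    "\nHigher R0 means each aggregate spawns more descendants per lifetime: "
    "the repeat\nexpansion amplifies fastest, repeat/RPR deletions slowest, "
    "and R1-5 is\nindistinguishable from wildtype."
)
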