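"""Run the complete synthetic sensing-volume study and summarize it.

Executes generate -> calibrate -> invert -> extract -> stats for three
liquids x two probes x two axes x seven frequencies x five replicates with
reflection noise 1e-3, then prints the 300 MHz condition summaries
(mean +/- SD sensing distance), the frequency-stability ANOVA table, and
the radius-vs-depth fits.  A p-value above 0.05 in every ANOVA row mirrors
the finding that the sensing volume is stable across the band.
"""

from oecp import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, noise_rho=1e-3))

print("condition summaries at 300 MHz (mean +/- sample SD, mm)")
sel = report.summaries[report.summaries.frequency_hz == 300e6]
for _, row in sel.iterrows():
    print(
        f"  {row.material:>16} {row.probe} {row.axis:<10} "
        f"{row.mean_mm:.3f} +/- {row.sd_mm:.3f} (n={row.n})"
    )

print("\nfrequency-stability one-way ANOVA (7 frequencies x 5 replicates)")
for _, row in report.anova.iterrows():
    print(
        f"  {row.material:>16} {row.probe} {row.axis:<10} "
        f"F={row.f_statistic:6.3f}  p={row.p_value:.4f}"
    )

print("\nradius-on-depth OLS per probe at 300 MHz")
sel = report.fits[report.fits.frequency_hz == 300e6]
for _, row in sel.iterrows():
    print(
        f"  {row.probe}: radius = {row.slope:.3f} * depth {row.intercept:+.3f}, "
        f"R^2 = {row.r_squared:.4f} (n={row.n})"
    )
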