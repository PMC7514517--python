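"""Calibrate, fit moment trend lines, and verify an out-of-window forecast.

Uses a planted panel with exactly linear trends: per-moment targets and
per-unit totals follow straight lines, so the regression-based forecast
machinery (constant per-capita rates, OLS-extrapolated totals, OLS-predicted
moment targets) can be checked against held-out years.
"""

from maxentpop import (
    GeneratorConfig,
    ModelConfig,
    PlantedSpec,
    calibrate,
    forecast,
    generate_planted_panel,
)

cfg = GeneratorConfig(seed=42, years=(1999, 2015), integer_counts=False)
panel, truth = generate_planted_panel(
    cfg, PlantedSpec(m_max=5, drift=0.15, truth_mode="linear")
)

mc = ModelConfig(m_max=truth.m_max, moment_reference="current")
cal = calibrate(panel, range(2000, 2011), mc)
fc = forecast(panel, cal, range(2011, 2016))

print("fitted moment trend lines (target = slope x year + intercept):")
for reg in fc.regressions:
    print(
        f"  moment {reg.m}: slope {reg.slope:12.5g}  intercept {reg.intercept:14.6g}"
        f"  correlation {reg.correlation:+.4f}"
    )

print(f"\ncalibration 2000-2010 mean relative error: {cal.window_mean_rel_err_pct:.3f}%")
for r in fc.results:
    print(f"  verification {r.year}: mean relative error {r.mean_rel_err_pct:6.3f}%")
print(f"forecast window mean: {fc.window_mean_rel_err_pct:.3f}%")
print()
print("With linear trends the forecast error stays at the calibration level:")
print("trend extrapolation is exact and only the moment truncation error remains.")
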