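"""Calibrate the integrated model and compare restriction configurations.

Reproduces the central calibration experiment on a synthetic panel: a
marginal single-flow model, a moments-only model and the integrated model
(three flow rows + ten index moments, units reindexed in descending
population order, moment targets from the previous year's distribution).
"""

from maxentpop import GeneratorConfig, ModelConfig, calibrate, error_report, generate_panel

panel = generate_panel(GeneratorConfig(seed=7, years=(1999, 2010)))
years = range(2000, 2011)

configs = {
    "students only (marginal)": ModelConfig(flow_variables=("students",), m_max=0),
    "ten moments only": ModelConfig(flow_variables=(), m_max=10),
    "integrated (3 flows + 10 moments)": ModelConfig(m_max=10),
}
for name, cfg in configs.items():
    cal = calibrate(panel, years, cfg)
    print(
        f"{name:36s} mean relative error {cal.window_mean_rel_err_pct:7.3f}%   "
        f"RMSE {cal.window_rmse:.6f}"
    )

cal = calibrate(panel, years, ModelConfig(m_max=10))
rep = error_report(cal.results, cal.ordering)
head = rep.per_tu.head(3)
tail = rep.per_tu.tail(3)
print("\nper-unit mean relative error, most populated units:")
print(head.to_string(index=False))
print("least populated units:")
print(tail.to_string(index=False))
print()
print("Flow restrictions alone cannot localize the distribution; adding index")
print("moments of the previous year collapses the error to a few percent.  On")
print("noisy or real panels the residual error concentrates in the small units")
print("at the tail of the ordering; the per-unit profile above makes that")
print("comparison directly.")
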