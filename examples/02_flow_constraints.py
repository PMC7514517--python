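"""Build the three socio-ecological flow restrictions for one year.

A flow restriction couples each unit's flow total and per-capita rate
(g_i = total_i x rate_i) to a national target: the self-weighted mean per
department times the national per-capita rate.  The observed population
shares satisfy every such restriction identically — the restrictions carry
the macro-state information without fixing the distribution outright.
"""

import numpy as np

from maxentpop import GeneratorConfig, MacroState, build_flow_constraint, generate_panel

panel = generate_panel(GeneratorConfig(seed=11, years=(2007, 2007)))
records = panel.records(2007)
macro = MacroState.from_records(records)
shares = np.array([r.b for r in records]) / macro.B

print(f"national totals: B={macro.B:.3e} inhabitants, U={macro.U:.3e} students,")
print(f"                 CE={macro.CE:.3e} kWh, CW={macro.CW:.3e} m^3")
print(f"per-capita rates: A={macro.A:.4f} students/inhab, E={macro.E:.1f} kWh/inhab,")
print(f"                  W={macro.W:.1f} m^3/inhab")
print()
for variable in ("students", "electricity", "water"):
    row = build_flow_constraint(records, variable, macro)
    lhs = float(row.g @ shares)
    print(f"{row.label:18s} target C = {row.C:.6e}   sum p_i g_i = {lhs:.6e}")
print()
print("Each left-hand side equals its target to machine precision: the true")
print("shares are always feasible for the flow restrictions.")
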