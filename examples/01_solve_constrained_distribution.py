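"""Solve a small maximum-entropy problem under a mean-index constraint.

Among all distributions on five units whose mean index is 2.1 (pulled below
the symmetric value 3), the entropy maximizer is the geometric-like
exponential family member shown here.
"""

import numpy as np

from maxentpop import ConstraintSet, solve_maxent

g = np.arange(1.0, 6.0)  # unit indices 1..5
cs = ConstraintSet(g[None, :], np.array([2.1]), labels=("mean index",))
sol = solve_maxent(cs)

print("shares        :", np.round(sol.p.p, 5))
print("entropy (nats):", round(sol.entropy, 5), "of at most", round(np.log(5), 5))
print("multiplier    :", round(sol.lambdas[0], 5))
print("residual      :", f"{sol.residuals[0]:.2e}", "after", sol.iterations, "iterations")
print()
print("The shares decay geometrically: the constraint pushes mass toward low")
print("indices while entropy keeps the distribution as even as possible.")
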