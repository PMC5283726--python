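"""Reinfection counting: better early dynamics, identical endemic state.

Node states carry the number of past infections (capped at L).  The
endemic equilibrium equals the standard pairwise model's for every L, and
the quasi-equilibrium prevalence is reached long before a significant
fraction of the population hits the cap.
"""

import numpy as np

from sisnet import (EpidemicParams, build_pairwise, build_reinfection_model,
                    growth_rate_ode, solve_endemic)

N, k, L = 10000.0, 3, 50
params = EpidemicParams(tau=1.0, gamma=1.0)

pw = build_pairwise(N, k, params)
prev_pw = solve_endemic(pw).prevalence
rm = build_reinfection_model(N, k, params, L)
prev_rm = solve_endemic(rm).prevalence
print(f"pairwise endemic prevalence      : {prev_pw:.6f}")
print(f"reinfection (L={L}) endemic       : {prev_rm:.6f}"
      f"   |difference| = {abs(prev_rm - prev_pw):.2e}")

print(f"pairwise growth rate             : {growth_rate_ode(pw):.4f}")
print(f"reinfection (L={L}) growth rate   : {growth_rate_ode(rm):.4f}")

# how much of the population has hit the cap when prevalence equilibrates?
t_grid = np.linspace(0, 40, 81)
_, Y = rm.integrate(rm.initial_state(1e-3), t_grid)
for t, y in zip(t_grid, Y):
    if abs(rm.prevalence(y) - prev_pw) < 0.01 * prev_pw:
        frac_L = rm.observables(y)["class_L_fraction"]
        print(f"prevalence within 1% of endemic at t = {t:.1f}; "
              f"fraction in the cap class: {frac_L:.3%}")
        break

print("\nThe counting classes refine transients only: the equilibrium is")
print("exactly the pairwise one, reached before the cap matters.")
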