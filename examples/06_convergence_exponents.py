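"""Error scaling of the closure hierarchies at the critical point.

At the (simulation-estimated) critical transmission rate the true endemic
prevalence vanishes, so a closure model's predicted prevalence there IS
its error.  Fitting log(error) against log(order) over the structured
orders (>= 2) measures how fast each hierarchy converges.
"""

from sisnet import (chain_builder, error_scaling, k3_motif_builder,
                    k3_neighbourhood_builder)

print("k = 3, tau_C = 0.544 (estimated from large-scale simulation):")
fit = error_scaling(k3_motif_builder(), [2, 3, 4], tau_ref=0.544)
print(f"  motif family m=2..4        : errors {[f'{e:.4f}' for e in fit.errors]}"
      f" -> exponent {fit.exponent:.2f}")
fit = error_scaling(k3_neighbourhood_builder(), [2, 3], tau_ref=0.544)
print(f"  neighbourhood family n=2..3: errors {[f'{e:.4f}' for e in fit.errors]}"
      f" -> exponent {fit.exponent:.2f}")

print("k = 2, tau_C = 1.6489 (contact process):")
fit = error_scaling(chain_builder(), list(range(2, 13)), tau_ref=1.6489)
print(f"  chain family m=2..12       : exponent {fit.exponent:.3f} "
      f"(drop-lowest {fit.exponent_drop_lowest:.3f}, R^2 {fit.r_squared:.3f})")

print("\nThe k=3 hierarchies converge fast (|exponent| ~ 3); the 1-d contact")
print("process converges extremely slowly (~ m^-0.27): near criticality the")
print("correlation length exceeds any finite motif.")
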