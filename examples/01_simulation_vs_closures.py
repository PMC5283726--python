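"""Endemic prevalence: exact simulation against the closure hierarchy.

Builds a locally tree-like 3-regular network, measures the quasi-stationary
prevalence of SIS dynamics at tau = gamma = 1, and compares it with the
predictions of successively richer closure models.  The models approach the
simulated value from above as they resolve more local structure.
"""

from sisnet import (EpidemicParams, build_meanfield, build_neighbourhood_n2,
                    build_neighbourhood_n3, build_k3_motif_model,
                    build_pairwise, generate_k_regular,
                    quasi_stationary_prevalence, solve_endemic)

N, k = 20000, 3
params = EpidemicParams(tau=1.0, gamma=1.0)

net = generate_k_regular(N, k, seed=1)  # girth >= 6: short loops removed
mean_I, mean_SI, _ = quasi_stationary_prevalence(net, params, t_burn=100,
                                                 t_meas=400, seed=2)
print(f"simulated quasi-stationary prevalence : {mean_I / N:.4f}")

for label, model in [
        ("mean-field (m=1)      ", build_meanfield(N, k, params)),
        ("pairwise (m=2)        ", build_pairwise(N, k, params)),
        ("neighbourhood (n=2)   ", build_neighbourhood_n2(N, k, params)),
        ("motif (m=3)           ", build_k3_motif_model(3, N, params).model),
        ("motif (m=4)           ", build_k3_motif_model(4, N, params).model),
        ("neighbourhood (n=3)   ", build_neighbourhood_n3(N, k, params))]:
    prev = solve_endemic(model).prevalence
    print(f"{label}: {prev:.4f}   (excess over simulation "
          f"{prev - mean_I / N:+.4f})")

print("\nEach line is an ODE model's endemic prevalence; the excess shrinks")
print("as the closure captures larger neighbourhoods of the network.")
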