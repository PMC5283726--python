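# sisnet

SIS (susceptible–infectious–susceptible) epidemics on static contact
networks: exact stochastic simulation side by side with a hierarchy of
systematic moment-closure approximations, built for studying *when and how
fast* closure models converge to the true network dynamics.

Most sexually transmitted infections recover to susceptibility rather than
immunity, so their network dynamics are SIS — the contact process: a
susceptible node with `j` infectious neighbours becomes infectious at rate
`τ·j`, every infectious node recovers at rate `γ`. Unlike SIR on trees,
SIS admits no exact low-dimensional reduction; the interesting question is
the quality of the available approximations, which is sharpest on low,
homogeneous degree (k = 2, 3) where local S–I correlations are strongest.

The package implements, on one common ODE-model contract:

| family | order parameter | closure |
|---|---|---|
| mean-field | m = n = 1 | `[SI] ≈ (k/N)[S][I]` |
| pairwise | m = 2 | Kirkwood `[ABC] ≈ ((k−1)/k)[AB][BC]/[B]` |
| reinfection counting | cap L | pairwise over states `(S/I, #past infections ≤ L)` |
| motif (subgraph) | m | all states of connected m-node subgraphs; generalized Kirkwood over the (m+1)-subgraph overlap lattice — chains for k = 2 up to m = 16, path/star motifs for k = 3, m = 3, 4 |
| neighbourhood (effective degree) | n | `[S_y], [I_y]` (n = 2) and canonical radius-2 balls (n = 3) with consistency-closed boundary forces |

plus a degree-structured (risk-structured) mean-field model for
heterogeneous networks, and the simulation side: Molloy–Reed graph
generation with short cycles removed (girth ≥ 6), finite Cayley trees, an
exact numba Gillespie engine with quasi-stationary restarts, a 2^N
master-equation oracle for tiny networks, and variance-reduced estimators
that exploit the exact expected rate of change `τ[SI] − γ[I]` of any
configuration.

## A worked example

```python
from sisnet import (EpidemicParams, build_neighbourhood_n3, build_pairwise,
                    generate_k_regular, quasi_stationary_prevalence,
                    solve_endemic)

params = EpidemicParams(tau=1.0, gamma=1.0)
net = generate_k_regular(20000, 3, seed=1)           # girth >= 6
mean_I, _, _ = quasi_stationary_prevalence(net, params, t_burn=100,
                                           t_meas=400, seed=2)
print(f"simulated prevalence        : {mean_I / net.N:.4f}")
print(f"pairwise (m=2) prediction   : "
      f"{solve_endemic(build_pairwise(20000, 3, params)).prevalence:.4f}")
print(f"neighbourhood n=3 prediction: "
      f"{solve_endemic(build_neighbourhood_n3(20000, 3, params)).prevalence:.4f}")
```

prints

```
simulated prevalence        : 0.5909
pairwise (m=2) prediction   : 0.6000
neighbourhood n=3 prediction: 0.5906
```

— the classic pair approximation overshoots the endemic prevalence by
~0.009 at `τ = γ = 1` on a 3-regular network, while the extended
neighbourhood model is within simulation noise.  The `examples/`
directory walks through each capability: simulation vs the hierarchy,
early growth rates on Cayley trees, reinfection counting, the chain-motif
hierarchy, neighbourhood combinatorics (5 / 7 / 27 / 165 / 65,015
equations), convergence exponents, the simulated critical point, and the
heterogeneity error grid.

A thin CLI mirrors the common queries:

```sh
sisnet count-equations --degrees 1,2,3 -n 3
sisnet solve --family neighbourhood --order 2 -k 3 --tau 1.0
sisnet critical-tau --method sim -k 3 --lo 0.50 --hi 0.60 --seed 1
sisnet scaling --family chain-k2 --tau-ref 1.6489
```

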