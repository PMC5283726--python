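# Methods

## The process and its moment hierarchy

The SIS contact process on an undirected simple graph with adjacency
matrix A: node i is susceptible (S) or infectious (I); S→I at rate
τ·(number of infectious neighbours), I→S at rate γ. All models in the
package are written in the double-sum counting convention: `[A]` is the
expected number of nodes in state A and `[AB]` the expected number of
*ordered* adjacent pairs, so `[SI] = [IS]` equals the number of S–I edges
while `[SS]` and `[II]` count each same-state edge twice; on a k-regular
graph `Σ_B [AB] = k[A]` and `[SS] + 2[SI] + [II] = kN`.

Expectations of single counts obey `d[I]/dt = τ[SI] − γ[I]` exactly; each
approximation family closes the hierarchy at a different level:

* **mean-field** (order 1): `[SI] ≈ (k/N)[S][I]`; endemic prevalence
  `1 − γ/(τk)`, threshold `γ/k`, invasion growth rate `τk − γ`.
* **pairwise** (order 2): pair equations closed by the Kirkwood triple
  `[ABC] ≈ ((k−1)/k)[AB][BC]/[B]`, with `[II]` and `[S]` eliminated by
  conservation. Threshold `γ/(k−1)` (determinant of the 2×2 disease-free
  Jacobian in `([SI],[II])`).
* **reinfection counting** (cap L): node states carry the number of past
  infections, S_p (p = 0..L), I_p (p = 1..L); infection maps S_p to
  I_{min(p+1,L)}. Pair variables `[A_p B_q]` evolve by the subscripted
  pair equations, closed by the Kirkwood form with the *central*
  individual keeping its subscript and summed outer positions
  unsubscripted (`[S_p I] = Σ_q [S_p I_q]`). Summing over subscripts
  reproduces the unsubscripted equations identically (tested), so the
  endemic equilibrium equals the pairwise one for every L while the
  transient — where the correlation between infectious and
  recently-recovered nodes matters — is far more accurate.
* **motif models** (order m): the expected counts of every S/I state of
  connected m-node subgraphs. Rates involve (m+1)-node subgraphs, closed
  by the generalized Kirkwood construction: multiply the constituent
  m-subgraph counts, divide by the over-counted overlap counts one level
  down, correct again at the next level, and so on through the overlap
  lattice. All closures are evaluated in conditional form — the
  probability that the external node is infectious given the motif state —
  with 0/0 defined as 0 and each conditional clipped to its physical
  range.
  * k = 2: the m-motifs are windows of m consecutive nodes (2^m states;
    m = 1 is mean-field, m = 2 pairwise). The boundary closure conditions
    the external node's state on the m−1 nodes nearest the boundary.
    Reflection symmetry is preserved by the dynamics rather than factored
    out; the independent dimension is the number of reversal classes,
    `2^(m−1) + 2^(⌊(m+1)/2⌋−1)`, minus one conservation relation (32,895
    at m = 16).
  * k = 3 (girth ≥ 6, so all small subgraphs are trees): m = 3 tracks
    ordered 3-path counts; m = 4 adds 4-paths and the star (claw). The
    three closure patterns are the 5-path (chain rule), the star
    (`P(x|abc) ≈ P(x|ab)P(x|cb)/P(x|b)` for the third neighbour of the
    path centre), and the "chair" for inner path positions.
* **neighbourhood models** (order n): n = 2 tracks `[S_y], [I_y]`, the
  numbers of S/I nodes with y infectious neighbours; the forces of
  infection on a susceptible neighbour of an S- or I-centre are found by
  re-centring on that susceptible and averaging over consistent
  neighbourhoods (the S–S-edge- and S–I-edge-biased means of τy). n = 3
  tracks canonical radius-2 balls — centre state plus an unordered
  multiset of branches `(root state, multiset of child states)` — with
  all events inside the ball exact. The force on a susceptible
  second-ring node u is obtained by re-centring on u's *parent* v: among
  tracked balls, those whose centre matches v's state, one branch matches
  the branch through the original centre in full, and whose remaining
  root states match {u, v's other children} contribute, weighted by
  count and branch multiplicity; the average number of infectious
  children of the u-matched branch gives the expected infectious outside
  neighbours. Re-centring on the parent (rather than on u itself) is what
  makes the k = 2 ball model coincide *exactly* with the order-5 chain
  motif model — the m = 2n − 1 equivalence, which the tests verify to
  machine precision through the two independent code paths.

### Equation counting for heterogeneous degrees

`count_equations` enumerates canonical configurations: for n = 2, centre
(state, degree d) × unordered multisets of d neighbour (state, degree)
descriptors; for n = 3 each branch additionally carries the unordered
multiset of its d′−1 second-ring (state, degree) descriptors; minus one
global conservation relation. This convention reproduces 5 (k=2), 7
(k=3), 27 (degrees {1,2}), 165 ({1,2,3}) and 65,015 ({1,2,3}, n=3), and
for homogeneous degree equals the dimension of the built models.

### Dimension bookkeeping of the reinfection model

The implementation stores singles and symmetry-reduced pair blocks —
`2L² + 5L + 2` raw variables. The headline dimension reported for the
family, `2L² − 1`, counts independent pair variables only (singles are
pair marginals) after removing the 2L + 2 marginal-consistency relations
and the L recovered-class redundancies; both counts are exposed
(`reinfection_dimension`, `reinfection_raw_dimension`).

## Numerical choices

* **Integration**: LSODA with rtol 1e−8 and atol 1e−10·N for systems up
  to ~600 variables, RK45 beyond (the large systems are non-stiff on the
  relevant time scales). Conservation drift along trajectories is checked
  to < 1e−8 relative.
* **Endemic equilibria** (`solve_endemic`): integrate from seed
  prevalence 1e−3 (pair/motif variables at independence) until the
  residual or the prevalence trend stalls, then polish with a root finder
  (Powell hybrid below 600 variables, Newton–Krylov above) on the
  augmented system in which one row per conservation relation is replaced
  by the conservation residual. The polish is accepted only as a *local*
  refinement (relative step < 0.05): the reinfection system has spurious
  distant fixed points with partially-drained counting classes that a
  global root finder can jump to from the quasi-equilibrium plateau.
  Collapse onto the disease-free state is detected and reported as
  prevalence 0.
* **Growth rates** (`growth_rate_ode`): several closures are *not
  differentiable* at the disease-free equilibrium — ratio terms such as
  `[S_p I]/[S_p]` or the effective-degree forces are 0/0 there and their
  limit depends on the direction of approach, so a finite-difference
  Jacobian is ill-defined (coordinate-wise differencing gives genuinely
  wrong dominant eigenvalues for the n = 2 model). The linearised
  dynamics are positively homogeneous of degree one on the physical cone,
  and the growth rate is computed by a renormalised-flow (nonlinear
  power) iteration: integrate a seed of size 1e−9·N, measure the
  log-slope of the infectious count over Δt = 4, rescale, repeat to
  convergence (1e−10 relative). For smooth models this equals the
  Jacobian eigenvalue (`growth_rate_jacobian` cross-checks mean-field and
  pairwise).
* **Closure guards**: every conditional is clipped to its physical range
  ([0,1] for probabilities, [0, k−1] for expected outside-infectious
  counts); denominators ≤ 0 yield 0. This matters only for roundoff-level
  negative counts near the disease-free state.
* **Degree-distribution fitting**: the truncated discretised Gaussian
  `P(k) ∝ exp(−α(k−K)²)`, k ≥ k_min, is fitted to a target mean and
  variance by trust-region least squares in the re-parameterisation
  curvature + tilt about k_min (`exp(−αx² − βx)`, x = k − k_min), which
  stays well-scaled in the geometric-tail regime α → 0, K → −∞ where the
  raw parameters are collinear. The family's variance at fixed mean is
  bounded above by the geometric tail (e.g. variance ≤ 2 at mean 3 with
  k_min = 2); targets beyond the bound raise a constraint failure.

## Simulation and estimators

* **Gillespie engine**: rejection-free in time with thinning in the event
  choice — the rate bound is `γ n_I + τ Σ_{i∈I} deg_i`; infection
  attempts pick an infectious source (degree-weighted by rejection) and a
  uniform neighbour, accepted if susceptible. Null events advance time
  only, leaving the chain exact. `[I]` and the pair counts are maintained
  incrementally, O(k) per event. A single integer seed fixes the entire
  event sequence.
* **Quasi-stationary conditioning**: on absorption the state is restored
  from a snapshot refreshed every few time units (conditioning on
  non-extinction); the burn-in discards max(10/γ, time of the first
  prevalence-slope sign change).
* **Endemic prevalence estimator**: over the quasi-stationary window the
  exact expected rate `r_t = τ[SI]_t − γ[I]_t` is regressed on the
  prevalence `I_t`; the root of the fitted line is the estimate, with a
  delta-method standard error. On matched windows its sampling variance
  is several-fold below the plain time average's (tested), because the
  regression removes the component of noise that the restoring force
  itself explains.
* **Early growth rates**: on a finite Cayley tree (no clustering), each
  replicate starts with the root infectious and stops when any leaf is
  infected (boundary censoring). The per-replicate estimate is
  `∫r dt / ∫I dt` over the window from the first time `I ≥ min_count` to
  the leaf hit — exact for a clean exponential and variance-reduced by
  using expected rates — pooled with `∫I dt` weights. The instantaneous
  rate starts at the mean-field value `τk − γ` and relaxes downward as
  local correlations build, so estimates with early windows are biased
  upward; defaults (depth 12, min_count 30) trade this bias against
  replicate cost, and the comparison tests use later windows.
* **Critical point by finite-size scaling**
  (`critical_tau_simulation`): a (τ, N) cell is supercritical when the
  prevalence is *sustained* — no absorption/restart event over the whole
  burn-in + measurement window and mean count above 5. The naive
  criterion "mean quasi-stationary count > 5" cannot work: under restart
  conditioning the subcritical occupancy is itself ~5 nodes independent
  of N. The per-size pseudo-threshold is the midpoint of the bracketing
  grid step (0.01 wide), and the critical point is the least-squares
  extrapolation linear in 1/N; the quoted uncertainty combines half the
  grid step with the extrapolation standard error. With sizes
  2,000–20,000 this gives τ_C = 0.543–0.545 for k = 3 (γ = 1) across
  seeds. For k = 2 the same protocol at desk scale only brackets the
  contact-process value 1.6489 from below, with bias decreasing in N —
  the 1-d correlation length makes full convergence far more expensive.

## Convergence analysis

At the critical transmission rate the true endemic prevalence vanishes in
the large-N limit, so a closure model's predicted prevalence there *is*
its error. `error_scaling` computes these errors per order and fits
log(error) against log(order) by least squares. The fits are taken over
the structured orders (m, n ≥ 2), uniformly for all three hierarchies:
the order-1 mean-field model resolves no network structure, its threshold
(γ/k) lies far from the evaluation point, and including it makes the
slope unstable against dropping the lowest order — the robustness
diagnostic `exponent_drop_lowest` shifts by ~26% for the k = 3 motif
family with order 1 included versus ~4% without. Measured exponents at
N-independent scale: k = 3 motif family (m = 2..4 at τ = 0.544) ≈ −2.9;
k = 3 neighbourhood family (n = 2..3) ≈ −3.4 (−3.3 with n = 1 included);
k = 2 chain family (m = 2..12 at τ = 1.6489) ≈ −0.29, a clean power law
(R² > 0.99) whose slow decay reflects the diverging correlation length of
the 1-d contact process. The chain range stops at m = 12 (4,096-variable
solves) rather than m = 16 (65,536), which changes the slope by < 1%.

## What the generators emulate — and what they do not

`generate_k_regular` produces configuration-model graphs with cycles
shorter than 6 removed by random double-edge swaps, so the closure
models' tree-likeness assumption holds out to the motif sizes used; real
contact networks are clustered, degree-assortative and temporally
dynamic, none of which these ensembles (or the closures) represent.
Passing tests therefore demonstrate correctness of the hierarchy *on its
own model class* — static, locally tree-like, Markovian SIS — not
accuracy on empirical sexual-contact networks. The heterogeneity grid
uses i.i.d. truncated-Gaussian degrees with τ = 2/mean so that endemic
prevalence stays in a comparable band; degree correlations are absent by
construction.

## Known limitations

* The k = 3 motif closures (m = 3, 4) follow the generalized Kirkwood
  recipe in conditional form; other faithful realisations of the same
  recipe (e.g. unnormalised count quotients, alternative marginal
  consistency constraints) differ at the few-percent level in the
  near-critical error, which is within the stated tolerance of the
  convergence-exponent checks but visible in their third significant
  digit.
* The n = 3 heterogeneous-degree systems are counted, not solved
  (65,015 equations for degrees {1,2,3}).
* Quasi-stationary simulation estimates carry an O(1/N) conditioning
  bias; the estimator comparisons use N large enough that it is below
  their noise floors.
* `DegreeDistSpec.rho` (the normaliser of the raw Gaussian weights)
  overflows for extreme geometric-tail fits; the pmf itself is computed
  stably in the expanded form and is unaffected.
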