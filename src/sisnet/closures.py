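"""Closure-model contract and the basic SIS closures.

A :class:`ClosureModel` is a finite ODE system produced by a model builder:
state labels, a right-hand side, conservation relations, and hooks for
extracting prevalence, building initial conditions and linearising about the
disease-free equilibrium.  The builders here are

* ``build_meanfield`` — the classic homogeneous model, closing the pair
  count by independence, [SI] ~ (k/N)[S][I];
* ``build_pairwise`` — the standard pair approximation, closing triples by
  the Kirkwood form [ABC] ~ ((k-1)/k) [AB][BC]/[B];
* ``build_risk_structured_meanfield`` — one S/I pair per degree class with
  degree-weighted (proportionate) mixing and no pair correlations.

Pair counts follow the directed convention: [SI] counts ordered S-I
adjacent pairs, so [SI] = [IS] and [SS] counts each S-S edge twice.  Under
this convention sum_B [AB] = k [A] on a k-regular graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import integrate as sci_integrate
from scipy import linalg as sla
from scipy import optimize
from scipy.sparse.linalg import LinearOperator, eigs

from .params import EpidemicParams


class SolverFailure(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# the model contract
# ---------------------------------------------------------------------------

@dataclass
class ClosureModel:
    """A finite ODE approximation of SIS dynamics on a network.

    Attributes
    ----------
    labels : names of the state variables (length = n_vars).
    rhs : map y -> dy/dt with epidemic parameters baked in.
    conserved : list of (a, c) pairs; a @ y == c is preserved by rhs.
    dimension : number of independent variables (n_vars minus independent
        conservation relations); the raw variable count is ``n_vars``.
    dfe_state : the disease-free equilibrium state vector.
    infection_mask : boolean array selecting the coordinates whose
        linearisation about the DFE carries the epidemic growth (neutral
        redistribution directions are excluded).
    prevalence : map y -> fraction infectious in [0, 1].
    initial_state : map seed-prevalence -> state vector (pair/motif
        variables at independence values).
    observables : map y -> dict with at least S and I (and SS/SI/II where
        defined) on the node/pair counting scale.
    """

    name: str
    labels: list
    rhs: Callable
    N: float
    k: float
    params: EpidemicParams
    dfe_state: np.ndarray
    infection_mask: np.ndarray
    prevalence: Callable
    initial_state: Callable
    conserved: list = field(default_factory=list)
    dimension: int = 0
    observables: Optional[Callable] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_vars(self):
        return len(self.labels)

    def rhs_t(self, t, y):
        return self.rhs(y)

    def integrate(self, y0, t_grid, rtol=1e-8, atol=None, method=None):
        """Integrate the model over ``t_grid`` (stiff-capable for small
        systems, explicit RK for large ones); returns (t_grid, Y)."""
        y0 = np.asarray(y0, dtype=float)
        if atol is None:
            atol = 1e-10 * max(self.N, 1.0)
        if method is None:
            method = "LSODA" if self.n_vars <= 600 else "RK45"
        sol = sci_integrate.solve_ivp(
            self.rhs_t, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
            method=method, rtol=rtol, atol=atol)
        if not sol.success:
            raise SolverFailure(f"integration failed: {sol.message}")
        return sol.t, sol.y.T

    def check_conservation(self, Y):
        """Max relative drift of every conservation relation over states Y."""
        drift = 0.0
        for a, c in self.conserved:
            vals = Y @ a
            drift = max(drift, float(np.max(np.abs(vals - c)) / max(abs(c), 1.0)))
        return drift


@dataclass
class EquilibriumResult:
    prevalence: float
    state: np.ndarray
    stable: Optional[bool]
    residual: float
    converged: bool
    zero_slope: bool = False
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generic machinery
# ---------------------------------------------------------------------------

def _augmented_root_fun(model):
    """Replace one rhs row per conservation relation by the conservation
    residual, making the fixed point isolated for Newton-type solvers."""
    rows = []
    used = set()
    for a, c in model.conserved:
        order = np.argsort(-np.abs(a))
        row = next(int(i) for i in order if int(i) not in used)
        used.add(row)
        rows.append((row, a, c))
    scale = max(model.N, 1.0)

    def fun(y):
        r = np.asarray(model.rhs(y), dtype=float).copy()
        for row, a, c in rows:
            r[row] = (a @ y - c)
        return r / scale

    return fun


def solve_endemic(model, init=1e-3, t_chunk=60.0, max_chunks=60,
                  res_tol=1e-11, polish=True):
    """Endemic equilibrium of a closure model.

    Integrates from a small seed prevalence until near-stationarity, then
    polishes with a damped-Newton root find (hybr for small systems,
    Newton–Krylov for large ones).  If the trajectory collapses onto the
    disease-free state the DFE is reported with prevalence 0; otherwise the
    stable endemic equilibrium is returned.
    """
    y = model.initial_state(init)
    scale = max(model.N, 1.0)
    t_done = 0.0
    hist = []
    for _ in range(max_chunks):
        _, Y = model.integrate(y, np.array([0.0, t_chunk]))
        y = Y[-1]
        t_done += t_chunk
        prev = model.prevalence(y)
        hist.append(prev)
        res = np.max(np.abs(model.rhs(y))) / scale
        if prev < 1e-9:
            return EquilibriumResult(0.0, model.dfe_state.copy(), True, res,
                                     True, diagnostics={"t": t_done,
                                                        "branch": "dfe"})
        if res < res_tol:
            break
        # slow near-critical relaxation: hand over to Newton once the
        # trajectory has clearly stopped moving on the prevalence scale
        if len(hist) >= 3 and abs(hist[-1] - hist[-2]) < 1e-7 * max(prev, 1e-6):
            break
    res = np.max(np.abs(model.rhs(y))) / scale
    converged = res < res_tol
    if polish:
        fun = _augmented_root_fun(model)
        try:
            if model.n_vars <= 600:
                sol = optimize.root(fun, y, method="hybr",
                                    options={"xtol": 1e-13})
                cand = sol.x
            else:
                cand = optimize.newton_krylov(fun, y, f_tol=1e-13,
                                              maxiter=200)
            # accept only a local refinement: the root finder must not jump
            # to a distant (possibly spurious) fixed point
            step_ok = np.max(np.abs(cand - y)) / scale < 0.05
            if step_ok and np.max(np.abs(model.rhs(cand))) / scale < max(res, 1e-9):
                y = cand
        except Exception:
            pass
        res = np.max(np.abs(model.rhs(y))) / scale
        converged = res < 1e-8
    prev = model.prevalence(y)
    if prev < 1e-9:
        return EquilibriumResult(0.0, model.dfe_state.copy(), True, res, True,
                                 diagnostics={"t": t_done, "branch": "dfe"})
    stable = None
    if model.n_vars <= 400:
        J = _fd_jacobian(model.rhs, y, np.arange(model.n_vars), scale)
        ev = np.linalg.eigvals(J)
        # conservation relations contribute exact zero modes; ignore them
        tol0 = 1e-7 * max(1.0, np.abs(ev).max())
        stable = bool(np.max(ev.real[ev.real > tol0], initial=-np.inf) <= tol0)
    return EquilibriumResult(float(prev), y, stable, res, converged,
                             diagnostics={"t": t_done, "branch": "endemic"})


def _fd_jacobian(rhs, y0, idx, scale):
    """Central-difference Jacobian of rhs restricted to coordinates idx."""
    y0 = np.asarray(y0, dtype=float)
    n = len(idx)
    J = np.empty((n, n))
    h = 1e-7 * max(scale, 1.0)
    for col, j in enumerate(idx):
        yp = y0.copy()
        ym = y0.copy()
        yp[j] += h
        ym[j] -= h
        J[:, col] = (np.asarray(rhs(yp)) - np.asarray(rhs(ym)))[idx] / (2 * h)
    return J


def growth_rate_ode(model, eps=1e-9, dt=4.0, tol=1e-10, max_iters=80):
    """Early epidemic growth rate at the disease-free equilibrium.

    The linearised dynamics about the DFE are positively homogeneous of
    degree one but, for closures whose denominators vanish there (ratio
    terms like [S_p I]/[S_p]), not a plain Jacobian: the response depends
    on the direction of the perturbation within the physical cone.  The
    dominant growth rate is therefore computed by a renormalised-flow
    (nonlinear power) iteration: integrate a small physical seed, measure
    the log-slope of the infectious count, rescale the perturbation back to
    size ``eps`` and repeat until the slope converges.  For smooth models
    this equals the dominant eigenvalue of the DFE Jacobian restricted to
    the infection subspace.
    """
    dfe = model.dfe_state
    scale = max(model.N, 1.0)
    delta = model.initial_state(eps) - dfe
    m0 = model.prevalence(dfe + delta) * model.N
    if m0 <= 0:
        raise SolverFailure("seed state carries no infection")
    delta *= eps * scale / m0
    r_prev = None
    for _ in range(max_iters):
        y = dfe + delta
        m_start = model.prevalence(y) * model.N
        _, Y = model.integrate(y, np.array([0.0, dt]), rtol=1e-11,
                               atol=1e-8 * eps * scale)
        y_end = Y[-1]
        m_end = model.prevalence(y_end) * model.N
        if not np.isfinite(m_end) or m_end <= 0:
            raise SolverFailure("growth-rate flow left the physical cone")
        r = np.log(m_end / m_start) / dt
        delta = (y_end - dfe) * (eps * scale / m_end)
        if r_prev is not None and abs(r - r_prev) < tol * max(1.0, abs(r)):
            return float(r)
        r_prev = r
    return float(r_prev)


def growth_rate_jacobian(model):
    """Dominant DFE eigenvalue by finite-difference Jacobian (valid for
    models whose closure is smooth at the DFE, e.g. mean-field/pairwise)."""
    idx = np.flatnonzero(model.infection_mask)
    J = _fd_jacobian(model.rhs, model.dfe_state, idx, max(model.N, 1.0))
    return float(np.linalg.eigvals(J).real.max())


def critical_tau_ode(builder, gamma=1.0, bracket=(0.05, 3.0), tol=1e-4,
                     method="equilibrium"):
    """Critical transmission rate of a closure family by bisection.

    ``builder`` maps tau -> ClosureModel.  With ``method='equilibrium'``
    (default) the bisection is on the existence of a stable endemic
    equilibrium (prevalence > 1e-6); ``method='growth'`` bisects on the sign
    of the disease-free growth rate (equivalent for these models and much
    cheaper).
    """
    lo, hi = bracket

    def supercritical(tau):
        model = builder(tau)
        if method == "growth":
            return growth_rate_ode(model) > 0
        return solve_endemic(model).prevalence > 1e-6

    if supercritical(lo) or not supercritical(hi):
        raise ValueError(f"bracket {bracket} does not straddle the threshold")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if supercritical(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def relative_error(prev_ode, prev_sim):
    """Percentage relative error 100 * |ODE - simulation| / simulation."""
    if prev_sim <= 0:
        raise ValueError("simulation prevalence must be positive")
    return 100.0 * abs(prev_ode - prev_sim) / prev_sim


# ---------------------------------------------------------------------------
# mean-field
# ---------------------------------------------------------------------------

def build_meanfield(N, k, params):
    """Homogeneous mean-field SIS model: d[I]/dt = tau (k/N)[S][I] - gamma [I]
    with [S] = N - [I].  One independent dimension."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tau, gamma = params.tau, params.gamma

    def rhs(y):
        I = y[0]
        S = N - I
        return np.array([tau * (k / N) * S * I - gamma * I])

    def observables(y):
        I = float(y[0])
        S = N - I
        SI = (k / N) * S * I
        return {"S": S, "I": I, "SS": (k / N) * S * S, "SI": SI,
                "II": (k / N) * I * I}

    return ClosureModel(
        name="meanfield", labels=["I"], rhs=rhs, N=N, k=k, params=params,
        dfe_state=np.array([0.0]), infection_mask=np.array([True]),
        prevalence=lambda y: float(y[0]) / N,
        initial_state=lambda eps: np.array([eps * N]),
        conserved=[], dimension=1, observables=observables,
        meta={"family": "meanfield", "order": 1})


def meanfield_endemic_prevalence(k, params):
    """Closed-form endemic prevalence 1 - gamma/(tau k) (0 if subcritical)."""
    if params.tau * k <= params.gamma:
        return 0.0
    return 1.0 - params.gamma / (params.tau * k)


# ---------------------------------------------------------------------------
# standard pairwise (m = 2)
# ---------------------------------------------------------------------------

def kirkwood_triple(AB, BC, B, k):
    """[ABC] ~ ((k-1)/k) [AB][BC]/[B], defined as 0 when [B] = 0 (pair
    counts vanish at least linearly with the singleton count)."""
    if B <= 0:
        return 0.0
    return (k - 1) / k * AB * BC / B


def build_pairwise(N, k, params):
    """Standard pair approximation on a k-regular network.

    Variables [SS] and [SI] (directed pair counts); [II] = kN - [SS] - 2[SI]
    and [S] = ([SS] + [SI])/k are eliminated.  Triples are closed by the
    Kirkwood form.
    """
    if k < 2:
        raise ValueError("pairwise model needs k >= 2")
    tau, gamma = params.tau, params.gamma
    kN = k * N

    def rhs(y):
        SS, SI = y
        S = (SS + SI) / k
        II = kN - SS - 2 * SI
        SSI = kirkwood_triple(SS, SI, S, k)
        ISI = kirkwood_triple(SI, SI, S, k)
        dSS = 2 * gamma * SI - 2 * tau * SSI
        dSI = gamma * II + tau * SSI - tau * SI - gamma * SI - tau * ISI
        return np.array([dSS, dSI])

    def prevalence(y):
        SS, SI = y
        return float(N - (SS + SI) / k) / N

    def initial_state(eps):
        S, I = (1 - eps) * N, eps * N
        return np.array([k / N * S * S, k / N * S * I])

    def observables(y):
        SS, SI = float(y[0]), float(y[1])
        S = (SS + SI) / k
        return {"S": S, "I": N - S, "SS": SS, "SI": SI,
                "II": kN - SS - 2 * SI}

    return ClosureModel(
        name="pairwise", labels=["SS", "SI"], rhs=rhs, N=N, k=k,
        params=params, dfe_state=np.array([kN, 0.0]),
        infection_mask=np.array([True, True]),
        prevalence=prevalence, initial_state=initial_state,
        conserved=[], dimension=2, observables=observables,
        meta={"family": "pairwise", "order": 2})


# ---------------------------------------------------------------------------
# risk-structured mean-field
# ---------------------------------------------------------------------------

def build_risk_structured_meanfield(spec, N, params, p_floor=1e-10):
    """Degree-structured mean-field model with proportionate mixing.

    One S/I compartment pair per degree class; the force of infection on a
    degree-k susceptible is tau * k * Theta where
    Theta = sum_k' k' [I_k'] / sum_k' k' N_k' is the probability that a
    randomly chosen contact stub points at an infectious node.  Degree
    classes with probability below ``p_floor`` are dropped.  For a point
    mass this reduces exactly to ``build_meanfield``.
    """
    tau, gamma = params.tau, params.gamma
    pmf = np.asarray(spec.pmf, dtype=float)
    support = np.asarray(spec.support, dtype=float)
    keep = pmf > p_floor
    degs = support[keep]
    Nk = N * pmf[keep] / pmf[keep].sum()
    stub_total = float((degs * Nk).sum())
    n = len(degs)
    kbar = float((degs * Nk).sum() / N)

    def rhs(y):
        I = y
        S = Nk - I
        theta = float((degs * I).sum()) / stub_total
        return tau * degs * S * theta - gamma * I

    def prevalence(y):
        return float(y.sum()) / N

    def initial_state(eps):
        return eps * Nk

    def observables(y):
        I = float(y.sum())
        return {"S": N - I, "I": I}

    return ClosureModel(
        name="risk_structured_meanfield",
        labels=[f"I_k{int(d)}" for d in degs],
        rhs=rhs, N=N, k=kbar, params=params,
        dfe_state=np.zeros(n), infection_mask=np.ones(n, dtype=bool),
        prevalence=prevalence, initial_state=initial_state,
        conserved=[], dimension=n, observables=observables,
        meta={"family": "risk_structured_meanfield", "degrees": degs.tolist(),
              "class_sizes": Nk.tolist()})
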