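"""Exact stochastic SIS dynamics and variance-reduced estimators.

The process is the contact process of the package overview: a susceptible
node with j infectious neighbours becomes infectious at rate tau * j, and
every infectious node recovers at rate gamma.  ``gillespie_sis`` draws
statistically exact realisations (numba event loop); a full
master-equation solver on the 2^N state space serves as an oracle for tiny
networks.

Two estimator improvements exploit that the *expected* rate of change of
prevalence, tau [SI] - gamma [I], is an exact function of the current
configuration: ``endemic_prevalence_estimate`` locates the endemic
equilibrium as the root of the rate-vs-prevalence regression (smaller
variance than the plain time average), and ``early_growth_rate_sim``
estimates the invasion growth rate on a Cayley tree from accumulated
expected rates, censoring each run when infection reaches a leaf.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from ._kernels import gillespie_run, qs_mean_prevalence
from .networks import Network, generate_cayley_tree
from .params import EpidemicParams


@dataclass
class SimState:
    """A network configuration with cached [I] and [SI] counts.

    [SI] follows the double-sum convention: each unordered S-I edge
    contributes one ordered (S, I) pair, so [SI] equals the number of S-I
    edges (and [IS] = [SI]).
    """

    node_states: np.ndarray  # int8, 0 = S, 1 = I
    I: int
    SI: int

    @classmethod
    def from_states(cls, network, node_states):
        s = np.asarray(node_states, dtype=np.int8)
        I = int(s.sum())
        SI = 0
        for i, j in network.edges:
            if s[i] != s[j]:
                SI += 1
        return cls(node_states=s, I=I, SI=SI)


@dataclass
class Trajectory:
    """Recorded time series of node and pair counts.

    Columns use the double-sum (ordered) pair convention of the closure
    models: SS and II count both orderings of a same-state edge (twice the
    undirected counts) while SI counts the S-I edges once per ordered
    direction consistent with [SI] = [IS].
    """

    times: np.ndarray
    I: np.ndarray
    SI: np.ndarray
    SS: np.ndarray
    II: np.ndarray
    N: int
    meta: dict = field(default_factory=dict)

    @property
    def S(self):
        return self.N - self.I

    def expected_rates(self, params):
        return params.tau * self.SI - params.gamma * self.I

    def to_frame(self, params=None):
        df = pd.DataFrame({"t": self.times, "S": self.S, "I": self.I,
                           "SS": self.SS, "SI": self.SI, "II": self.II})
        if params is not None:
            df["expected_rate"] = self.expected_rates(params)
        return df

    def write_csv(self, path, params=None):
        path = Path(path)
        self.to_frame(params).to_csv(path, index=False)
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump({"N": self.N, **self.meta}, fh, indent=1, default=str)

    @classmethod
    def read_csv(cls, path):
        path = Path(path)
        df = pd.read_csv(path)
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        N = int(meta.get("N", (df["S"] + df["I"]).iloc[0]))
        return cls(times=df["t"].to_numpy(), I=df["I"].to_numpy(),
                   SI=df["SI"].to_numpy(), SS=df["SS"].to_numpy(),
                   II=df["II"].to_numpy(), N=N, meta=meta)


def _initial_state_array(network, initial_infected, rng):
    state = np.zeros(network.N, dtype=np.int8)
    if np.isscalar(initial_infected):
        count = int(initial_infected)
        if count < 1:
            raise ValueError("initial infection must be non-empty")
        idx = rng.choice(network.N, size=count, replace=False)
        state[idx] = 1
    else:
        idx = list(initial_infected)
        if not idx:
            raise ValueError("initial infection must be non-empty")
        state[np.asarray(idx, dtype=int)] = 1
    return state


def gillespie_sis(network, params, initial_infected, t_max, seed=None,
                  record_interval=0.1, qs_restart=False, snapshot_dt=1.0,
                  stop_nodes=None):
    """Statistically exact SIS realisation on ``network``.

    Records counts at multiples of ``record_interval`` plus the
    absorption/stop time.  ``qs_restart=True`` restores a periodically
    refreshed snapshot on absorption (quasi-stationary conditioning).
    ``stop_nodes`` (an iterable of node ids) stops the run as soon as one
    of them becomes infectious (used for Cayley-tree leaf censoring).
    Identical (network, params, seed) gives an identical event sequence.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(seed)
    state = _initial_state_array(network, initial_infected, rng)
    indptr, indices = network.to_csr()
    stop_mask = np.zeros(network.N, dtype=np.bool_)
    if stop_nodes is not None:
        stop_mask[np.asarray(list(stop_nodes), dtype=int)] = True
    times, I, SI, ss, ii, n_restarts, t_stop = gillespie_run(
        indptr, indices, state, float(params.tau), float(params.gamma),
        float(t_max), float(record_interval), int(rng.integers(2**31)),
        bool(qs_restart), float(snapshot_dt), stop_mask)
    return Trajectory(
        times=times, I=I.astype(float), SI=SI.astype(float),
        SS=2.0 * ss, II=2.0 * ii, N=network.N,
        meta={"tau": params.tau, "gamma": params.gamma, "seed": seed,
              "n_restarts": int(n_restarts),
              "t_stop": float(t_stop), **network.meta})


# ---------------------------------------------------------------------------
# master-equation oracle
# ---------------------------------------------------------------------------

def master_equation_oracle(network, params, initial_distribution, t_grid):
    """Exact expectations E[I](t), E[SI](t) by solving the forward equation
    on the full 2^N state space (N <= 12).  Verification oracle only.

    ``initial_distribution`` may be a node-state tuple/array (a point mass)
    or a full probability vector over the 2^N states (bit i of the state
    index = node i infectious).
    """
    N = network.N
    if N > 12:
        raise ValueError("master equation oracle limited to N <= 12")
    n_states = 1 << N
    adj = network.adjacency_lists()
    tau, gamma = params.tau, params.gamma

    rows, cols, vals = [], [], []
    nI = np.zeros(n_states)
    nSI = np.zeros(n_states)
    for s in range(n_states):
        out = 0.0
        cnt_si = 0
        for i in range(N):
            inf_n = sum((s >> j) & 1 for j in adj[i])
            if (s >> i) & 1:
                nI[s] += 1
                rows.append(s ^ (1 << i))
                cols.append(s)
                vals.append(gamma)
                out += gamma
            else:
                cnt_si += inf_n
                if inf_n:
                    rows.append(s | (1 << i))
                    cols.append(s)
                    vals.append(tau * inf_n)
                    out += tau * inf_n
        nSI[s] = cnt_si
        rows.append(s)
        cols.append(s)
        vals.append(-out)
    Q = sparse.csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))

    p0 = np.zeros(n_states)
    init = np.asarray(initial_distribution)
    if init.shape == (n_states,) and not np.issubdtype(init.dtype, np.integer):
        p0[:] = init
    elif len(init) == N:
        idx = sum((1 << i) for i in range(N) if init[i])
        p0[idx] = 1.0
    else:
        p0[:] = init
    p0 /= p0.sum()

    sol = solve_ivp(lambda t, p: Q @ p, (t_grid[0], t_grid[-1]), p0,
                    t_eval=t_grid, method="LSODA", rtol=1e-10,
                    atol=1e-13)
    P = sol.y.T
    EI = P @ nI
    ESI = P @ nSI
    return Trajectory(times=np.asarray(t_grid, dtype=float), I=EI, SI=ESI,
                      SS=np.full(len(t_grid), np.nan),
                      II=np.full(len(t_grid), np.nan), N=N,
                      meta={"oracle": True, "tau": tau, "gamma": gamma})


# ---------------------------------------------------------------------------
# expected-rate estimators
# ---------------------------------------------------------------------------

def expected_rate_of_change(state, params):
    """Exact expected d[I]/dt of a configuration: tau [SI] - gamma [I]."""
    return params.tau * state.SI - params.gamma * state.I


def endemic_prevalence_estimate(trajectory, params, burn_in=None):
    """Endemic prevalence from the rate-vs-prevalence regression.

    Over a quasi-stationary window, the expected rate r_t = tau [SI]_t -
    gamma [I]_t is (noisily) linear in prevalence I_t with negative slope;
    its root is the endemic equilibrium.  Returns (estimate in nodes,
    standard error, zero_slope flag).  The default burn-in discards
    max(10/gamma, time of the first prevalence-slope sign change).
    """
    t = trajectory.times
    if burn_in is None:
        burn_in = 10.0 / params.gamma
        dI = np.diff(trajectory.I)
        sign_change = np.nonzero(np.sign(dI[:-1]) * np.sign(dI[1:]) < 0)[0]
        if len(sign_change):
            burn_in = max(burn_in, t[int(sign_change[0]) + 1])
    keep = t >= burn_in
    I = np.asarray(trajectory.I, dtype=float)[keep]
    r = np.asarray(trajectory.expected_rates(params), dtype=float)[keep]
    if len(I) < 20:
        raise ValueError("need >= 20 points in the quasi-stationary window")
    if np.ptp(I) < 1e-12:
        return float(I[0]), 0.0, True
    X = np.column_stack([np.ones_like(I), I])
    beta, res, *_ = np.linalg.lstsq(X, r, rcond=None)
    a, b = beta
    n = len(I)
    resid = r - X @ beta
    s2 = float(resid @ resid) / max(n - 2, 1)
    cov = s2 * np.linalg.inv(X.T @ X)
    if abs(b) < 1e-12:
        return float(I.mean()), float(I.std(ddof=1) / np.sqrt(n)), True
    root = -a / b
    # delta method for var(-a/b)
    g = np.array([-1.0 / b, a / b ** 2])
    se = float(np.sqrt(g @ cov @ g))
    return float(root), se, False


def naive_prevalence_estimate(trajectory, params, burn_in=None):
    """Plain time-average of prevalence over the same window (baseline)."""
    t = trajectory.times
    if burn_in is None:
        burn_in = 10.0 / params.gamma
    I = np.asarray(trajectory.I, dtype=float)[t >= burn_in]
    return float(I.mean()), float(I.std(ddof=1) / np.sqrt(len(I)))


def early_growth_rate_sim(k, params, depth=10, replicates=20, seed=None,
                          record_interval=0.05, min_count=5):
    """Invasion growth rate on a finite Cayley tree.

    Each replicate starts with the root infectious and runs until any leaf
    becomes infectious (censoring boundary effects).  Per replicate the
    growth rate is estimated as the ratio of accumulated expected rates to
    accumulated prevalence, int r dt / int I dt, over the window from the
    first time I >= min_count to the leaf hit; replicates are pooled with
    int I dt weights.  Returns (rate, standard error, extinction fraction).
    """
    if depth < 3:
        raise ValueError("depth must be >= 3")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = generate_cayley_tree(k, depth)
    leaves = [i for i, d in enumerate(tree.degree_sequence) if d == 1]
    rng = np.random.default_rng(seed)
    rates, weights = [], []
    n_extinct = 0
    for _ in range(replicates):
        traj = gillespie_sis(
            tree, params, initial_infected=[0], t_max=1e4,
            seed=int(rng.integers(2**31)),
            record_interval=record_interval, stop_nodes=leaves)
        if traj.meta["t_stop"] < 0:
            n_extinct += 1
            continue
        I = traj.I
        r = traj.expected_rates(params)
        start = np.argmax(I >= min_count)
        if I[start] < min_count or start >= len(I) - 2:
            n_extinct += 1
            continue
        dt = np.diff(traj.times[start:])
        Imid = 0.5 * (I[start:-1] + I[start + 1:])
        rmid = 0.5 * (r[start:-1] + r[start + 1:])
        int_I = float((Imid * dt).sum())
        int_r = float((rmid * dt).sum())
        if int_I <= 0:
            continue
        rates.append(int_r / int_I)
        weights.append(int_I)
    frac_extinct = n_extinct / replicates
    if not rates:
        return np.nan, np.nan, frac_extinct
    rates = np.array(rates)
    weights = np.array(weights)
    mean = float(np.average(rates, weights=weights))
    if len(rates) > 1:
        var = float(np.average((rates - mean) ** 2, weights=weights))
        se = np.sqrt(var / (len(rates) - 1))
    else:
        se = np.nan
    return mean, float(se), frac_extinct


def quasi_stationary_prevalence(network, params, t_burn=100.0, t_meas=500.0,
                                seed=None, initial_fraction=0.5,
                                snapshot_dt=2.0):
    """Time-averaged quasi-stationary ([I], [SI]) conditioned on
    non-extinction (snapshot-restart method).  Returns (mean I count,
    mean SI edge count, number of restarts)."""
    rng = np.random.default_rng(seed)
    state = np.zeros(network.N, dtype=np.int8)
    idx = rng.choice(network.N, size=max(1, int(initial_fraction * network.N)),
                     replace=False)
    state[idx] = 1
    indptr, indices = network.to_csr()
    mean_I, mean_SI, n_restarts = qs_mean_prevalence(
        indptr, indices, state, float(params.tau), float(params.gamma),
        float(t_burn), float(t_meas), int(rng.integers(2**31)),
        float(snapshot_dt))
    return mean_I, mean_SI, int(n_restarts)
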