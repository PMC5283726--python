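"""Contact-network generation for SIS epidemic studies.

The simulation substrate throughout the package is a static, undirected,
simple graph.  Three ensembles are provided:

* ``generate_k_regular`` — Molloy–Reed (configuration-model) k-regular
  graphs with short cycles removed by degree-preserving double-edge swaps,
  so that the network is locally tree-like (girth >= 6 by default).
* ``generate_cayley_tree`` — finite Cayley trees (internal degree k), which
  eliminate clustering entirely and are used for early-growth-rate studies.
* ``generate_heterogeneous`` — configuration-model graphs whose degrees are
  drawn i.i.d. from a discretised, truncated Gaussian
  ``P(k) = rho * exp(-alpha (k - K)^2)`` for ``k >= k_min``, with
  ``(alpha, K)`` fitted to a requested mean and variance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import optimize


class ConstraintFailure(RuntimeError):
    """A generator could not satisfy its structural constraints."""


@dataclass(frozen=True)
class Network:
    """Immutable undirected simple graph with 0-based contiguous node ids.

    Invariants (checked on construction): no self-edges, no multi-edges,
    symmetric adjacency, sum(degrees) == 2 * n_edges.
    """

    N: int
    edges: frozenset  # frozenset of (i, j) tuples with i < j
    degree_sequence: tuple
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        deg = np.zeros(self.N, dtype=np.int64)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-edge at node {i}")
            if not (0 <= i < self.N and 0 <= j < self.N):
                raise ValueError(f"edge ({i},{j}) out of range")
            if i > j:
                raise ValueError("edges must be stored as (i, j) with i < j")
            deg[i] += 1
            deg[j] += 1
        if tuple(deg.tolist()) != tuple(self.degree_sequence):
            raise ValueError("degree_sequence inconsistent with edge set")
        if int(deg.sum()) != 2 * len(self.edges):
            raise ValueError("handshake identity violated")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_edges(cls, N, edges, meta=None):
        es = frozenset((min(i, j), max(i, j)) for i, j in edges)
        deg = np.zeros(N, dtype=np.int64)
        for i, j in es:
            if not (0 <= i < N and 0 <= j < N):
                raise ValueError(f"edge ({i},{j}) out of range for N={N}")
            deg[i] += 1
            deg[j] += 1
        return cls(N=N, edges=es, degree_sequence=tuple(deg.tolist()),
                   meta=dict(meta or {}))

    @classmethod
    def from_networkx(cls, g, meta=None):
        mapping = {v: i for i, v in enumerate(g.nodes())}
        return cls.from_edges(g.number_of_nodes(),
                              ((mapping[u], mapping[v]) for u, v in g.edges()),
                              meta=meta)

    # -- queries ------------------------------------------------------
    @property
    def n_edges(self):
        return len(self.edges)

    def A(self, i, j):
        """Adjacency query: 1 if i~j else 0 (A(i,i) == 0)."""
        if i == j:
            return 0
        return 1 if (min(i, j), max(i, j)) in self.edges else 0

    def adjacency_lists(self):
        """Neighbour lists as a list of sorted lists."""
        adj = [[] for _ in range(self.N)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return [sorted(a) for a in adj]

    def to_csr(self):
        """(indptr, indices) arrays in CSR layout, neighbours sorted."""
        adj = self.adjacency_lists()
        indptr = np.zeros(self.N + 1, dtype=np.int64)
        for i, a in enumerate(adj):
            indptr[i + 1] = indptr[i] + len(a)
        indices = np.empty(indptr[-1], dtype=np.int64)
        for i, a in enumerate(adj):
            indices[indptr[i]:indptr[i + 1]] = a
        return indptr, indices

    def to_networkx(self):
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(self.edges)
        return g

    # -- IO ------------------------------------------------------------
    def write_edgelist(self, path):
        """Plain-text edge list, one 'i j' per line (0-based, each edge once),
        with a JSON metadata sidecar at <path>.json."""
        path = Path(path)
        with open(path, "w") as fh:
            for i, j in sorted(self.edges):
                fh.write(f"{i} {j}\n")
        sidecar = {"N": self.N, **{k: v for k, v in self.meta.items()}}
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1, default=str)

    @classmethod
    def read_edgelist(cls, path, N=None):
        path = Path(path)
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                i, j = line.split()[:2]
                edges.append((int(i), int(j)))
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            N = N or meta.get("N")
        if N is None:
            N = 1 + max(max(e) for e in edges)
        return cls.from_edges(N, edges, meta=meta)


# ---------------------------------------------------------------------------
# short-cycle removal
# ---------------------------------------------------------------------------

def _edge_in_short_cycle(adj, u, v, max_len):
    """True if edge (u,v) lies on a cycle of length <= max_len, i.e. there is
    an alternative u->v path of length <= max_len - 1 avoiding the edge."""
    # BFS from u up to depth max_len - 1, not using edge (u, v) directly.
    depth = {u: 0}
    frontier = [u]
    for d in range(1, max_len):
        nxt = []
        for x in frontier:
            for y in adj[x]:
                if x == u and y == v:
                    continue  # skip the direct edge
                if y == v:
                    return True
                if y not in depth:
                    depth[y] = d
                    nxt.append(y)
        frontier = nxt
        if not frontier:
            break
    return False


def _remove_short_cycles(adj, edges, rng, min_girth, retry_factor=100):
    """Randomly shuffle connections (double-edge swaps) until no cycle of
    length <= min_girth - 1 remains.  Degree-preserving by construction.

    ``adj`` is a list of sets, ``edges`` a list of (i, j) tuples (i < j);
    both are modified in place.  Raises ConstraintFailure on exhausting the
    retry budget.
    """
    max_cycle = min_girth - 1
    if max_cycle < 3:
        return
    edge_index = {e: t for t, e in enumerate(edges)}
    budget = retry_factor * max(len(edges), 1)

    def bad_edges():
        return [e for e in edges if _edge_in_short_cycle(adj, e[0], e[1], max_cycle)]

    bad = bad_edges()
    swaps = 0
    while bad:
        e1 = bad[rng.integers(len(bad))]
        if e1 not in edge_index:  # stale entry from a previous swap
            bad = [e for e in bad if e in edge_index]
            continue
        u, v = e1
        # pick a random partner edge and swap endpoints: (u,v),(x,y) -> (u,x),(v,y)
        for _ in range(200):
            if swaps >= budget:
                raise ConstraintFailure(
                    f"girth >= {min_girth} not reached within retry budget; "
                    f"{len(bad)} short-cycle edges remain")
            swaps += 1
            x, y = edges[rng.integers(len(edges))]
            if rng.random() < 0.5:
                x, y = y, x
            # new edges (u, x) and (v, y)
            if len({u, v, x, y}) < 4:
                continue
            if x in adj[u] or y in adj[v]:
                continue
            e2 = (min(x, y), max(x, y))
            if e2 == e1 or e2 not in edge_index:
                continue
            for (a, b) in (e1, e2):
                adj[a].discard(b)
                adj[b].discard(a)
            for (a, b) in ((u, x), (v, y)):
                adj[a].add(b)
                adj[b].add(a)
            # update edge bookkeeping
            for old, new in ((e1, (min(u, x), max(u, x))),
                             (e2, (min(v, y), max(v, y)))):
                t = edge_index.pop(old)
                edges[t] = new
                edge_index[new] = t
            break
        else:
            continue
        # recheck lazily every few hundred swaps to amortise the scan
        if swaps % 200 == 0 or len(bad) <= 2:
            bad = bad_edges()
        else:
            bad = [e for e in bad if e in edge_index
                   and _edge_in_short_cycle(adj, e[0], e[1], max_cycle)]
        if not bad:
            bad = bad_edges()


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_k_regular(N, k, seed=None, min_girth=6):
    """k-regular configuration-model graph with cycles shorter than
    ``min_girth`` removed by random double-edge swaps.

    Raises ValueError when N*k is odd and ConstraintFailure when the swap
    budget is exhausted before reaching the girth constraint.
    """
    if N < 1 or k < 1:
        raise ValueError("need N >= 1 and k >= 1")
    if (N * k) % 2 != 0:
        raise ValueError(f"N*k = {N * k} is odd: no {k}-regular graph on {N} nodes")
    if k >= N:
        raise ValueError("k must be < N for a simple graph")
    rng = np.random.default_rng(seed)
    g = nx.random_regular_graph(k, N, seed=int(rng.integers(2**31)))
    adj = [set(g.neighbors(i)) for i in range(N)]
    edges = [(min(u, v), max(u, v)) for u, v in g.edges()]
    _remove_short_cycles(adj, edges, rng, min_girth)
    net = Network.from_edges(N, edges, meta={
        "generator": "k_regular", "k": k, "seed": seed, "min_girth": min_girth})
    assert all(d == k for d in net.degree_sequence)
    return net


def generate_cayley_tree(k, depth):
    """Finite Cayley tree: the root and every internal node have degree k;
    nodes at graph distance ``depth`` from the root are leaves (degree 1).

    Node count is 1 + k((k-1)^depth - 1)/(k-2) for k >= 3 and 2*depth + 1
    for k = 2 (a path).
    """
    if k < 2:
        raise ValueError("Cayley tree needs k >= 2")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    edges = []
    next_id = 1
    frontier = [0]
    for gen in range(depth):
        new_frontier = []
        for node in frontier:
            n_children = k if gen == 0 else k - 1
            for _ in range(n_children):
                edges.append((node, next_id))
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    return Network.from_edges(next_id, edges, meta={
        "generator": "cayley_tree", "k": k, "depth": depth})


def cayley_tree_size(k, depth):
    """Closed-form node count of ``generate_cayley_tree(k, depth)``."""
    if k == 2:
        return 2 * depth + 1
    return 1 + k * ((k - 1) ** depth - 1) // (k - 2)


# ---------------------------------------------------------------------------
# truncated-Gaussian degree distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegreeDistSpec:
    """Discretised Gaussian degree distribution
    ``P(k) = rho * exp(-alpha (k - K)^2)`` supported on ``k >= k_min``.

    ``alpha`` controls the width, ``K`` the centre and ``rho`` normalises;
    ``target_mean``/``target_variance`` record the moments the fit aimed at.
    """

    alpha: float
    K: float
    rho: float
    k_min: int = 2
    k_max: int = 500
    target_mean: float = float("nan")
    target_variance: float = float("nan")

    @property
    def support(self):
        return np.arange(self.k_min, self.k_max + 1)

    @property
    def pmf(self):
        # -alpha (k - K)^2 expanded about k_min (constant dropped): the
        # expanded form is exact and numerically stable even in the
        # geometric-tail limit alpha -> 0, K -> -inf where the raw square
        # suffers catastrophic cancellation
        x = self.support - float(self.k_min)
        beta = 2.0 * self.alpha * (self.k_min - self.K)
        e = -self.alpha * x ** 2 - beta * x
        w = np.exp(e - e.max())
        return w / w.sum()

    @property
    def mean(self):
        k = self.support
        return float((k * self.pmf).sum())

    @property
    def variance(self):
        k = self.support
        p = self.pmf
        mu = (k * p).sum()
        return float(((k - mu) ** 2 * p).sum())

    def sample(self, size, rng):
        return rng.choice(self.support, size=size, p=self.pmf)


def point_mass_spec(k):
    """Degenerate distribution P(k) = 1 (alpha -> infinity limit)."""
    return DegreeDistSpec(alpha=1e8, K=float(k), rho=1.0, k_min=k, k_max=k,
                          target_mean=float(k), target_variance=0.0)


def fit_degree_distribution(target_mean, target_variance, k_min=2, rtol=1e-6):
    """Find (alpha, K) so the discretised Gaussian on k >= k_min matches the
    requested mean and variance to relative tolerance ``rtol``.

    A zero target variance degenerates to a point mass at round(target_mean).
    Raises ConstraintFailure for infeasible targets (mean below k_min, or a
    variance the truncated support cannot realise).
    """
    if target_mean < k_min:
        raise ConstraintFailure(
            f"target mean {target_mean} below minimum degree {k_min}")
    if target_variance < 0:
        raise ConstraintFailure("variance must be >= 0")
    if target_variance < 1e-12:
        k0 = int(round(target_mean))
        if abs(k0 - target_mean) > 1e-9:
            raise ConstraintFailure(
                "zero variance requires an integer mean on the lattice")
        return point_mass_spec(k0)

    k_max = int(max(4 * target_mean + 10 * math.sqrt(target_variance), 30))
    k = np.arange(k_min, k_max + 1, dtype=float)
    x = k - k_min

    # The Gaussian family exp(-alpha (k - K)^2) is re-parameterised about
    # k_min as exp(-alpha x^2 - beta x), x = k - k_min and
    # beta = 2 alpha (K_min - K) ... i.e. curvature + tilt: (alpha, beta)
    # remain O(1) in the geometric-tail regime (alpha -> 0, K -> -inf)
    # where the raw parameters are collinear and root finders stall.
    def moments(params):
        log_alpha, beta = params
        alpha = math.exp(log_alpha)
        e = -alpha * x ** 2 - beta * x
        w = np.exp(e - e.max())
        s = w.sum()
        if not np.isfinite(s) or s <= 0:
            return np.array([1e6, 1e6])
        p = w / s
        mu = (k * p).sum()
        var = ((k - mu) ** 2 * p).sum()
        return np.array([mu - target_mean, var - target_variance])

    a0 = max(0.5 / target_variance, 1e-3)
    guesses = [(math.log(a0), -2 * a0 * (target_mean - k_min)),
               (0.0, -2.0 * (target_mean - k_min)),
               (math.log(0.1), 0.0)]
    excess = target_mean - k_min
    if excess > 0:  # geometric-tail seed with matching mean
        r = excess / (1.0 + excess)
        guesses.append((math.log(1e-4), math.log(1.0 / r)))

    def rel_err(p):
        resid = moments(p)
        return abs(resid[0]) / max(target_mean, 1) + \
            abs(resid[1]) / max(target_variance, 1)

    best = None
    for guess in guesses:
        sol = optimize.least_squares(moments, np.array(guess),
                                     xtol=3e-16, ftol=3e-16, gtol=3e-16)
        for cand in (np.array(guess), sol.x):
            err = rel_err(cand)
            if best is None or err < best[1]:
                best = (cand, err)
        if best[1] < rtol:
            break
    if best is None or best[1] > rtol:
        raise ConstraintFailure(
            f"could not match mean={target_mean}, variance={target_variance} "
            f"on support k >= {k_min}")
    log_alpha, beta = best[0]
    alpha = math.exp(log_alpha)
    K = k_min - beta / (2 * alpha)
    spec = DegreeDistSpec(alpha=alpha, K=float(K), rho=1.0,
                          k_min=k_min, k_max=k_max,
                          target_mean=target_mean,
                          target_variance=target_variance)
    # rho normalises the raw Gaussian weights (log-domain evaluation; for
    # extreme geometric-tail fits the raw weights underflow and rho
    # overflows to inf -- the pmf itself never uses rho)
    from scipy.special import logsumexp
    e_raw = -alpha * (spec.support - K) ** 2
    with np.errstate(over="ignore"):
        object.__setattr__(spec, "rho", float(np.exp(-logsumexp(e_raw))))
    return spec


def generate_heterogeneous(spec, N, seed=None, min_girth=2):
    """Configuration-model graph with i.i.d. degrees from ``spec``.

    If the sampled degree sum is odd, one uniformly chosen node's degree is
    resampled until the total is even (minimal perturbation of the
    distribution).  Self- and multi-edges are removed by double-edge swaps;
    pass ``min_girth >= 6`` to also remove short cycles as in
    ``generate_k_regular``.
    """
    if N < 10:
        raise ValueError("N must be >= 10")
    rng = np.random.default_rng(seed)
    degrees = np.asarray(spec.sample(N, rng), dtype=int)
    if degrees.sum() % 2 != 0:
        for _ in range(1000):
            i = int(rng.integers(N))
            d = int(spec.sample(1, rng)[0])
            if (degrees.sum() - degrees[i] + d) % 2 == 0:
                degrees[i] = d
                break
        else:
            raise ConstraintFailure("could not parity-correct the degree sequence")
    if degrees.max() >= N:
        raise ConstraintFailure("a sampled degree exceeds N-1: wiring impossible")
    g = nx.configuration_model(degrees.tolist(),
                               seed=int(rng.integers(2**31)))
    # collapse to a simple graph, then repair the degree sequence by swaps
    simple = nx.Graph()
    simple.add_nodes_from(range(N))
    lost = []  # stubs lost to self loops / parallel edges
    for u, v in g.edges():
        if u == v or simple.has_edge(u, v):
            lost.append((u, v))
        else:
            simple.add_edge(u, v)
    adj = [set(simple.neighbors(i)) for i in range(N)]
    edges = [(min(u, v), max(u, v)) for u, v in simple.edges()]
    # re-wire lost stubs by splitting existing edges (degree-restoring swap):
    # connect u and v into edge (x, y) -> (u, x), (v, y)
    for u, v in lost:
        ok = False
        for _ in range(10 * len(edges) + 100):
            t = int(rng.integers(len(edges)))
            x, y = edges[t]
            if rng.random() < 0.5:
                x, y = y, x
            # new edges will be (u, x) and (v, y)
            if x in (u, v) or y in (u, v):
                continue
            if x in adj[u] or y in adj[v]:
                continue
            if u == v and x == y:
                continue
            adj[x].discard(y)
            adj[y].discard(x)
            adj[u].add(x)
            adj[x].add(u)
            adj[v].add(y)
            adj[y].add(v)
            edges[t] = (min(u, x), max(u, x))
            edges.append((min(v, y), max(v, y)))
            ok = True
            break
        if not ok:
            raise ConstraintFailure("could not re-wire multi/self edges")
    if min_girth > 3:
        _remove_short_cycles(adj, edges, rng, min_girth)
    net = Network.from_edges(N, edges, meta={
        "generator": "heterogeneous", "seed": seed,
        "alpha": spec.alpha, "K": spec.K, "k_min": spec.k_min,
        "target_mean": spec.target_mean,
        "target_variance": spec.target_variance})
    if sorted(net.degree_sequence) != sorted(degrees.tolist()):
        raise ConstraintFailure("degree sequence not preserved by re-wiring")
    return net
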