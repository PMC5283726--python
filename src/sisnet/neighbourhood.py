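"""Neighbourhood (effective-degree) models of SIS dynamics.

The order-n = 2 model tracks [S_y] and [I_y], the expected numbers of
susceptible/infectious nodes with y infectious neighbours (y = 0..k).  The
forces of infection acting on a susceptible neighbour of an S- or I-centre
(lambda_S, lambda_I) are obtained by re-centring the neighbourhood on that
susceptible and averaging over consistent neighbourhoods:

    lambda_S = tau * sum_y (k-y) y [S_y] / sum_y (k-y) [S_y]
    lambda_I = tau * sum_y y^2   [S_y] / sum_y y     [S_y]

The order-n = 3 model extends the tracked state to the radius-2 ball
(centre, neighbours, neighbours-of-neighbours) up to branch-permutation
symmetry.  Events internal to the ball are exact; the force of infection on
a susceptible second-ring node u is found by re-centring on u's first-ring
parent v and averaging over tracked balls consistent with the shared
overlap (v; the branch through the original centre, fully specified; the
root states of v's remaining branches), with ties between equivalent
branches weighted by multiplicity.  For k = 2 this re-centring conditions
on the four in-ball nodes nearest the boundary and the model coincides with
the order-5 chain motif model.

``count_equations`` reproduces the size of the heterogeneous-degree systems
by enumerating canonical configurations (multisets of neighbour/branch
descriptors) and subtracting the single global conservation relation.
"""

from __future__ import annotations

from itertools import combinations_with_replacement
from math import comb
from dataclasses import dataclass

import numpy as np

from .closures import ClosureModel, build_meanfield
from .params import EpidemicParams


# ---------------------------------------------------------------------------
# n = 2
# ---------------------------------------------------------------------------

def build_neighbourhood_n2(N, k, params):
    """Effective-degree model: variables [S_y], [I_y] for y = 0..k.

    2(k+1) raw variables, one conservation relation (total population), so
    2(k+1) - 1 independent equations: 5 for k = 2, 7 for k = 3.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tau, gamma = params.tau, params.gamma
    ks = np.arange(k + 1, dtype=float)
    nv = 2 * (k + 1)

    def rhs(y):
        S = y[:k + 1]
        I = y[k + 1:]
        denS = float(((k - ks) * S).sum())
        numS = float(((k - ks) * ks * S).sum())
        lamS = min(max(tau * numS / denS, 0.0), tau * k) if denS > 0 else 0.0
        denI = float((ks * S).sum())
        numI = float((ks * ks * S).sum())
        lamI = min(max(tau * numI / denI, 0.0), tau * k) if denI > 0 else 0.0

        dS = np.zeros(k + 1)
        dI = np.zeros(k + 1)
        for yy in range(k + 1):
            dS[yy] += gamma * I[yy] - tau * yy * S[yy] \
                - lamS * (k - yy) * S[yy] - gamma * yy * S[yy]
            dI[yy] += tau * yy * S[yy] - gamma * I[yy] \
                - lamI * (k - yy) * I[yy] - gamma * yy * I[yy]
            if yy > 0:
                dS[yy] += lamS * (k + 1 - yy) * S[yy - 1]
                dI[yy] += lamI * (k + 1 - yy) * I[yy - 1]
            if yy < k:
                dS[yy] += gamma * (yy + 1) * S[yy + 1]
                dI[yy] += gamma * (yy + 1) * I[yy + 1]
        return np.concatenate([dS, dI])

    def prevalence(y):
        return float(y[k + 1:].sum()) / N

    def initial_state(eps):
        from scipy.stats import binom
        w = binom.pmf(np.arange(k + 1), k, eps)
        return np.concatenate([N * (1 - eps) * w, N * eps * w])

    dfe = np.zeros(nv)
    dfe[0] = N
    mask = np.ones(nv, dtype=bool)
    mask[0] = False

    def observables(y):
        S = y[:k + 1]
        I = y[k + 1:]
        SI = float((ks * S).sum())      # directed S-I pairs
        II = float((ks * I).sum())
        SS = float(((k - ks) * S).sum())
        return {"S": float(S.sum()), "I": float(I.sum()),
                "SS": SS, "SI": SI, "II": II}

    labels = [f"S_{y}" for y in range(k + 1)] + [f"I_{y}" for y in range(k + 1)]
    return ClosureModel(
        name=f"neighbourhood_n2_k{k}", labels=labels, rhs=rhs, N=N, k=k,
        params=params, dfe_state=dfe, infection_mask=mask,
        prevalence=prevalence, initial_state=initial_state,
        conserved=[(np.ones(nv), float(N))],
        dimension=nv - 1, observables=observables,
        meta={"family": "neighbourhood", "order": 2})


# ---------------------------------------------------------------------------
# n = 3: radius-2 ball model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _BallSpace:
    k: int
    branch_types: tuple       # (root_state, sorted child-state tuple)
    balls: tuple              # (centre_state, sorted branch-type-id tuple)
    index: dict


def _ball_space(k):
    child_multisets = list(combinations_with_replacement((0, 1), k - 1))
    branch_types = [(r, cm) for r in (0, 1) for cm in child_multisets]
    bt_index = {t: i for i, t in enumerate(branch_types)}
    balls = []
    for c in (0, 1):
        for branches in combinations_with_replacement(range(len(branch_types)), k):
            balls.append((c, branches))
    index = {b: i for i, b in enumerate(balls)}
    return _BallSpace(k, tuple(branch_types), tuple(balls), index), bt_index


def build_neighbourhood_n3(N, k, params):
    """Extended neighbourhood model: canonical radius-2 ball states.

    Supported for k in {2, 3}.  Internal transmission and recovery are
    exact; second-ring susceptibles receive the consistency-closed external
    force described in the module docstring.
    """
    if k not in (2, 3):
        raise ValueError("n=3 neighbourhood model supports k in {2, 3}")
    tau, gamma = params.tau, params.gamma
    space, bt_index = _ball_space(k)
    branch_types = space.branch_types
    balls = space.balls
    n = len(balls)

    def canon_ball(c, branch_list):
        return (c, tuple(sorted(branch_list)))

    # ---- transition table -------------------------------------------------
    # Each entry: (src, dst, kind, coeff, pattern) where kind is
    # 'const' (rate = coeff), 'lin' handled inside coeff already constant,
    # or 'ext' (rate = coeff * phi[pattern]).
    # Patterns for the external force on a second-ring susceptible u with
    # parent branch b = (s_v, children) inside ball (s_c, branches):
    #   (s_v, overlap branch type seen from v = (s_c, sorted other-root
    #    states), sorted other-children-of-v states)
    patterns = {}

    def pattern_id(p):
        if p not in patterns:
            patterns[p] = len(patterns)
        return patterns[p]

    const_entries = []   # (src, dst, rate)
    ext_entries = []     # (src, dst, mult, pattern_id)

    for bi, (c, brs) in enumerate(balls):
        btypes = [branch_types[t] for t in brs]
        roots = [bt[0] for bt in btypes]
        # centre events
        if c == 1:
            const_entries.append((bi, space.index[canon_ball(0, brs)], gamma))
        else:
            nI = sum(roots)
            if nI:
                const_entries.append((bi, space.index[canon_ball(1, brs)],
                                      tau * nI))
        # branch-root events
        for j, (r, children) in enumerate(btypes):
            mult = 1  # each occurrence handled; identical branches produce
            # identical entries which accumulate correctly below
            if r == 1:
                new_t = bt_index[(0, children)]
                dst = space.index[canon_ball(c, brs[:j] + (new_t,) + brs[j + 1:])]
                const_entries.append((bi, dst, gamma))
            else:
                rate = tau * (c + sum(children))
                if rate:
                    new_t = bt_index[(1, children)]
                    dst = space.index[canon_ball(c, brs[:j] + (new_t,) + brs[j + 1:])]
                    const_entries.append((bi, dst, rate))
            # child events
            for ci, ch in enumerate(set(children)):
                m_child = children.count(ch)
                others = list(children)
                others.remove(ch)
                if ch == 1:
                    new_children = tuple(sorted(others + [0]))
                    new_t = bt_index[(r, new_children)]
                    dst = space.index[canon_ball(c, brs[:j] + (new_t,) + brs[j + 1:])]
                    const_entries.append((bi, dst, gamma * m_child))
                else:
                    new_children = tuple(sorted(others + [1]))
                    new_t = bt_index[(r, new_children)]
                    dst = space.index[canon_ball(c, brs[:j] + (new_t,) + brs[j + 1:])]
                    if r == 1:  # infection by the parent
                        const_entries.append((bi, dst, tau * m_child))
                    # external force on the susceptible second-ring node
                    other_roots = tuple(sorted(roots[:j] + roots[j + 1:]))
                    pat = (r, c, other_roots, tuple(sorted(others)))
                    ext_entries.append((bi, dst, m_child, pattern_id(pat)))

    # accumulate constant-rate entries into a sparse linear operator
    from scipy import sparse
    rows, cols, vals = [], [], []
    for src, dst, rate in const_entries:
        rows += [src, dst]
        cols += [src, src]
        vals += [-rate, rate]
    L = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    ext_src = np.array([e[0] for e in ext_entries])
    ext_dst = np.array([e[1] for e in ext_entries])
    ext_mult = np.array([e[2] for e in ext_entries], dtype=float)
    ext_pat = np.array([e[3] for e in ext_entries])

    # ---- phi matrices -----------------------------------------------------
    # The external force on a susceptible second-ring node u (parent v,
    # centre c) is phi = tau * E[# infectious external neighbours of u].
    # Re-centre on the parent v: in a ball B'' centred at a v-like node, the
    # branch through u has root u and children = u's external neighbours.
    # Compatibility with the original ball fixes the centre state (s_v),
    # the branch through the original centre in full, (s_c, children =
    # other first-ring root states), and the root states of the remaining
    # branches ({u: S} + v's other children); the average over matching
    # assignments weights identical branches by multiplicity.
    n_pat = len(patterns)
    W = np.zeros((n_pat, n))   # denominator: number of matched assignments
    A = np.zeros((n_pat, n))   # numerator: infectious children of u-branch
    for pat, pid in patterns.items():
        s_v, s_c, other_roots, other_children = pat
        t_full = bt_index[(s_c, tuple(sorted(other_roots)))]
        want_rest_roots = sorted((0,) + other_children)
        for bi, (cc, brs) in enumerate(balls):
            if cc != s_v:
                continue
            bl = list(brs)
            for j in range(k):
                if bl[j] != t_full:
                    continue
                rest = bl[:j] + bl[j + 1:]
                rest_roots = sorted(branch_types[t][0] for t in rest)
                if rest_roots != want_rest_roots:
                    continue
                for t in rest:
                    rr, rch = branch_types[t]
                    if rr == 0:  # a candidate u-branch (susceptible root)
                        W[pid, bi] += 1
                        A[pid, bi] += sum(rch)

    def rhs(B):
        dB = L @ B
        den = W @ B
        num = A @ B
        phi = tau * np.clip(
            np.divide(num, den, out=np.zeros(n_pat), where=den > 0),
            0.0, float(k - 1))
        f = ext_mult * phi[ext_pat] * B[ext_src]
        np.subtract.at(dB, ext_src, f)
        np.add.at(dB, ext_dst, f)
        return dB

    def prevalence(B):
        centreI = np.array([c for (c, _) in balls], dtype=float)
        return float((centreI * B).sum()) / N

    from math import factorial

    def initial_state(eps):
        q = (1 - eps, eps)
        p_branch = {}
        for t, (r, children) in enumerate(branch_types):
            cnt1 = sum(children)
            # multinomial weight of the sorted child multiset
            ways = comb(k - 1, cnt1)
            p_branch[t] = q[r] * ways * (eps ** cnt1) * ((1 - eps) ** (k - 1 - cnt1))
        B = np.zeros(n)
        for bi, (c, brs) in enumerate(balls):
            counts = {}
            for t in brs:
                counts[t] = counts.get(t, 0) + 1
            ways = factorial(k)
            pb = 1.0
            for t, m in counts.items():
                ways //= factorial(m)
                pb *= p_branch[t] ** m
            B[bi] = N * q[c] * ways * pb
        return B

    dfe = np.zeros(n)
    all_s_branch = bt_index[(0, tuple([0] * (k - 1)))]
    dfe[space.index[(0, tuple([all_s_branch] * k))]] = N
    mask = dfe == 0

    labels = []
    for c, brs in balls:
        parts = []
        for t in brs:
            r, ch = branch_types[t]
            parts.append("SI"[r] + "".join("SI"[x] for x in ch))
        labels.append("SI"[c] + "(" + ",".join(parts) + ")")

    return ClosureModel(
        name=f"neighbourhood_n3_k{k}", labels=labels, rhs=rhs, N=N, k=k,
        params=params, dfe_state=dfe, infection_mask=mask,
        prevalence=prevalence, initial_state=initial_state,
        conserved=[(np.ones(n), float(N))],
        dimension=n - 1, observables=None,
        meta={"family": "neighbourhood", "order": 3, "n_balls": n})


def build_neighbourhood_family(n, N, k, params):
    """n = 1 mean-field, n = 2 effective-degree, n = 3 extended ball."""
    if n == 1:
        return build_meanfield(N, k, params)
    if n == 2:
        return build_neighbourhood_n2(N, k, params)
    if n == 3:
        return build_neighbourhood_n3(N, k, params)
    raise ValueError("neighbourhood order n must be in {1, 2, 3}")


# ---------------------------------------------------------------------------
# equation counting
# ---------------------------------------------------------------------------

def count_equations(degree_set, n):
    """Number of independent ODEs of the order-n neighbourhood model for a
    network whose degrees take values in ``degree_set``.

    n = 2: configurations are (centre state, centre degree d, unordered
    multiset of d neighbour (state, degree) descriptors).  n = 3: each
    neighbour descriptor of degree d' additionally carries an unordered
    multiset of its d'-1 second-ring (state, degree) descriptors.  The
    count sums over both centre states and all centre degrees, minus one
    for the global conservation relation.

    Homogeneous checks: {2} -> 5 and {3} -> 7 at n = 2; heterogeneous
    degree sets {1,2} -> 27 and {1,2,3} -> 165 at n = 2, and {1,2,3} ->
    65,015 at n = 3.
    """
    degrees = sorted(set(int(d) for d in degree_set))
    if not degrees or min(degrees) < 1:
        raise ValueError("degree_set must contain positive integers")
    if n == 2:
        n_nbr_types = 2 * len(degrees)  # (state, degree)
        total = sum(2 * comb(n_nbr_types + d - 1, d) for d in degrees)
        return total - 1
    if n == 3:
        n_second = 2 * len(degrees)
        n_branch = sum(2 * comb(n_second + (d1 - 1) - 1, d1 - 1)
                       for d1 in degrees)
        total = sum(2 * comb(n_branch + d - 1, d) for d in degrees)
        return total - 1
    raise ValueError("n must be 2 or 3")
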