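"""Motif (subgraph) expansions of SIS dynamics.

The order-m motif model tracks the expected counts of every S/I state of
connected m-node subgraphs; their rates of change involve (m+1)-node
subgraphs, which are closed by the generalised Kirkwood construction: the
product of the constituent m-motif counts divided by the over-counted
(m-1)-motif overlap counts, corrected at the next level down, and so on.

Two network classes are covered:

* degree k = 2 (the 1-d contact process): the only m-motif is the chain of
  m consecutive nodes.  ``build_chain_motif_model`` implements the full
  hierarchy (m = 1 is mean-field, m = 2 the standard pairwise model), with
  the state space of all 2^m windows; reflection symmetry is preserved by
  the dynamics rather than factored out, and the reported dimension counts
  canonical classes minus one conservation relation.
* degree k = 3 with girth >= 6: the tree motifs are the 3-path (m = 3) and
  the 4-path plus the star/claw (m = 4); ``build_k3_motif_model`` builds
  both orders.

Closures are written in conditional form: the probability that a node just
outside the motif is infectious, given the motif state, is a Kirkwood
product/quotient of conditionals taken from the tracked counts.  All
denominators define 0/0 = 0 (counts vanish at least linearly together).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .closures import ClosureModel, build_meanfield
from .params import EpidemicParams


# ---------------------------------------------------------------------------
# chain-state enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifState:
    """A motif topology plus an S/I labelling, up to automorphism."""

    shape: str
    state_string: str

    @property
    def canonical_form(self):
        if self.shape == "chain":
            return min(self.state_string, self.state_string[::-1])
        if self.shape == "star":
            # centre first, leaves sorted
            return self.state_string[0] + "".join(sorted(self.state_string[1:]))
        return self.state_string

    def canonical(self):
        return MotifState(self.shape, self.canonical_form)


@dataclass
class MotifSystem:
    """A motif expansion order: shape inventory, canonical states and the
    ClosureModel realising its ODEs."""

    order: int
    shapes: list
    canonical_states: list
    model: ClosureModel
    dimension: int = 0

    def __post_init__(self):
        if not self.dimension:
            self.dimension = len(self.canonical_states) - 1


def _reverse_bits(b, m):
    r = 0
    for _ in range(m):
        r = (r << 1) | (b & 1)
        b >>= 1
    return r


def enumerate_chain_states(m):
    """All S/I labellings of an m-chain up to reversal symmetry.

    The number of canonical classes is 2^(m-1) + 2^(M-1) with
    M = floor((m+1)/2): half of 2^m plus one for each palindrome.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    seen = set()
    out = []
    for b in range(2 ** m):
        s = "".join("I" if (b >> i) & 1 else "S" for i in range(m))
        c = min(s, s[::-1])
        if c not in seen:
            seen.add(c)
            out.append(MotifState("chain", c))
    return out


def chain_state_count(m):
    """Closed-form count of chain states up to reversal."""
    M = (m + 1) // 2
    return 2 ** (m - 1) + 2 ** (M - 1)


def chain_dimension(m):
    """Independent dimension of the order-m chain model (one conservation
    relation removed)."""
    return chain_state_count(m) - 1


# ---------------------------------------------------------------------------
# chain motif model (k = 2)
# ---------------------------------------------------------------------------

def build_chain_motif_model(m, N, params):
    """Order-m chain motif model for a degree-2 network.

    State variables are the counts c(b) of windows of m consecutive nodes in
    configuration b (one window per node on a large ring, sum c = N).  The
    boundary terms close the (m+1)-chain by
    [x b0..b_{m-1}] ~ [x b0..b_{m-2}] [b0..b_{m-1}] / [b0..b_{m-2}],
    i.e. the external node's state is conditioned on the m-1 nodes nearest
    the boundary.  m = 1 collapses to mean-field, m = 2 to the standard
    pairwise model.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    tau, gamma = params.tau, params.gamma
    n = 2 ** m
    states = np.arange(n)
    popcnt = np.array([bin(b).count("1") for b in range(n)])

    # linear part: recovery and internal infection
    rows, cols, vals = [], [], []

    def add_flux(src, dst, rate):
        rows.append(src)
        cols.append(src)
        vals.append(-rate)
        rows.append(dst)
        cols.append(src)
        vals.append(rate)

    for b in range(n):
        for i in range(m):
            bit = (b >> i) & 1
            if bit:
                add_flux(b, b ^ (1 << i), gamma)
            else:
                n_int = 0
                if i > 0:
                    n_int += (b >> (i - 1)) & 1
                if i < m - 1:
                    n_int += (b >> (i + 1)) & 1
                if n_int:
                    add_flux(b, b | (1 << i), tau * n_int)
    L = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    # boundary bookkeeping (precomputed gathers)
    M1 = (1 << (m - 1)) - 1
    u_left = states & M1                  # m-1 nodes nearest the left edge
    idxL_S = u_left << 1                  # window S.u
    idxL_I = (u_left << 1) | 1            # window I.u
    v_right = states >> 1                 # m-1 nodes nearest the right edge
    idxR_S = v_right
    idxR_I = v_right | (1 << (m - 1))
    left_src = states[(states & 1) == 0]
    left_dst = left_src | 1
    right_src = states[((states >> (m - 1)) & 1) == 0]
    right_dst = right_src | (1 << (m - 1))

    def rhs(c):
        dc = L @ c
        denL = c[idxL_S] + c[idxL_I]
        pL = np.clip(np.divide(c[idxL_I], denL, out=np.zeros(n),
                               where=denL > 0), 0.0, 1.0)
        denR = c[idxR_S] + c[idxR_I]
        pR = np.clip(np.divide(c[idxR_I], denR, out=np.zeros(n),
                               where=denR > 0), 0.0, 1.0)
        fL = tau * pL[left_src] * c[left_src]
        np.subtract.at(dc, left_src, fL)
        np.add.at(dc, left_dst, fL)
        fR = tau * pR[right_src] * c[right_src]
        np.subtract.at(dc, right_src, fR)
        np.add.at(dc, right_dst, fR)
        return dc

    def prevalence(c):
        return float((popcnt * c).sum() / (m * N))

    def initial_state(eps):
        q = np.array([1 - eps, eps])
        c = np.ones(n)
        for b in range(n):
            p = 1.0
            for i in range(m):
                p *= q[(b >> i) & 1]
            c[b] = N * p
        return c

    def observables(c):
        I = prevalence(c) * N
        obs = {"S": N - I, "I": I}
        if m >= 2:
            # directed pair counts from the first two window positions
            SS = SI = II = 0.0
            for b in range(n):
                s0, s1 = (b >> 0) & 1, (b >> 1) & 1
                if s0 == 0 and s1 == 0:
                    SS += c[b]
                elif s0 != s1:
                    SI += c[b]
                else:
                    II += c[b]
            obs.update({"SS": 2 * SS, "SI": SI + SI, "II": 2 * II})
        return obs

    mask = np.ones(n, dtype=bool)
    mask[0] = False  # the all-S window is the neutral direction at the DFE
    dfe = np.zeros(n)
    dfe[0] = N
    model = ClosureModel(
        name=f"chain_m{m}", labels=[
            "".join("I" if (b >> i) & 1 else "S" for i in range(m))
            for b in range(n)],
        rhs=rhs, N=N, k=2, params=params, dfe_state=dfe,
        infection_mask=mask, prevalence=prevalence,
        initial_state=initial_state,
        conserved=[(np.ones(n), float(N))],
        dimension=chain_dimension(m), observables=observables,
        meta={"family": "chain_motif", "order": m})
    return MotifSystem(order=m, shapes=["chain"],
                       canonical_states=enumerate_chain_states(m),
                       model=model, dimension=chain_dimension(m))


# ---------------------------------------------------------------------------
# k = 3 motif models (m = 3 path; m = 4 path + star)
# ---------------------------------------------------------------------------

def _bits(idx, n):
    return tuple((idx >> i) & 1 for i in range(n))


def _idx(bits):
    return sum(b << i for i, b in enumerate(bits))


def _safe_ratio(num, den, hi=np.inf):
    """num/den with 0/0 -> 0, clipped to the physical range [0, hi]."""
    out = np.divide(num, den, out=np.zeros_like(np.asarray(num, dtype=float)),
                    where=np.asarray(den) > 0)
    return np.clip(out, 0.0, hi)


def build_k3_motif_model(m, N, params):
    """Motif model of order m in {3, 4} on a 3-regular, locally tree-like
    network.

    m = 3 tracks ordered 3-path counts T[abc] (sum = 6N); m = 4 adds
    ordered 4-path counts T4[abcd] (sum = 12N) and ordered star counts
    St[b; l1 l2 l3] (sum = 6N).  External forces are closed by conditional
    Kirkwood quotients, e.g. for the third neighbour x of the centre of a
    3-path a-b-c:  P(x=I | a,b,c) ~ P(x=I | a,b) P(x=I | c,b) / P(x=I | b).
    """
    if m == 3:
        return _build_k3_m3(N, params)
    if m == 4:
        return _build_k3_m4(N, params)
    raise ValueError("k=3 motif models support m in {3, 4} only")


def _build_k3_m3(N, params):
    tau, gamma = params.tau, params.gamma
    k = 3
    n = 8  # states of (a, b, c)
    T_total = N * k * (k - 1)  # ordered 3-paths

    states = [(a, b, c) for c in (0, 1) for b in (0, 1) for a in (0, 1)]
    # index helper: bit0 = a, bit1 = b, bit2 = c

    def rhs(T):
        # marginals (directed pair counts P[ab] and node counts)
        P = np.zeros((2, 2))
        for idx in range(n):
            a, b, c = _bits(idx, 3)
            P[a, b] += T[idx] / (k - 1)
        node = P.sum(axis=1) / k  # [S], [I]

        # conditionals
        # extL[a][b]: expected infectious external neighbours of the end
        # node a of an (a,b) pair = T[I a b] / P[a b]
        def TT(a, b, c):
            return T[_idx((a, b, c))]

        dT = np.zeros(n)

        def flux(src, dst, rate):
            dT[src] -= rate
            dT[dst] += rate

        for idx in range(n):
            a, b, c = _bits(idx, 3)
            cnt = T[idx]
            # recoveries
            for pos, s in enumerate((a, b, c)):
                if s == 1:
                    new = [a, b, c]
                    new[pos] = 0
                    flux(idx, _idx(new), gamma * cnt)
            # internal infections
            if a == 0 and b == 1:
                flux(idx, _idx((1, b, c)), tau * cnt)
            if c == 0 and b == 1:
                flux(idx, _idx((a, b, 1)), tau * cnt)
            if b == 0:
                n_int = a + c
                if n_int:
                    flux(idx, _idx((a, 1, c)), tau * n_int * cnt)
            # external infection of end node a: 4-path closure
            if a == 0:
                lam = _safe_ratio(TT(1, a, b), P[a, b], hi=k - 1.0)
                flux(idx, _idx((1, b, c)), tau * lam * cnt)
            if c == 0:
                lam = _safe_ratio(TT(1, c, b), P[c, b], hi=k - 1.0)
                flux(idx, _idx((a, b, 1)), tau * lam * cnt)
            # external infection of the centre: star closure
            if b == 0:
                pI_ab = _safe_ratio(TT(a, b, 1), (k - 1) * P[a, b], hi=1.0)
                pI_cb = _safe_ratio(TT(c, b, 1), (k - 1) * P[c, b], hi=1.0)
                pI_b = _safe_ratio(P[b, 1], k * node[b], hi=1.0)
                pi = _safe_ratio(pI_ab * pI_cb, pI_b, hi=1.0)
                flux(idx, _idx((a, 1, c)), tau * (k - 2) * pi * cnt)
        return dT

    def prevalence(T):
        # average of the three position marginals
        tot = 0.0
        for idx in range(n):
            a, b, c = _bits(idx, 3)
            tot += T[idx] * (a + b + c)
        return float(tot / (3 * T_total) * 1.0)

    def initial_state(eps):
        q = (1 - eps, eps)
        T = np.zeros(n)
        for idx in range(n):
            a, b, c = _bits(idx, 3)
            T[idx] = T_total * q[a] * q[b] * q[c]
        return T

    dfe = np.zeros(n)
    dfe[0] = T_total
    mask = np.ones(n, dtype=bool)
    mask[0] = False

    def observables(T):
        P = np.zeros((2, 2))
        for idx in range(n):
            a, b, c = _bits(idx, 3)
            P[a, b] += T[idx] / (k - 1)
        node = P.sum(axis=1) / k
        return {"S": float(node[0]), "I": float(node[1]),
                "SS": float(P[0, 0]), "SI": float(P[0, 1]),
                "II": float(P[1, 1])}

    labels = ["".join("SI"[s] for s in _bits(idx, 3)) for idx in range(n)]
    canonical = sorted({min(l, l[::-1]) for l in labels})
    model = ClosureModel(
        name="k3_motif_m3", labels=labels, rhs=rhs, N=N, k=3, params=params,
        dfe_state=dfe, infection_mask=mask, prevalence=prevalence,
        initial_state=initial_state,
        conserved=[(np.ones(n), float(T_total))],
        dimension=len(canonical) - 1, observables=observables,
        meta={"family": "k3_motif", "order": 3})
    return MotifSystem(order=3, shapes=["chain"],
                       canonical_states=[MotifState("chain", s) for s in canonical],
                       model=model, dimension=len(canonical) - 1)


def _build_k3_m4(N, params):
    tau, gamma = params.tau, params.gamma
    k = 3
    nP = 16  # 4-path states (a,b,c,d)
    nS = 16  # star states (b; l1,l2,l3), leaves kept ordered
    P_total = N * k * (k - 1) ** 2   # ordered 4-paths: 12N
    S_total = N * k * (k - 1) * (k - 2)  # ordered stars: 6N

    def rhs(y):
        T4 = y[:nP]
        St = y[nP:]

        # 3-path marginal from 4-paths: T3[abc] = sum_d T4[abcd]/(k-1)
        T3 = np.zeros(8)
        P2 = np.zeros((2, 2))
        for idx in range(nP):
            a, b, c, d = _bits(idx, 4)
            T3[_idx((a, b, c))] += T4[idx] / (k - 1)
        for idx3 in range(8):
            a, b, c = _bits(idx3, 3)
            P2[a, b] += T3[idx3] / (k - 1)

        def t3(a, b, c):
            return T3[_idx((a, b, c))]

        def t4(a, b, c, d):
            return T4[_idx((a, b, c, d))]

        def st(b, l1, l2, l3):
            return St[_idx((b, l1, l2, l3))]

        # conditional that a specific extra neighbour x of the left node of
        # an oriented path is infectious
        def p4(a, b, c):
            # x attached to a, conditioning on path (a,b,c)
            return _safe_ratio(t4(1, a, b, c), (k - 1) * t3(a, b, c), hi=1.0)

        def p3(a, b):
            # x attached to a, conditioning on edge (a,b)
            return _safe_ratio(t3(1, a, b), (k - 1) * P2[a, b], hi=1.0)

        def p_star(b, l1, l2):
            # third leaf of centre b given leaves l1, l2
            den = st(b, l1, l2, 0) + st(b, l1, l2, 1)
            return _safe_ratio(st(b, l1, l2, 1), den, hi=1.0)

        dP = np.zeros(nP)
        dS = np.zeros(nS)

        def fluxP(src, dst, rate):
            dP[src] -= rate
            dP[dst] += rate

        def fluxS(src, dst, rate):
            dS[src] -= rate
            dS[dst] += rate

        # ---- 4-path dynamics ----
        for idx in range(nP):
            cnt = T4[idx]
            a, b, c, d = _bits(idx, 4)
            ss = (a, b, c, d)
            for pos in range(4):
                s = ss[pos]
                new = list(ss)
                if s == 1:
                    new[pos] = 0
                    fluxP(idx, _idx(new), gamma * cnt)
                else:
                    new[pos] = 1
                    # internal neighbours along the path
                    nbrs = [p for p in (pos - 1, pos + 1) if 0 <= p < 4]
                    n_int = sum(ss[p] for p in nbrs)
                    if n_int:
                        fluxP(idx, _idx(new), tau * n_int * cnt)
                    # external force
                    if pos == 0:
                        lam = (k - 1) * p4(a, b, c)
                    elif pos == 3:
                        lam = (k - 1) * p4(d, c, b)
                    elif pos == 1:
                        # x on b: star around b with leaves a, c; tail d on c
                        pi = _safe_ratio(p_star(b, a, c) * p4(b, c, d),
                                         p3(b, c), hi=1.0)
                        lam = (k - 2) * pi
                    else:
                        pi = _safe_ratio(p_star(c, b, d) * p4(c, b, a),
                                         p3(c, b), hi=1.0)
                        lam = (k - 2) * pi
                    if lam:
                        fluxP(idx, _idx(new), tau * lam * cnt)

        # ---- star dynamics ----
        for idx in range(nS):
            cnt = St[idx]
            b, l1, l2, l3 = _bits(idx, 4)
            leaves = (l1, l2, l3)
            # centre
            if b == 1:
                fluxS(idx, _idx((0, l1, l2, l3)), gamma * cnt)
            else:
                n_int = sum(leaves)
                if n_int:
                    fluxS(idx, _idx((1, l1, l2, l3)), tau * n_int * cnt)
            # leaves
            for i in range(3):
                s = leaves[i]
                new = [b, l1, l2, l3]
                if s == 1:
                    new[1 + i] = 0
                    fluxS(idx, _idx(new), gamma * cnt)
                else:
                    new[1 + i] = 1
                    others = [leaves[j] for j in range(3) if j != i]
                    # internal: the centre
                    if b == 1:
                        fluxS(idx, _idx(new), tau * cnt)
                    # external: two further neighbours of the leaf
                    pi = _safe_ratio(p4(s, b, others[0]) * p4(s, b, others[1]),
                                     p3(s, b), hi=1.0)
                    if pi:
                        fluxS(idx, _idx(new), tau * (k - 1) * pi * cnt)
        return np.concatenate([dP, dS])

    def prevalence(y):
        T4 = y[:nP]
        tot = 0.0
        for idx in range(nP):
            tot += T4[idx] * sum(_bits(idx, 4))
        return float(tot / (4 * P_total))

    def initial_state(eps):
        q = (1 - eps, eps)
        y = np.zeros(nP + nS)
        for idx in range(nP):
            a, b, c, d = _bits(idx, 4)
            y[idx] = P_total * q[a] * q[b] * q[c] * q[d]
        for idx in range(nS):
            b, l1, l2, l3 = _bits(idx, 4)
            y[nP + idx] = S_total * q[b] * q[l1] * q[l2] * q[l3]
        return y

    dfe = np.zeros(nP + nS)
    dfe[0] = P_total
    dfe[nP] = S_total
    mask = np.ones(nP + nS, dtype=bool)
    mask[0] = False
    mask[nP] = False

    consP = np.zeros(nP + nS)
    consP[:nP] = 1
    consS = np.zeros(nP + nS)
    consS[nP:] = 1

    path_labels = ["".join("SI"[s] for s in _bits(i, 4)) for i in range(nP)]
    star_labels = ["*" + "".join("SI"[s] for s in _bits(i, 4))
                   for i in range(nS)]
    canon = sorted({min(l, l[::-1]) for l in path_labels}) + sorted(
        {l[:2] + "".join(sorted(l[2:])) for l in star_labels})
    model = ClosureModel(
        name="k3_motif_m4", labels=path_labels + star_labels,
        rhs=rhs, N=N, k=3, params=params, dfe_state=dfe,
        infection_mask=mask, prevalence=prevalence,
        initial_state=initial_state,
        conserved=[(consP, float(P_total)), (consS, float(S_total))],
        dimension=len(canon) - 2, observables=None,
        meta={"family": "k3_motif", "order": 4})
    return MotifSystem(order=4, shapes=["chain", "star"],
                       canonical_states=[MotifState("chain", s) if not s.startswith("*")
                                         else MotifState("star", s[1:])
                                         for s in canon],
                       model=model, dimension=len(canon) - 2)


def build_k3_motif_family(m, N, params):
    """Unified k=3 motif hierarchy: m=1 mean-field, m=2 pairwise,
    m in {3,4} the motif systems above.  Returns a ClosureModel."""
    from .closures import build_pairwise
    if m == 1:
        return build_meanfield(N, 3, params)
    if m == 2:
        return build_pairwise(N, 3, params)
    return build_k3_motif_model(m, N, params).model


def as_model(obj):
    """Accept a ClosureModel or a MotifSystem."""
    return obj.model if isinstance(obj, MotifSystem) else obj
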