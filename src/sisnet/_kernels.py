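"""Numba event-loop kernels for exact SIS simulation.

The continuous-time Markov chain is simulated by a thinned Gillespie
scheme: the total event-rate bound is gamma * n_I + tau * sum of degrees
over infectious nodes; infection attempts pick an infectious node
(degree-weighted by rejection) and one of its neighbours uniformly, and
are accepted only if the neighbour is susceptible.  Null events advance
time but change nothing, which leaves the process statistically exact.

Pair counts are maintained incrementally: ``si`` is the number of S-I
edges (the [SI] of the double-sum counting convention), ``ss``/``ii`` the
undirected same-state edge counts (so [SS] = 2 ss, [II] = 2 ii).
"""

import numba
import numpy as np
from numba import njit


@njit(cache=True)
def _pair_counts(indptr, indices, state):
    ss = si = ii = 0
    n = len(indptr) - 1
    for u in range(n):
        for e in range(indptr[u], indptr[u + 1]):
            v = indices[e]
            if v > u:
                if state[u] == 0 and state[v] == 0:
                    ss += 1
                elif state[u] == 1 and state[v] == 1:
                    ii += 1
                else:
                    si += 1
    return ss, si, ii


@njit(cache=True)
def gillespie_run(indptr, indices, state, tau, gamma, t_max, record_dt,
                  seed, qs_restart, snapshot_dt, stop_mask):
    """Exact SIS realisation.

    state : int8 array (0 = S, 1 = I), modified in place.
    qs_restart : if True, on absorption the state is restored from a
        periodically refreshed snapshot (quasi-stationary conditioning).
    stop_mask : bool array; the run stops as soon as a node with
        stop_mask[node] becomes infectious (pass all-False to disable).

    Returns (times, I, SI, ss, ii, n_restarts, t_stop) where the series
    are sampled at multiples of record_dt (plus the stop time).
    """
    np.random.seed(seed)
    n = len(indptr) - 1
    deg = np.empty(n, dtype=np.int64)
    for u in range(n):
        deg[u] = indptr[u + 1] - indptr[u]
    dmax = deg.max()

    # infectious bookkeeping
    i_list = np.empty(n, dtype=np.int64)
    i_pos = np.full(n, -1, dtype=np.int64)
    n_i = 0
    sumdeg_i = 0
    for u in range(n):
        if state[u] == 1:
            i_list[n_i] = u
            i_pos[u] = n_i
            n_i += 1
            sumdeg_i += deg[u]
    inf_nbrs = np.zeros(n, dtype=np.int64)
    for u in range(n):
        for e in range(indptr[u], indptr[u + 1]):
            if state[indices[e]] == 1:
                inf_nbrs[u] += 1
    ss, si, ii = _pair_counts(indptr, indices, state)

    n_rec = int(t_max / record_dt) + 2
    times = np.empty(n_rec)
    rec_I = np.empty(n_rec, dtype=np.int64)
    rec_SI = np.empty(n_rec, dtype=np.int64)
    rec_SS = np.empty(n_rec, dtype=np.int64)
    rec_II = np.empty(n_rec, dtype=np.int64)
    k_rec = 0
    t_next = 0.0

    # quasi-stationary snapshot
    snap_state = state.copy()
    snap_inf = inf_nbrs.copy()
    snap_counts = np.array([n_i, sumdeg_i, ss, si, ii], dtype=np.int64)
    t_snap = snapshot_dt
    n_restarts = 0

    t = 0.0
    t_stop = -1.0
    stopped = False
    while t < t_max and not stopped:
        if n_i == 0:
            if qs_restart and snap_counts[0] > 0:
                state[:] = snap_state
                inf_nbrs[:] = snap_inf
                n_i = snap_counts[0]
                sumdeg_i = snap_counts[1]
                ss, si, ii = snap_counts[2], snap_counts[3], snap_counts[4]
                n_i2 = 0
                for u in range(n):
                    if state[u] == 1:
                        i_list[n_i2] = u
                        i_pos[u] = n_i2
                        n_i2 += 1
                    else:
                        i_pos[u] = -1
                n_restarts += 1
            else:
                break
        rate = gamma * n_i + tau * sumdeg_i
        t_new = t + np.random.exponential(1.0 / rate)
        # sample times in [t, t_new) carry the pre-event state
        while t_next < min(t_new, t_max) and k_rec < n_rec:
            times[k_rec] = t_next
            rec_I[k_rec] = n_i
            rec_SI[k_rec] = si
            rec_SS[k_rec] = ss
            rec_II[k_rec] = ii
            k_rec += 1
            t_next += record_dt
        t = t_new
        if t >= t_max:
            break
        if t >= t_snap and qs_restart:
            snap_state[:] = state
            snap_inf[:] = inf_nbrs
            snap_counts[0] = n_i
            snap_counts[1] = sumdeg_i
            snap_counts[2] = ss
            snap_counts[3] = si
            snap_counts[4] = ii
            t_snap = t + snapshot_dt
        if np.random.random() < gamma * n_i / rate:
            # recovery of a uniform infectious node
            j = int(np.random.random() * n_i)
            u = i_list[j]
            state[u] = 0
            last = i_list[n_i - 1]
            i_list[j] = last
            i_pos[last] = j
            i_pos[u] = -1
            n_i -= 1
            sumdeg_i -= deg[u]
            for e in range(indptr[u], indptr[u + 1]):
                v = indices[e]
                inf_nbrs[v] -= 1
                if state[v] == 1:
                    ii -= 1
                    si += 1
                else:
                    si -= 1
                    ss += 1
        else:
            # infection attempt: degree-weighted infectious source
            while True:
                j = int(np.random.random() * n_i)
                u = i_list[j]
                if deg[u] == dmax or np.random.random() * dmax < deg[u]:
                    break
            e = indptr[u] + int(np.random.random() * deg[u])
            v = indices[e]
            if state[v] == 0:
                state[v] = 1
                i_list[n_i] = v
                i_pos[v] = n_i
                n_i += 1
                sumdeg_i += deg[v]
                for e2 in range(indptr[v], indptr[v + 1]):
                    w = indices[e2]
                    inf_nbrs[w] += 1
                    if state[w] == 1:
                        si -= 1
                        ii += 1
                    else:
                        ss -= 1
                        si += 1
                if stop_mask[v]:
                    t_stop = t
                    stopped = True
    # final sample at the stop/absorption time
    if k_rec < n_rec:
        times[k_rec] = t if t < t_max else t_max
        rec_I[k_rec] = n_i
        rec_SI[k_rec] = si
        rec_SS[k_rec] = ss
        rec_II[k_rec] = ii
        k_rec += 1
    return (times[:k_rec], rec_I[:k_rec], rec_SI[:k_rec], rec_SS[:k_rec],
            rec_II[:k_rec], n_restarts, t_stop)


@njit(cache=True)
def qs_mean_prevalence(indptr, indices, state, tau, gamma, t_burn, t_meas,
                       seed, snapshot_dt):
    """Time-averaged quasi-stationary infectious count (and S-I edge count)
    over [t_burn, t_burn + t_meas], conditioning on non-extinction via
    snapshot restarts."""
    np.random.seed(seed)
    n = len(indptr) - 1
    deg = np.empty(n, dtype=np.int64)
    for u in range(n):
        deg[u] = indptr[u + 1] - indptr[u]
    dmax = deg.max()
    i_list = np.empty(n, dtype=np.int64)
    i_pos = np.full(n, -1, dtype=np.int64)
    n_i = 0
    sumdeg_i = 0
    for u in range(n):
        if state[u] == 1:
            i_list[n_i] = u
            i_pos[u] = n_i
            n_i += 1
            sumdeg_i += deg[u]
    inf_nbrs = np.zeros(n, dtype=np.int64)
    for u in range(n):
        for e in range(indptr[u], indptr[u + 1]):
            if state[indices[e]] == 1:
                inf_nbrs[u] += 1
    si = 0
    for u in range(n):
        if state[u] == 0:
            si += inf_nbrs[u]

    snap_state = state.copy()
    snap_inf = inf_nbrs.copy()
    snap_ni = n_i
    snap_sumdeg = sumdeg_i
    snap_si = si
    t_snap = snapshot_dt
    n_restarts = 0

    t = 0.0
    t_end = t_burn + t_meas
    acc_I = 0.0
    acc_SI = 0.0
    acc_T = 0.0
    while t < t_end:
        if n_i == 0:
            if snap_ni > 0:
                state[:] = snap_state
                inf_nbrs[:] = snap_inf
                n_i = snap_ni
                sumdeg_i = snap_sumdeg
                si = snap_si
                n_i2 = 0
                for u in range(n):
                    if state[u] == 1:
                        i_list[n_i2] = u
                        i_pos[u] = n_i2
                        n_i2 += 1
                    else:
                        i_pos[u] = -1
                n_restarts += 1
            else:
                break
        rate = gamma * n_i + tau * sumdeg_i
        dt = np.random.exponential(1.0 / rate)
        t_new = t + dt
        if t_new > t_burn:
            lo = t if t > t_burn else t_burn
            hi = t_new if t_new < t_end else t_end
            if hi > lo:
                acc_I += n_i * (hi - lo)
                acc_SI += si * (hi - lo)
                acc_T += hi - lo
        t = t_new
        if t >= t_end:
            break
        if t >= t_snap:
            snap_state[:] = state
            snap_inf[:] = inf_nbrs
            snap_ni = n_i
            snap_sumdeg = sumdeg_i
            snap_si = si
            t_snap = t + snapshot_dt
        if np.random.random() < gamma * n_i / rate:
            j = int(np.random.random() * n_i)
            u = i_list[j]
            state[u] = 0
            last = i_list[n_i - 1]
            i_list[j] = last
            i_pos[last] = j
            i_pos[u] = -1
            n_i -= 1
            sumdeg_i -= deg[u]
            for e in range(indptr[u], indptr[u + 1]):
                v = indices[e]
                inf_nbrs[v] -= 1
                if state[v] == 0:
                    si -= 1
                else:
                    si += 1
        else:
            while True:
                j = int(np.random.random() * n_i)
                u = i_list[j]
                if deg[u] == dmax or np.random.random() * dmax < deg[u]:
                    break
            e = indptr[u] + int(np.random.random() * deg[u])
            v = indices[e]
            if state[v] == 0:
                state[v] = 1
                i_list[n_i] = v
                i_pos[v] = n_i
                n_i += 1
                sumdeg_i += deg[v]
                for e2 in range(indptr[v], indptr[v + 1]):
                    w = indices[e2]
                    inf_nbrs[w] += 1
                    if state[w] == 0:
                        si += 1
                    else:
                        si -= 1
    if acc_T == 0.0:
        return 0.0, 0.0, n_restarts
    return acc_I / acc_T, acc_SI / acc_T, n_restarts
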