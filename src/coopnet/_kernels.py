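"""Numba kernels for the game dynamics hot loop.

Graphs enter as CSR adjacency (``indptr``, ``indices``) with sorted neighbor
lists.  All kernels draw from numba's internal Mersenne-Twister state, which is
independent of numpy's global state; callers seed it through :func:`seed_rng`
before a kernel sequence that must be reproducible.
"""

import numpy as np
from numba import njit

RULE_RECOLONIZE = 0
RULE_FERMI = 1
RULE_UNCONDITIONAL = 2


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def payoff_kernel(indptr, indices, strat, T, R, P, S):
    n = indptr.size - 1
    pay = np.zeros(n)
    for x in range(n):
        sx = strat[x]
        acc = 0.0
        for e in range(indptr[x], indptr[x + 1]):
            sy = strat[indices[e]]
            if sx == 1:
                acc += R if sy == 1 else S
            else:
                acc += T if sy == 1 else P
        pay[x] = acc
    return pay


@njit(cache=True)
def recolonize_step(indptr, indices, strat, pay, degrees, D):
    """Synchronous recolonization: each site is kept by its occupant with the
    focal-retention product prod_l (1 - W_l), otherwise taken over by neighbor
    y with relative probability W_y / sum_l W_l, where
    W_y = max(0, P_y - P_x) / (D * max(d_x, d_y))."""
    n = indptr.size - 1
    out = np.empty(n, np.int8)
    maxdeg = 0
    for x in range(n):
        if degrees[x] > maxdeg:
            maxdeg = degrees[x]
    w = np.empty(maxdeg)
    for x in range(n):
        px = pay[x]
        dx = degrees[x]
        start = indptr[x]
        deg = indptr[x + 1] - start
        retain = 1.0
        tot = 0.0
        for t in range(deg):
            y = indices[start + t]
            py = pay[y]
            if py > px:
                dy = degrees[y]
                dmax = dx if dx > dy else dy
                wv = (py - px) / (D * dmax)
            else:
                wv = 0.0
            w[t] = wv
            retain *= 1.0 - wv
            tot += wv
        if tot <= 0.0 or np.random.random() < retain:
            out[x] = strat[x]
        else:
            u = np.random.random() * tot
            c = 0.0
            pick = -1
            for t in range(deg):
                c += w[t]
                if w[t] > 0.0 and u < c:
                    pick = indices[start + t]
                    break
            if pick < 0:  # rounding spill: last positive-weight neighbor
                for t in range(deg - 1, -1, -1):
                    if w[t] > 0.0:
                        pick = indices[start + t]
                        break
            out[x] = strat[pick]
    return out


@njit(cache=True)
def fermi_step(indptr, indices, strat, pay, k):
    """Synchronous Fermi rule: each learner picks one neighbor uniformly and
    adopts its strategy with probability 1/(1+exp((P_learner - P_model)/k))."""
    n = indptr.size - 1
    out = np.empty(n, np.int8)
    for z in range(n):
        start = indptr[z]
        deg = indptr[z + 1] - start
        if deg == 0:
            out[z] = strat[z]
            continue
        wnode = indices[start + np.random.randint(0, deg)]
        prob = 1.0 / (1.0 + np.exp((pay[z] - pay[wnode]) / k))
        if np.random.random() < prob:
            out[z] = strat[wnode]
        else:
            out[z] = strat[z]
    return out


@njit(cache=True)
def unconditional_step(indptr, indices, strat, pay):
    """Synchronous unconditional imitation: copy the strictly richer best
    neighbor; ties among equally best neighbors broken uniformly."""
    n = indptr.size - 1
    out = np.empty(n, np.int8)
    for x in range(n):
        px = pay[x]
        start = indptr[x]
        deg = indptr[x + 1] - start
        best = px
        count = 0
        for t in range(deg):
            py = pay[indices[start + t]]
            if py > best:
                best = py
                count = 1
            elif py == best and best > px:
                count += 1
        if best > px:
            j = np.random.randint(0, count)
            seen = 0
            for t in range(deg):
                if pay[indices[start + t]] == best:
                    if seen == j:
                        out[x] = strat[indices[start + t]]
                        break
                    seen += 1
        else:
            out[x] = strat[x]
    return out


@njit(cache=True)
def _coop_freq(strat):
    c = 0
    for i in range(strat.size):
        if strat[i] == 1:
            c += 1
    return c / strat.size


@njit(cache=True)
def _is_homogeneous(strat):
    s0 = strat[0]
    for i in range(1, strat.size):
        if strat[i] != s0:
            return False
    return True


@njit(cache=True)
def evaluate_kernel(indptr, indices, degrees, rule_id, k, T, R, P, S, D,
                    n_transient, n_average, init_strat):
    """One equilibrium cooperation-level sample.

    Runs ``n_transient`` synchronous generations, then averages the
    cooperation frequency recorded after each of the next ``n_average``
    generations.  ``init_strat[0] < 0`` requests a random half/half strategy
    initialization; otherwise ``init_strat`` is used as-is (test hook).
    Once the state is homogeneous it is absorbing under all three rules, so
    the remaining window is filled with the constant frequency.
    """
    n = indptr.size - 1
    if init_strat[0] < 0:
        strat = np.empty(n, np.int8)
        for i in range(n):
            strat[i] = 1 if np.random.random() < 0.5 else 0
    else:
        strat = init_strat.copy()
    total = 0.0
    recorded = 0
    g = 0
    ngen = n_transient + n_average
    while g < ngen:
        if _is_homogeneous(strat):
            total += (n_average - recorded) * _coop_freq(strat)
            recorded = n_average
            break
        pay = payoff_kernel(indptr, indices, strat, T, R, P, S)
        if rule_id == RULE_RECOLONIZE:
            strat = recolonize_step(indptr, indices, strat, pay, degrees, D)
        elif rule_id == RULE_FERMI:
            strat = fermi_step(indptr, indices, strat, pay, k)
        else:
            strat = unconditional_step(indptr, indices, strat, pay)
        g += 1
        if g > n_transient:
            total += _coop_freq(strat)
            recorded += 1
    return total / n_average


@njit(cache=True)
def replicate_step(indptr, indices, strat, pay, degrees, D, k, rule_id,
                   n_rep):
    """n_rep independent synchronous single steps from one fixed state;
    returns the resulting strategy matrix (Monte-Carlo oracle helper)."""
    n = indptr.size - 1
    out = np.empty((n_rep, n), np.int8)
    for r in range(n_rep):
        if rule_id == RULE_RECOLONIZE:
            out[r] = recolonize_step(indptr, indices, strat, pay, degrees, D)
        elif rule_id == RULE_FERMI:
            out[r] = fermi_step(indptr, indices, strat, pay, k)
        else:
            out[r] = unconditional_step(indptr, indices, strat, pay)
    return out


@njit(cache=True)
def local_clustering_sum(indptr, indices):
    """Sum over nodes of the local clustering coefficient
    |E(Gamma_i)| / (d_i (d_i - 1) / 2); nodes with d_i < 2 contribute 0.
    Neighbor lists must be sorted (binary search membership)."""
    n = indptr.size - 1
    total = 0.0
    for i in range(n):
        start = indptr[i]
        deg = indptr[i + 1] - start
        if deg < 2:
            continue
        links = 0
        for a in range(deg):
            u = indices[start + a]
            for b in range(a + 1, deg):
                v = indices[start + b]
                # binary search v in u's sorted neighbor list
                lo = indptr[u]
                hi = indptr[u + 1]
                while lo < hi:
                    mid = (lo + hi) // 2
                    if indices[mid] < v:
                        lo = mid + 1
                    else:
                        hi = mid
                if lo < indptr[u + 1] and indices[lo] == v:
                    links += 1
        total += links / (deg * (deg - 1) / 2.0)
    return total
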