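"""Numba-compiled inner loops.

The event loop is the hot path of every experiment (a desk-scale phase
point is ~1.5e7 events), so it is compiled with numba.  Kernels mutate
the strategy array in place and draw from numba's own global RNG, seeded
explicitly at kernel entry, which keeps every call reproducible.

Selection weights are computed as ``exp(w * (p - max p))`` so that large
``w * p`` never overflows; the deterministic ``w = inf`` limit takes an
argmax with uniform tie-breaking.
"""

import numpy as np
from numba import njit

__all__ = ["run_events_kernel", "run_line_pinned_kernel"]


@njit(cache=True, inline="always")
def _payoff_one(indptr, indices, labels, strategies, act, i, b):
    p = 0.0
    li = labels[i]
    si = strategies[i]
    for e in range(indptr[i], indptr[i + 1]):
        j = indices[e]
        p += b * act[strategies[j], li] - act[si, labels[j]]
    return p


@njit(cache=True)
def run_events_kernel(
    indptr,
    indices,
    labels,
    strategies,
    act,
    n_events,
    b,
    w,
    mu,
    seed,
    deterministic,
):
    """Advance by ``n_events`` asynchronous update events (in place)."""
    np.random.seed(seed)
    n = labels.shape[0]
    maxdeg = 0
    for i in range(n):
        d = indptr[i + 1] - indptr[i]
        if d > maxdeg:
            maxdeg = d
    pbuf = np.empty(maxdeg)
    for _ in range(n_events):
        i = np.random.randint(0, n)
        coin = np.random.random()
        if coin < mu:
            strategies[i] = np.random.randint(0, 4)
            continue
        s0 = indptr[i]
        deg = indptr[i + 1] - s0
        if deg == 0:
            continue  # isolated agent: imitation undefined, event wasted
        pmax = -1.0e300
        for k in range(deg):
            p = _payoff_one(indptr, indices, labels, strategies, act, indices[s0 + k], b)
            pbuf[k] = p
            if p > pmax:
                pmax = p
        if deterministic:
            nties = 0
            for k in range(deg):
                if pbuf[k] == pmax:
                    nties += 1
            r = np.random.randint(0, nties)
            for k in range(deg):
                if pbuf[k] == pmax:
                    if r == 0:
                        strategies[i] = strategies[indices[s0 + k]]
                        break
                    r -= 1
        else:
            tot = 0.0
            for k in range(deg):
                pbuf[k] = np.exp(w * (pbuf[k] - pmax))
                tot += pbuf[k]
            u = np.random.random() * tot
            acc = 0.0
            for k in range(deg):
                acc += pbuf[k]
                if u < acc or k == deg - 1:
                    strategies[i] = strategies[indices[s0 + k]]
                    break


@njit(cache=True)
def run_line_pinned_kernel(
    labels,
    strategies,
    act,
    n_events,
    b,
    w,
    seed,
    green_index,
    thin,
    deterministic,
):
    """Mutation-free 1D line dynamics with both end strategies pinned.

    Agents sit on a path graph; the two outermost agents are excluded from
    focal selection so their strategies never change.  Every ``thin``
    events the state is classified by the strategy the green agent holds:
    1 if it is covered by the discriminating domain (COOP_BLUE), 0 if by
    the full-cooperation domain (COOP_ALL), -1 if the two-domain structure
    is broken (more than one domain wall; should never occur when the
    initial state is two-domain).  Returns the int8 sample array.
    """
    np.random.seed(seed)
    n = labels.shape[0]
    n_samples = n_events // thin
    samples = np.empty(n_samples, dtype=np.int8)
    s_idx = 0
    for ev in range(n_events):
        i = 1 + np.random.randint(0, n - 2)
        # payoffs of the two neighbours
        pl = 0.0
        pr = 0.0
        # left neighbour i-1
        jl = i - 1
        li = labels[jl]
        si = strategies[jl]
        if jl - 1 >= 0:
            pl += b * act[strategies[jl - 1], li] - act[si, labels[jl - 1]]
        pl += b * act[strategies[jl + 1], li] - act[si, labels[jl + 1]]
        # right neighbour i+1
        jr = i + 1
        li = labels[jr]
        si = strategies[jr]
        pr += b * act[strategies[jr - 1], li] - act[si, labels[jr - 1]]
        if jr + 1 < n:
            pr += b * act[strategies[jr + 1], li] - act[si, labels[jr + 1]]
        if deterministic:
            if pl > pr:
                strategies[i] = strategies[jl]
            elif pr > pl:
                strategies[i] = strategies[jr]
            elif np.random.random() < 0.5:
                strategies[i] = strategies[jl]
            else:
                strategies[i] = strategies[jr]
        else:
            # P(copy left) = 1 / (1 + exp(w*(pr - pl))), shift-safe logistic
            d = w * (pr - pl)
            if d > 700.0:
                p_left = 0.0
            elif d < -700.0:
                p_left = 1.0
            else:
                p_left = 1.0 / (1.0 + np.exp(d))
            if np.random.random() < p_left:
                strategies[i] = strategies[jl]
            else:
                strategies[i] = strategies[jr]
        if (ev + 1) % thin == 0 and s_idx < n_samples:
            walls = 0
            for k in range(n - 1):
                if strategies[k] != strategies[k + 1]:
                    walls += 1
            if walls != 1:
                samples[s_idx] = -1
            elif strategies[green_index] == 2:  # COOP_BLUE covers the green agent
                samples[s_idx] = 1
            else:
                samples[s_idx] = 0
            s_idx += 1
    return samples
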