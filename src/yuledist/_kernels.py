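"""Numba kernels: KMC tree generation and ensemble statistic accumulation.

The event loop follows the kinetic Monte Carlo scheme: with M alive lineages
the waiting time to the next event is Exponential(mean 1/(M(lambda+mu))), a
uniformly chosen lineage then splits with probability lambda/(lambda+mu) or
dies; the event whose waiting time overshoots T is discarded and the state is
frozen at T.  Extant lineages are marked observed with probability sigma using
the same per-tree RNG stream.

Nodes are appended parent-before-child, so reverse iteration gives a valid
post-order for subtree tallies.  Statistic extraction works on the genealogy
directly: a split node whose child subtrees hold m1 and m2 observed leaves
contributes m1*m2 pairs at distance 2(T - t_split); n-th nearest distances
come from walking each observed leaf's ancestor path and accumulating
opposite-side subtree counts; a cherry is a split node with exactly one
observed leaf on each side.
"""
import numpy as np
from numba import njit

KIND_SPLIT = 0
KIND_DEATH = 1
KIND_EXTANT = 2


@njit(cache=True)
def _kmc(lam, mu, sigma, T, seed, cap):
    """Simulate one tree; returns (parent, t_birth, t_end, kind, observed, ok)."""
    np.random.seed(seed)
    n = 64
    parent = np.full(n, -1, np.int64)
    tb = np.zeros(n)
    te = np.zeros(n)
    kind = np.zeros(n, np.int8)
    alive = np.empty(n, np.int64)
    alive[0] = 0
    na = 1
    nn = 1
    t = 0.0
    tot = lam + mu
    ok = True
    while na > 0 and tot > 0.0:
        dt = np.random.exponential(1.0 / (na * tot))
        if t + dt > T:
            break
        t += dt
        i = np.random.randint(na)
        node = alive[i]
        if np.random.random() < lam / tot:
            if nn + 2 > parent.shape[0]:
                m = parent.shape[0] * 2
                p2 = np.full(m, -1, np.int64); p2[:nn] = parent[:nn]; parent = p2
                b2 = np.zeros(m); b2[:nn] = tb[:nn]; tb = b2
                e2 = np.zeros(m); e2[:nn] = te[:nn]; te = e2
                k2 = np.zeros(m, np.int8); k2[:nn] = kind[:nn]; kind = k2
                a2 = np.empty(m, np.int64); a2[:na] = alive[:na]; alive = a2
            te[node] = t
            kind[node] = KIND_SPLIT
            parent[nn] = node; tb[nn] = t
            parent[nn + 1] = node; tb[nn + 1] = t
            alive[i] = nn
            alive[na] = nn + 1
            na += 1
            nn += 2
            if na > cap:
                ok = False
                break
        else:
            te[node] = t
            kind[node] = KIND_DEATH
            alive[i] = alive[na - 1]
            na -= 1
    obs = np.zeros(nn, np.bool_)
    if ok:
        for i in range(na):
            te[alive[i]] = T
            kind[alive[i]] = KIND_EXTANT
        for i in range(nn):
            if kind[i] == KIND_EXTANT and np.random.random() < sigma:
                obs[i] = True
    return parent[:nn], tb[:nn], te[:nn], kind[:nn], obs, ok


@njit(cache=True)
def _children(parent):
    n = parent.shape[0]
    ch1 = np.full(n, -1, np.int64)
    ch2 = np.full(n, -1, np.int64)
    for i in range(n):
        p = parent[i]
        if p >= 0:
            if ch1[p] < 0:
                ch1[p] = i
            else:
                ch2[p] = i
    return ch1, ch2


@njit(cache=True)
def _obs_counts(parent, kind, obs):
    """Observed-leaf count of every subtree (reverse index order = post-order)."""
    n = parent.shape[0]
    cnt = np.zeros(n, np.int64)
    for i in range(n - 1, -1, -1):
        if kind[i] == KIND_EXTANT and obs[i]:
            cnt[i] += 1
        p = parent[i]
        if p >= 0:
            cnt[p] += cnt[i]
    return cnt


@njit(cache=True, inline="always")
def _bin_of(d, width, nbins):
    if d < 0.0:
        return -1
    b = int(d / width)
    if b >= nbins:
        # last bin is closed on the right
        if d <= width * nbins * (1.0 + 1e-12):
            return nbins - 1
        return -1
    return b


@njit(cache=True)
def _interval_occupancy(lam, mu, sigma, T, seeds, t_lo, t_hi, cap, nmax):
    """Tally, over trees, the number of observed pairs separated by a time in
    [t_lo, t_hi); returns (tally[n] for n = 0..nmax with overflow slot, failures)."""
    tally = np.zeros(nmax + 2, np.int64)
    failed = 0
    for s in range(seeds.shape[0]):
        parent, tb, te, kind, obs, ok = _kmc(lam, mu, sigma, T, seeds[s], cap)
        if not ok:
            failed += 1
            continue
        cnt = _obs_counts(parent, kind, obs)
        ch1, ch2 = _children(parent)
        c = 0
        for i in range(parent.shape[0]):
            if kind[i] == KIND_SPLIT:
                d = 2.0 * (T - te[i])
                if t_lo <= d < t_hi:
                    c += cnt[ch1[i]] * cnt[ch2[i]]
        tally[c if c <= nmax else nmax + 1] += 1
    return tally, failed


@njit(cache=True)
def _ensemble(lam, mu, sigma, T, seeds, nbins, hi, ns, cap, occ_nmax, leaf_max):
    """Accumulate per-bin statistics over len(seeds) independent trees.

    Rows of the output arrays: 0 pairwise, 1 cherry, 2 min2, then one row per
    entry of ``ns`` (n-th nearest neighbour ranks).  Returns (sums, sumsq,
    nonzero-tree counts, pairwise bin occupancy tallies, observed-leaf-count
    histogram, extant-leaf-count histogram, number of capped trees).
    """
    S = seeds.shape[0]
    K = 3 + ns.shape[0]
    sums = np.zeros((K, nbins))
    sumsq = np.zeros((K, nbins))
    nonzero = np.zeros((K, nbins), np.int64)
    occ = np.zeros((nbins, occ_nmax + 2), np.int64)
    leafh = np.zeros(leaf_max + 1, np.int64)
    extanth = np.zeros(leaf_max + 1, np.int64)
    counts = np.zeros((K, nbins))
    width = hi / nbins
    nmax_req = 1
    for kk in range(ns.shape[0]):
        if ns[kk] > nmax_req:
            nmax_req = ns[kk]
    failed = 0
    for s in range(S):
        parent, tb, te, kind, obs, ok = _kmc(lam, mu, sigma, T, seeds[s], cap)
        if not ok:
            failed += 1
            continue
        counts[:, :] = 0.0
        n = parent.shape[0]
        Mobs = 0
        Mext = 0
        for i in range(n):
            if kind[i] == KIND_EXTANT:
                Mext += 1
                if obs[i]:
                    Mobs += 1
        leafh[min(Mobs, leaf_max)] += 1
        extanth[min(Mext, leaf_max)] += 1
        cnt = _obs_counts(parent, kind, obs)
        ch1, ch2 = _children(parent)
        for i in range(n):
            if kind[i] == KIND_SPLIT:
                c1 = cnt[ch1[i]]
                c2 = cnt[ch2[i]]
                if c1 > 0 and c2 > 0:
                    b = _bin_of(2.0 * (T - te[i]), width, nbins)
                    if b >= 0:
                        counts[0, b] += c1 * c2
                        if c1 == 1 and c2 == 1:
                            counts[1, b] += 1.0
        if Mobs >= 2:
            d1 = np.empty(Mobs)
            j = 0
            for i in range(n):
                if kind[i] == KIND_EXTANT and obs[i]:
                    rank = 0
                    node = i
                    got_d1 = False
                    while parent[node] >= 0:
                        p = parent[node]
                        sib = ch2[p] if ch1[p] == node else ch1[p]
                        c = cnt[sib]
                        if c > 0:
                            d = 2.0 * (T - te[p])
                            if not got_d1:
                                d1[j] = d
                                got_d1 = True
                            for kk in range(ns.shape[0]):
                                nw = ns[kk]
                                if rank < nw <= rank + c:
                                    b = _bin_of(d, width, nbins)
                                    if b >= 0:
                                        counts[3 + kk, b] += 1.0
                            rank += c
                            if rank >= nmax_req:
                                break
                        node = p
                    j += 1
            d1s = np.sort(d1)
            for k2 in range(Mobs - 1):
                b = _bin_of(d1s[k2], width, nbins)
                if b >= 0:
                    counts[2, b] += Mobs - 1 - k2
        for kk in range(K):
            for b in range(nbins):
                c = counts[kk, b]
                sums[kk, b] += c
                sumsq[kk, b] += c * c
                if c > 0.0:
                    nonzero[kk, b] += 1
        for b in range(nbins):
            c = int(counts[0, b])
            occ[b, c if c <= occ_nmax else occ_nmax + 1] += 1
    return sums, sumsq, nonzero, occ, leafh, extanth, failed
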