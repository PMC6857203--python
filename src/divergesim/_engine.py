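"""Low-level coalescent engine (numba-compiled).

Two-population structured coalescent with three backward-time epochs:

* epoch 0, ``[0, t1)``   -- per-population sizes may change exponentially
  (endpoint-parameterised growth), per-epoch migration;
* epoch 1, ``[t1, tT)``  -- constant per-population sizes, per-epoch migration;
* epoch 2, ``[tT, inf)`` -- single panmictic ancestral population.

All times are in units of ``4*N_ref`` generations and sizes are relative to
``N_ref`` (the ms convention).  The per-lineage backward migration rate for a
lineage currently in population *i* is ``2*M_ji / n_i(t)`` where ``M_ji`` is
the number of immigrant individuals per generation entering *i* and ``n_i``
the relative size, so the stored timeline carries the numerators ``2*M``.

Sample masks: each tree node stores the set of tips below it as a 64-bit
mask (tip *i* -> bit *i*), which caps the sample at 64 haplotypes.  Tips
``0..nK-1`` belong to population K, tips ``nK..nK+nW-1`` to population W, and
haplotypes ``(2j, 2j+1)`` form diploid individual *j* -- the bit-parallel
tricks below (heterozygote masks, dosage cross-products) rely on that fixed
pairing and on even per-population sample sizes.

Timeline layout (float64[13]):
    0 t1   1 tT   2 nK0  3 nW0  4 aK   5 aW
    6 nK1  7 nW1  8 nA   9 mK0  10 mW0 11 mK1 12 mW1
where ``a*`` are backward growth exponents in epoch 0
(``n(t) = n0 * exp(a*t)``) and ``m*`` the ``2*M`` migration numerators
(``mK`` acts on lineages in K, i.e. uses ``M_{W->K}``).

Per-locus statistics row (STAT_* indices): pi_K, pi_W, D_K, D_W, F_ST
(Weir-Cockerham, diploid, ratio of sums), d_XY, d_f, mean dosage r^2,
segregating sites, pooled Tajima's D.  Undefined values are NaN.
"""

import math

import numpy as np
from numba import njit

# timeline field indices
TL_T1, TL_TT, TL_NK0, TL_NW0, TL_AK, TL_AW = 0, 1, 2, 3, 4, 5
TL_NK1, TL_NW1, TL_NA, TL_MK0, TL_MW0, TL_MK1, TL_MW1 = 6, 7, 8, 9, 10, 11, 12
TL_LEN = 13

# statistic row indices
(STAT_PI_K, STAT_PI_W, STAT_D_K, STAT_D_W, STAT_FST, STAT_DXY,
 STAT_DF, STAT_R2, STAT_S, STAT_D_POOL) = range(10)
N_STATS = 10

_MAX_EVENTS = 50_000_000
_EVEN = np.uint64(0x5555555555555555)


@njit(cache=True, inline="always")
def _popcount(x):
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + (
        (x >> np.uint64(2)) & np.uint64(0x3333333333333333))
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> np.uint64(56)


@njit(cache=True, inline="always")
def _rotpair(x):
    """Swap the two bits of every (even, odd) bit pair."""
    return ((x & _EVEN) << np.uint64(1)) | ((x >> np.uint64(1)) & _EVEN)



# --- fast inline RNG for the event loop (xorshift128+, seeded via splitmix64) ---

@njit(cache=True, inline="always")
def _splitmix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _xs_next(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    return (s0 + s1) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _xs_unif(state):
    """Uniform double in [0, 1)."""
    return float(_xs_next(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _xs_exp(state):
    u = _xs_unif(state)
    return -np.log(1.0 - u)


@njit(cache=True, inline="always")
def _xs_randint(state, k):
    """Uniform integer in [0, k)."""
    r = int(_xs_unif(state) * k)
    if r >= k:
        r = k - 1
    return r


@njit(cache=True, inline="always")
def _xs_seed(state, seed):
    z = _splitmix64(np.uint64(seed))
    state[0] = _splitmix64(z)
    state[1] = _splitmix64(state[0])



@njit(cache=True)
def _xs_poisson(state, lam):
    """Poisson draw: Knuth product for small lam, Hormann PTRS for lam >= 10."""
    if lam <= 0.0:
        return 0
    if lam < 10.0:
        L = np.exp(-lam)
        k = 0
        p = 1.0
        while True:
            p *= _xs_unif(state)
            if p <= L:
                return k
            k += 1
    b = 0.931 + 2.53 * np.sqrt(lam)
    a = -0.059 + 0.02483 * b
    inv_alpha = 1.1239 + 1.1328 / (b - 3.4)
    v_r = 0.9277 - 3.6224 / (b - 2.0)
    log_lam = np.log(lam)
    while True:
        u = _xs_unif(state) - 0.5
        v = _xs_unif(state)
        us = 0.5 - abs(u)
        k = int(np.floor((2.0 * a / us + b) * u + lam + 0.43))
        if us >= 0.07 and v <= v_r:
            return k
        if k < 0 or (us < 0.013 and v > us):
            continue
        if np.log(v) * inv_alpha <= k * log_lam - lam - math.lgamma(k + 1.0):
            return k


@njit(cache=True)
def _wait_time(t, t0, base, alpha, C, E):
    """Time to exhaust integrated hazard E for rate C / (base*exp(alpha*(u-t0)))."""
    if C <= 0.0:
        return np.inf
    if alpha == 0.0:
        return E * base / C
    x = np.exp(-alpha * (t - t0)) - E * base * alpha / C
    if x <= 0.0:
        return np.inf
    return -np.log(x) / alpha - (t - t0)


@njit(cache=True)
def _sim_tree(tl, nK, nW, parent, node_time, masks, state):
    """Simulate one genealogy; fills parent/node_time/masks. Returns 0 on success."""
    n = nK + nW
    lin = np.empty((2, n), dtype=np.int32)
    cnt = np.zeros(2, dtype=np.int64)
    for i in range(nK):
        lin[0, i] = i
    cnt[0] = nK
    for i in range(nW):
        lin[1, i] = nK + i
    cnt[1] = nW
    for i in range(n):
        parent[i] = -1
        node_time[i] = 0.0
        masks[i] = np.uint64(1) << np.uint64(i)

    t = 0.0
    epoch = 0
    if tl[TL_T1] <= 0.0:  # no T1 boundary: epoch 0 is empty
        epoch = 1
    nxt = n  # next internal node id
    k = n
    events = 0
    while k > 1:
        if epoch == 0:
            eb = tl[TL_T1]
            t0 = 0.0
            baseK, baseW = tl[TL_NK0], tl[TL_NW0]
            aK, aW = tl[TL_AK], tl[TL_AW]
            mK, mW = tl[TL_MK0], tl[TL_MW0]
        elif epoch == 1:
            eb = tl[TL_TT]
            t0 = tl[TL_T1]
            baseK, baseW = tl[TL_NK1], tl[TL_NW1]
            aK, aW = 0.0, 0.0
            mK, mW = tl[TL_MK1], tl[TL_MW1]
        else:
            eb = np.inf
            t0 = tl[TL_TT]
            baseK, baseW = tl[TL_NA], 1.0
            aK, aW = 0.0, 0.0
            mK, mW = 0.0, 0.0
        constant = aK == 0.0 and aW == 0.0
        invK = 1.0 / baseK
        invW = 1.0 / baseW if baseW > 0.0 else 0.0

        while k > 1:
            events += 1
            if events > _MAX_EVENTS:
                return 1
            kK = cnt[0]
            kW = cnt[1]
            CK = (kK - 1 + mK) * kK
            CW = (kW - 1 + mW) * kW
            if constant:
                RK = CK * invK
                R = RK + CW * invW
                if R <= 0.0:
                    t = eb
                    break
                dt = _xs_exp(state) / R
                if t + dt >= eb:
                    t = eb
                    break
                t += dt
                u = _xs_unif(state) * R
                if u < RK:
                    pop, C, kp = 0, CK, kK
                    w = u / RK
                else:
                    pop, C, kp = 1, CW, kW
                    w = (u - RK) / (R - RK)
            else:
                dtK = _wait_time(t, t0, baseK, aK, CK, _xs_exp(state)) \
                    if CK > 0.0 else np.inf
                dtW = _wait_time(t, t0, baseW, aW, CW, _xs_exp(state)) \
                    if CW > 0.0 else np.inf
                if dtK <= dtW:
                    pop, dt, C, kp = 0, dtK, CK, kK
                else:
                    pop, dt, C, kp = 1, dtW, CW, kW
                if t + dt >= eb:
                    t = eb
                    break
                t += dt
                w = _xs_unif(state)

            if w * C < kp * (kp - 1):
                # coalescence in pop
                i = _xs_randint(state, kp)
                j = _xs_randint(state, kp - 1)
                if j >= i:
                    j += 1
                a = lin[pop, i]
                b = lin[pop, j]
                parent[a] = nxt
                parent[b] = nxt
                node_time[nxt] = t
                masks[nxt] = masks[a] | masks[b]
                parent[nxt] = -1
                lin[pop, i] = nxt
                lin[pop, j] = lin[pop, kp - 1]
                cnt[pop] -= 1
                nxt += 1
                k -= 1
            else:
                # migration: lineage moves to the other population
                i = _xs_randint(state, kp)
                other = 1 - pop
                lin[other, cnt[other]] = lin[pop, i]
                cnt[other] += 1
                lin[pop, i] = lin[pop, kp - 1]
                cnt[pop] -= 1

        if k > 1 and t == eb:
            epoch += 1
            if epoch == 2:
                # merge: all lineages into population 0
                for i in range(cnt[1]):
                    lin[0, cnt[0] + i] = lin[1, i]
                cnt[0] += cnt[1]
                cnt[1] = 0
    return 0


@njit(cache=True)
def _tajima_d(pi_sum, S, n):
    """Tajima's D from summed mean pairwise differences and S (NaN if S < 3)."""
    if S < 3 or n < 4:
        return np.nan
    a1 = 0.0
    a2 = 0.0
    for i in range(1, n):
        a1 += 1.0 / i
        a2 += 1.0 / (i * i)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0.0:
        return np.nan
    return (pi_sum - S / a1) / np.sqrt(var)


@njit(cache=True)
def _pair_r2(cu, squ, mu, cv, sqv, mv, nd):
    """Squared dosage correlation between two branch mutation columns."""
    cross = float(_popcount(mu & mv)) + float(_popcount(mu & _rotpair(mv)))
    cov = nd * cross - cu * cv
    vu = nd * squ - cu * cu
    vv = nd * sqv - cv * cv
    if vu <= 0.0 or vv <= 0.0:
        return -1.0
    return (cov * cov) / (vu * vv)


@njit(cache=True)
def _locus_stats(parent, node_time, masks, nK, nW, theta, L,
                 r2_exact_cap, r2_sample_pairs, bs, act, cs, sq, cum, state,
                 out):
    """Per-locus statistics from branch-level Poisson mutation counts.

    ``bs``/``act``/``cs``/``sq``/``cum`` are caller-provided scratch arrays of
    length 2*(nK+nW)-1.
    """
    n = nK + nW
    nnode = 2 * n - 1
    maskK = (np.uint64(1) << np.uint64(nK)) - np.uint64(1)
    nd = n // 2
    ndK = nK // 2
    ndW = nW // 2
    evenK = _EVEN & maskK
    evenAll = _EVEN & ((np.uint64(1) << np.uint64(n)) - np.uint64(1))
    two_pop = nW > 0

    # hoisted reciprocal constants
    inv_nK = 1.0 / nK
    inv_piK = 2.0 / (nK * (nK - 1.0))
    inv_piP = 2.0 / (n * (n - 1.0))
    if two_pop:
        inv_nW = 1.0 / nW
        inv_piW = 2.0 / (nW * (nW - 1.0))
        inv_ndK = 1.0 / ndK
        inv_ndW = 1.0 / ndW
        n1 = float(ndK)
        n2 = float(ndW)
        nbar = 0.5 * (n1 + n2)
        nc = 2.0 * nbar - (n1 * n1 + n2 * n2) / (2.0 * nbar)
        inv_2nbar = 1.0 / (2.0 * nbar)
        inv_nbar = 1.0 / nbar
        nbar_over_nc = nbar / nc
        inv_nbar1 = 1.0 / (nbar - 1.0)
        nbar_ratio = nbar * inv_nbar1
        h_coef = (2.0 * nbar - 1.0) / (4.0 * nbar)
    else:
        inv_nW = inv_piW = inv_ndK = inv_ndW = 0.0
        nbar_over_nc = inv_nbar1 = nbar_ratio = h_coef = 0.0
        n1 = n2 = nbar = inv_2nbar = inv_nbar = 0.0

    S = 0
    piK = 0.0
    piW = 0.0
    piP = 0.0
    dxy = 0.0
    df = 0.0
    SK = 0
    SW = 0
    fnum = 0.0
    fden = 0.0
    nact = 0
    tot = 0

    for i in range(nnode):
        p = parent[i]
        if p < 0:
            continue
        bl = node_time[p] - node_time[i]
        if bl <= 0.0:
            continue
        b = _xs_poisson(state, bl * theta)
        if b == 0:
            continue
        s = float(b)
        S += b
        m = masks[i]
        cK = float(_popcount(m & maskK))
        cP = cK
        if 0.0 < cK < nK:
            SK += b
            piK += s * cK * (nK - cK) * inv_piK
        if two_pop:
            mw = m >> np.uint64(nK)
            cW = float(_popcount(mw))
            cP = cK + cW
            if 0.0 < cW < nW:
                SW += b
                piW += s * cW * (nW - cW) * inv_piW
            pk = cK * inv_nK
            pw = cW * inv_nW
            dxy += s * (pk + pw - 2.0 * pk * pw)
            if (cK == nK and cW == 0.0) or (cK == 0.0 and cW == nW):
                df += s
            # Weir-Cockerham (1984) variance components, diploid, two pops
            hetK = float(_popcount((m ^ (m >> np.uint64(1))) & evenK))
            hetA = float(_popcount((m ^ (m >> np.uint64(1))) & evenAll))
            hetW = hetA - hetK
            h1 = hetK * inv_ndK
            h2 = hetW * inv_ndW
            pbar = (n1 * pk + n2 * pw) * inv_2nbar
            s2 = (n1 * (pk - pbar) ** 2 + n2 * (pw - pbar) ** 2) * inv_nbar
            hbar = (n1 * h1 + n2 * h2) * inv_2nbar
            pq = pbar * (1.0 - pbar)
            inner = pq - 0.5 * s2 - 0.25 * hbar
            a = nbar_over_nc * (s2 - inner * inv_nbar1)
            bb = nbar_ratio * (pq - 0.5 * s2 - hbar * h_coef)
            cc = 0.5 * hbar
            fnum += s * a
            fden += s * (a + bb + cc)
            homA = float(_popcount(m & (m >> np.uint64(1)) & evenAll))
        else:
            hetA = float(_popcount((m ^ (m >> np.uint64(1))) & evenAll))
            homA = float(_popcount(m & (m >> np.uint64(1)) & evenAll))
        piP += s * cP * (n - cP) * inv_piP
        # dosage summaries for r^2
        act[nact] = i
        cs[nact] = cP
        sq[nact] = hetA + 4.0 * homA
        tot += b
        cum[nact] = tot
        bs[nact] = b
        nact += 1

    out[STAT_PI_K] = piK / L
    out[STAT_PI_W] = piW / L if two_pop else np.nan
    out[STAT_D_K] = _tajima_d(piK, SK, nK)
    out[STAT_D_W] = _tajima_d(piW, SW, nW) if two_pop else np.nan
    out[STAT_D_POOL] = _tajima_d(piP, S, n)
    out[STAT_FST] = fnum / fden if fden != 0.0 else np.nan
    out[STAT_DXY] = dxy / L if two_pop else np.nan
    out[STAT_DF] = df if two_pop else np.nan
    out[STAT_S] = S

    # mean pairwise dosage r^2 within the locus
    if S < 2:
        out[STAT_R2] = np.nan
        return
    npairs_total = S * (S - 1) // 2
    r2_sum = 0.0
    r2_n = 0.0
    fnd = float(nd)
    if npairs_total <= r2_exact_cap:
        for ii in range(nact):
            si = float(bs[ii])
            if si > 1.0:
                r2_sum += si * (si - 1.0) / 2.0
                r2_n += si * (si - 1.0) / 2.0
            for jj in range(ii + 1, nact):
                sj = float(bs[jj])
                r2 = _pair_r2(cs[ii], sq[ii], masks[act[ii]],
                              cs[jj], sq[jj], masks[act[jj]], fnd)
                if r2 >= 0.0:
                    r2_sum += si * sj * r2
                    r2_n += si * sj
    else:
        drawn = 0
        attempts = 0
        while drawn < r2_sample_pairs and attempts < 20 * r2_sample_pairs:
            attempts += 1
            u = _xs_randint(state, S)
            v = _xs_randint(state, S)
            if u == v:
                continue
            # locate branches by binary search on cumulative counts
            lo = 0
            hi = nact - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if cum[mid] > u:
                    hi = mid
                else:
                    lo = mid + 1
            bi = lo
            lo = 0
            hi = nact - 1
            while lo < hi:
                mid = (lo + hi) // 2
                if cum[mid] > v:
                    hi = mid
                else:
                    lo = mid + 1
            bj = lo
            drawn += 1
            if bi == bj:
                r2_sum += 1.0
                r2_n += 1.0
            else:
                r2 = _pair_r2(cs[bi], sq[bi], masks[act[bi]],
                              cs[bj], sq[bj], masks[act[bj]], fnd)
                if r2 >= 0.0:
                    r2_sum += r2
                    r2_n += 1.0
    out[STAT_R2] = r2_sum / r2_n if r2_n > 0.0 else np.nan


@njit(cache=True)
def simulate_stats_batch(timelines, nK, nW, theta, L, n_loci, seeds,
                         r2_exact_cap, r2_sample_pairs):
    """Simulate ``n_loci`` independent loci per timeline; return per-locus stats.

    ``seeds`` has shape (n_sims, n_loci): one stream per locus so locus j of
    simulation i is reproducible independently of the others.
    """
    n_sims = timelines.shape[0]
    n = nK + nW
    nnode = 2 * n - 1
    out = np.full((n_sims, n_loci, N_STATS), np.nan)
    parent = np.empty(nnode, dtype=np.int32)
    node_time = np.empty(nnode, dtype=np.float64)
    masks = np.empty(nnode, dtype=np.uint64)
    bs = np.empty(nnode, dtype=np.int64)
    act = np.empty(nnode, dtype=np.int64)
    cs = np.empty(nnode, dtype=np.float64)
    sq = np.empty(nnode, dtype=np.float64)
    cum = np.empty(nnode, dtype=np.int64)
    state = np.empty(2, dtype=np.uint64)
    for i in range(n_sims):
        for j in range(n_loci):
            _xs_seed(state, seeds[i, j])
            status = _sim_tree(timelines[i], nK, nW, parent, node_time, masks,
                               state)
            if status != 0:
                continue
            _locus_stats(parent, node_time, masks, nK, nW, theta, L,
                         r2_exact_cap, r2_sample_pairs, bs, act, cs, sq, cum,
                         state, out[i, j])
    return out


@njit(cache=True)
def simulate_tree(timeline, nK, nW, seed):
    """Simulate a single genealogy; returns (parent, node_time, masks, status)."""
    n = nK + nW
    parent = np.empty(2 * n - 1, dtype=np.int32)
    node_time = np.empty(2 * n - 1, dtype=np.float64)
    masks = np.empty(2 * n - 1, dtype=np.uint64)
    np.random.seed(seed)
    state = np.empty(2, dtype=np.uint64)
    _xs_seed(state, seed)
    status = _sim_tree(timeline, nK, nW, parent, node_time, masks, state)
    return parent, node_time, masks, status
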