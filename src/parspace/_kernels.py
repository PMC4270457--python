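"""Numba-compiled Gillespie loops for the two lattice simulators.

Both kernels realise the direct-method SSA with per-category propensity
sums maintained incrementally.  Site-weighted selections (which mobile
molecule hops, which polymeric subunit depolymerizes) go through Fenwick
(binary-indexed) trees over long-axis columns, giving O(log n) selection.
Reflecting boundaries, hard walls and leak hops are realised as null
events / thinning, which leaves the sampled Markov process exact
(uniformization: adding self-loops does not change the law).

These functions are internal; use :mod:`parspace.immobilization` and
:mod:`parspace.directed` for the documented surfaces.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------- Fenwick


@njit(cache=True)
def _fw_build(counts, tree):
    tree[:] = 0
    for i in range(len(counts)):
        if counts[i]:
            _fw_update(tree, i, counts[i])


@njit(cache=True)
def _fw_update(tree, i, delta):
    i += 1
    n = len(tree) - 1
    while i <= n:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fw_sample(tree, r):
    """Return the smallest 0-based index whose cumulative count exceeds r."""
    pos = 0
    n = len(tree) - 1
    pw = 1
    while (pw << 1) <= n:
        pw <<= 1
    rem = r
    while pw:
        nxt = pos + pw
        if nxt <= n and tree[nxt] <= rem:
            rem -= tree[nxt]
            pos = nxt
        pw >>= 1
    return pos  # 0-based


# ------------------------------------------------- diffusion/immobilization


@njit(cache=True)
def di_run(
    seed,
    dx,
    h_A,          # D_A/dx^2, per molecule per direction
    h_P,          # D_P/dx^2, per plasmid per direction (when mobile)
    k_on,
    k_AB,
    k_B,
    k_W,
    k_off,
    max_bound,
    immobilize_threshold,
    A0,           # int64[max_cols] initial mobile counts (first n_cols used)
    n_cols0,
    plas_site0,   # int64[n_p0]
    plas_bound0,  # int64[n_p0]
    A_ADP0,
    A_CYTO0,
    T,
    out_dt,
    growth_interval,   # <=0: no growth
    dup_times,         # float64[:], sorted
    density,           # dimers per µm maintained at growth; <=0: fixed count
):
    max_cols = len(A0)
    max_p = len(plas_site0) + len(dup_times)
    np.random.seed(seed)

    A = A0.copy()
    n_cols = n_cols0
    tree = np.zeros(max_cols + 1, dtype=np.int64)
    _fw_build(A[:n_cols], tree)
    n_mob = np.int64(A[:n_cols].sum())

    plas_site = np.zeros(max_p, dtype=np.int64)
    plas_bound = np.zeros(max_p, dtype=np.int64)
    n_p = len(plas_site0)
    plas_site[:n_p] = plas_site0
    plas_bound[:n_p] = plas_bound0
    a_adp = np.int64(A_ADP0)
    a_cyto = np.int64(A_CYTO0)

    n_out = int(T / out_dt) + 2
    out_t = np.zeros(n_out)
    out_sites = np.full((n_out, max_p), -1, dtype=np.int64)
    out_bound = np.zeros((n_out, max_p), dtype=np.int64)
    out_np = np.zeros(n_out, dtype=np.int64)
    out_kymo = np.zeros((n_out, max_cols), dtype=np.int32)
    out_adp = np.zeros(n_out, dtype=np.int64)
    out_cyto = np.zeros(n_out, dtype=np.int64)
    out_ncols = np.zeros(n_out, dtype=np.int64)
    i_out = 0

    t = 0.0
    next_out = 0.0
    next_growth = growth_interval if growth_interval > 0 else 2 * T + 1.0
    i_dup = 0
    status = 0  # 0 ok; 1 bound-count invariant breach

    while True:
        # scheduled horizon
        t_sched = next_out
        if next_growth < t_sched:
            t_sched = next_growth
        if i_dup < len(dup_times) and dup_times[i_dup] < t_sched:
            t_sched = dup_times[i_dup]
        if T < t_sched:
            t_sched = T

        # propensities (small categories recomputed each step)
        a1 = 2.0 * h_A * n_mob
        a2 = 2.0 * h_P * n_p
        a3 = 0.0
        a4 = 0.0
        for p in range(n_p):
            if plas_bound[p] < max_bound:
                a3 += k_AB * A[plas_site[p]]
            a4 += k_B * plas_bound[p]
        a5 = k_W * a_adp
        a6 = k_on * a_cyto
        a7 = k_off * n_mob
        a_tot = a1 + a2 + a3 + a4 + a5 + a6 + a7

        if a_tot > 0.0:
            dt = -np.log(np.random.random()) / a_tot
        else:
            dt = 2.0 * (t_sched - t) + 1.0

        if t + dt >= t_sched:
            t = t_sched
            if t_sched == next_out:
                out_t[i_out] = t
                out_np[i_out] = n_p
                for p in range(n_p):
                    out_sites[i_out, p] = plas_site[p]
                    out_bound[i_out, p] = plas_bound[p]
                for i in range(n_cols):
                    out_kymo[i_out, i] = A[i]
                out_adp[i_out] = a_adp
                out_cyto[i_out] = a_cyto
                out_ncols[i_out] = n_cols
                i_out += 1
                next_out += out_dt
                if t >= T:
                    break
            elif t_sched == T:
                break
            elif t_sched == next_growth:
                if n_cols + 2 <= max_cols:
                    pos = np.random.randint(0, n_cols + 1)
                    for i in range(n_cols - 1, pos - 1, -1):
                        A[i + 2] = A[i]
                    A[pos] = 0
                    A[pos + 1] = 0
                    n_cols += 2
                    for p in range(n_p):
                        if plas_site[p] >= pos:
                            plas_site[p] += 2
                    _fw_build(A[:n_cols], tree)
                    if density > 0:
                        target = np.int64(round(density * n_cols * dx))
                        total = (
                            np.int64(A[:n_cols].sum())
                            + np.int64(plas_bound[:n_p].sum())
                            + a_adp
                            + a_cyto
                        )
                        if target > total:
                            a_adp += target - total
                next_growth += growth_interval
            else:  # duplication
                k = np.random.randint(0, n_p)
                plas_site[n_p] = plas_site[k]
                plas_bound[n_p] = 0
                n_p += 1
                i_dup += 1
            continue

        t += dt
        r = np.random.random() * a_tot
        if r < a1:
            # mobile ParA-ATP hop
            i = _fw_sample(tree, np.random.randint(0, n_mob))
            j = i + 1 if np.random.random() < 0.5 else i - 1
            if 0 <= j < n_cols:
                A[i] -= 1
                A[j] += 1
                _fw_update(tree, i, -1)
                _fw_update(tree, j, 1)
            # else: reflecting boundary, null event
        elif r < a1 + a2:
            p = np.random.randint(0, n_p)
            if plas_bound[p] < immobilize_threshold:
                j = plas_site[p] + (1 if np.random.random() < 0.5 else -1)
                if 0 <= j < n_cols:
                    plas_site[p] = j
        elif r < a1 + a2 + a3:
            rr = (r - a1 - a2) / k_AB
            acc = 0.0
            for p in range(n_p):
                if plas_bound[p] < max_bound:
                    acc += A[plas_site[p]]
                    if rr < acc:
                        A[plas_site[p]] -= 1
                        _fw_update(tree, plas_site[p], -1)
                        n_mob -= 1
                        plas_bound[p] += 1
                        if plas_bound[p] > max_bound:
                            status = 1
                        break
        elif r < a1 + a2 + a3 + a4:
            rr = (r - a1 - a2 - a3) / k_B
            acc = 0.0
            for p in range(n_p):
                acc += plas_bound[p]
                if rr < acc:
                    plas_bound[p] -= 1
                    a_adp += 1
                    break
        elif r < a1 + a2 + a3 + a4 + a5:
            a_adp -= 1
            a_cyto += 1
        elif r < a1 + a2 + a3 + a4 + a5 + a6:
            a_cyto -= 1
            i = np.random.randint(0, n_cols)
            A[i] += 1
            _fw_update(tree, i, 1)
            n_mob += 1
        else:
            # spontaneous hydrolysis of nucleoid-bound mobile ParA-ATP
            i = _fw_sample(tree, np.random.randint(0, n_mob))
            A[i] -= 1
            _fw_update(tree, i, -1)
            n_mob -= 1
            a_adp += 1
        if status != 0:
            break

    return (
        out_t[:i_out],
        out_sites[:i_out],
        out_bound[:i_out],
        out_np[:i_out],
        out_kymo[:i_out],
        out_adp[:i_out],
        out_cyto[:i_out],
        out_ncols[:i_out],
        status,
    )


# ------------------------------------------------------- directed motion


@njit(cache=True)
def _dm_refresh(A, P, nuc_col, elo_col, tot, lo, hi, n_cols, n_short):
    """Recompute per-column polymerization weights on [lo, hi].

    nuc_col[i] = sum_j A[i,j]*A[i+1,j] over rows where both sites are
    polymer-free (nucleation pairs); elo_col[i] = sum_j A[i,j] * (number of
    polymeric long-axis neighbours) over polymer-free sites (elongation).
    tot[0], tot[1] hold the exact integer totals.
    """
    if lo < 0:
        lo = 0
    if hi > n_cols - 1:
        hi = n_cols - 1
    for i in range(lo, hi + 1):
        old_n = nuc_col[i]
        old_e = elo_col[i]
        nn = np.int64(0)
        ee = np.int64(0)
        for j in range(n_short):
            if P[i, j] == 0:
                if i + 1 < n_cols and P[i + 1, j] == 0:
                    nn += A[i, j] * A[i + 1, j]
                nb = np.int64(0)
                if i > 0:
                    nb += P[i - 1, j]
                if i + 1 < n_cols:
                    nb += P[i + 1, j]
                ee += A[i, j] * nb
        nuc_col[i] = nn
        elo_col[i] = ee
        tot[0] += nn - old_n
        tot[1] += ee - old_e


@njit(cache=True)
def _dm_remove_poly(
    A, P, mobile_col, poly_col, treeM, treeP, nuc_col, elo_col, tot,
    counters, i, j, n_cols, n_short,
):
    """Remove the polymeric subunit at (i, j) and reclassify any neighbour
    left as an isolated single subunit into a mobile molecule at its site
    (polymers have >=2 subunits by the nucleation definition).
    counters = [n_mob, n_poly]."""
    P[i, j] = 0
    poly_col[i] -= 1
    _fw_update(treeP, i, -1)
    counters[1] -= 1
    lo = i - 2
    hi = i + 2
    for d in (-1, 1):
        k = i + d
        if 0 <= k < n_cols and P[k, j] == 1:
            left = P[k - 1, j] if k > 0 else np.int64(0)
            right = P[k + 1, j] if k + 1 < n_cols else np.int64(0)
            if left == 0 and right == 0:
                P[k, j] = 0
                poly_col[k] -= 1
                _fw_update(treeP, k, -1)
                counters[1] -= 1
                A[k, j] += 1
                mobile_col[k] += 1
                _fw_update(treeM, k, 1)
                counters[0] += 1
                if k - 2 < lo:
                    lo = k - 2
                if k + 2 > hi:
                    hi = k + 2
    _dm_refresh(A, P, nuc_col, elo_col, tot, lo, hi, n_cols, n_short)


@njit(cache=True)
def dm_run(
    seed,
    dx,
    h_A,          # D_A/dx^2 per molecule per direction
    h_P,          # D_P/dx^2 per plasmid per direction
    k_on,
    k_B,          # polymeric-at-plasmid hydrolysis
    k_mB,         # mobile-at-plasmid hydrolysis
    k_W,
    k_dm,         # directed step per adjacent-column polymeric subunit
    k_p,
    k_dp,
    leak,         # probability factor for mobile hops into a plasmid column
                  # (0 = hard wall, wild type)
    A0,           # int64[max_cols, n_short] initial mobile counts
    n_cols0,
    plas_col0,    # int64[n_p0]
    A_ADP0,
    A_CYTO0,
    T,
    out_dt,
    growth_interval,
    dup_times,
    density,
):
    max_cols, n_short = A0.shape
    max_p = len(plas_col0) + len(dup_times)
    np.random.seed(seed)

    A = A0.copy()
    P = np.zeros((max_cols, n_short), dtype=np.int64)
    n_cols = n_cols0
    mobile_col = np.zeros(max_cols, dtype=np.int64)
    poly_col = np.zeros(max_cols, dtype=np.int64)
    for i in range(n_cols):
        for j in range(n_short):
            mobile_col[i] += A[i, j]
    treeM = np.zeros(max_cols + 1, dtype=np.int64)
    treeP = np.zeros(max_cols + 1, dtype=np.int64)
    _fw_build(mobile_col[:n_cols], treeM)
    counters = np.zeros(2, dtype=np.int64)  # [n_mob, n_poly]
    counters[0] = mobile_col[:n_cols].sum()

    nuc_col = np.zeros(max_cols, dtype=np.int64)
    elo_col = np.zeros(max_cols, dtype=np.int64)
    tot = np.zeros(2, dtype=np.int64)  # [nuc_tot, elo_tot]
    _dm_refresh(A, P, nuc_col, elo_col, tot, 0, n_cols - 1, n_cols, n_short)

    plas_col = np.zeros(max_p, dtype=np.int64)
    n_p = len(plas_col0)
    plas_col[:n_p] = plas_col0
    plas_in_col = np.zeros(max_cols, dtype=np.int64)
    for p in range(n_p):
        plas_in_col[plas_col[p]] += 1
    a_adp = np.int64(A_ADP0)
    a_cyto = np.int64(A_CYTO0)

    n_dir = 4 if n_short > 1 else 2

    n_out = int(T / out_dt) + 2
    out_t = np.zeros(n_out)
    out_cols = np.full((n_out, max_p), -1, dtype=np.int64)
    out_np = np.zeros(n_out, dtype=np.int64)
    out_mob = np.zeros((n_out, max_cols), dtype=np.int32)
    out_pol = np.zeros((n_out, max_cols), dtype=np.int32)
    out_P = np.zeros((n_out, max_cols, n_short), dtype=np.int8)
    out_adp = np.zeros(n_out, dtype=np.int64)
    out_cyto = np.zeros(n_out, dtype=np.int64)
    out_ncols = np.zeros(n_out, dtype=np.int64)
    i_out = 0

    t = 0.0
    next_out = 0.0
    next_growth = growth_interval if growth_interval > 0 else 2 * T + 1.0
    i_dup = 0
    status = 0

    while True:
        t_sched = next_out
        if next_growth < t_sched:
            t_sched = next_growth
        if i_dup < len(dup_times) and dup_times[i_dup] < t_sched:
            t_sched = dup_times[i_dup]
        if T < t_sched:
            t_sched = T

        a_hop = n_dir * h_A * counters[0]
        a_ph = 2.0 * h_P * n_p
        a_on = k_on * a_cyto
        a_w = k_W * a_adp
        a_dp = k_dp * counters[1]
        a_nuc = k_p * tot[0]
        a_elo = k_p * tot[1]
        a_kb = 0.0
        a_kmb = 0.0
        a_dm = 0.0
        for p in range(n_p):
            c = plas_col[p]
            a_kb += poly_col[c]
            # ParB-parC reaches mobile ParA-ATP in the plasmid's column and
            # the two adjacent columns (same contact neighbourhood as k_dm)
            a_kmb += mobile_col[c]
            if c > 0:
                a_dm += poly_col[c - 1]
                a_kmb += mobile_col[c - 1]
            if c + 1 < n_cols:
                a_dm += poly_col[c + 1]
                a_kmb += mobile_col[c + 1]
        a_kb *= k_B
        a_kmb *= k_mB
        a_dm *= k_dm
        a_tot = a_hop + a_ph + a_on + a_w + a_dp + a_nuc + a_elo + a_kb + a_kmb + a_dm

        if a_tot > 0.0:
            dt = -np.log(np.random.random()) / a_tot
        else:
            dt = 2.0 * (t_sched - t) + 1.0

        if t + dt >= t_sched:
            t = t_sched
            if t_sched == next_out:
                out_t[i_out] = t
                out_np[i_out] = n_p
                for p in range(n_p):
                    out_cols[i_out, p] = plas_col[p]
                for i in range(n_cols):
                    out_mob[i_out, i] = mobile_col[i]
                    out_pol[i_out, i] = poly_col[i]
                    for j in range(n_short):
                        out_P[i_out, i, j] = P[i, j]
                out_adp[i_out] = a_adp
                out_cyto[i_out] = a_cyto
                out_ncols[i_out] = n_cols
                i_out += 1
                next_out += out_dt
                if t >= T:
                    break
            elif t_sched == T:
                break
            elif t_sched == next_growth:
                if n_cols + 2 <= max_cols:
                    pos = np.random.randint(0, n_cols + 1)
                    for i in range(n_cols - 1, pos - 1, -1):
                        for j in range(n_short):
                            A[i + 2, j] = A[i, j]
                            P[i + 2, j] = P[i, j]
                        mobile_col[i + 2] = mobile_col[i]
                        poly_col[i + 2] = poly_col[i]
                        plas_in_col[i + 2] = plas_in_col[i]
                    for i in range(pos, pos + 2):
                        for j in range(n_short):
                            A[i, j] = 0
                            P[i, j] = 0
                        mobile_col[i] = 0
                        poly_col[i] = 0
                        plas_in_col[i] = 0
                    n_cols += 2
                    for p in range(n_p):
                        if plas_col[p] >= pos:
                            plas_col[p] += 2
                    _fw_build(mobile_col[:n_cols], treeM)
                    _fw_build(poly_col[:n_cols], treeP)
                    tot[0] = 0
                    tot[1] = 0
                    nuc_col[:] = 0
                    elo_col[:] = 0
                    _dm_refresh(A, P, nuc_col, elo_col, tot, 0, n_cols - 1,
                                n_cols, n_short)
                    if density > 0:
                        target = np.int64(round(density * n_cols * dx))
                        total = counters[0] + counters[1] + a_adp + a_cyto
                        if target > total:
                            a_adp += target - total
                next_growth += growth_interval
            else:
                k = np.random.randint(0, n_p)
                plas_col[n_p] = plas_col[k]
                plas_in_col[plas_col[k]] += 1
                n_p += 1
                i_dup += 1
            continue

        t += dt
        r = np.random.random() * a_tot
        if r < a_hop:
            # mobile ParA-ATP hop (4-neighbour; walls/boundaries -> null)
            i = _fw_sample(treeM, np.random.randint(0, counters[0]))
            rr = np.random.randint(0, mobile_col[i])
            j = 0
            acc = A[i, 0]
            while acc <= rr:
                j += 1
                acc += A[i, j]
            d = np.random.randint(0, n_dir)
            ti = i
            tj = j
            if d == 0:
                ti = i - 1
            elif d == 1:
                ti = i + 1
            elif d == 2:
                tj = j - 1
            else:
                tj = j + 1
            ok = 0 <= ti < n_cols and 0 <= tj < n_short
            if ok and ti != i and plas_in_col[ti] > 0:
                # hopping into a plasmid column: hard wall (leak=0) or leak
                if leak <= 0.0 or np.random.random() >= leak:
                    ok = False
            if ok:
                A[i, j] -= 1
                A[ti, tj] += 1
                if ti != i:
                    mobile_col[i] -= 1
                    mobile_col[ti] += 1
                    _fw_update(treeM, i, -1)
                    _fw_update(treeM, ti, 1)
                lo = (i if i < ti else ti) - 1
                hi = (i if i > ti else ti) + 1
                _dm_refresh(A, P, nuc_col, elo_col, tot, lo, hi, n_cols, n_short)
        elif r < a_hop + a_ph:
            p = np.random.randint(0, n_p)
            c = plas_col[p]
            blocked = poly_col[c] > 0
            if not blocked and c > 0:
                blocked = poly_col[c - 1] > 0
            if not blocked and c + 1 < n_cols:
                blocked = poly_col[c + 1] > 0
            if not blocked:
                tc = c + (1 if np.random.random() < 0.5 else -1)
                if 0 <= tc < n_cols:
                    plas_in_col[c] -= 1
                    plas_in_col[tc] += 1
                    plas_col[p] = tc
        elif r < a_hop + a_ph + a_on:
            a_cyto -= 1
            i = np.random.randint(0, n_cols)
            j = np.random.randint(0, n_short)
            A[i, j] += 1
            mobile_col[i] += 1
            _fw_update(treeM, i, 1)
            counters[0] += 1
            _dm_refresh(A, P, nuc_col, elo_col, tot, i - 1, i + 1, n_cols, n_short)
        elif r < a_hop + a_ph + a_on + a_w:
            a_adp -= 1
            a_cyto += 1
        elif r < a_hop + a_ph + a_on + a_w + a_dp:
            # spontaneous depolymerization -> mobile at the same site
            i = _fw_sample(treeP, np.random.randint(0, counters[1]))
            rr = np.random.randint(0, poly_col[i])
            j = 0
            acc = P[i, 0]
            while acc <= rr:
                j += 1
                acc += P[i, j]
            A[i, j] += 1
            mobile_col[i] += 1
            _fw_update(treeM, i, 1)
            counters[0] += 1
            _dm_remove_poly(A, P, mobile_col, poly_col, treeM, treeP,
                            nuc_col, elo_col, tot, counters, i, j,
                            n_cols, n_short)
        elif r < a_hop + a_ph + a_on + a_w + a_dp + a_nuc:
            rr = np.random.randint(0, tot[0])
            i = 0
            acc = nuc_col[0]
            while acc <= rr:
                i += 1
                acc += nuc_col[i]
            rr2 = np.random.randint(0, nuc_col[i])
            j = -1
            acc2 = np.int64(0)
            for jj in range(n_short):
                if P[i, jj] == 0 and P[i + 1, jj] == 0:
                    acc2 += A[i, jj] * A[i + 1, jj]
                    if acc2 > rr2:
                        j = jj
                        break
            A[i, j] -= 1
            A[i + 1, j] -= 1
            P[i, j] = 1
            P[i + 1, j] = 1
            mobile_col[i] -= 1
            mobile_col[i + 1] -= 1
            poly_col[i] += 1
            poly_col[i + 1] += 1
            _fw_update(treeM, i, -1)
            _fw_update(treeM, i + 1, -1)
            _fw_update(treeP, i, 1)
            _fw_update(treeP, i + 1, 1)
            counters[0] -= 2
            counters[1] += 2
            _dm_refresh(A, P, nuc_col, elo_col, tot, i - 2, i + 3, n_cols, n_short)
        elif r < a_hop + a_ph + a_on + a_w + a_dp + a_nuc + a_elo:
            rr = np.random.randint(0, tot[1])
            i = 0
            acc = elo_col[0]
            while acc <= rr:
                i += 1
                acc += elo_col[i]
            rr2 = np.random.randint(0, elo_col[i])
            j = -1
            acc2 = np.int64(0)
            for jj in range(n_short):
                if P[i, jj] == 0:
                    nb = np.int64(0)
                    if i > 0:
                        nb += P[i - 1, jj]
                    if i + 1 < n_cols:
                        nb += P[i + 1, jj]
                    acc2 += A[i, jj] * nb
                    if acc2 > rr2:
                        j = jj
                        break
            A[i, j] -= 1
            P[i, j] = 1
            mobile_col[i] -= 1
            poly_col[i] += 1
            _fw_update(treeM, i, -1)
            _fw_update(treeP, i, 1)
            counters[0] -= 1
            counters[1] += 1
            _dm_refresh(A, P, nuc_col, elo_col, tot, i - 2, i + 2, n_cols, n_short)
        elif r < a_hop + a_ph + a_on + a_w + a_dp + a_nuc + a_elo + a_kb:
            rr = (r - (a_hop + a_ph + a_on + a_w + a_dp + a_nuc + a_elo)) / k_B
            acc = 0.0
            c = -1
            for p in range(n_p):
                acc += poly_col[plas_col[p]]
                if rr < acc:
                    c = plas_col[p]
                    break
            rr2 = np.random.randint(0, poly_col[c])
            j = 0
            acc2 = P[c, 0]
            while acc2 <= rr2:
                j += 1
                acc2 += P[c, j]
            a_adp += 1
            _dm_remove_poly(A, P, mobile_col, poly_col, treeM, treeP,
                            nuc_col, elo_col, tot, counters, c, j,
                            n_cols, n_short)
        elif r < a_hop + a_ph + a_on + a_w + a_dp + a_nuc + a_elo + a_kb + a_kmb:
            rr = (r - (a_hop + a_ph + a_on + a_w + a_dp + a_nuc + a_elo + a_kb)) / k_mB
            acc = 0.0
            c = -1
            for p in range(n_p):
                pc = plas_col[p]
                acc += mobile_col[pc]
                if rr < acc:
                    c = pc
                    break
                if pc > 0:
                    acc += mobile_col[pc - 1]
                    if rr < acc:
                        c = pc - 1
                        break
                if pc + 1 < n_cols:
                    acc += mobile_col[pc + 1]
                    if rr < acc:
                        c = pc + 1
                        break
            rr2 = np.random.randint(0, mobile_col[c])
            j = 0
            acc2 = A[c, 0]
            while acc2 <= rr2:
                j += 1
                acc2 += A[c, j]
            A[c, j] -= 1
            mobile_col[c] -= 1
            _fw_update(treeM, c, -1)
            counters[0] -= 1
            a_adp += 1
            _dm_refresh(A, P, nuc_col, elo_col, tot, c - 1, c + 1, n_cols, n_short)
        else:
            # directed step: plasmid moves onto an adjacent polymeric subunit,
            # which is simultaneously hydrolysed to cytoplasmic ParA-ADP
            rr = (r - (a_hop + a_ph + a_on + a_w + a_dp + a_nuc + a_elo
                       + a_kb + a_kmb)) / k_dm
            acc = 0.0
            psel = -1
            tc = -1
            for p in range(n_p):
                c = plas_col[p]
                if c > 0 and poly_col[c - 1] > 0:
                    acc += poly_col[c - 1]
                    if rr < acc:
                        psel = p
                        tc = c - 1
                        break
                if c + 1 < n_cols and poly_col[c + 1] > 0:
                    acc += poly_col[c + 1]
                    if rr < acc:
                        psel = p
                        tc = c + 1
                        break
            if psel >= 0:
                rr2 = np.random.randint(0, poly_col[tc])
                j = 0
                acc2 = P[tc, 0]
                while acc2 <= rr2:
                    j += 1
                    acc2 += P[tc, j]
                plas_in_col[plas_col[psel]] -= 1
                plas_in_col[tc] += 1
                plas_col[psel] = tc
                a_adp += 1
                _dm_remove_poly(A, P, mobile_col, poly_col, treeM, treeP,
                                nuc_col, elo_col, tot, counters, tc, j,
                                n_cols, n_short)
        if status != 0:
            break

    return (
        out_t[:i_out],
        out_cols[:i_out],
        out_np[:i_out],
        out_mob[:i_out],
        out_pol[:i_out],
        out_P[:i_out],
        out_adp[:i_out],
        out_cyto[:i_out],
        out_ncols[:i_out],
        status,
    )
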