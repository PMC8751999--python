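"""Numba kernels for the grand-canonical Monte Carlo engine.

The microstate is held in flat arrays (see :class:`motiflattice.state.
LatticeConfig` for the layout).  Energy bookkeeping is exact: the kernel
tracks two integers, ``Q`` (number of bonded sites) and ``W`` (sum of
``r_i r_j`` over adjacent site pairs), so the total energy ``-Q - J*W``
never accumulates floating-point drift.

Move codes: 0 end, 1 corner, 2 reptation, 3 contraction, 4 expansion,
5 cluster translation, 6 insertion, 7 deletion.
"""

import numpy as np
from numba import njit

LOG13 = np.log(13.0)

# scal layout
N_POLY, QTOT, WTOT = 0, 1, 2


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _can_add(site, t, site_n, site_na):
    if site_n[site] >= 2:
        return False
    if t == 0:
        return site_na[site] == 0
    return site_n[site] - site_na[site] == 0


@njit(cache=True, inline="always")
def _add(site, p, m, t, site_n, site_na, occ_p, occ_m, nbrt, scal):
    w = 0
    for j in range(12):
        w += site_n[nbrt[site, j]]
    scal[WTOT] += w
    slot = site_n[site]
    occ_p[site, slot] = p
    occ_m[site, slot] = m
    site_n[site] += 1
    if t == 0:
        site_na[site] += 1
    if site_n[site] == 2:
        scal[QTOT] += 1


@njit(cache=True, inline="always")
def _remove(site, p, m, t, site_n, site_na, occ_p, occ_m, nbrt, scal):
    if site_n[site] == 2:
        scal[QTOT] -= 1
    if occ_p[site, 0] == p and occ_m[site, 0] == m:
        occ_p[site, 0] = occ_p[site, 1]
        occ_m[site, 0] = occ_m[site, 1]
    occ_p[site, 1] = -1
    occ_m[site, 1] = -1
    site_n[site] -= 1
    if t == 0:
        site_na[site] -= 1
    w = 0
    for j in range(12):
        w += site_n[nbrt[site, j]]
    scal[WTOT] -= w


@njit(cache=True, inline="always")
def _is_adjacent(nbrt, s1, s2):
    for j in range(12):
        if nbrt[s1, j] == s2:
            return True
    return False


@njit(cache=True)
def _metropolis_dn0(dQ, dW, beta, J):
    dH = -float(dQ) - J * float(dW)
    if dH <= 0.0:
        return True
    return np.random.random() < np.exp(-beta * dH)


@njit(cache=True)
def run_steps(pos, types, nbrt, dims, site_n, site_na, occ_p, occ_m, scal,
              beta, mu, J, h_tab, move_cum, n_steps, sample_every,
              pn, hist2d, e_min, e_bin,
              traj_every, traj, traj_len,
              acc, in_cluster, stack, new_sites, old_sites,
              s_work, t_work, cluster_cap):
    """Advance the chain by ``n_steps`` elementary proposals."""
    L = types.shape[0]
    V = site_n.shape[0]
    n_max = pos.shape[0]
    n_ebins = hist2d.shape[1]
    cands = np.empty(13, dtype=np.int64)

    for step in range(n_steps):
        u01 = np.random.random()
        mv = 0
        while move_cum[mv] < u01:
            mv += 1
        acc[mv, 0] += 1
        n = scal[N_POLY]
        accepted = False

        # ---------------- end move ----------------
        if mv == 0:
            if n > 0:
                p = np.random.randint(0, n)
                if L == 1:
                    # single-monomer chains: relocate to a neighbor site
                    u = pos[p, 0]
                    v = nbrt[u, np.random.randint(0, 12)]
                    t = types[0]
                    q0, w0 = scal[QTOT], scal[WTOT]
                    _remove(u, p, 0, t, site_n, site_na, occ_p, occ_m, nbrt,
                            scal)
                    if _can_add(v, t, site_n, site_na):
                        _add(v, p, 0, t, site_n, site_na, occ_p, occ_m, nbrt,
                             scal)
                        pos[p, 0] = v
                        if _metropolis_dn0(scal[QTOT] - q0, scal[WTOT] - w0,
                                           beta, J):
                            accepted = True
                        else:
                            _remove(v, p, 0, t, site_n, site_na, occ_p, occ_m,
                                    nbrt, scal)
                            _add(u, p, 0, t, site_n, site_na, occ_p, occ_m,
                                 nbrt, scal)
                            pos[p, 0] = u
                    else:
                        _add(u, p, 0, t, site_n, site_na, occ_p, occ_m, nbrt,
                             scal)
                else:
                    e = 0 if np.random.random() < 0.5 else L - 1
                    anchor = 1 if e == 0 else L - 2
                    u = pos[p, e]
                    ua = pos[p, anchor]
                    if u != ua:
                        v = nbrt[ua, np.random.randint(0, 12)]
                        if v != u:
                            t = types[e]
                            q0, w0 = scal[QTOT], scal[WTOT]
                            _remove(u, p, e, t, site_n, site_na, occ_p, occ_m,
                                    nbrt, scal)
                            if _can_add(v, t, site_n, site_na):
                                _add(v, p, e, t, site_n, site_na, occ_p, occ_m,
                                     nbrt, scal)
                                pos[p, e] = v
                                if _metropolis_dn0(scal[QTOT] - q0,
                                                   scal[WTOT] - w0, beta, J):
                                    accepted = True
                                else:
                                    _remove(v, p, e, t, site_n, site_na, occ_p,
                                            occ_m, nbrt, scal)
                                    _add(u, p, e, t, site_n, site_na, occ_p,
                                         occ_m, nbrt, scal)
                                    pos[p, e] = u
                            else:
                                _add(u, p, e, t, site_n, site_na, occ_p, occ_m,
                                     nbrt, scal)

        # ---------------- corner move ----------------
        elif mv == 1:
            if n > 0 and L >= 3:
                p = np.random.randint(0, n)
                k = 1 + np.random.randint(0, L - 2)
                u = pos[p, k]
                u0 = pos[p, k - 1]
                u1 = pos[p, k + 1]
                if u != u0 and u != u1:
                    nc = 0
                    for j in range(12):
                        w = nbrt[u0, j]
                        if w == u or w == u1:
                            continue
                        if u0 == u1 or _is_adjacent(nbrt, w, u1):
                            cands[nc] = w
                            nc += 1
                    if nc > 0:
                        v = cands[np.random.randint(0, nc)]
                        t = types[k]
                        q0, w0 = scal[QTOT], scal[WTOT]
                        _remove(u, p, k, t, site_n, site_na, occ_p, occ_m,
                                nbrt, scal)
                        if _can_add(v, t, site_n, site_na):
                            _add(v, p, k, t, site_n, site_na, occ_p, occ_m,
                                 nbrt, scal)
                            pos[p, k] = v
                            if _metropolis_dn0(scal[QTOT] - q0,
                                               scal[WTOT] - w0, beta, J):
                                accepted = True
                            else:
                                _remove(v, p, k, t, site_n, site_na, occ_p,
                                        occ_m, nbrt, scal)
                                _add(u, p, k, t, site_n, site_na, occ_p,
                                     occ_m, nbrt, scal)
                                pos[p, k] = u
                        else:
                            _add(u, p, k, t, site_n, site_na, occ_p, occ_m,
                                 nbrt, scal)

        # ---------------- reptation ----------------
        elif mv == 2:
            if n > 0 and L >= 2:
                p = np.random.randint(0, n)
                toward_head = np.random.random() < 0.5
                lead = 0 if toward_head else L - 1
                choice = np.random.randint(0, 13)
                ulead = pos[p, lead]
                tgt = nbrt[ulead, choice] if choice < 12 else ulead
                if toward_head:
                    new_sites[0] = tgt
                    for k in range(1, L):
                        new_sites[k] = pos[p, k - 1]
                else:
                    new_sites[L - 1] = tgt
                    for k in range(L - 1):
                        new_sites[k] = pos[p, k + 1]
                # contiguity of the new leading pair: tgt is adjacent or equal
                # to the old lead site by construction; same-site requires
                # complementary types
                ok = True
                if choice == 12:
                    second = 1 if toward_head else L - 2
                    if types[lead] == types[second]:
                        ok = False
                if ok:
                    q0, w0 = scal[QTOT], scal[WTOT]
                    for k in range(L):
                        old_sites[k] = pos[p, k]
                        _remove(old_sites[k], p, k, types[k], site_n, site_na,
                                occ_p, occ_m, nbrt, scal)
                    placed = 0
                    for k in range(L):
                        if _can_add(new_sites[k], types[k], site_n, site_na):
                            _add(new_sites[k], p, k, types[k], site_n, site_na,
                                 occ_p, occ_m, nbrt, scal)
                            placed += 1
                        else:
                            break
                    if placed == L:
                        if _metropolis_dn0(scal[QTOT] - q0, scal[WTOT] - w0,
                                           beta, J):
                            for k in range(L):
                                pos[p, k] = new_sites[k]
                            accepted = True
                        else:
                            for k in range(L):
                                _remove(new_sites[k], p, k, types[k], site_n,
                                        site_na, occ_p, occ_m, nbrt, scal)
                            for k in range(L):
                                _add(old_sites[k], p, k, types[k], site_n,
                                     site_na, occ_p, occ_m, nbrt, scal)
                    else:
                        for k in range(placed - 1, -1, -1):
                            _remove(new_sites[k], p, k, types[k], site_n,
                                    site_na, occ_p, occ_m, nbrt, scal)
                        for k in range(L):
                            _add(old_sites[k], p, k, types[k], site_n,
                                 site_na, occ_p, occ_m, nbrt, scal)

        # ---------------- contraction ----------------
        elif mv == 3:
            if n > 0 and L >= 2:
                p = np.random.randint(0, n)
                k = np.random.randint(0, L - 1)
                d = np.random.randint(0, 2)
                mover = k + 1 if d == 0 else k
                stay = k if d == 0 else k + 1
                u_stay = pos[p, stay]
                u_m = pos[p, mover]
                if u_m != u_stay and types[k] != types[k + 1]:
                    other = mover + 1 if mover > stay else mover - 1
                    chain_ok = True
                    if 0 <= other < L:
                        uo = pos[p, other]
                        if uo != u_stay and not _is_adjacent(nbrt, uo, u_stay):
                            chain_ok = False
                    if chain_ok:
                        t = types[mover]
                        q0, w0 = scal[QTOT], scal[WTOT]
                        _remove(u_m, p, mover, t, site_n, site_na, occ_p,
                                occ_m, nbrt, scal)
                        if _can_add(u_stay, t, site_n, site_na):
                            _add(u_stay, p, mover, t, site_n, site_na, occ_p,
                                 occ_m, nbrt, scal)
                            pos[p, mover] = u_stay
                            if _metropolis_dn0(scal[QTOT] - q0,
                                               scal[WTOT] - w0, beta, J):
                                accepted = True
                            else:
                                _remove(u_stay, p, mover, t, site_n, site_na,
                                        occ_p, occ_m, nbrt, scal)
                                _add(u_m, p, mover, t, site_n, site_na, occ_p,
                                     occ_m, nbrt, scal)
                                pos[p, mover] = u_m
                        else:
                            _add(u_m, p, mover, t, site_n, site_na, occ_p,
                                 occ_m, nbrt, scal)

        # ---------------- expansion ----------------
        elif mv == 4:
            if n > 0 and L >= 2:
                p = np.random.randint(0, n)
                k = np.random.randint(0, L - 1)
                d = np.random.randint(0, 2)
                mover = k if d == 0 else k + 1
                u = pos[p, k]
                if pos[p, k + 1] == u:
                    v = nbrt[u, np.random.randint(0, 12)]
                    other = k - 1 if mover == k else k + 2
                    chain_ok = True
                    if 0 <= other < L:
                        uo = pos[p, other]
                        if uo != v and not _is_adjacent(nbrt, uo, v):
                            chain_ok = False
                    if chain_ok:
                        t = types[mover]
                        q0, w0 = scal[QTOT], scal[WTOT]
                        _remove(u, p, mover, t, site_n, site_na, occ_p, occ_m,
                                nbrt, scal)
                        if _can_add(v, t, site_n, site_na):
                            _add(v, p, mover, t, site_n, site_na, occ_p,
                                 occ_m, nbrt, scal)
                            pos[p, mover] = v
                            if _metropolis_dn0(scal[QTOT] - q0,
                                               scal[WTOT] - w0, beta, J):
                                accepted = True
                            else:
                                _remove(v, p, mover, t, site_n, site_na,
                                        occ_p, occ_m, nbrt, scal)
                                _add(u, p, mover, t, site_n, site_na, occ_p,
                                     occ_m, nbrt, scal)
                                pos[p, mover] = u
                        else:
                            _add(u, p, mover, t, site_n, site_na, occ_p,
                                 occ_m, nbrt, scal)

        # ---------------- cluster translation ----------------
        elif mv == 5:
            if n > 0:
                p0 = np.random.randint(0, n)
                direction = np.random.randint(0, 12)
                for i in range(n):
                    in_cluster[i] = False
                nstack = 0
                stack[nstack] = p0
                nstack += 1
                in_cluster[p0] = True
                csize = 0
                nseen = 1
                while nstack > 0 and nseen <= cluster_cap:
                    nstack -= 1
                    pc = stack[nstack]
                    csize += 1
                    for k in range(L):
                        v = pos[pc, k]
                        if site_n[v] == 2:
                            for slot in range(2):
                                q = occ_p[v, slot]
                                if q != pc and not in_cluster[q]:
                                    in_cluster[q] = True
                                    stack[nstack] = q
                                    nstack += 1
                                    nseen += 1
                if nstack > 0:
                    csize = cluster_cap + 1
                # oversized clusters are rejected outright (symmetric in both
                # directions, so detailed balance is unaffected); validity
                # otherwise requires every shifted site to hold no external
                # monomer
                ok = csize <= cluster_cap
                for i in range(n):
                    if not in_cluster[i]:
                        continue
                    for k in range(L):
                        v = nbrt[pos[i, k], direction]
                        for slot in range(site_n[v]):
                            if not in_cluster[occ_p[v, slot]]:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if ok:
                    q0, w0 = scal[QTOT], scal[WTOT]
                    for i in range(n):
                        if in_cluster[i]:
                            for k in range(L):
                                _remove(pos[i, k], i, k, types[k], site_n,
                                        site_na, occ_p, occ_m, nbrt, scal)
                    for i in range(n):
                        if in_cluster[i]:
                            for k in range(L):
                                v = nbrt[pos[i, k], direction]
                                _add(v, i, k, types[k], site_n, site_na,
                                     occ_p, occ_m, nbrt, scal)
                    # bonds must be conserved by construction
                    if _metropolis_dn0(scal[QTOT] - q0, scal[WTOT] - w0,
                                       beta, J):
                        for i in range(n):
                            if in_cluster[i]:
                                for k in range(L):
                                    pos[i, k] = nbrt[pos[i, k], direction]
                        accepted = True
                    else:
                        for i in range(n):
                            if in_cluster[i]:
                                for k in range(L):
                                    _remove(nbrt[pos[i, k], direction], i, k,
                                            types[k], site_n, site_na, occ_p,
                                            occ_m, nbrt, scal)
                        for i in range(n):
                            if in_cluster[i]:
                                for k in range(L):
                                    _add(pos[i, k], i, k, types[k], site_n,
                                         site_na, occ_p, occ_m, nbrt, scal)

        # ---------------- CBMC insertion ----------------
        elif mv == 6:
            if n < n_max:
                head = np.random.randint(0, V)
                if _can_add(head, types[0], site_n, site_na):
                    q0, w0 = scal[QTOT], scal[WTOT]
                    _add(head, n, 0, types[0], site_n, site_na, occ_p, occ_m,
                         nbrt, scal)
                    pos[n, 0] = head
                    log_r = 0.0
                    placed = 1
                    for k in range(1, L):
                        u = pos[n, k - 1]
                        nc = 0
                        for j in range(12):
                            w = nbrt[u, j]
                            if _can_add(w, types[k], site_n, site_na):
                                cands[nc] = w
                                nc += 1
                        if _can_add(u, types[k], site_n, site_na):
                            cands[nc] = u
                            nc += 1
                        if nc == 0:
                            break
                        v = cands[np.random.randint(0, nc)]
                        _add(v, n, k, types[k], site_n, site_na, occ_p, occ_m,
                             nbrt, scal)
                        pos[n, k] = v
                        log_r += np.log(float(nc))
                        placed += 1
                    if placed == L:
                        dH = -float(scal[QTOT] - q0) - J * float(scal[WTOT] - w0)
                        log_acc = (np.log(float(V) / float(n + 1)) + log_r
                                   - (L - 1) * LOG13
                                   - beta * (dH - mu)
                                   - beta * (h_tab[n + 1] - h_tab[n]))
                        if log_acc >= 0.0 or np.random.random() < np.exp(log_acc):
                            scal[N_POLY] = n + 1
                            accepted = True
                    if not accepted:
                        for k in range(placed - 1, -1, -1):
                            _remove(pos[n, k], n, k, types[k], site_n, site_na,
                                    occ_p, occ_m, nbrt, scal)
                            pos[n, k] = -1

        # ---------------- deletion ----------------
        elif mv == 7:
            if n > 0:
                p = np.random.randint(0, n)
                q0, w0 = scal[QTOT], scal[WTOT]
                for k in range(L):
                    old_sites[k] = pos[p, k]
                    _remove(old_sites[k], p, k, types[k], site_n, site_na,
                            occ_p, occ_m, nbrt, scal)
                dH = -float(scal[QTOT] - q0) - J * float(scal[WTOT] - w0)
                # retrace to recover the Rosenbluth weight (restores state)
                log_r = 0.0
                _add(old_sites[0], p, 0, types[0], site_n, site_na, occ_p,
                     occ_m, nbrt, scal)
                for k in range(1, L):
                    u = old_sites[k - 1]
                    nc = 0
                    for j in range(12):
                        if _can_add(nbrt[u, j], types[k], site_n, site_na):
                            nc += 1
                    if _can_add(u, types[k], site_n, site_na):
                        nc += 1
                    log_r += np.log(float(nc))
                    _add(old_sites[k], p, k, types[k], site_n, site_na, occ_p,
                         occ_m, nbrt, scal)
                log_acc = (np.log(float(n) / float(V)) + (L - 1) * LOG13
                           - log_r - beta * (dH + mu)
                           - beta * (h_tab[n - 1] - h_tab[n]))
                if log_acc >= 0.0 or np.random.random() < np.exp(log_acc):
                    # actually delete: remove monomers, swap last polymer in
                    for k in range(L):
                        _remove(old_sites[k], p, k, types[k], site_n, site_na,
                                occ_p, occ_m, nbrt, scal)
                        pos[p, k] = -1
                    last = n - 1
                    if p != last:
                        for k in range(L):
                            s = pos[last, k]
                            for slot in range(2):
                                if occ_p[s, slot] == last and occ_m[s, slot] == k:
                                    occ_p[s, slot] = p
                                    break
                            pos[p, k] = pos[last, k]
                            pos[last, k] = -1
                    scal[N_POLY] = n - 1
                    accepted = True

        if accepted:
            acc[mv, 1] += 1

        # ---------------- sampling ----------------
        if sample_every > 0 and (step + 1) % sample_every == 0:
            nn = scal[N_POLY]
            e = -float(scal[QTOT]) - J * float(scal[WTOT])
            pn[nn] += 1.0
            eb = int((e - e_min) / e_bin)
            if eb < 0:
                eb = 0
            elif eb >= n_ebins:
                eb = n_ebins - 1
            hist2d[nn, eb] += 1.0

        if traj_every > 0 and (step + 1) % traj_every == 0:
            row = traj_len[0]
            if row < traj.shape[0]:
                nn = scal[N_POLY]
                for i in range(nn):
                    s_work[i] = 0
                    t_work[i] = 0
                t_tot = 0
                for v in range(V):
                    if site_n[v] == 2:
                        pa = occ_p[v, 0]
                        pb = occ_p[v, 1]
                        if pa == pb:
                            s_work[pa] += 1
                        else:
                            t_tot += 1
                            t_work[pa] += 1
                            t_work[pb] += 1
                s_sum = 0.0
                s_sq = 0.0
                t_sum = 0.0
                t_sq = 0.0
                for i in range(nn):
                    s_sum += s_work[i]
                    s_sq += s_work[i] * s_work[i]
                    t_sum += t_work[i]
                    t_sq += t_work[i] * t_work[i]
                rg_sum = 0.0
                rg_sq = 0.0
                n2n3 = dims[1] * dims[2]
                for i in range(nn):
                    # unwrap along the backbone in primitive coordinates
                    ci = 0.0
                    cj = 0.0
                    ck = 0.0
                    pi = 0
                    pj = 0
                    pk = 0
                    # accumulate positions and squared cartesian radii
                    sx = 0.0
                    sy = 0.0
                    sz = 0.0
                    sxx = 0.0
                    syy = 0.0
                    szz = 0.0
                    prev_i = 0
                    prev_j = 0
                    prev_k = 0
                    for k in range(L):
                        v = pos[i, k]
                        vi = v // n2n3
                        vj = (v // dims[2]) % dims[1]
                        vk = v % dims[2]
                        if k == 0:
                            pi = vi
                            pj = vj
                            pk = vk
                        else:
                            di = vi - prev_i
                            dj = vj - prev_j
                            dk = vk - prev_k
                            if di > dims[0] // 2:
                                di -= dims[0]
                            elif di < -(dims[0] // 2):
                                di += dims[0]
                            if dj > dims[1] // 2:
                                dj -= dims[1]
                            elif dj < -(dims[1] // 2):
                                dj += dims[1]
                            if dk > dims[2] // 2:
                                dk -= dims[2]
                            elif dk < -(dims[2] // 2):
                                dk += dims[2]
                            pi += di
                            pj += dj
                            pk += dk
                        prev_i = vi
                        prev_j = vj
                        prev_k = vk
                        # cartesian via primitive vectors
                        x = (pi + pk) / np.sqrt(2.0)
                        y = (pi + pj) / np.sqrt(2.0)
                        z = (pj + pk) / np.sqrt(2.0)
                        sx += x
                        sy += y
                        sz += z
                        sxx += x * x
                        syy += y * y
                        szz += z * z
                    rg2 = ((sxx - sx * sx / L) + (syy - sy * sy / L)
                           + (szz - sz * sz / L)) / L
                    if rg2 < 0.0:
                        rg2 = 0.0
                    rg = np.sqrt(rg2)
                    rg_sum += rg
                    rg_sq += rg * rg
                e = -float(scal[QTOT]) - J * float(scal[WTOT])
                traj[row, 0] = step + 1
                traj[row, 1] = nn
                traj[row, 2] = e
                traj[row, 3] = s_sum
                traj[row, 4] = s_sq
                traj[row, 5] = t_sum
                traj[row, 6] = t_sq
                traj[row, 7] = t_tot
                traj[row, 8] = rg_sum
                traj[row, 9] = rg_sq
                traj_len[0] = row + 1
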