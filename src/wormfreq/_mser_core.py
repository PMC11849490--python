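"""Numba kernels for the MSER component-tree sweep and ellipse fitting.

Bright-on-dark convention: the gray threshold sweeps downward from the
brightest level, so connected components of {pixels >= t} grow as t
decreases.  A component is maximally stable where its relative area change
over ``delta`` gray levels is locally minimal and below ``max_variation``.

The sweep records one (root, level, area) entry per live component per gray
level, but only once a component has reached ``min_area`` — smaller
components can neither be emitted nor absorb anything bigger, so their
history is irrelevant.  Records per root sit at consecutive descending
levels, which makes area lookups simple offsets.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _find(parent, p):
    root = p
    while parent[root] != root:
        root = parent[root]
    while parent[p] != root:  # path compression
        nxt = parent[p]
        parent[p] = root
        p = nxt
    return root


@njit(cache=True)
def _union(parent, area, birth, death, absorbed_into, a, b, lvl):
    ra = _find(parent, a)
    rb = _find(parent, b)
    if ra == rb:
        return
    # survivor: earlier-born (higher birth level), then larger area, then lower index
    if birth[ra] != birth[rb]:
        keep_a = birth[ra] > birth[rb]
    elif area[ra] != area[rb]:
        keep_a = area[ra] > area[rb]
    else:
        keep_a = ra < rb
    if keep_a:
        s, t = ra, rb
    else:
        s, t = rb, ra
    parent[t] = s
    area[s] += area[t]
    death[t] = lvl
    absorbed_into[t] = s


@njit(cache=True)
def mvee_weights(p, tol, max_iter):
    """Khachiyan iteration for the minimum-volume enclosing ellipse.

    ``p`` is (k, 2); returns the optimal point weights u (length k).
    """
    k = p.shape[0]
    u = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        x00 = x01 = x02 = x11 = x12 = x22 = 0.0
        for i in range(k):
            ui = u[i]
            a = p[i, 0]
            b = p[i, 1]
            x00 += ui * a * a
            x01 += ui * a * b
            x02 += ui * a
            x11 += ui * b * b
            x12 += ui * b
            x22 += ui
        det = (
            x00 * (x11 * x22 - x12 * x12)
            - x01 * (x01 * x22 - x12 * x02)
            + x02 * (x01 * x12 - x11 * x02)
        )
        if det == 0.0:
            break
        i00 = (x11 * x22 - x12 * x12) / det
        i01 = (x02 * x12 - x01 * x22) / det
        i02 = (x01 * x12 - x02 * x11) / det
        i11 = (x00 * x22 - x02 * x02) / det
        i12 = (x01 * x02 - x00 * x12) / det
        i22 = (x00 * x11 - x01 * x01) / det
        mmax = -1.0
        jmax = 0
        for i in range(k):
            a = p[i, 0]
            b = p[i, 1]
            m = (
                a * (i00 * a + i01 * b + i02)
                + b * (i01 * a + i11 * b + i12)
                + (i02 * a + i12 * b + i22)
            )
            if m > mmax:
                mmax = m
                jmax = i
        if mmax <= 3.0 * (1.0 + tol):
            break
        step = (mmax - 3.0) / (3.0 * (mmax - 1.0))
        for i in range(k):
            u[i] *= 1.0 - step
        u[jmax] += step
    return u


@njit(cache=True)
def mser_sweep(img_q, order, delta, min_area, max_area, max_variation, min_level):
    """Detect maximally stable extremal regions of a uint8 image.

    ``order`` lists the flat indices of pixels with level >= min_level,
    sorted by gray level descending (ties in any stable order).  Returns
    parallel arrays (anchor_pixel, level, area, variation); region pixels are
    recovered by the caller from (anchor, level).
    """
    h, w = img_q.shape
    n = h * w
    flat = img_q.ravel()
    n_active = order.shape[0]

    parent = np.full(n, -1, np.int64)
    area = np.zeros(n, np.int64)
    birth = np.full(n, -1, np.int64)
    death = np.full(n, -1, np.int64)
    absorbed_into = np.full(n, -1, np.int64)

    max_rec = 1 << 18
    rec_root = np.empty(max_rec, np.int64)
    rec_area = np.empty(max_rec, np.int64)
    n_rec = 0
    rec_hi = np.full(n, -1, np.int64)  # highest recorded level per root
    rec_cnt = np.zeros(n, np.int64)  # number of recorded levels per root

    # live roots tracking: compact list, cleaned lazily at each level end
    live = np.empty(n, np.int64)
    n_live = 0

    idx = 0
    for lvl in range(255, min_level - 1, -1):
        while idx < n_active and flat[order[idx]] == lvl:
            p = order[idx]
            idx += 1
            parent[p] = p
            area[p] = 1
            birth[p] = lvl
            live[n_live] = p
            n_live += 1
            r = p // w
            c = p - r * w
            if r > 0 and parent[p - w] != -1:
                _union(parent, area, birth, death, absorbed_into, p, p - w, lvl)
            if r < h - 1 and parent[p + w] != -1:
                _union(parent, area, birth, death, absorbed_into, p, p + w, lvl)
            if c > 0 and parent[p - 1] != -1:
                _union(parent, area, birth, death, absorbed_into, p, p - 1, lvl)
            if c < w - 1 and parent[p + 1] != -1:
                _union(parent, area, birth, death, absorbed_into, p, p + 1, lvl)
        # compact the live list and record areas of large-enough roots
        m = 0
        for k in range(n_live):
            p2 = live[k]
            if parent[p2] == p2:
                live[m] = p2
                m += 1
                if area[p2] >= min_area and n_rec < max_rec:
                    rec_root[n_rec] = p2
                    rec_area[n_rec] = area[p2]
                    n_rec += 1
                    if rec_hi[p2] == -1:
                        rec_hi[p2] = lvl
                    rec_cnt[p2] += 1
        n_live = m

    # group records per root (append order is already by descending level,
    # and per-root levels are consecutive once min_area is reached)
    root_list = np.empty(max(n_rec, 1), np.int64)
    n_roots = 0
    # assign slot ids in first-appearance order
    slot_of = np.full(n, -1, np.int64)
    for i in range(n_rec):
        r0 = rec_root[i]
        if slot_of[r0] == -1:
            slot_of[r0] = n_roots
            root_list[n_roots] = r0
            n_roots += 1
    counts = np.zeros(n_roots + 1, np.int64)
    for i in range(n_rec):
        counts[slot_of[rec_root[i]] + 1] += 1
    for i in range(n_roots):
        counts[i + 1] += counts[i]
    series = np.empty(n_rec, np.int64)
    fill = np.zeros(n_roots, np.int64)
    for i in range(n_rec):
        sl = slot_of[rec_root[i]]
        series[counts[sl] + fill[sl]] = rec_area[i]
        fill[sl] += 1

    # stability analysis per recorded root
    max_out = 4096
    out_anchor = np.empty(max_out, np.int64)
    out_level = np.empty(max_out, np.int64)
    out_area = np.empty(max_out, np.int64)
    out_q = np.empty(max_out, np.float64)
    n_out = 0
    qbuf = np.empty(256, np.float64)

    for sl in range(n_roots):
        r0 = root_list[sl]
        hi = rec_hi[r0]
        cnt = rec_cnt[r0]
        lo = hi - cnt + 1
        base = counts[sl]  # series[base + (hi - t)] = area at level t

        for t in range(lo, hi + 1):
            at = series[base + hi - t]
            tp = t + delta
            if tp > hi:
                tp = hi
            a_plus = series[base + hi - tp]
            tm = t - delta
            if tm < min_level:
                tm = min_level
            # containing component's area at level tm (walk the absorber chain)
            cur = r0
            a_minus = at
            for _ in range(64):  # chain depth guard
                c_hi = rec_hi[cur]
                c_lo = c_hi - rec_cnt[cur] + 1
                if tm >= c_lo:
                    if tm <= c_hi:
                        a_minus = series[counts[slot_of[cur]] + c_hi - tm]
                    # tm above c_hi: component smaller than min_area there;
                    # keep the fallback a_minus = at
                    break
                nxt = absorbed_into[cur]
                if nxt == -1 or slot_of[nxt] == -1:
                    break
                cur = nxt
            if a_minus < at:
                a_minus = at
            qbuf[t] = (a_minus - a_plus) / at

        # maximal runs of acceptable levels; one region per run at min variation
        t = lo
        while t <= hi:
            at = series[base + hi - t]
            if not (qbuf[t] <= max_variation and min_area <= at <= max_area):
                t += 1
                continue
            run_start = t
            while t <= hi:
                at = series[base + hi - t]
                if not (qbuf[t] <= max_variation and min_area <= at <= max_area):
                    break
                t += 1
            run_end = t - 1
            qmin = 1e18
            for u in range(run_start, run_end + 1):
                if qbuf[u] < qmin:
                    qmin = qbuf[u]
            first = -1
            last = -1
            for u in range(run_start, run_end + 1):
                if qbuf[u] <= qmin + 1e-12:
                    if first == -1:
                        first = u
                    last = u
            t_star = (first + last) // 2
            if n_out < max_out:
                out_anchor[n_out] = r0
                out_level[n_out] = t_star
                out_area[n_out] = series[base + hi - t_star]
                out_q[n_out] = qbuf[t_star]
                n_out += 1
    return out_anchor[:n_out], out_level[:n_out], out_area[:n_out], out_q[:n_out]
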