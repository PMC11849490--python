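"""Independent brute-force oracles used to validate the implementation.

Each oracle is written directly from first principles (explicit loops, a
different optimisation algorithm, or an exhaustive scan) so it shares no code
path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def hu_brute_force(frame: np.ndarray) -> np.ndarray:
    """The 8 Hu invariants via explicit double sums over pixels."""
    f = np.asarray(frame, dtype=np.float64)
    h_, w_ = f.shape
    m00 = 0.0
    mx = 0.0
    my = 0.0
    for y in range(h_):
        for x in range(w_):
            m00 += f[y, x]
            mx += x * f[y, x]
            my += y * f[y, x]
    xc, yc = mx / m00, my / m00

    def mu(p, q):
        s = 0.0
        for y in range(h_):
            for x in range(w_):
                s += (x - xc) ** p * (y - yc) ** q * f[y, x]
        return s

    def eta(p, q):
        return mu(p, q) / m00 ** (1 + (p + q) / 2)

    n20, n02, n11 = eta(2, 0), eta(0, 2), eta(1, 1)
    n30, n21, n12, n03 = eta(3, 0), eta(2, 1), eta(1, 2), eta(0, 3)
    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11**2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = (n30 - 3 * n12) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2) + (
        3 * n21 - n03
    ) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    h6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (n30 + n12) * (n21 + n03)
    h7 = (3 * n21 - n03) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2) - (
        n30 - 3 * n12
    ) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    h8 = n11 * ((n30 + n12) ** 2 - (n03 + n21) ** 2) - (n20 - n02) * (n30 + n12) * (n03 + n21)
    return np.array([h1, h2, h3, h4, h5, h6, h7, h8])


def autocorr_brute_force(values: np.ndarray, tau_max: int) -> np.ndarray:
    """Ensemble autocorrelation via an explicit double loop."""
    v = np.asarray(values, dtype=np.float64)
    p, t = v.shape
    r = np.zeros(tau_max + 1)
    for tau in range(tau_max + 1):
        acc = 0.0
        for i in range(t - tau):
            a, b = v[:, i], v[:, i + tau]
            na, nb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
            if na > 0 and nb > 0:
                acc += float(a @ b) / (na * nb)
        r[tau] = acc / (t - tau)
    return r


def prominence_brute_force(series: np.ndarray, index: int, kind: str) -> float:
    """Topographic prominence by exhaustive scanning, truncated at the borders.

    For a peak: on each side walk until a strictly higher value (or the
    border), track the minimum; prominence = height - max(left min, right
    min).  Troughs are peaks of the negated series.
    """
    r = np.asarray(series, dtype=np.float64)
    if kind == "trough":
        return prominence_brute_force(-r, index, "peak")
    height = r[index]
    mins = []
    for step in (-1, 1):
        i = index + step
        if not 0 <= i < len(r):
            continue  # border side: contour truncated, side ignored
        lowest = height
        while 0 <= i < len(r) and r[i] <= height:
            lowest = min(lowest, r[i])
            i += step
        mins.append(lowest)
    if not mins:
        return 0.0
    return float(height - max(mins))


def mvee_multiplicative(points: np.ndarray, n_iter: int = 5000) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-volume enclosing ellipse by Titterington multiplicative updates.

    A different algorithm for the same D-optimal design dual: every weight is
    updated simultaneously as u_i <- u_i * M_i / (d+1).  Returns (center, A)
    with {p : (p-c)^T A (p-c) <= 1} scaled to contain all points.
    """
    p = np.asarray(points, dtype=np.float64)
    k, d = p.shape
    q = np.column_stack([p, np.ones(k)])
    u = np.full(k, 1.0 / k)
    for _ in range(n_iter):
        x = q.T @ (q * u[:, None])
        m = np.einsum("ij,jk,ik->i", q, np.linalg.inv(x), q)
        u = u * m / (d + 1)
        u /= u.sum()
    c = p.T @ u
    cov = (p.T * u) @ p - np.outer(c, c)
    a = np.linalg.inv(cov) / d
    dp = p - c
    scale = float(np.max(np.einsum("ij,jk,ik->i", dp, a, dp)))
    if scale > 1.0:
        a = a / scale
    return c, a


def ellipse_area(a_mat: np.ndarray) -> float:
    """Area of {x : x^T A x <= 1}."""
    return float(np.pi / np.sqrt(np.linalg.det(a_mat)))
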