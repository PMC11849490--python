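"""Central image moments and the eight Hu moment invariants.

The invariants are algebraic combinations of scaled central moments
eta_pq = mu_pq / mu_00^(1+(p+q)/2) up to order 3.  h1..h7 are the classical
Hu set; h8 is the additional third-order invariant whose sign, like h7's,
flips under image reflection.  Moments are computed on (background
subtracted) gray intensities, not on a binarized mask, so the invariants
respond to the intensity profile of the animal, not only its silhouette.

Coordinate convention: x = column index, y = row index, both 0-based with
pixel centers at integer coordinates.  Any consistent convention yields the
same invariant values up to the documented reflection behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MomentSet", "HuVector", "compute_moments", "hu_vector", "hu_from_frame"]

# (p, q) orders carried by a MomentSet
_ORDERS = [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)]


@dataclass
class MomentSet:
    """Central moments mu_pq (orders 0..3), scaled moments eta_pq, centroid (x, y)."""

    mu: dict[tuple[int, int], float]
    eta: dict[tuple[int, int], float]
    centroid: tuple[float, float]  # (xc, yc) = (col, row)


@dataclass
class HuVector:
    """The 8 Hu invariants h1..h8 of a single frame."""

    h: np.ndarray  # shape (8,)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        if self.h.shape != (8,):
            raise ValueError("HuVector requires exactly 8 components")


def compute_moments(frame: np.ndarray) -> MomentSet:
    """Centroid, central moments up to order 3, and scaled central moments.

    Raises
    ------
    ValueError
        If the frame has zero total intensity ("zero-mass image"); the
        ensemble builder treats such frames as missing and imputes them.
    """
    f = np.asarray(frame, dtype=np.float64)
    if f.ndim != 2:
        raise ValueError("frame must be 2-D")
    m00 = f.sum()
    if m00 <= 0:
        raise ValueError("zero-mass image: frame has no intensity")

    h, w = f.shape
    x = np.arange(w, dtype=np.float64)  # columns
    y = np.arange(h, dtype=np.float64)  # rows
    xc = (f.sum(axis=0) @ x) / m00
    yc = (f.sum(axis=1) @ y) / m00

    dx = x - xc  # per column
    dy = y - yc  # per row
    # Precompute powers; mu_pq = sum_y sum_x dy^q dx^p f  (x carries p, y carries q)
    xp = {p: dx**p for p in range(4)}
    yq = {q: dy**q for q in range(4)}
    mu: dict[tuple[int, int], float] = {}
    for p, q in _ORDERS:
        mu[(p, q)] = float(yq[q] @ f @ xp[p])

    eta: dict[tuple[int, int], float] = {}
    for p, q in _ORDERS:
        if p + q >= 2:
            eta[(p, q)] = mu[(p, q)] / m00 ** (1.0 + (p + q) / 2.0)
    return MomentSet(mu=mu, eta=eta, centroid=(float(xc), float(yc)))


def hu_vector(moments: MomentSet, h8_prefactor: str = "eta11") -> HuVector:
    """The 8 Hu invariants from a :class:`MomentSet`.

    Parameters
    ----------
    moments
        Output of :func:`compute_moments`.
    h8_prefactor
        ``"eta11"`` (default) uses the scaled moment eta_11 in the first term
        of h8, so h8 shares the spatial-scale invariance of h1..h7.
        ``"mu11"`` uses the raw central moment mu_11 instead, for comparison.
    """
    e = moments.eta
    n20, n02, n11 = e[(2, 0)], e[(0, 2)], e[(1, 1)]
    n30, n21, n12, n03 = e[(3, 0)], e[(2, 1)], e[(1, 2)], e[(0, 3)]

    a = n30 + n12
    b = n21 + n03
    c = n30 - 3 * n12
    d = 3 * n21 - n03

    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11**2
    h3 = c**2 + d**2
    h4 = a**2 + b**2
    h5 = c * a * (a**2 - 3 * b**2) + d * b * (3 * a**2 - b**2)
    h6 = (n20 - n02) * (a**2 - b**2) + 4 * n11 * a * b
    h7 = d * a * (a**2 - 3 * b**2) - c * b * (3 * a**2 - b**2)
    if h8_prefactor == "eta11":
        pre = n11
    elif h8_prefactor == "mu11":
        pre = moments.mu[(1, 1)]
    else:
        raise ValueError("h8_prefactor must be 'eta11' or 'mu11'")
    h8 = pre * (a**2 - b**2) - (n20 - n02) * a * b
    return HuVector(np.array([h1, h2, h3, h4, h5, h6, h7, h8]))


def hu_from_frame(frame: np.ndarray, h8_prefactor: str = "eta11") -> HuVector:
    """Convenience: moments + invariants in one call."""
    return hu_vector(compute_moments(frame), h8_prefactor=h8_prefactor)
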