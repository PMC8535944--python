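"""Orthogonal Daubechies wavelet transform (periodized).

The scaling filter of the Daubechies family with ``order`` vanishing moments
(filter length 2*order) is computed by spectral factorization: the roots of
the binomial polynomial P(y) = sum_k C(order-1+k, k) y^k are mapped to the
z-plane and the minimum-phase half is kept, together with a zero of
multiplicity ``order`` at z = -1.  This reproduces the standard db filters
(db1 = Haar, db2 = [0.4830, 0.8365, 0.2241, -0.1294], ...) without an external
wavelet library.

The discrete transform uses periodization: each level stores ceil(n/2)
approximation and detail coefficients and the analysis/synthesis pair is
exactly orthogonal, so decompose -> reconstruct is the identity to machine
precision.  Odd-length inputs are extended by repeating the final sample; the
original length is tracked so reconstruction trims back.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import comb

from .errors import DepthError


@lru_cache(maxsize=None)
def daubechies_filter(order: int) -> tuple[float, ...]:
    """Return the Daubechies scaling (low-pass) filter with ``order`` vanishing moments."""
    if order < 1:
        raise ValueError("order must be >= 1")
    if order == 1:  # Haar
        return (1 / np.sqrt(2), 1 / np.sqrt(2))
    # P(y), lowest degree first
    p = np.array([comb(order - 1 + k, k, exact=True) for k in range(order)], dtype=float)
    yroots = np.roots(p[::-1])
    zroots = []
    for y in yroots:
        # y = (2 - z - 1/z)/4  =>  z^2 + (4y - 2) z + 1 = 0
        pair = np.roots([1.0, 4.0 * y - 2.0, 1.0])
        zroots.append(pair[np.argmin(np.abs(pair))])  # minimum-phase choice
    h = np.real(np.poly([-1.0] * order + list(zroots)))
    h *= np.sqrt(2.0) / h.sum()
    return tuple(h)


def quadrature_mirror(h: np.ndarray) -> np.ndarray:
    """High-pass filter g[n] = (-1)^n h[L-1-n] of a scaling filter h."""
    g = np.array(h[::-1], dtype=float)
    g[1::2] *= -1.0
    return g


def _analysis_step(x: np.ndarray, h: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One periodized analysis level: a[k] = sum_m h[m] x[(2k+m) mod n]."""
    if x.size % 2:
        x = np.concatenate([x, x[-1:]])
    n = x.size
    k = np.arange(n // 2)[:, None]
    m = np.arange(h.size)[None, :]
    idx = (2 * k + m) % n
    windows = x[idx]
    return windows @ h, windows @ g


def _synthesis_step(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_analysis_step` (exact for orthonormal filters)."""
    n = 2 * a.size
    x = np.zeros(n)
    k = np.arange(a.size)[:, None]
    m = np.arange(h.size)[None, :]
    idx = ((2 * k + m) % n).ravel()
    np.add.at(x, idx, (a[:, None] * h[None, :]).ravel())
    np.add.at(x, idx, (d[:, None] * g[None, :]).ravel())
    return x


@dataclass
class WaveletDecomposition:
    """Multilevel DWT: approximation at the deepest level plus detail bands.

    ``details[0]`` is the deepest (coarsest) detail band. ``lengths`` records
    the pre-padding input length at every level so synthesis can trim.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    lengths: list[int]
    order: int

    @property
    def levels(self) -> int:
        return len(self.details)

    def bands(self) -> list[np.ndarray]:
        """All coefficient bands, approximation first."""
        return [self.approx, *self.details]


def wavedec(x: np.ndarray, order: int = 6, levels: int = 5) -> WaveletDecomposition:
    """Multilevel periodized DWT with a Daubechies-``order`` filter."""
    x = np.asarray(x, dtype=np.float64)
    h = np.asarray(daubechies_filter(order))
    g = quadrature_mirror(h)
    min_len = h.size
    details: list[np.ndarray] = []
    lengths: list[int] = []
    a = x
    for _ in range(levels):
        if a.size < min_len:
            raise DepthError(
                f"signal of {x.size} samples too short for {levels} levels "
                f"with a length-{h.size} filter"
            )
        lengths.append(a.size)
        a, d = _analysis_step(a, h, g)
        details.append(d)
    details.reverse()
    return WaveletDecomposition(approx=a, details=details, lengths=lengths[::-1], order=order)


def waverec(dec: WaveletDecomposition) -> np.ndarray:
    """Reconstruct the signal from a (possibly thresholded) decomposition."""
    h = np.asarray(daubechies_filter(dec.order))
    g = quadrature_mirror(h)
    a = dec.approx
    for d, n in zip(dec.details, dec.lengths):
        a = _synthesis_step(a, d, h, g)[:n]
    return a
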