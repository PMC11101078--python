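"""Natural-abundance convolution and deconvolution of isotopologue vectors.

A molecule with ``j`` tracer-labeled carbons out of ``n`` still has ``n - j``
carbons that may carry 13C at the natural abundance ``p13`` (~1.07%).  The
probability of observing it at mass shift ``i`` is therefore binomial:

    P(i | j) = C(n - j, i - j) * p13**(i - j) * (1 - p13)**(n - i)    (i >= j)

Stacking these probabilities column-wise gives a lower-triangular correction
matrix ``M`` with unit column sums.  The forward model is ``measured = M @ true``;
correction solves the inverse problem under a nonnegativity constraint
(:func:`scipy.optimize.nnls`), which reduces to exact sequential stripping in
the noise-free case but stays well behaved on noisy vectors.

Only 13C satellites are treated: at 70,000 resolving power the extracted
isotopologue series is the carbon one, and only M+1..M+3-type carbon
satellites need compensating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

from .label_engine import MID

#: standard natural 13C abundance (fraction of carbon atoms)
DEFAULT_P13 = 0.0107


@dataclass(frozen=True, eq=False)
class CorrectionMatrix:
    n_carbons: int
    p13: float
    entries: np.ndarray  # (n+1, n+1), lower-triangular, unit column sums


@dataclass(frozen=True)
class CorrectedMID:
    """A deconvolved MID together with the residual norm of the NNLS fit."""

    fractions: tuple[float, ...]
    residual: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)


def build_correction_matrix(n_carbons: int, p13: float = DEFAULT_P13) -> CorrectionMatrix:
    """Binomial natural-abundance matrix: entry (i, j) = P(observed m+i | j labeled)."""
    if not 0.0 <= p13 < 1.0:
        raise ValueError(f"p13 must lie in [0, 1), got {p13}")
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    n = n_carbons
    m = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        # the n-j unlabeled carbons pick up 0..n-j natural 13C atoms
        m[j:, j] = binom.pmf(np.arange(n - j + 1), n - j, p13)
    return CorrectionMatrix(n, p13, m)


def apply_natural_abundance(true_mid: MID | np.ndarray, matrix: CorrectionMatrix) -> np.ndarray:
    """Forward-convolve a tracer-only MID with natural abundance."""
    vec = true_mid.as_array() if isinstance(true_mid, MID) else np.asarray(true_mid, float)
    if vec.shape != (matrix.n_carbons + 1,):
        raise ValueError(
            f"MID length {vec.shape[0]} does not match matrix for {matrix.n_carbons} carbons"
        )
    return matrix.entries @ vec


def correct_mid(measured: np.ndarray, matrix: CorrectionMatrix) -> CorrectedMID:
    """Deconvolve a measured isotopologue vector into the tracer-only MID.

    Solves ``matrix @ x ~= measured`` under ``x >= 0`` and renormalizes ``x``
    to unit sum; the returned residual is the Euclidean norm of the NNLS
    misfit on the (sum-normalized) measured vector.
    """
    b = np.asarray(measured, dtype=float)
    if b.shape != (matrix.n_carbons + 1,):
        raise ValueError(
            f"measured length {b.shape[0]} does not match matrix for {matrix.n_carbons} carbons"
        )
    if (b < 0).any():
        raise ValueError("measured intensities must be nonnegative")
    total = b.sum()
    if total <= 0:
        raise ValueError("measured vector is all zero; nothing to correct")
    b = b / total
    x, residual = nnls(matrix.entries, b)
    if x.sum() <= 0:
        raise ValueError("deconvolution produced an all-zero solution")
    x = x / x.sum()
    return CorrectedMID(tuple(x), float(residual))
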