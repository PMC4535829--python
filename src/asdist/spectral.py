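"""Distance matrices, the unitary 2D DFT, and the amplitude spectrum distance.

The amplitude spectrum distance (ASD) between two fragments P and Q is the
Frobenius (2-norm) distance between the entry-wise moduli of the unitary 2D
discrete Fourier transforms of their internal C-alpha distance matrices::

    ASD(P, Q) = || |F D_P| - |F D_Q| ||_2

with the unitary convention ``(F M)_{m,n} = (1/N) sum_{p,q} M_{p,q}
exp(-2 i pi ((p-1) m / N + (q-1) n / N))`` so that the transform preserves the
Frobenius norm (Parseval).  Because the modulus discards phase, ASD is
invariant under isometries (including mirroring), sequential reversal and
circular index shifts — the properties that make it tolerant to indels and
window shifts where superposition scores are not.

By default :func:`asd` operates on matrices zero-padded to dimension
``N_P + N_Q``, which extends the score to fragments of different lengths and
bounds it by the mismatch of the two matrices in their best circular
alignment.  The unpadded form, the length-normalized form (NASD) and the
low-frequency truncated form are exposed separately.
"""
from __future__ import annotations

import math
from typing import Union

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .fragment import CAlphaFragment, LengthMismatchError

__all__ = [
    "distance_matrix",
    "dft2_unitary",
    "dft2_naive",
    "amplitude_spectrum",
    "frobenius_norm",
    "pad_matrix",
    "asd",
    "asd_unpadded",
    "nasd",
    "asd_truncated",
    "validate_distance_matrix",
]

FragmentLike = Union[CAlphaFragment, np.ndarray]

#: Largest dimension accepted by the quadruple-sum reference transform.
_NAIVE_MAX_N = 64


def distance_matrix(fragment: CAlphaFragment) -> np.ndarray:
    """Internal C-alpha distance matrix ``D[i, j] = ||p_i - p_j||``.

    Symmetric with a zero diagonal; invariant under rotation, translation
    and mirroring of the fragment, which every downstream score inherits.
    """
    coords = fragment.coords if isinstance(fragment, CAlphaFragment) else np.asarray(fragment, float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return squareform(pdist(coords))


def validate_distance_matrix(matrix: np.ndarray, *, atol: float = 0.0) -> np.ndarray:
    """Check symmetry, zero diagonal and nonnegativity; return as float array."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"distance matrix must be square, got shape {m.shape}")
    if not np.array_equal(m, m.T) and not np.allclose(m, m.T, atol=atol, rtol=0):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(m) != 0) and not np.allclose(np.diag(m), 0, atol=atol):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(m < 0):
        raise ValueError("distance matrix entries must be nonnegative")
    return m


def dft2_unitary(matrix: np.ndarray) -> np.ndarray:
    """Unitary 2D DFT of a real square matrix, computed by FFT in O(N^2 log N).

    The 1/N prefactor makes the transform norm-preserving:
    ``||F M||_2 == ||M||_2`` exactly (Parseval).
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"input must be square, got shape {m.shape}")
    return np.fft.fft2(m, norm="ortho")


def dft2_naive(matrix: np.ndarray) -> np.ndarray:
    """Direct quadruple-sum evaluation of the unitary 2D DFT (test oracle).

    O(N^4); refuses N > 64.  Kept deliberately independent of the FFT path.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"input must be square, got shape {m.shape}")
    n = m.shape[0]
    if n > _NAIVE_MAX_N:
        raise ValueError(f"naive DFT refused for N={n} > {_NAIVE_MAX_N}")
    out = np.empty((n, n), dtype=np.complex128)
    p = np.arange(n)
    q = np.arange(n)
    for mm in range(n):
        for nn in range(n):
            phase = np.exp(-2j * np.pi * (p[:, None] * mm + q[None, :] * nn) / n)
            out[mm, nn] = np.sum(m * phase) / n
    return out


def amplitude_spectrum(matrix: np.ndarray) -> np.ndarray:
    """Entry-wise moduli of the unitary 2D DFT of a (distance) matrix."""
    return np.abs(dft2_unitary(matrix))


def frobenius_norm(matrix: np.ndarray) -> float:
    """2-norm ``sqrt(sum |M[i,j]|^2)`` of a real or complex matrix."""
    m = np.asarray(matrix)
    return float(np.sqrt(np.sum(np.abs(m) ** 2)))


def pad_matrix(matrix: np.ndarray, n_total: int) -> np.ndarray:
    """Zero-pad a square matrix into the top-left block of an n_total square.

    Amplitude spectra are invariant to circular shifts of the padded matrix,
    so the block placement is immaterial (tested); top-left is the convention.
    """
    m = np.asarray(matrix, dtype=np.float64)
    n = m.shape[0]
    if n_total < n:
        raise ValueError(f"cannot pad {n}x{n} matrix into {n_total}x{n_total}")
    out = np.zeros((n_total, n_total), dtype=np.float64)
    out[:n, :n] = m
    return out


def _as_matrix(obj: FragmentLike) -> np.ndarray:
    """Accept a fragment or a precomputed distance matrix."""
    if isinstance(obj, CAlphaFragment):
        return distance_matrix(obj)
    arr = np.asarray(obj, dtype=np.float64)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1]:
        return validate_distance_matrix(arr, atol=1e-9)
    if arr.ndim == 2 and arr.shape[1] == 3:
        return distance_matrix(CAlphaFragment(arr))
    raise ValueError(
        "expected a CAlphaFragment, an (N, 3) coordinate array or a square distance matrix"
    )


def asd_unpadded(p: FragmentLike, q: FragmentLike) -> float:
    """ASD on the raw (unpadded) distance matrices; requires equal lengths.

    This is the form for which the circular-permutation identity
    ``asd_unpadded(P, P >> s) == 0`` and the RMSD_d bound are stated.
    """
    dp, dq = _as_matrix(p), _as_matrix(q)
    if dp.shape != dq.shape:
        raise LengthMismatchError(
            f"fragments have lengths {dp.shape[0]} and {dq.shape[0]}; "
            "use the padded asd() for unequal lengths"
        )
    return frobenius_norm(amplitude_spectrum(dp) - amplitude_spectrum(dq))


def asd(p: FragmentLike, q: FragmentLike, *, pad: bool = True) -> float:
    """Amplitude spectrum distance, computed on zero-padded matrices.

    Both distance matrices are padded to dimension ``N_P + N_Q`` (equal-length
    inputs are also padded, to ``2N``), which is the package default score.
    ``pad=False`` falls back to the unpadded form and then requires equal
    lengths.

    A pseudometric: symmetric, zero on self, satisfies the triangle
    inequality; zero also between a fragment and its mirror image or its
    reversal, which is why it is not a metric.
    """
    if not pad:
        return asd_unpadded(p, q)
    dp, dq = _as_matrix(p), _as_matrix(q)
    if dp.shape[0] < 2 or dq.shape[0] < 2:
        raise ValueError("fragments must have at least 2 residues")
    n_total = dp.shape[0] + dq.shape[0]
    sp = amplitude_spectrum(pad_matrix(dp, n_total))
    sq = amplitude_spectrum(pad_matrix(dq, n_total))
    return frobenius_norm(sp - sq)


def nasd(p: FragmentLike, q: FragmentLike) -> float:
    """Length-normalized ASD on padded matrices.

    Each amplitude spectrum is divided by the Frobenius norm of its distance
    matrix before differencing, removing the gross dependence of the score on
    fragment length (and on uniform coordinate scaling).  Normalized spectra
    are unit vectors with nonnegative entries, so the value lies in
    ``[0, sqrt(2)]``.
    """
    dp, dq = _as_matrix(p), _as_matrix(q)
    np_, nq_ = frobenius_norm(dp), frobenius_norm(dq)
    if np_ == 0.0 or nq_ == 0.0:
        raise ZeroDivisionError("degenerate all-zero distance matrix")
    n_total = dp.shape[0] + dq.shape[0]
    sp = amplitude_spectrum(pad_matrix(dp, n_total)) / np_
    sq = amplitude_spectrum(pad_matrix(dq, n_total)) / nq_
    return frobenius_norm(sp - sq)


def asd_truncated(p: FragmentLike, q: FragmentLike, k: int) -> float:
    """ASD restricted to the k x k low-frequency block of the padded spectra.

    Frequencies 0..k-1 (including the dominant DC term) in both dimensions;
    nondecreasing in k and equal to :func:`asd` at the full dimension.  A
    cheap surrogate when many comparisons are needed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dp, dq = _as_matrix(p), _as_matrix(q)
    n_total = dp.shape[0] + dq.shape[0]
    if k > n_total:
        raise ValueError(f"k={k} exceeds the padded dimension {n_total}")
    sp = amplitude_spectrum(pad_matrix(dp, n_total))
    sq = amplitude_spectrum(pad_matrix(dq, n_total))
    return frobenius_norm(sp[:k, :k] - sq[:k, :k])


def rmsd_d_upper_bound(n: int, rmsd_d_value: float) -> float:
    """Provable cap on the unpadded ASD of two length-n fragments.

    ``ASD(P,Q) <= ||D_P - D_Q||_2 = sqrt(N(N-1)) * RMSD_d(P,Q)`` by the
    reverse triangle inequality and Parseval; the factor counts each residue
    pair twice because the distance matrix is symmetric.
    """
    return math.sqrt(n * (n - 1)) * rmsd_d_value
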