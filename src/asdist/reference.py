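"""Reference scores: superposition RMSD, distance-matrix RMSD_d, chirality.

These are the classical comparisons the spectral score is benchmarked
against.  RMSD is the minimum root-mean-square residual over proper
rigid-body superpositions (Kabsch); RMSD_d compares internal distance
matrices directly; the chirality sign separates genuine matches from
mirror-image matches, which every internal-distance score (RMSD_d included)
cannot distinguish on its own.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fragment import CAlphaFragment, LengthMismatchError
from .spectral import distance_matrix

__all__ = ["SuperpositionResult", "rmsd", "rmsd_d", "chirality_sign"]

#: Relative singular-value threshold below which det(P^T Q) is indeterminate.
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rigid-body superposition of fragment p onto q.

    ``rotation @ (p - p_centroid) + translation`` approximates q; ``rmsd`` is
    the minimized root-mean-square residual.  ``chirality_sign`` is the sign
    of det(P^T Q) on centered coordinates: +1 for a genuine match, -1 when a
    mirror image would superpose better, 0 when the geometry is degenerate
    and the sign is indeterminate.  ``degenerate`` flags (near-)collinear
    inputs for which the optimal rotation is not unique.
    """

    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray
    chirality_sign: int
    degenerate: bool = False


def _centered(p: CAlphaFragment, q: CAlphaFragment) -> tuple[np.ndarray, np.ndarray]:
    if len(p) != len(q):
        raise LengthMismatchError(
            f"superposition scores need equal lengths, got {len(p)} and {len(q)}"
        )
    pc = p.coords - p.coords.mean(axis=0)
    qc = q.coords - q.coords.mean(axis=0)
    return pc, qc


def rmsd(p: CAlphaFragment, q: CAlphaFragment) -> SuperpositionResult:
    """Least-squares rigid-body superposition (Kabsch, proper rotations only).

    The covariance ``H = P_c^T Q_c`` is decomposed by SVD and the rotation is
    forced to det = +1; mirror improvement is reported through
    ``chirality_sign`` rather than absorbed into the fit, so a fragment and
    its mirror image generally have a nonzero RMSD here.
    """
    pc, qc = _centered(p, q)
    n = len(p)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    residuals = (pc @ rot.T) - qc
    value = float(np.sqrt(np.sum(residuals**2) / n))
    translation = q.coords.mean(axis=0) - rot @ p.coords.mean(axis=0)
    # near-collinear traces leave the rotation about the common axis free
    degenerate = bool(s[1] <= _DEGENERATE_RTOL * max(s[0], 1.0))
    return SuperpositionResult(
        rmsd=value,
        rotation=rot,
        translation=translation,
        chirality_sign=chirality_sign(p, q),
        degenerate=degenerate,
    )


def rmsd_d(p: CAlphaFragment, q: CAlphaFragment) -> float:
    """Root-mean-square difference of internal distances over residue pairs.

    ``sqrt( (1 / C(N,2)) * sum_{i<j} (D_P[i,j] - D_Q[i,j])^2 )`` — no
    superposition involved, hence invariant to isometries and mirroring.
    """
    if len(p) != len(q):
        raise LengthMismatchError(
            f"rmsd_d needs equal lengths, got {len(p)} and {len(q)}"
        )
    n = len(p)
    diff = distance_matrix(p) - distance_matrix(q)
    iu = np.triu_indices(n, k=1)
    return float(np.sqrt(np.sum(diff[iu] ** 2) / math.comb(n, 2)))


def chirality_sign(p: CAlphaFragment, q: CAlphaFragment) -> int:
    """Sign of det(P^T Q) on centered coordinate matrices.

    +1: the match is not a mirror; -1: a better superposition is obtained by
    mirroring one fragment; 0: indeterminate (degenerate geometry, e.g.
    coplanar points make the determinant vanish).  Centering makes the test
    translation-invariant and equal to the sign of the Kabsch covariance
    determinant.
    """
    pc, qc = _centered(p, q)
    h = pc.T @ qc
    s = np.linalg.svd(h, compute_uv=False)
    if s[2] <= _DEGENERATE_RTOL * max(s[0], 1.0):
        return 0
    det = np.linalg.det(h)
    return 1 if det > 0 else -1
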