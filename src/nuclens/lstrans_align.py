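"""Weighted least-squares superposition of point sets by the proper-rotation
polar factor (absolute-orientation problem).

The optimal translation aligns the weighted centroids; the optimal rotation
is obtained from the SVD of the weighted cross-correlation matrix with the
smallest singular direction sign-corrected so that det R = +1.  This is the
orthogonal factor of the polar decomposition restricted to SO(3) and attains
the *global* minimum of the weighted least-squares objective — not merely a
stationary point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AlignmentResult", "best_fit", "apply_transform", "rmsd"]

#: relative singular-value threshold for flagging degenerate (rank-deficient
#: or tie-broken) correlation matrices
_DEGENERACY_RTOL = 1e-8


@dataclass
class AlignmentResult:
    rotation: np.ndarray      # 3×3 proper rotation, det = +1
    translation: np.ndarray   # length 3, Å
    rmsd_before: float
    rmsd_after: float
    degenerate: bool = False


def rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted root-mean-square deviation sqrt(Σw‖a−b‖²/Σw) between two
    equally sized coordinate sets of shape (N, 3)."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    w = _check_weights(weights, len(a))
    d2 = ((a - b) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def _check_weights(weights: np.ndarray | None, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have length {n}")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    return w


def best_fit(moving: np.ndarray, reference: np.ndarray,
             weights: np.ndarray | None = None) -> AlignmentResult:
    """Find the rigid transform (proper rotation + translation) minimizing the
    weighted squared deviation of ``moving`` onto ``reference``.

    Both inputs are (N, 3) arrays with identical atom ordering.  Returns the
    transform together with the weighted RMSD before and at the optimum.
    """
    x = np.asarray(moving, dtype=float).reshape(-1, 3)
    y = np.asarray(reference, dtype=float).reshape(-1, 3)
    if x.shape != y.shape:
        raise ValueError(f"coordinate shapes differ: {x.shape} vs {y.shape}")
    if len(x) < 1:
        raise ValueError("need at least one atom")
    w = _check_weights(weights, len(x))

    rmsd_before = rmsd(x, y, w)

    wsum = w.sum()
    cx = (w[:, None] * x).sum(axis=0) / wsum
    cy = (w[:, None] * y).sum(axis=0) / wsum
    xc = x - cx
    yc = y - cy

    # weighted cross-correlation A = Σ w x xᵀy (3×3)
    a = (w[:, None] * xc).T @ yc
    u, s, vt = np.linalg.svd(a)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    # proper-rotation polar factor: flip the smallest singular direction
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T

    smax = max(s[0], 1.0)
    degenerate = bool(
        s[2] <= _DEGENERACY_RTOL * smax
        or (d < 0 and (s[1] - s[2]) <= _DEGENERACY_RTOL * smax)
        or (s[0] - s[1]) <= _DEGENERACY_RTOL * smax and d < 0
    )

    translation = cy - rot @ cx
    moved = xc @ rot.T + cy
    rmsd_after = rmsd(moved, y, w)
    return AlignmentResult(
        rotation=rot,
        translation=translation,
        rmsd_before=rmsd_before,
        rmsd_after=rmsd_after,
        degenerate=degenerate,
    )


def apply_transform(result: AlignmentResult, coords: np.ndarray) -> np.ndarray:
    """Apply R·x + t to an (M, 3) coordinate array."""
    c = np.asarray(coords, dtype=float).reshape(-1, 3)
    return c @ result.rotation.T + result.translation
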