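"""Registration of serial tissue sections.

Serial 3-μm sections are related to a close approximation by a similarity
transform (rotation + isotropic scale + translation).  The landmark route
solves the least-squares similarity (or full affine) in closed form — the
orthogonal-Procrustes-with-scale (Umeyama) solution; the landmark-free route
refines an initial transform by iterative closest point (ICP) on PCK+
centroids.  ICP can converge to a wrong optimum from a gross initialization;
the fit residual ``rmse_um`` is always reported so such failures are visible.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .io_core import Transform2D


def apply_transform(xy: np.ndarray, t: Transform2D) -> np.ndarray:
    """Map points through ``p -> A p + t``."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return xy @ t.linear.T + t.translation


def invert_transform(t: Transform2D) -> Transform2D:
    inv = np.linalg.inv(t.linear)
    return Transform2D(inv, -inv @ t.translation, kind=t.kind, rmse_um=t.rmse_um)


def compose(outer: Transform2D, inner: Transform2D) -> Transform2D:
    """Transform equivalent to applying ``inner`` then ``outer``."""
    kind = "affine" if "affine" in (outer.kind, inner.kind) else "similarity"
    return Transform2D(
        outer.linear @ inner.linear,
        outer.linear @ inner.translation + outer.translation,
        kind=kind,
    )


def estimate_transform(moving: np.ndarray, fixed: np.ndarray,
                       kind: str = "similarity") -> Transform2D:
    """Least-squares transform mapping paired ``moving`` points onto ``fixed``.

    ``kind="similarity"`` uses the closed-form Umeyama solution (s·R + t,
    det(R) = +1); ``kind="affine"`` solves the normal equations and needs
    ≥ 3 non-collinear pairs.
    """
    moving = np.asarray(moving, dtype=float).reshape(-1, 2)
    fixed = np.asarray(fixed, dtype=float).reshape(-1, 2)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must be paired point sets of equal length")
    n = len(moving)

    if kind == "similarity":
        if n < 2:
            raise ValueError("similarity estimation needs >= 2 point pairs")
        mu_m, mu_f = moving.mean(0), fixed.mean(0)
        X, Y = moving - mu_m, fixed - mu_f
        cov = Y.T @ X / n
        U, D, Vt = np.linalg.svd(cov)
        S = np.eye(2)
        if np.linalg.det(U) * np.linalg.det(Vt) < 0:
            S[1, 1] = -1.0
        R = U @ S @ Vt
        var_m = (X**2).sum() / n
        if var_m == 0:
            raise ValueError("moving points are coincident")
        s = float(np.trace(np.diag(D) @ S) / var_m)
        A = s * R
        t = mu_f - A @ mu_m
    elif kind == "affine":
        if n < 3:
            raise ValueError("affine estimation needs >= 3 point pairs")
        M = np.hstack([moving, np.ones((n, 1))])
        if np.linalg.matrix_rank(M) < 3:
            raise np.linalg.LinAlgError("collinear points: affine fit is rank-deficient")
        sol, *_ = np.linalg.lstsq(M, fixed, rcond=None)
        A = sol[:2].T
        t = sol[2]
    else:
        raise ValueError(f"unknown transform kind {kind!r}")

    out = Transform2D(A, t, kind=kind)
    resid = apply_transform(moving, out) - fixed
    out.rmse_um = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return out


def refine_icp(moving: np.ndarray, fixed: np.ndarray,
               init: Transform2D | None = None, kind: str = "similarity",
               max_iter: int = 50, tol: float = 1e-6) -> Transform2D:
    """Iterative closest point: alternate nearest-neighbor matching and
    closed-form re-estimation until the matched-pair rmse stops improving."""
    moving = np.asarray(moving, dtype=float).reshape(-1, 2)
    fixed = np.asarray(fixed, dtype=float).reshape(-1, 2)
    if len(moving) == 0 or len(fixed) == 0:
        raise ValueError("point clouds must be nonempty")
    t = init or Transform2D.identity()
    tree = cKDTree(fixed)
    prev_rmse = np.inf
    for _ in range(max_iter):
        mapped = apply_transform(moving, t)
        dist, idx = tree.query(mapped)
        rmse = float(np.sqrt((dist**2).mean()))
        if prev_rmse - rmse < tol:
            t.rmse_um = rmse
            break
        prev_rmse = rmse
        t = estimate_transform(moving, fixed[idx], kind=kind)
        t.rmse_um = rmse
    else:
        mapped = apply_transform(moving, t)
        dist, _ = tree.query(mapped)
        t.rmse_um = float(np.sqrt((dist**2).mean()))
    return t
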