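"""Sparse CCA by penalized matrix decomposition (PMD).

One mode of sparse canonical correlation analysis is the rank-1 penalized
decomposition of the cross-product matrix K = X'Y: find unit-L2 weight
vectors u (behavioral) and v (imaging) maximizing u' K v subject to the L1
bounds ||u||_1 <= c_x and ||v||_1 <= c_y, with c in [1, sqrt(dim)].  The
solution alternates closed-form updates, each a soft-thresholding of K v
(resp. K' u) followed by L2 normalization, with the threshold chosen by
binary search so the L1 bound holds.

Only the first mode is fitted; deflation to further modes is out of scope.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .data_io import StandardizedPair

__all__ = ["SCCAModel", "DegenerateFitError", "soft_threshold",
           "l1_unit_vector", "fit_scca"]


class DegenerateFitError(RuntimeError):
    """The alternating updates produced an identically-zero weight vector."""


@dataclass
class SCCAModel:
    """A fitted sparse-CCA mode.

    Attributes
    ----------
    wx, wy : ndarray
        Unit-L2 sparse weight vectors for the behavioral (p) and imaging (q)
        blocks.
    cx, cy : float
        The L1 bounds the fit was run at.
    r : float
        Canonical correlation — the Pearson correlation of the two variates.
    variate_x, variate_y : ndarray
        X @ wx and Y @ wy.
    objective_path : list of float
        u'Kv after each alternating iteration (non-decreasing).
    """

    wx: np.ndarray
    wy: np.ndarray
    cx: float
    cy: float
    r: float
    variate_x: np.ndarray
    variate_y: np.ndarray
    n_iter: int
    converged: bool
    objective_path: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cx": self.cx, "cy": self.cy, "r": self.r,
            "n_iter": self.n_iter, "converged": self.converged,
            "wx": self.wx.tolist(), "wy": self.wy.tolist(),
        }


def soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise sign(a_i) * max(|a_i| - delta, 0); delta >= 0."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def l1_unit_vector(a: np.ndarray, c: float, tol: float = 1e-10) -> np.ndarray:
    """Soft-threshold ``a`` and L2-normalize so that the L1 norm is <= c.

    Returns w = S(a, d) / ||S(a, d)||_2 for the smallest threshold d >= 0
    (binary search on d to ``tol``) satisfying ||w||_1 <= c.  With c = 1 the
    result has a single nonzero; with c >= ||a||_1/||a||_2 no shrinkage is
    applied.  ``c`` must lie in [1, sqrt(len(a))].
    """
    a = np.asarray(a, dtype=float)
    if not 1 <= c <= np.sqrt(a.size) + 1e-12:
        raise ValueError(f"c={c} outside [1, sqrt({a.size})]")
    norm = np.linalg.norm(a)
    if norm == 0:
        raise DegenerateFitError("zero input vector")
    w = a / norm
    if np.abs(w).sum() <= c + 1e-9:  # slack absorbs exact-tie roundoff
        return w
    # bisect on the threshold d; the L1/L2 ratio of S(a, d) is continuous and
    # strictly decreasing on (0, max|a|).  Sorted cumulative sums make each
    # ratio evaluation O(log d) instead of a full soft-threshold pass; plain
    # Python floats here beat numpy scalar dispatch by an order of magnitude.
    abs_asc = np.sort(np.abs(a))
    cum1 = [0.0]
    cum2 = [0.0]
    for v in abs_asc[::-1].tolist():
        cum1.append(cum1[-1] + v)
        cum2.append(cum2[-1] + v * v)
    asc_list = abs_asc.tolist()
    d = len(asc_list)

    def ratio(delta: float) -> float:
        k = d - bisect_right(asc_list, delta)
        if k == 0:
            return 0.0
        l1 = cum1[k] - k * delta
        l2sq = cum2[k] - 2.0 * delta * cum1[k] + k * delta * delta
        if l2sq <= 0.0:
            return math.inf
        return l1 / math.sqrt(l2sq)

    lo, hi = 0.0, asc_list[-1]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ratio(mid) > c:
            lo = mid
        else:
            hi = mid
    s = soft_threshold(a, hi)
    n2 = np.linalg.norm(s)
    if n2 == 0:
        raise DegenerateFitError("soft threshold annihilated the vector")
    return s / n2


def _pmd_rank1(K: np.ndarray, cx: float, cy: float, max_iter: int = 100,
               tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray, int, bool,
                                           list[float]]:
    """Alternating L1-constrained rank-1 updates of the cross matrix K (p x q).

    wy is initialized from the leading right singular vector of K
    (deterministic), so repeated fits are bit-reproducible.  The objective
    u'Kv is checked to be non-decreasing across iterations.
    """
    # leading right singular vector; economy SVD is cheap at these shapes
    _, _, vt = np.linalg.svd(K, full_matrices=False)
    wy = vt[0]
    wx = np.zeros(K.shape[0])
    obj_path: list[float] = []
    prev_obj = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wx_new = l1_unit_vector(K @ wy, cx)
        wy_new = l1_unit_vector(K.T @ wx_new, cy)
        obj = float(wx_new @ K @ wy_new)
        # slack covers the finite-precision threshold search; near-tied
        # solutions (e.g. exactly collinear columns) oscillate at this scale
        if obj < prev_obj - 1e-6 * max(1.0, abs(prev_obj)):
            raise RuntimeError(
                f"PMD objective decreased ({prev_obj} -> {obj})")
        obj_path.append(obj)
        delta = max(np.abs(wx_new - wx).max(), np.abs(wy_new - wy).max())
        wx, wy = wx_new, wy_new
        prev_obj = obj
        if delta < tol:
            converged = True
            break
    return wx, wy, it, converged, obj_path


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def fit_scca(pair: StandardizedPair, cx: float, cy: float,
             max_iter: int = 100, tol: float = 1e-6,
             seed: int | None = None, check_standardized: bool = True
             ) -> SCCAModel:
    """Fit the first sparse-CCA mode of a standardized block pair.

    Parameters
    ----------
    pair : StandardizedPair
        Row-aligned z-scored blocks (X: n x p behavioral, Y: n x q imaging).
    cx, cy : float
        L1 bounds on the weight vectors, in [1, sqrt(p)] and [1, sqrt(q)];
        smaller values give sparser weights.
    seed : int, optional
        Unused by the deterministic SVD initialization; accepted so callers
        can thread a seed through uniformly (reserved for random restarts).

    Notes
    -----
    The sign of a CCA mode is arbitrary.  The convention here: flip wy so the
    canonical correlation is non-negative, then flip (wx, wy) jointly so the
    largest-magnitude behavioral weight is positive.
    """
    X, Y = pair.X, pair.Y
    if check_standardized:
        for M, lab in ((X, "X"), (Y, "Y")):
            if (np.abs(M.mean(axis=0)).max() > 1e-8
                    or np.abs(M.std(axis=0, ddof=1) - 1).max() > 1e-6):
                raise ValueError(
                    f"{lab} is not z-standardized; use standardize_pair first")
    p, q = X.shape[1], Y.shape[1]
    if not 1 <= cx <= np.sqrt(p) + 1e-12:
        raise ValueError(f"cx={cx} outside [1, sqrt({p})]")
    if not 1 <= cy <= np.sqrt(q) + 1e-12:
        raise ValueError(f"cy={cy} outside [1, sqrt({q})]")
    K = X.T @ Y
    wx, wy, n_iter, converged, obj_path = _pmd_rank1(
        K, cx, cy, max_iter=max_iter, tol=tol)
    vx, vy = X @ wx, Y @ wy
    r = _pearson(vx, vy)
    if np.isnan(r):
        raise DegenerateFitError("constant canonical variate")
    if r < 0:
        wy, vy, r = -wy, -vy, -r
    j = int(np.argmax(np.abs(wx)))
    if wx[j] < 0:
        wx, wy, vx, vy = -wx, -wy, -vx, -vy
    return SCCAModel(wx=wx, wy=wy, cx=float(cx), cy=float(cy), r=r,
                     variate_x=vx, variate_y=vy, n_iter=n_iter,
                     converged=converged, objective_path=obj_path)
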