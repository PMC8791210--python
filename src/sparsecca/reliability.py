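"""Stability and out-of-sample validity of a sparse-CCA mode.

Three complementary resampling checks:

* **Leave-one-out (LOO) weight stability** — refit with each subject removed
  and correlate the refit weight vector with the full-sample one; values near
  1 mean no single subject drives the mode.
* **RR-score** — for many random half-splits, fit on the training half,
  compute the test half's variable-to-variate loading vector with the
  training weights, and correlate each split's loading vector with the mean
  loading vector over all splits.  Scores near 1 mean any test half
  reproduces the same variable-association profile; the per-split scores are
  floored at 0 so the index lives in [0, 1], and summarized by their median
  and standard deviation.
* **Split-half prediction** — fit on the training half, project the held-out
  half with the training weights, and record the correlation of the held-out
  variates: the mode's out-of-sample predictive validity.

Every refit's sign is arbitrary, so refits are sign-aligned to the
full-sample solution before any correlation is taken.  Half-splits are
stratified by group label when labels exist, so both groups appear in every
half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import StandardizedPair, zscore
from .pmd import DegenerateFitError, fit_scca

__all__ = ["LOOResult", "ReliabilityReport", "loo_stability", "rr_score",
           "split_half_prediction", "reliability_report"]


@dataclass
class LOOResult:
    """Per-subject leave-one-out weight-stability correlations."""

    corrs: np.ndarray        # concatenated (wx, wy) correlation, length n
    corrs_x: np.ndarray      # behavioral-side weights only
    corrs_y: np.ndarray      # imaging-side weights only
    failed_subjects: list[int]


@dataclass
class ReliabilityReport:
    """Full reliability suite for one fitted mode."""

    loo_corrs: np.ndarray
    rr_scores: np.ndarray
    rr_median: float
    rr_sd: float
    splithalf_rs: np.ndarray
    splithalf_mean: float
    splithalf_sd: float
    n_splits: int
    seed: int
    n_skipped_rr: int = 0
    n_skipped_splithalf: int = 0

    def summary(self) -> dict:
        return {
            "loo_min": float(np.min(self.loo_corrs)),
            "loo_median": float(np.median(self.loo_corrs)),
            "rr_median": self.rr_median,
            "rr_sd": self.rr_sd,
            "splithalf_mean": self.splithalf_mean,
            "splithalf_sd": self.splithalf_sd,
            "n_splits": self.n_splits,
            "seed": self.seed,
            "n_skipped_rr": self.n_skipped_rr,
            "n_skipped_splithalf": self.n_skipped_splithalf,
        }


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def _refit_subset(pair: StandardizedPair, rows: np.ndarray, cx: float,
                  cy: float, max_iter: int, tol: float):
    """Re-standardize a row subset and fit; the subset loses exact z-scoring."""
    sub = StandardizedPair(
        X=zscore(pair.X[rows]), Y=zscore(pair.Y[rows]),
        names_x=pair.names_x, names_y=pair.names_y)
    return fit_scca(sub, cx, cy, max_iter=max_iter, tol=tol,
                    check_standardized=False)


def loo_stability(pair: StandardizedPair, cx: float, cy: float,
                  max_iter: int = 100, tol: float = 1e-6) -> LOOResult:
    """Leave-one-out weight stability at fixed sparsity bounds.

    For each subject i the remaining n-1 rows are re-standardized and refit;
    the refit weights are sign-aligned to the full-sample fit and the Pearson
    correlation of the concatenated (wx, wy) vectors is recorded (per-side
    correlations are retained as well).  A degenerate refit is recorded as
    NaN with the subject listed in ``failed_subjects``.
    """
    n = pair.n
    if n < 10:
        raise ValueError("leave-one-out requires at least 10 subjects")
    full = fit_scca(pair, cx, cy, max_iter=max_iter, tol=tol)
    w_full = np.concatenate([full.wx, full.wy])
    corrs = np.full(n, np.nan)
    corrs_x = np.full(n, np.nan)
    corrs_y = np.full(n, np.nan)
    failed: list[int] = []
    for i in range(n):
        rows = np.delete(np.arange(n), i)
        try:
            m = _refit_subset(pair, rows, cx, cy, max_iter, tol)
        except DegenerateFitError:
            failed.append(i)
            continue
        w = np.concatenate([m.wx, m.wy])
        if _corr(w, w_full) < 0:
            w = -w
        corrs[i] = _corr(w, w_full)
        corrs_x[i] = _corr(w[:full.wx.size], full.wx)
        corrs_y[i] = _corr(w[full.wx.size:], full.wy)
    return LOOResult(corrs=corrs, corrs_x=corrs_x, corrs_y=corrs_y,
                     failed_subjects=failed)


def _half_split(n: int, rng: np.random.Generator,
                group_labels=None) -> tuple[np.ndarray, np.ndarray]:
    """Random half/half partition, stratified by group when labels exist.

    Training and test sizes differ by at most 1 overall and per group.
    """
    if group_labels is None:
        perm = rng.permutation(n)
        return perm[: n // 2], perm[n // 2:]
    group_labels = np.asarray(group_labels, dtype=object)
    train_parts, test_parts = [], []
    for g in dict.fromkeys(group_labels):  # first-appearance order
        idx = np.flatnonzero(group_labels == g)
        perm = idx[rng.permutation(idx.size)]
        train_parts.append(perm[: idx.size // 2])
        test_parts.append(perm[idx.size // 2:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


def _test_loadings(pair: StandardizedPair, rows: np.ndarray, wx: np.ndarray,
                   wy: np.ndarray, use_own_stats: bool) -> np.ndarray:
    """Concatenated variable-to-opposing-variate correlations on a test half.

    Test rows are re-standardized with their own means/sds by default
    (loadings are scale-free correlations, so this only guards against
    subset-induced offsets); projecting raw training-standardized rows is
    available as the alternative.
    """
    Xt, Yt = pair.X[rows], pair.Y[rows]
    if use_own_stats:
        sx = Xt.std(axis=0, ddof=1)
        sy = Yt.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            Xt = np.where(sx > 0, (Xt - Xt.mean(axis=0)) / sx, 0.0)
            Yt = np.where(sy > 0, (Yt - Yt.mean(axis=0)) / sy, 0.0)
    vx, vy = Xt @ wx, Yt @ wy
    out = np.empty(Xt.shape[1] + Yt.shape[1])
    for block, v, sl in ((Xt, vy, slice(0, Xt.shape[1])),
                         (Yt, vx, slice(Xt.shape[1], None))):
        C = block - block.mean(axis=0)
        norms = np.linalg.norm(C, axis=0)
        vv = v - v.mean()
        nv = np.linalg.norm(vv)
        with np.errstate(invalid="ignore", divide="ignore"):
            ld = (C.T @ vv) / (norms * nv)
        out[sl] = np.where((norms == 0) | (nv == 0), np.nan, ld)
    return out


def rr_score(pair: StandardizedPair, cx: float, cy: float,
             n_splits: int = 5000, seed: int = 0,
             use_own_stats: bool = True, max_iter: int = 100,
             tol: float = 1e-6
             ) -> tuple[np.ndarray, float, float, int]:
    """Redundancy-reliability of the mode's loading profile across half-splits.

    Returns (rr_scores, rr_median, rr_sd, n_skipped).  Each split's test-half
    loading vector is sign-aligned to the full-sample loading vector, then
    correlated with the elementwise mean of all splits' vectors; per-split
    values are floored at 0.  Degenerate training fits are skipped and
    counted.
    """
    if pair.n < 10:
        raise ValueError("half-split reliability requires at least 10 subjects")
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    full = fit_scca(pair, cx, cy, max_iter=max_iter, tol=tol)
    l_full = np.concatenate([
        _col_corrs(pair.X, pair.Y @ full.wy),
        _col_corrs(pair.Y, pair.X @ full.wx),
    ])
    rng = np.random.default_rng(seed)
    vectors = []
    skipped = 0
    for _ in range(n_splits):
        train, test = _half_split(pair.n, rng, pair.group_labels)
        try:
            m = _refit_subset(pair, train, cx, cy, max_iter, tol)
        except DegenerateFitError:
            skipped += 1
            continue
        L = _test_loadings(pair, test, m.wx, m.wy, use_own_stats)
        if _corr(L, l_full) < 0:
            L = -L
        vectors.append(L)
    if not vectors:
        raise DegenerateFitError("every training split degenerated")
    Lmat = np.vstack(vectors)
    mean_L = np.nanmean(Lmat, axis=0)
    scores = np.array([max(_corr(L, mean_L), 0.0) for L in Lmat])
    return scores, float(np.median(scores)), float(scores.std(ddof=1)), skipped


def split_half_prediction(pair: StandardizedPair, cx: float, cy: float,
                          n_splits: int = 5000, seed: int = 0,
                          use_own_stats: bool = True, max_iter: int = 100,
                          tol: float = 1e-6
                          ) -> tuple[np.ndarray, float, float, int]:
    """Out-of-sample variate correlation across random half-splits.

    Each split fits on the training half and applies the training weights to
    the re-standardized held-out half; the recorded r_s is the Pearson
    correlation of the held-out variates.  Returns
    (splithalf_rs, mean, sd, n_skipped).
    """
    if pair.n < 10:
        raise ValueError("half-split reliability requires at least 10 subjects")
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    rng = np.random.default_rng(seed)
    rs = []
    skipped = 0
    for _ in range(n_splits):
        train, test = _half_split(pair.n, rng, pair.group_labels)
        try:
            m = _refit_subset(pair, train, cx, cy, max_iter, tol)
        except DegenerateFitError:
            skipped += 1
            continue
        Xt, Yt = pair.X[test], pair.Y[test]
        if use_own_stats:
            Xt, Yt = zscore(Xt), zscore(Yt)
        rs.append(_corr(Xt @ m.wx, Yt @ m.wy))
    if not rs:
        raise DegenerateFitError("every training split degenerated")
    rs = np.asarray(rs)
    return rs, float(rs.mean()), float(rs.std(ddof=1)), skipped


def _col_corrs(block: np.ndarray, v: np.ndarray) -> np.ndarray:
    C = block - block.mean(axis=0)
    norms = np.linalg.norm(C, axis=0)
    vv = v - v.mean()
    nv = np.linalg.norm(vv)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (C.T @ vv) / (norms * nv)
    return np.where(norms == 0, np.nan, out)


def reliability_report(pair: StandardizedPair, cx: float, cy: float,
                       n_splits: int = 5000, seed: int = 0,
                       max_iter: int = 100, tol: float = 1e-6
                       ) -> ReliabilityReport:
    """Run the full reliability suite and collect the summaries."""
    loo = loo_stability(pair, cx, cy, max_iter=max_iter, tol=tol)
    rr, rr_med, rr_sd, skip_rr = rr_score(
        pair, cx, cy, n_splits=n_splits, seed=seed,
        max_iter=max_iter, tol=tol)
    sh, sh_mean, sh_sd, skip_sh = split_half_prediction(
        pair, cx, cy, n_splits=n_splits, seed=seed + 1,
        max_iter=max_iter, tol=tol)
    return ReliabilityReport(
        loo_corrs=loo.corrs, rr_scores=rr, rr_median=rr_med, rr_sd=rr_sd,
        splithalf_rs=sh, splithalf_mean=sh_mean, splithalf_sd=sh_sd,
        n_splits=int(n_splits), seed=int(seed),
        n_skipped_rr=skip_rr, n_skipped_splithalf=skip_sh)
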