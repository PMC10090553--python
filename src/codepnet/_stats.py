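"""Vectorised pairwise-complete correlation kernels.

Many-vs-one Pearson and Spearman with per-pair missingness masks: each row of
``X`` is correlated against ``y`` using only the positions where both values
are finite, which is how dependency screens over DepMap-style matrices (with
unstructured gene x line gaps) must behave.  Two-sided p-values come from the
t transform ``t = r * sqrt((n - 2) / (1 - r^2))`` with ``n - 2`` degrees of
freedom, i.e. the exact-null test for bivariate-normal data and the classic
approximation for Spearman's rho.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

_TINY = np.finfo(np.float64).tiny


def masked_pearson(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise-complete Pearson r of every row of X against y.

    Parameters
    ----------
    X : (g, n) array, NaN = missing
    y : (n,) array, NaN = missing

    Returns
    -------
    r, p_two_sided, n_used : (g,) arrays.  r is NaN where fewer than 3
    complete pairs exist or either vector is constant on the complete pairs;
    p is NaN wherever r is.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or y.ndim != 1 or X.shape[1] != y.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape} vs y {y.shape}")
    mask = np.isfinite(X) & np.isfinite(y)[None, :]
    n = mask.sum(axis=1)
    Xm = np.where(mask, X, 0.0)
    Ym = np.where(mask, y[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Xm.sum(axis=1) / n
        my = Ym.sum(axis=1) / n
        Xc = np.where(mask, X - mx[:, None], 0.0)
        Yc = np.where(mask, y[None, :] - my[:, None], 0.0)
        sxy = (Xc * Yc).sum(axis=1)
        sxx = (Xc * Xc).sum(axis=1)
        syy = (Yc * Yc).sum(axis=1)
        r = sxy / np.sqrt(sxx * syy)
    # Constant-on-complete-pairs detection is exact (range of masked values),
    # not a float tolerance on the variance.
    hi = np.where(mask, X, -np.inf).max(axis=1)
    lo = np.where(mask, X, np.inf).min(axis=1)
    const_x = hi == lo
    yhi = np.where(mask, y[None, :], -np.inf).max(axis=1)
    ylo = np.where(mask, y[None, :], np.inf).min(axis=1)
    const_y = yhi == ylo
    bad = (n < 3) | const_x | const_y
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    p = _r_to_p(r, n)
    return r, p, n


def _r_to_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t transform; floored at the smallest positive float."""
    with np.errstate(invalid="ignore", divide="ignore"):
        df = n - 2
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, np.clip(p, _TINY, 1.0))
    return p


def masked_spearman(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise-complete Spearman rho (Pearson on midranks) of rows of X vs y.

    Ranks are recomputed per row because the complete-pair mask differs per
    row: the anchor's ranks must be taken over exactly the positions present
    for that gene.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    mask = np.isfinite(X) & np.isfinite(y)[None, :]
    Xm = np.where(mask, X, np.nan)
    Ym = np.where(mask, y[None, :], np.nan)
    rx = stats.rankdata(Xm, axis=1, nan_policy="omit")
    ry = stats.rankdata(Ym, axis=1, nan_policy="omit")
    # rankdata leaves NaN in place for omitted entries, so the Pearson kernel
    # sees the same mask.
    return _masked_pearson_rows(rx, ry)


def _masked_pearson_rows(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise pairwise-complete Pearson between two equally-shaped matrices."""
    mask = np.isfinite(X) & np.isfinite(Y)
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(mask, X, 0.0).sum(axis=1) / n
        my = np.where(mask, Y, 0.0).sum(axis=1) / n
        Xc = np.where(mask, X - mx[:, None], 0.0)
        Yc = np.where(mask, Y - my[:, None], 0.0)
        r = (Xc * Yc).sum(axis=1) / np.sqrt((Xc * Xc).sum(axis=1) * (Yc * Yc).sum(axis=1))
    hix = np.where(mask, X, -np.inf).max(axis=1)
    lox = np.where(mask, X, np.inf).min(axis=1)
    hiy = np.where(mask, Y, -np.inf).max(axis=1)
    loy = np.where(mask, Y, np.inf).min(axis=1)
    bad = (n < 3) | (hix == lox) | (hiy == loy)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    return r, _r_to_p(r, n), n


def pearson_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Single-pair pairwise-complete Pearson (r, p, n)."""
    r, p, n = masked_pearson(np.asarray(x, dtype=float)[None, :], np.asarray(y, dtype=float))
    return float(r[0]), float(p[0]), int(n[0])


def spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Single-pair pairwise-complete Spearman (rho, p, n)."""
    r, p, n = masked_spearman(np.asarray(x, dtype=float)[None, :], np.asarray(y, dtype=float))
    return float(r[0]), float(p[0]), int(n[0])
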