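"""Detection of features dynamically regulated along a pseudotime.

Pseudotime itself is an input (inferred upstream, e.g. by diffusion maps
plus principal curves).  Each feature is fitted with a Gaussian
identity-link additive model realized as a fixed-knot cubic B-spline
regression (default 4 spline degrees of freedom, interior knots at
pseudotime quantiles) and tested against the intercept-only model with an
exact F-test.  P-values are corrected across features by Benjamini-
Hochberg; features with q below the threshold are called dynamic, with a
direction summary from the fitted curve's endpoints.  LOESS-style local
linear smoothing with tricube weights provides display curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.interpolate
import scipy.stats

from .stats import bh_adjust


class DynamicsError(ValueError):
    pass


P_FLOOR = 1e-300  # numerical floor; perfect fits report p < 1e-12 anyway


def spline_basis(pseudotime: np.ndarray, df: int = 4) -> np.ndarray:
    """Cubic B-spline basis with ``df`` columns (intercept excluded).

    Interior knots (df − 3 of them) sit at pseudotime quantiles; boundary
    knots at the range.  Mirrors the usual regression-spline basis used
    for additive-model smooth terms.
    """
    t = np.asarray(pseudotime, dtype=float)
    if df < 3:
        raise DynamicsError("spline df must be >= 3 (cubic)")
    lo, hi = t.min(), t.max()
    if lo == hi:
        raise DynamicsError("constant pseudotime")
    n_interior = df - 3
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(t, qs)
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    design = scipy.interpolate.BSpline.design_matrix(
        np.clip(t, lo, hi), knots, 3
    ).toarray()
    # drop the first column: with the model intercept it spans the constant
    return design[:, 1:]


@dataclass(frozen=True)
class DynamicTestResult:
    feature_id: str
    fit_df: int
    f_statistic: float
    p_value: float
    q_value: float | None = None
    direction: str | None = None


def _fit_f_test(
    values: np.ndarray, basis: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """F-test of the spline model against intercept-only; returns
    (F, p, fitted values)."""
    n, k = basis.shape
    design = np.column_stack([np.ones(n), basis])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    fitted = design @ beta
    rss1 = float(((values - fitted) ** 2).sum())
    rss0 = float(((values - values.mean()) ** 2).sum())
    df_resid = n - k - 1
    if df_resid <= 0:
        raise DynamicsError("not enough cells for the spline degrees of freedom")
    if rss0 <= 0:
        return 0.0, 1.0, fitted  # constant values: nothing to explain
    if rss1 <= 1e-12 * rss0:
        return np.inf, P_FLOOR, fitted  # perfect fit limit
    f = ((rss0 - rss1) / k) / (rss1 / df_resid)
    p = float(scipy.stats.f.sf(f, k, df_resid))
    return float(f), max(p, P_FLOOR), fitted


def _direction(fitted_sorted: np.ndarray) -> str:
    """Direction by endpoint comparison of the fitted curve.

    If the endpoint change covers at least half the fitted range the
    curve is called increasing/decreasing; otherwise non-monotone.
    """
    span = fitted_sorted[-1] - fitted_sorted[0]
    rng = fitted_sorted.max() - fitted_sorted.min()
    if rng == 0 or abs(span) < 0.5 * rng:
        return "non-monotone"
    return "increasing" if span > 0 else "decreasing"


def dynamic_feature_test(
    values, pseudotime, spline_df: int = 4, feature_id: str = "feature"
) -> DynamicTestResult:
    """Test one feature for dynamic regulation along pseudotime."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(t)):
        raise DynamicsError("pseudotime must be finite")
    if v.size != t.size:
        raise DynamicsError("values and pseudotime must have equal length")
    if v.size < spline_df + 2:
        raise DynamicsError(f"need at least {spline_df + 2} cells")
    basis = spline_basis(t, spline_df)
    f, p, fitted = _fit_f_test(v, basis)
    order = np.argsort(t, kind="stable")
    return DynamicTestResult(
        feature_id=feature_id,
        fit_df=spline_df,
        f_statistic=f,
        p_value=p,
        direction=_direction(fitted[order]),
    )


def screen_dynamic(
    matrix,
    pseudotime,
    q_threshold: float = 0.05,
    spline_df: int = 4,
    hvg_fraction: float | None = None,
) -> pd.DataFrame:
    """Screen a features x cells matrix for pseudotime-dynamic features.

    Fits every (optionally variance-pre-filtered) feature, corrects
    p-values across tested features by Benjamini-Hochberg, and returns a
    table sorted by q with columns (feature_id, fit_df, f_statistic, p,
    q, dynamic, direction).  ``hvg_fraction`` keeps the top fraction of
    features by variance of log1p signal before testing.
    """
    df_in = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if df_in else np.asarray(matrix, dtype=float)
    names = list(matrix.index) if df_in else [f"f{i}" for i in range(x.shape[0])]
    t = np.asarray(pseudotime, dtype=float)
    if x.shape[0] == 0:
        return pd.DataFrame(
            columns=[
                "feature_id", "fit_df", "f_statistic", "p_value", "q_value",
                "dynamic", "direction",
            ]
        )
    if x.shape[1] != t.size:
        raise DynamicsError("matrix columns must match pseudotime length")
    if hvg_fraction is not None:
        if not 0 < hvg_fraction <= 1:
            raise DynamicsError("hvg_fraction must be in (0, 1]")
        var = np.log1p(np.clip(x, 0, None)).var(axis=1)
        k = max(1, int(round(hvg_fraction * x.shape[0])))
        keep = np.sort(np.argsort(-var, kind="stable")[:k])
        x, names = x[keep], [names[i] for i in keep]

    basis = spline_basis(t, spline_df)
    n, kb = basis.shape[0], basis.shape[1]
    design = np.column_stack([np.ones(n), basis])
    # batched least squares across features
    pinv = np.linalg.pinv(design)
    beta = pinv @ x.T  # (k+1) x features
    fitted = design @ beta  # cells x features
    resid = x.T - fitted
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((x.T - x.T.mean(axis=0)) ** 2).sum(axis=0)
    df_resid = n - kb - 1
    if df_resid <= 0:
        raise DynamicsError("not enough cells for the spline degrees of freedom")
    with np.errstate(invalid="ignore", divide="ignore"):
        f = ((rss0 - rss1) / kb) / (rss1 / df_resid)
    p = scipy.stats.f.sf(f, kb, df_resid)
    p = np.where(rss0 <= 0, 1.0, p)
    p = np.where((rss1 <= 1e-12 * rss0) & (rss0 > 0), P_FLOOR, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), P_FLOOR, 1.0)
    q = bh_adjust(p)
    order_t = np.argsort(t, kind="stable")
    directions = [
        _direction(fitted[order_t, j]) if q[j] < q_threshold else None
        for j in range(len(names))
    ]
    out = pd.DataFrame(
        {
            "feature_id": names,
            "fit_df": spline_df,
            "f_statistic": f,
            "p_value": p,
            "q_value": q,
            "dynamic": q < q_threshold,
            "direction": directions,
        }
    )
    return out.sort_values(["q_value", "feature_id"], kind="stable").reset_index(
        drop=True
    )


def loess_smooth(
    values, pseudotime, span: float = 0.75, grid_size: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """LOESS-style smoothed conditional mean on a pseudotime grid.

    Local linear fits with tricube weights over the ``span`` fraction of
    nearest points, evaluated at ``grid_size`` evenly spaced grid points.
    Returns (grid, fitted).  Deterministic; no robustness iterations.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    n = v.size
    if n < 10:
        raise DynamicsError("need at least 10 points for smoothing")
    if not 0 < span <= 1:
        raise DynamicsError("span must be in (0, 1]")
    k = int(np.ceil(span * n))
    if k < 3:
        raise DynamicsError(f"span {span} gives only {k} local points; need >= 3")
    grid = np.linspace(t.min(), t.max(), grid_size)
    fitted = np.empty(grid_size)
    for i, g in enumerate(grid):
        d = np.abs(t - g)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = np.finfo(float).tiny
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        sw = w.sum()
        if sw == 0:
            fitted[i] = v[np.argmin(d)]
            continue
        # weighted local line: solve 2x2 normal equations
        tw = t - g
        s0, s1, s2 = sw, (w * tw).sum(), (w * tw**2).sum()
        b0, b1 = (w * v).sum(), (w * v * tw).sum()
        det = s0 * s2 - s1**2
        if det <= np.finfo(float).tiny * max(s0 * s2, 1.0):
            fitted[i] = b0 / s0
        else:
            fitted[i] = (s2 * b0 - s1 * b1) / det
    return grid, fitted
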