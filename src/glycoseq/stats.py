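"""Statistical toolbox for glycan-profile comparisons.

Contains the Brunner-Munzel rank test (a two-sample test of stochastic
equality that assumes neither normality nor equal variances), multiple-
testing corrections, Pearson correlation utilities, mean-centered PCA,
and the adjusted Rand index for comparing partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import adjusted_rand_score


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Brunner-Munzel


@dataclass(frozen=True)
class BMTestResult:
    """Result of a Brunner-Munzel test.

    ``effect_estimate`` is the probability that a draw from the second
    sample exceeds a draw from the first, ties counted half:
    P(X < Y) + 0.5 P(X = Y).  ``degenerate`` flags zero rank variance
    (e.g. complete separation), where the t reference is undefined and
    the p-value is reported as NaN.
    """

    statistic: float
    degrees_of_freedom: float
    p_value: float
    effect_estimate: float
    degenerate: bool = False
    adjusted_p: float | None = None


def brunner_munzel(x, y) -> BMTestResult:
    """Brunner-Munzel test from midrank formulas.

    The estimate p_hat = (mean pooled midrank of y − (n_y+1)/2) / n_x;
    the variance is built from the two within-sample rank variances;
    the statistic n_x n_y (mean_ry − mean_rx) / (N sqrt(n_x S_x^2 +
    n_y S_y^2)) is referred to a t distribution with Satterthwaite-type
    degrees of freedom.  Two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise StatsError("each sample needs at least 2 observations")
    N = nx + ny
    pooled = np.concatenate([x, y])
    r = scipy.stats.rankdata(pooled)  # midranks
    rx, ry = r[:nx], r[nx:]
    rx_within = scipy.stats.rankdata(x)
    ry_within = scipy.stats.rankdata(y)
    mx, my = rx.mean(), ry.mean()
    effect = (my - (ny + 1) / 2.0) / nx
    sx2 = np.sum((rx - rx_within - mx + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy2 = np.sum((ry - ry_within - my + (ny + 1) / 2.0) ** 2) / (ny - 1)
    pooled_var = nx * sx2 + ny * sy2
    if pooled_var <= 0:
        stat = np.inf if my > mx else (-np.inf if my < mx else 0.0)
        return BMTestResult(
            statistic=float(stat),
            degrees_of_freedom=float("nan"),
            p_value=float("nan") if stat != 0 else 1.0,
            effect_estimate=float(effect),
            degenerate=stat != 0,
        )
    stat = nx * ny * (my - mx) / (N * np.sqrt(pooled_var))
    df = pooled_var**2 / ((nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1))
    p = 2.0 * scipy.stats.t.sf(abs(stat), df)
    return BMTestResult(
        statistic=float(stat),
        degrees_of_freedom=float(df),
        p_value=float(min(p, 1.0)),
        effect_estimate=float(effect),
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: min(1, m * p); m defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must be in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must be in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# correlation


def correlation_matrix(profiles) -> tuple[pd.DataFrame, list[str]]:
    """Probe-probe Pearson correlation over cells.

    ``profiles`` is cells x probes (DataFrame or array).  Constant probes
    have their off-diagonal entries set to 0 and are returned as flags;
    the diagonal is always 1.
    """
    df = isinstance(profiles, pd.DataFrame)
    x = profiles.to_numpy(dtype=float) if df else np.asarray(profiles, dtype=float)
    if x.shape[0] < 3:
        raise StatsError("need at least 3 cells for correlation")
    names = list(profiles.columns) if df else [f"p{i}" for i in range(x.shape[1])]
    sd = x.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    flagged = [n for n, c in zip(names, constant) if c]
    return pd.DataFrame(corr, index=names, columns=names), flagged


def gene_feature_correlation(expression, feature) -> pd.DataFrame:
    """Pearson correlation of every gene with a per-cell feature.

    ``expression`` is genes x cells; ``feature`` is a per-cell signal
    (e.g. a lectin).  Returns a table (gene, r, constant) sorted by r
    descending, ties broken lexicographically by gene id.  Constant genes
    get r = 0 and are flagged.
    """
    df = isinstance(expression, pd.DataFrame)
    x = expression.to_numpy(dtype=float) if df else np.asarray(expression, dtype=float)
    f = np.asarray(feature, dtype=float)
    if x.shape[1] != f.size:
        raise StatsError("expression columns must match feature cells")
    genes = list(expression.index) if df else [f"g{i}" for i in range(x.shape[0])]
    xc = x - x.mean(axis=1, keepdims=True)
    fc = f - f.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sf = np.sqrt((fc**2).sum())
    constant = sx == 0
    if sf == 0:
        raise StatsError("feature is constant across cells")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = xc @ fc / (sx * sf)
    r[constant] = 0.0
    out = pd.DataFrame({"gene": genes, "r": r, "constant": constant})
    out = out.sort_values(["r", "gene"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components, orthonormal columns
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    centering: np.ndarray


def pca(matrix, n_components: int | None = None) -> PCAResult:
    """Mean-centered PCA via singular value decomposition.

    No variance scaling is applied (mean-centering only).  Sign
    convention: the largest-magnitude loading of each component is
    positive.  ``n_components`` beyond the matrix rank is truncated with
    a warning.
    """
    x = np.asarray(
        matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else matrix, dtype=float
    )
    n, m = x.shape
    if n < 2:
        raise StatsError("need at least 2 samples")
    center = x.mean(axis=0)
    xc = x - center
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(n, m) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n_components is None:
        n_components = rank
    elif n_components > rank:
        import warnings

        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    loadings = vt[:n_components].T
    # deterministic sign: largest |loading| positive per component
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
    scores = xc @ loadings
    var = (s[:n_components] ** 2) / (n - 1)
    total_var = (s**2).sum() / (n - 1)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance=var,
        explained_variance_ratio=var / total_var if total_var > 0 else var * 0.0,
        centering=center,
    )


# ---------------------------------------------------------------------------
# partitions


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (pair counting)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise StatsError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))
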