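"""Partial least squares linking gene expression to lectin signals.

Given paired per-cell matrices X (cells x genes) and Y (cells x lectins),
PLS extracts components maximizing the covariance between the X scores T
and Y scores U, decomposing the processed blocks as

    X = T P' + E        Y = U Q' + F

Components are extracted by NIPALS with deflation: X is deflated by its
score/loading pair (t, p) and Y by its own score/loading pair (u, q), so
both decomposition identities hold exactly on the residuals.  The
gene-lectin association matrix is A = P Q' summed over selected
components; single-component selections give rank-1 association maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PLSError(ValueError):
    pass


class PLSConvergenceError(PLSError):
    pass


@dataclass
class PLSModel:
    """Fitted PLS decomposition.

    ``weights_W`` (genes) and ``weights_C`` (lectins) are the unit-norm
    direction vectors; ``loadings_P`` / ``loadings_Q`` are the regression
    loadings such that X_processed = T P' + E and Y_processed = U Q' + F.
    Centering/scaling vectors record the preprocessing of each block.
    """

    scores_T: np.ndarray
    scores_U: np.ndarray
    loadings_P: np.ndarray
    loadings_Q: np.ndarray
    weights_W: np.ndarray
    weights_C: np.ndarray
    residual_E: np.ndarray
    residual_F: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    lectin_ids: list[str] = field(default_factory=list)
    n_iterations: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.scores_T.shape[1]

    def x_processed(self) -> np.ndarray:
        return self.scores_T @ self.loadings_P.T + self.residual_E

    def y_processed(self) -> np.ndarray:
        return self.scores_U @ self.loadings_Q.T + self.residual_F


def _as_array(block, axis_name: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(block, pd.DataFrame):
        return block.to_numpy(dtype=float), list(block.columns)
    arr = np.asarray(block, dtype=float)
    return arr, [f"{axis_name}{i}" for i in range(arr.shape[1])]


def _preprocess(x: np.ndarray, scale: bool, names: list[str]):
    center = x.mean(axis=0)
    xc = x - center
    if scale:
        sd = xc.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            raise PLSError(
                f"zero-variance features cannot be scaled: {[names[i] for i in zero]}"
            )
        return xc / sd, center, sd
    return xc, center, np.ones(x.shape[1])


def fit_pls(
    X,
    Y,
    n_components: int = 10,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSModel:
    """Fit a PLS model of X (cells x genes) against Y (cells x lectins).

    Both blocks are column-centered and, by default, scaled to unit
    variance.  NIPALS iterates per component to tolerance ``tol`` on the
    gene weight vector; the sign convention makes the largest-magnitude
    gene weight positive.  T columns are mutually orthogonal.
    """
    x, gene_ids = _as_array(X, "gene")
    y, lectin_ids = _as_array(Y, "lectin")
    n = x.shape[0]
    if y.shape[0] != n:
        raise PLSError(f"cell mismatch: X has {n} rows, Y has {y.shape[0]}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise PLSError("inputs must be finite")
    m, p = x.shape[1], y.shape[1]
    if n_components > min(n - 1, m, p):
        raise PLSError(
            f"n_components={n_components} exceeds min(n-1, genes, lectins)="
            f"{min(n - 1, m, p)}"
        )
    xw, x_center, x_scale = _preprocess(x, scale, gene_ids)
    yw, y_center, y_scale = _preprocess(y, scale, lectin_ids)

    T = np.zeros((n, n_components))
    U = np.zeros((n, n_components))
    P = np.zeros((m, n_components))
    Q = np.zeros((p, n_components))
    W = np.zeros((m, n_components))
    C = np.zeros((p, n_components))
    iters: list[int] = []

    Ex, Fy = xw.copy(), yw.copy()
    for k in range(n_components):
        # deterministic start: Y column with the largest residual variance
        u = Fy[:, np.argmax(Fy.var(axis=0))].copy()
        if np.allclose(u, 0):
            raise PLSConvergenceError(f"component {k + 1}: Y residual is zero")
        w_old = np.zeros(m)
        for it in range(1, max_iter + 1):
            w = Ex.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise PLSConvergenceError(f"component {k + 1}: zero weight vector")
            w /= norm
            t = Ex @ w
            c = Fy.T @ t
            c_norm = np.linalg.norm(c)
            if c_norm == 0:
                raise PLSConvergenceError(f"component {k + 1}: zero Y weight vector")
            c /= c_norm
            u = Fy @ c
            if np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        else:
            raise PLSConvergenceError(
                f"component {k + 1} did not converge in {max_iter} iterations"
            )
        # sign convention: largest-magnitude gene weight positive
        if w[np.argmax(np.abs(w))] < 0:
            w, t, c, u = -w, -t, -c, -u
        tt = t @ t
        uu = u @ u
        if tt == 0 or uu == 0:
            raise PLSConvergenceError(f"component {k + 1}: degenerate scores")
        p_load = Ex.T @ t / tt
        q_load = Fy.T @ u / uu
        Ex = Ex - np.outer(t, p_load)
        Fy = Fy - np.outer(u, q_load)
        T[:, k], U[:, k] = t, u
        P[:, k], Q[:, k] = p_load, q_load
        W[:, k], C[:, k] = w, c
        iters.append(it)

    return PLSModel(
        scores_T=T,
        scores_U=U,
        loadings_P=P,
        loadings_Q=Q,
        weights_W=W,
        weights_C=C,
        residual_E=Ex,
        residual_F=Fy,
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
        gene_ids=gene_ids,
        lectin_ids=lectin_ids,
        n_iterations=iters,
    )


def association_matrix(model: PLSModel, components="all") -> pd.DataFrame:
    """Gene-lectin association A = sum over components of p_k q_k'.

    ``components`` is "all" or an iterable of 1-based component numbers;
    a single component yields that component's rank-1 association.
    """
    if components == "all":
        idx = list(range(model.n_components))
    else:
        idx = [int(k) - 1 for k in components]
        if not idx:
            raise PLSError("empty component selection")
        bad = [k + 1 for k in idx if k < 0 or k >= model.n_components]
        if bad:
            raise PLSError(f"components out of range: {bad}")
    a = model.loadings_P[:, idx] @ model.loadings_Q[:, idx].T
    return pd.DataFrame(a, index=model.gene_ids, columns=model.lectin_ids)


def component_weights(
    model: PLSModel, component: int
) -> tuple[pd.Series, pd.Series]:
    """Ranked gene and lectin weights for one 1-based component.

    Both vectors have unit norm; sorting is by weight descending.  These
    are the inputs for downstream gene-set selection (enrichment itself
    is external).
    """
    if not 1 <= component <= model.n_components:
        raise PLSError(f"component {component} not in 1..{model.n_components}")
    k = component - 1
    genes = pd.Series(
        model.weights_W[:, k], index=model.gene_ids, name=f"gene_weight_c{component}"
    ).sort_values(ascending=False, kind="stable")
    lectins = pd.Series(
        model.weights_C[:, k],
        index=model.lectin_ids,
        name=f"lectin_weight_c{component}",
    ).sort_values(ascending=False, kind="stable")
    return genes, lectins
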