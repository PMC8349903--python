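"""PLS regression of gene expression against lectin signals."""

import numpy as np
import pandas as pd
import pytest

from glycoseq.pls import (
    PLSError,
    association_matrix,
    component_weights,
    fit_pls,
)
from glycoseq.qc import clr_normalize, lognormalize_rna
from glycoseq.simulate import (
    AssociationBlock,
    MultimodalTruth,
    simulate_association_gaussian,
    simulate_multimodal,
)


def processed(x):
    xc = x - x.mean(axis=0)
    return xc / xc.std(axis=0, ddof=1)


class TestFitPLS:
    def test_first_component_matches_svd_oracle(self):
        """Component-1 weights equal the leading singular vectors of the
        processed cross-covariance X'Y, up to sign."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 8))
        a = rng.standard_normal(8)
        b = rng.standard_normal(4)
        Y = np.outer(X @ a, b)  # noiseless rank-1 link
        model = fit_pls(X, Y + rng.standard_normal(Y.shape) * 1e-8, n_components=1)
        u, s, vt = np.linalg.svd(processed(X).T @ processed(Y))
        assert abs(model.weights_W[:, 0] @ u[:, 0]) == pytest.approx(1.0, abs=1e-6)
        assert abs(model.weights_C[:, 0] @ vt[0]) == pytest.approx(1.0, abs=1e-6)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((25, 10))
        Y = rng.standard_normal((25, 5))
        model = fit_pls(X, Y, n_components=4)
        gram = model.scores_T.T @ model.scores_T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_decomposition_identities(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 7))
        Y = rng.standard_normal((20, 4))
        model = fit_pls(X, Y, n_components=3)
        assert np.allclose(model.x_processed(), processed(X), atol=1e-8)
        assert np.allclose(model.y_processed(), processed(Y), atol=1e-8)

    def test_score_covariance_non_increasing(self):
        """The objective NIPALS greedily maximizes — the T/U score
        covariance — decreases across components."""
        X, Y, _ = simulate_association_gaussian(seed=4)
        model = fit_pls(X, Y, n_components=4)
        cov = [
            abs(model.scores_T[:, k] @ model.scores_U[:, k]) for k in range(4)
        ]
        assert all(cov[k + 1] <= cov[k] + 1e-8 for k in range(3))

    def test_explained_y_variance_non_increasing_on_structured_data(self):
        """When the planted low-rank structure dominates (factor strengths
        3 > 2 > 1 > noise), each component explains no more Y variance
        than the one before."""
        rng = np.random.default_rng(0)
        z = rng.standard_normal((3, 96))
        X = sum(
            np.outer(z[i], rng.standard_normal(50)) * s
            for i, s in enumerate((3, 2, 1))
        ) + rng.standard_normal((96, 50))
        Y = sum(
            np.outer(z[i], rng.standard_normal(10)) * s
            for i, s in enumerate((3, 2, 1))
        ) + rng.standard_normal((96, 10))
        model = fit_pls(X, Y, n_components=4)
        per_comp = [
            (np.outer(model.scores_U[:, k], model.loadings_Q[:, k]) ** 2).sum()
            for k in range(4)
        ]
        assert all(per_comp[k + 1] <= per_comp[k] + 1e-8 for k in range(3))

    def test_zero_variance_column_error(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        Y = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(PLSError, match="zero-variance"):
            fit_pls(X, Y, n_components=1)

    def test_too_many_components_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(PLSError, match="n_components"):
            fit_pls(rng.standard_normal((5, 3)), rng.standard_normal((5, 2)), 4)

    def test_cell_mismatch_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(PLSError, match="cell mismatch"):
            fit_pls(rng.standard_normal((5, 3)), rng.standard_normal((6, 2)), 1)


class TestAssociation:
    def test_single_component_is_rank_one(self):
        X, Y, _ = simulate_association_gaussian(seed=0)
        model = fit_pls(X, Y, n_components=1)
        A = association_matrix(model).to_numpy()
        assert np.linalg.matrix_rank(A) == 1
        assert np.allclose(A, np.outer(model.loadings_P[:, 0], model.loadings_Q[:, 0]))

    def test_explicit_matrix_product(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((15, 3))
        Y = rng.standard_normal((15, 2))
        model = fit_pls(X, Y, n_components=2)
        A = association_matrix(model).to_numpy()
        assert np.allclose(A, model.loadings_P @ model.loadings_Q.T)
        A1 = association_matrix(model, components=[1]).to_numpy()
        assert np.allclose(
            A1, np.outer(model.loadings_P[:, 0], model.loadings_Q[:, 0])
        )

    def test_recovery_correlation_at_snr2(self):
        """Planted low-rank association at per-feature SNR 2, n = 96:
        recovered A correlates >= 0.9 with the planted pattern."""
        X, Y, A_true = simulate_association_gaussian(seed=3)
        model = fit_pls(X, Y, n_components=1)
        A = association_matrix(model).to_numpy()
        corr = np.corrcoef(A.ravel(), A_true.ravel())[0, 1]
        assert corr >= 0.9

    def test_two_block_precision(self):
        """On the multimodal generator with two planted blocks, the
        top-|A| entries recover the planted pairs (precision >= 0.8)."""
        truth = MultimodalTruth(
            seed=1,
            blocks=[
                AssociationBlock(tuple(range(0, 8)), (0, 1)),
                AssociationBlock(tuple(range(8, 16)), (2,)),
            ],
            dynamic_features=[],
        )
        data = simulate_multimodal(truth)
        y = clr_normalize(data.glycan_counts)
        x = lognormalize_rna(data.rna_counts).T.loc[y.index]
        model = fit_pls(x, y, n_components=2)
        A = np.abs(association_matrix(model).to_numpy())
        A_true = data.association_truth.to_numpy()
        k = int((A_true > 0).sum())
        top = set(np.argsort(-A.ravel())[:k])
        planted = set(np.flatnonzero(A_true.ravel() > 0))
        assert len(top & planted) / k >= 0.8

    def test_empty_selection_error(self):
        X, Y, _ = simulate_association_gaussian(seed=0)
        model = fit_pls(X, Y, n_components=1)
        with pytest.raises(PLSError, match="empty"):
            association_matrix(model, components=[])


class TestComponentWeights:
    def test_planted_drivers_on_top(self):
        X, Y, _ = simulate_association_gaussian(
            gene_block=tuple(range(8)), lectin_block=(0, 1, 2), seed=2
        )
        model = fit_pls(X, Y, n_components=1)
        genes, lectins = component_weights(model, 1)
        top_genes = {int(g[4:]) for g in genes.index[:8]}
        assert top_genes == set(range(8))
        assert {int(l[6:]) for l in lectins.index[:3]} == {0, 1, 2}

    def test_unit_norm(self):
        X, Y, _ = simulate_association_gaussian(seed=0)
        model = fit_pls(X, Y, n_components=2)
        for k in (1, 2):
            genes, lectins = component_weights(model, k)
            assert np.linalg.norm(genes.to_numpy()) == pytest.approx(1.0)
            assert np.linalg.norm(lectins.to_numpy()) == pytest.approx(1.0)

    def test_sign_equivariance_under_column_flip(self):
        """Flipping one lectin column's sign flips only its loading signs;
        weight magnitudes are unchanged."""
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 6))
        Y = rng.standard_normal((40, 3)) + X[:, :3]
        m0 = fit_pls(X, Y, n_components=2, scale=False)
        Y_flipped = Y.copy()
        Y_flipped[:, 1] *= -1
        m1 = fit_pls(X, Y_flipped, n_components=2, scale=False)
        assert np.allclose(np.abs(m0.weights_C), np.abs(m1.weights_C), atol=1e-8)
        assert np.allclose(m0.weights_W, m1.weights_W, atol=1e-8)
        assert np.allclose(m0.loadings_Q[1], -m1.loadings_Q[1], atol=1e-8)

    def test_out_of_range_component(self):
        X, Y, _ = simulate_association_gaussian(seed=0)
        model = fit_pls(X, Y, n_components=1)
        with pytest.raises(PLSError):
            component_weights(model, 2)


def test_dataframe_feature_names():
    rng = np.random.default_rng(8)
    x = pd.DataFrame(rng.standard_normal((12, 4)), columns=list("ABCD"))
    y = pd.DataFrame(rng.standard_normal((12, 2)), columns=["L1", "L2"])
    model = fit_pls(x, y, n_components=1)
    A = association_matrix(model)
    assert list(A.index) == list("ABCD") and list(A.columns) == ["L1", "L2"]
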