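"""Brunner-Munzel test, corrections, correlations, PCA, and ARI."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from glycoseq.stats import (
    StatsError,
    adjusted_rand_index,
    bh_adjust,
    bonferroni,
    brunner_munzel,
    correlation_matrix,
    gene_feature_correlation,
    pca,
)


def bm_oracle(x, y):
    """First-principles Brunner-Munzel: effect by enumerating all pairs,
    rank variances recomputed directly from the definitions."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    effect = sum(
        1.0 if xi < yj else (0.5 if xi == yj else 0.0)
        for xi in x
        for yj in y
    ) / (nx * ny)
    r = scipy.stats.rankdata(np.concatenate([x, y]))
    rx, ry = r[:nx], r[nx:]
    sx2 = np.var(rx - scipy.stats.rankdata(x), ddof=1)
    sy2 = np.var(ry - scipy.stats.rankdata(y), ddof=1)
    N = nx + ny
    stat = nx * ny * (ry.mean() - rx.mean()) / (N * np.sqrt(nx * sx2 + ny * sy2))
    df = (nx * sx2 + ny * sy2) ** 2 / (
        (nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1)
    )
    return effect, stat, df


class TestBrunnerMunzel:
    def test_identical_samples(self):
        res = brunner_munzel([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.effect_estimate == 0.5
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_pairwise_enumeration_oracle(self):
        x, y = (1, 2, 3, 4), (2, 3, 4, 5)
        res = brunner_munzel(x, y)
        effect, stat, df = bm_oracle(x, y)
        assert res.effect_estimate == pytest.approx(effect)
        assert res.statistic == pytest.approx(stat)
        assert res.degrees_of_freedom == pytest.approx(df)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(15)
        y = rng.standard_normal(20) + 0.3
        res = brunner_munzel(x, y)
        ref = scipy.stats.brunnermunzel(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        effect, _, _ = bm_oracle(x, y)
        assert res.effect_estimate == pytest.approx(effect)

    def test_complete_separation_is_degenerate(self):
        res = brunner_munzel([1, 2, 3], [10, 11, 12])
        assert res.effect_estimate == 1.0
        assert res.degenerate and np.isnan(res.p_value)

    @pytest.mark.parametrize("seed", range(3))
    def test_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed + 100)
        x = rng.standard_normal(12)
        y = rng.standard_normal(9) + 0.5
        fwd, rev = brunner_munzel(x, y), brunner_munzel(y, x)
        assert fwd.effect_estimate + rev.effect_estimate == pytest.approx(1.0)
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.statistic == pytest.approx(-rev.statistic)

    def test_too_small_sample(self):
        with pytest.raises(StatsError):
            brunner_munzel([1], [2, 3])


class TestCorrections:
    def test_bonferroni_scaling(self):
        out = bonferroni([0.01, 0.02, 0.03], m=3)
        assert np.allclose(out, [0.03, 0.06, 0.09])

    def test_bonferroni_caps_at_one(self):
        assert bonferroni([0.9], m=5).tolist() == [1.0]

    def test_bh_single_p_unchanged(self):
        assert bh_adjust([0.037]).tolist() == [0.037]

    def test_bh_hand_step_up(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        # explicit step-up: sorted p (0.005, 0.01, 0.03, 0.04), n=4
        # raw q = (0.02, 0.02, 0.04, 0.04); monotone from the top: same
        expected = {0.005: 0.02, 0.01: 0.02, 0.03: 0.04, 0.04: 0.04}
        q = bh_adjust(p)
        for pi, qi in zip(p, q):
            assert qi == pytest.approx(expected[pi])

    @pytest.mark.parametrize("seed", range(3))
    def test_bh_matches_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(size=50)
        _, ref, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), ref)

    def test_bh_dominates_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(StatsError):
            bh_adjust([1.2])


class TestCorrelation:
    def test_duplicated_probe(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(10)
        corr, flagged = correlation_matrix(np.column_stack([a, a, rng.standard_normal(10)]))
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert not flagged

    def test_negated_probe(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(10)
        corr, _ = correlation_matrix(np.column_stack([a, -a]))
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_direct_formula_5_cells(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((5, 3))
        corr, _ = correlation_matrix(x)
        for i, j in itertools.combinations(range(3), 2):
            xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
            expected = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
            assert corr.iloc[i, j] == pytest.approx(expected)
        assert np.allclose(corr, corr.T) and np.allclose(np.diag(corr), 1.0)

    def test_constant_probe_flagged_zero(self):
        x = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        corr, flagged = correlation_matrix(
            pd.DataFrame(x, columns=["const", "var"])
        )
        assert flagged == ["const"]
        assert corr.loc["const", "var"] == 0.0 and corr.loc["const", "const"] == 1.0


class TestGeneFeatureCorrelation:
    def test_identical_and_negated_genes(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal(20)
        expr = pd.DataFrame(
            np.vstack([f, -f, rng.standard_normal(20)]),
            index=["same", "anti", "noise"],
        )
        out = gene_feature_correlation(expr, f)
        assert out.iloc[0].gene == "same" and out.iloc[0].r == pytest.approx(1.0)
        assert out.iloc[-1].gene == "anti" and out.iloc[-1].r == pytest.approx(-1.0)

    def test_planted_correlation_recovered(self):
        """One gene = feature + noise tuned for r ~ 0.8 ranks first."""
        rng = np.random.default_rng(7)
        n = 96
        f = rng.standard_normal(n)
        sigma = np.sqrt(1 / 0.8**2 - 1)  # target Pearson r = 0.8
        planted = f + sigma * rng.standard_normal(n)
        expr = np.vstack([planted, rng.standard_normal((50, n))])
        out = gene_feature_correlation(
            pd.DataFrame(expr, index=["planted"] + [f"g{i}" for i in range(50)]), f
        )
        assert out.iloc[0].gene == "planted"
        assert abs(out.iloc[0].r - 0.8) < 0.1

    def test_constant_gene_flagged(self):
        expr = np.vstack([np.full(10, 2.0), np.arange(10.0)])
        out = gene_feature_correlation(expr, np.arange(10.0))
        row = out[out.constant]
        assert len(row) == 1 and row.iloc[0].r == 0.0


class TestPCA:
    def test_collinear_data(self):
        t = np.arange(10.0)
        res = pca(np.column_stack([t, 2 * t]))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_completeness(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 5))
        res = pca(x)
        recon = res.scores @ res.loadings.T + res.centering
        assert np.allclose(recon, x)

    def test_eigen_oracle_4x3(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 3))
        res = pca(x, n_components=2)
        cov = np.cov(x, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        for k in range(2):
            v = evecs[:, order[k]]
            cos = abs(v @ res.loadings[:, k])
            assert cos == pytest.approx(1.0)
            assert res.explained_variance[k] == pytest.approx(evals[order[k]])

    def test_variance_sums_to_total(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((20, 6))
        res = pca(x)
        total = ((x - x.mean(0)) ** 2).sum() / (len(x) - 1)
        assert res.explained_variance.sum() == pytest.approx(total)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_orthonormal_loadings_and_sign(self):
        rng = np.random.default_rng(3)
        res = pca(rng.standard_normal((15, 4)))
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(res.loadings.shape[1]))
        for k in range(res.loadings.shape[1]):
            j = np.argmax(np.abs(res.loadings[:, k]))
            assert res.loadings[j, k] > 0

    def test_rank_truncation_warns(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.warns(UserWarning, match="rank"):
            res = pca(x, n_components=2)
        assert res.loadings.shape[1] == 1


class TestARI:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [5, 5, 9, 9]) == pytest.approx(1.0)

    def test_singletons_vs_one_cluster(self):
        assert adjusted_rand_index(range(6), [0] * 6) == pytest.approx(0.0)

    def test_pair_counting_oracle(self):
        """Matches explicit contingency-table pair counting."""
        a, b = [1, 1, 2, 2, 3], [1, 1, 1, 2, 2]
        n = len(a)
        same_a = {(i, j) for i, j in itertools.combinations(range(n), 2) if a[i] == a[j]}
        same_b = {(i, j) for i, j in itertools.combinations(range(n), 2) if b[i] == b[j]}
        n_pairs = n * (n - 1) / 2
        n11 = len(same_a & same_b)
        exp = len(same_a) * len(same_b) / n_pairs
        max_idx = (len(same_a) + len(same_b)) / 2
        expected = (n11 - exp) / (max_idx - exp)
        assert adjusted_rand_index(a, b) == pytest.approx(expected)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, size=30)
        b = rng.integers(0, 3, size=30)
        perm = {0: "x", 1: "y", 2: "z", 3: "w"}
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index([perm[i] for i in a], b)
        )
        assert adjusted_rand_index(a, b) <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(StatsError):
            adjusted_rand_index([1, 2], [1, 2, 3])
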