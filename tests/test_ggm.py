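import warnings

import numpy as np
import pytest

from phenonet import (
    EBICGraphLasso,
    ebic,
    edge_density,
    edge_density_percent,
    glasso_fit,
    lambda_grid,
    precision_to_partial,
    select_gamma,
    select_network,
)
from phenonet.ggm import EDGE_EPS
from phenonet.simulate import (
    TrueNetworkSpec,
    generate_true_network,
    latent_correlation,
)


def _sample_corr(seed, p=8, n=500, density=0.3):
    spec = TrueNetworkSpec(p=p, density=density, weight_low=0.25,
                           weight_high=0.4, seed=seed)
    W = generate_true_network(spec)
    R = latent_correlation(W)
    rng = np.random.default_rng(1000 + seed)
    X = rng.multivariate_normal(np.zeros(p), R, size=n)
    return np.corrcoef(X, rowvar=False), W


def _edges(K):
    iu = np.triu_indices(K.shape[0], 1)
    return int((np.abs(K[iu]) > EDGE_EPS).sum())


class TestGlassoFit:
    def test_identity_input_gives_diagonal_precision(self):
        K = glasso_fit(np.eye(5), 0.1)
        assert _edges(K) == 0

    def test_lambda_above_max_offdiagonal_empties_graph(self):
        S, _ = _sample_corr(0)
        lam_max = np.abs(S - np.diag(np.diag(S))).max()
        K = glasso_fit(S, lam_max * 1.0001)
        assert _edges(K) == 0

    def test_bivariate_closed_form(self):
        """p=2, S12=0.5, lambda=0.1: the penalized covariance off-diagonal is
        sign(s)(|s|-lambda)=0.4, hence partial correlation 0.4."""
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        W = precision_to_partial(glasso_fit(S, 0.1))
        assert W[0, 1] == pytest.approx(0.4, abs=1e-6)

    def test_matches_independent_solver(self):
        """Support and values agree with sklearn's graphical lasso."""
        from sklearn.covariance import graphical_lasso

        S, _ = _sample_corr(1)
        for lam in (0.3, 0.1, 0.05):
            K = glasso_fit(S, lam, tol=1e-8)
            _, prec = graphical_lasso(S, alpha=lam, tol=1e-9, max_iter=500)
            assert np.abs(K - prec).max() < 5e-4
            assert np.array_equal(np.abs(K) > 1e-8, np.abs(prec) > 1e-8)

    def test_non_psd_input_directs_to_repair(self):
        M = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        with pytest.raises(ValueError, match="nearest_psd"):
            glasso_fit(M, 0.1)

    def test_lambda_zero_reproduces_sample_partial_correlations(self):
        S, _ = _sample_corr(2)
        W = precision_to_partial(glasso_fit(S, 0.0))
        K = np.linalg.inv(S)
        d = np.sqrt(np.diag(K))
        expect = -K / np.outer(d, d)
        np.fill_diagonal(expect, 0.0)
        assert np.abs(W - expect).max() < 1e-6


class TestLambdaGrid:
    def test_endpoints_and_length(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        grid = lambda_grid(S, n_lambda=100)
        assert grid[0] == pytest.approx(0.5)
        assert grid[-1] == pytest.approx(0.005)
        assert grid.size == 100
        assert np.all(np.diff(grid) < 0)

    def test_two_point_grid(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert lambda_grid(S, n_lambda=2) == pytest.approx([0.5, 0.005])

    def test_degenerate_all_zero_offdiagonal(self):
        with pytest.warns(UserWarning):
            grid = lambda_grid(np.eye(3))
        assert grid.tolist() == [0.0]


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        S, _ = _sample_corr(3)
        K = glasso_fit(S, 0.05)
        n = 500
        sign, logdet = np.linalg.slogdet(K)
        ll = (n / 2) * (logdet - np.trace(S @ K))
        assert ebic(K, S, n, 0.0) == pytest.approx(
            -2 * ll + _edges(K) * np.log(n)
        )

    def test_diagonal_precision_has_zero_penalty(self):
        S = np.eye(4)
        K = np.diag([1.0, 2.0, 0.5, 1.0])
        n = 100
        ll = (n / 2) * (np.linalg.slogdet(K)[1] - np.trace(S @ K))
        assert ebic(K, S, n, 0.7) == pytest.approx(-2 * ll)

    def test_penalty_arithmetic(self):
        """E=55 edges, n=100, p=20, gamma=0.65: penalty = 55 log 100 +
        4*55*0.65*log 20 ~ 681.67."""
        rng = np.random.default_rng(0)
        p = 20
        K = np.eye(p) * 5.0
        iu, ju = np.triu_indices(p, 1)
        pick = rng.choice(iu.size, size=55, replace=False)
        K[iu[pick], ju[pick]] = K[ju[pick], iu[pick]] = 0.1
        assert np.linalg.eigvalsh(K)[0] > 0
        S = np.eye(p)
        penalty = ebic(K, S, 100, 0.65) - ebic(K, S, 100, 0.0) \
            + 55 * np.log(100)
        assert penalty == pytest.approx(681.674, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ebic(np.eye(3), np.eye(3), 1, 0.5)
        with pytest.raises(ValueError):
            ebic(-np.eye(3), np.eye(3), 100, 0.5)


class TestPrecisionToPartial:
    def test_diagonal_precision_gives_zero_weights(self):
        assert np.all(precision_to_partial(np.diag([2.0, 3.0])) == 0)

    def test_two_by_two_formula(self):
        K = np.array([[1.0, -0.5], [-0.5, 1.0]])
        assert precision_to_partial(K)[0, 1] == pytest.approx(0.5)

    def test_sign_flip(self):
        K = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert precision_to_partial(K)[0, 1] < 0


class TestEdgeDensity:
    @pytest.mark.parametrize("E, expected", [(55, 28.95), (70, 36.84),
                                             (0, 0.0)])
    def test_twenty_node_network(self, E, expected):
        assert edge_density_percent(20, E) == pytest.approx(expected,
                                                            abs=0.005)


class TestSelectNetwork:
    def test_identity_matrix_gives_empty_network(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = select_network(np.eye(6), 200, gamma=0.5)
        assert m.E == 0

    def test_selected_score_is_path_minimum(self):
        S, _ = _sample_corr(4)
        m = select_network(S, 500, gamma=0.5)
        finite = np.isfinite(m.ebic_path)
        assert m.ebic <= m.ebic_path[finite].min() + 1e-12

    def test_tie_break_prefers_larger_lambda(self):
        S, _ = _sample_corr(5)
        m = select_network(S, 500, gamma=0.5)
        first = np.flatnonzero(np.isclose(m.ebic_path, m.ebic))[0]
        assert m.lambda_ == pytest.approx(m.lambda_path[first])

    def test_weight_matrix_consistent_with_precision(self):
        S, _ = _sample_corr(6)
        m = select_network(S, 500, gamma=0.5)
        assert np.abs(m.W - precision_to_partial(m.K)).max() < 1e-12
        assert np.all(np.abs(m.W) < 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_edge_count_monotone_along_path(self, seed):
        """On (noise-free) latent correlation matrices of random sparse
        truths the lasso support grows steadily as the penalty decreases.
        (On noisy sample matrices, edges of negligible magnitude can flicker
        near their activation point - a documented glasso property.)"""
        from phenonet._glasso import glasso_path
        from phenonet.simulate import (
            TrueNetworkSpec, generate_true_network, latent_correlation,
        )

        spec = TrueNetworkSpec(p=8, density=0.25, weight_low=0.25,
                               weight_high=0.4, seed=seed)
        S = latent_correlation(generate_true_network(spec))
        lams = lambda_grid(S, n_lambda=100)
        Ks, _, _, ok = glasso_path(S, lams, tol=1e-7)
        assert ok.all()
        E = [_edges(K) for K in Ks]
        assert all(E[i] <= E[i + 1] for i in range(len(E) - 1))

    def test_higher_gamma_never_denser(self):
        for seed in range(5):
            S, _ = _sample_corr(seed, n=171)
            e_lo = select_network(S, 171, gamma=0.0).E
            e_hi = select_network(S, 171, gamma=0.65).E
            assert e_hi <= e_lo

    def test_refit_scoring_selects_sparser_support(self):
        S, W = _sample_corr(7, n=2000)
        m_pen = select_network(S, 2000, gamma=0.5)
        m_ref = select_network(S, 2000, gamma=0.5, refit=True)
        assert m_ref.E <= m_pen.E


class TestSelectGamma:
    def test_all_nonempty_returns_grid_maximum(self):
        S, _ = _sample_corr(8, n=2000)
        # strong correlations survive even gamma=1
        g = select_gamma([S], [2000])
        assert g == 1.0

    def test_identity_matrices_error(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="empty"):
                select_gamma([np.eye(5)], [100])

    def test_agrees_with_direct_scan(self):
        """The selected gamma is the largest grid value at which every
        network stays non-empty (verified by exhaustive scan)."""
        S1, _ = _sample_corr(9, n=80)
        S2, _ = _sample_corr(10, n=60)
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
        picked = select_gamma([S1, S2], [80, 60], gamma_grid=grid)
        feasible = [
            g for g in grid
            if all(select_network(S, n, gamma=float(g)).E > 0
                   for S, n in ((S1, 80), (S2, 60)))
        ]
        assert picked == max(feasible)


class TestEstimatorInterface:
    def test_pearson_mode_fits_and_exposes_attributes(self):
        S, _ = _sample_corr(11)
        rng = np.random.default_rng(0)
        X = rng.multivariate_normal(np.zeros(8), S, size=300)
        est = EBICGraphLasso(gamma=0.5, correlation="pearson").fit(X)
        assert est.weights_.shape == (8, 8)
        assert est.n_edges_ == est.network_.E
        assert est.get_params()["gamma"] == 0.5

    def test_precomputed_requires_n_samples(self):
        S, _ = _sample_corr(12)
        with pytest.raises(ValueError, match="n_samples"):
            EBICGraphLasso(correlation="precomputed").fit(S)

    def test_edge_recovery_in_calibration_regime(self):
        """Reduced-replicate edge recovery: with support-refit scoring the
        selection recovers strong true edges with high specificity."""
        sens, spec = [], []
        for seed in range(5):
            ts = TrueNetworkSpec(p=10, density=0.2, seed=seed)
            W = generate_true_network(ts)
            R = latent_correlation(W)
            rng = np.random.default_rng(2000 + seed)
            X = rng.multivariate_normal(np.zeros(10), R, size=2000)
            m = select_network(np.corrcoef(X, rowvar=False), 2000,
                               gamma=0.5, refit=True)
            iu = np.triu_indices(10, 1)
            true_e = np.abs(W[iu]) > EDGE_EPS
            strong = np.abs(W[iu]) >= 0.3
            est_e = np.abs(m.W[iu]) > EDGE_EPS
            if (true_e & strong).any():
                sens.append((true_e & strong & est_e).sum()
                            / (true_e & strong).sum())
            spec.append(((~true_e) & (~est_e)).sum() / (~true_e).sum())
        assert np.mean(sens) >= 0.9
        assert np.mean(spec) >= 0.9
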