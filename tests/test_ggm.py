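"""Graphical lasso estimation, penalty selection, bootstrap difference test."""

import warnings

import numpy as np
import pytest

from trpnet.ggm import (
    GaussianGraphicalModel,
    bootstrap_edge_difference,
    graphical_lasso,
    lambda_grid,
    sample_covariance,
    select_by_ic,
)

from .conftest import gaussian_table, make_table, planted_precision


class TestSampleCovariance:
    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=(5, 3))
        table = make_table(x)
        xc = x - x.mean(axis=0)
        np.testing.assert_allclose(
            sample_covariance(table), xc.T @ xc / 4, atol=1e-12
        )

    def test_identical_columns_correlate_perfectly(self):
        col = np.array([1.0, 2.0, 4.0, 3.0])
        table = make_table(np.column_stack([col, col])).standardize()
        S = sample_covariance(table)
        assert S[0, 1] == pytest.approx(1.0)

    def test_orthogonal_contrasts(self):
        a = np.array([1.0, 1.0, -1.0, -1.0])
        b = np.array([1.0, -1.0, 1.0, -1.0])
        S = sample_covariance(make_table(np.column_stack([a, b])))
        assert S[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="n="):
            sample_covariance(make_table(np.array([[1.0, 2.0]])))


class TestGraphicalLasso:
    def test_identity_fixed_point(self):
        fit = graphical_lasso(np.eye(3), lam=0.1)
        np.testing.assert_allclose(fit.precision, np.eye(3), atol=1e-8)
        assert fit.edge_count == 0

    def test_full_sparsity_threshold_exact(self, rng):
        S = np.eye(4)
        S[0, 1] = S[1, 0] = 0.4
        S[2, 3] = S[3, 2] = -0.25
        fit = graphical_lasso(S, lam=0.5)
        off = fit.precision[np.triu_indices(4, k=1)]
        assert np.all(off == 0.0)

    def test_lam_zero_is_matrix_inversion(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = graphical_lasso(S, lam=0.0)
        np.testing.assert_allclose(fit.precision, np.linalg.inv(S), atol=1e-6)
        assert fit.pcor[0, 1] == pytest.approx(0.5, abs=1e-9)

    def test_lam_zero_singular_advises_regularization(self):
        S = np.ones((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="lam > 0"):
            graphical_lasso(S, lam=0.0)

    def test_pcor_invariants(self, rng):
        x = rng.normal(size=(60, 5))
        S = np.corrcoef(x.T)
        fit = graphical_lasso(S, lam=0.05)
        assert np.all(np.diag(fit.pcor) == 0.0)
        np.testing.assert_allclose(fit.pcor, fit.pcor.T, atol=1e-12)
        assert np.all(np.abs(fit.pcor) < 1)
        assert np.all(np.linalg.eigvalsh(fit.precision) > 0)

    def test_matches_sklearn(self, rng):
        """Independent-solver cross-check on random well-conditioned inputs."""
        from sklearn.covariance import graphical_lasso as sk_glasso

        for _ in range(5):
            x = rng.normal(size=(120, 6))
            S = np.corrcoef(x.T)
            fit = graphical_lasso(S, lam=0.08, tol=1e-8)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = sk_glasso(S, alpha=0.08, tol=1e-8, max_iter=500)
            assert np.abs(fit.precision - prec).max() < 1e-2
            # penalized objectives agree far more tightly than entries
            def obj(theta):
                off = np.abs(theta).sum() - np.abs(np.diag(theta)).sum()
                return -np.linalg.slogdet(theta)[1] + (S * theta).sum() + 0.08 * off

            assert abs(obj(fit.precision) - obj(prec)) < 1e-3

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=(80, 5))
        S = np.corrcoef(x.T)
        perm = rng.permutation(5)
        fit = graphical_lasso(S, lam=0.1, tol=1e-8)
        fit_p = graphical_lasso(S[np.ix_(perm, perm)], lam=0.1, tol=1e-8)
        # agreement to solver precision; identical sparsity pattern exactly
        np.testing.assert_allclose(
            fit_p.pcor, fit.pcor[np.ix_(perm, perm)], atol=1e-3
        )
        np.testing.assert_array_equal(
            fit_p.pcor != 0, fit.pcor[np.ix_(perm, perm)] != 0
        )


class TestLambdaGrid:
    def test_log_spacing(self):
        S = np.eye(2)
        S[0, 1] = S[1, 0] = 0.8
        np.testing.assert_allclose(
            lambda_grid(S, n_points=3, min_ratio=0.01), [0.8, 0.08, 0.008]
        )

    def test_two_point_endpoints(self):
        S = np.eye(2)
        S[0, 1] = S[1, 0] = 0.5
        np.testing.assert_allclose(
            lambda_grid(S, n_points=2, min_ratio=0.1), [0.5, 0.05]
        )

    def test_identity_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            grid = lambda_grid(np.eye(3))
        np.testing.assert_array_equal(grid, [0.0])

    @pytest.mark.parametrize("kwargs", [{"n_points": 1}, {"min_ratio": 1.5}])
    def test_invalid_parameters(self, kwargs):
        S = np.eye(2)
        S[0, 1] = S[1, 0] = 0.5
        with pytest.raises(ValueError):
            lambda_grid(S, **kwargs)


class TestSelectByIC:
    def test_independent_data_selects_empty(self, rng):
        table = gaussian_table(np.eye(5), n=200, rng=rng)
        path = select_by_ic(table, n_points=30)
        assert path.selected.edge_count == 0

    def test_planted_edge_recovered(self, rng):
        theta = planted_precision(5, [(0, 1)], rho=0.6)
        table = gaussian_table(theta, n=200, rng=rng)
        fit = select_by_ic(table, n_points=30).selected
        assert fit.pcor[0, 1] != 0
        assert abs(fit.pcor[0, 1]) > 0.3

    def test_single_point_grid_forced(self, rng):
        table = gaussian_table(np.eye(3), n=50, rng=rng)
        path = select_by_ic(table, grid=[0.2])
        assert path.selected_index == 0
        assert path.selected.lam == 0.2

    def test_ties_prefer_sparser(self, rng):
        """With identical IC values the larger penalty wins by construction."""
        table = gaussian_table(np.eye(3), n=100, rng=rng)
        path = select_by_ic(table, n_points=10)
        ics = [f.ic_value for f in path.fits]
        best = min(ics)
        first_best = next(i for i, v in enumerate(ics) if v == best)
        assert path.selected_index == first_best

    def test_model_results_object(self, rng):
        theta = planted_precision(4, [(0, 1)], rho=0.5)
        table = gaussian_table(theta, n=150, rng=rng)
        res = GaussianGraphicalModel(table).fit(n_points=20)
        assert res.edge_count == res.fit.edge_count
        assert ("m0", "m1") in res.edge_set()
        assert "edges" in res.summary()

    def test_graphml_and_csv_export(self, rng, tmp_path):
        import networkx as nx

        theta = planted_precision(4, [(0, 1)], rho=0.5)
        table = gaussian_table(theta, n=150, rng=rng)
        res = GaussianGraphicalModel(table).fit(n_points=20)
        res.to_graphml(tmp_path / "g.graphml")
        g = nx.read_graphml(tmp_path / "g.graphml")
        assert g.has_edge("m0", "m1")
        assert g["m0"]["m1"]["pcor"] == pytest.approx(
            res.fit.edge_weights()[("m0", "m1")]
        )
        res.to_edge_csv(tmp_path / "e.csv")
        assert (tmp_path / "e.csv").read_text().startswith("var_a,var_b,pcor")


class TestBootstrapEdgeDifference:
    def test_small_B_rejected(self, rng):
        table = gaussian_table(np.eye(3), n=50, rng=rng)
        with pytest.raises(ValueError, match=">= 100"):
            bootstrap_edge_difference(table, B=50)

    def test_identity_pair_never_significant(self, rng):
        theta = planted_precision(4, [(0, 1), (2, 3)], rho=0.5)
        table = gaussian_table(theta, n=200, rng=rng)
        out = bootstrap_edge_difference(table, B=100, seed=3, n_points=10)
        same = out[out.edge_a == out.edge_b]
        assert len(same) >= 1
        assert not same.significant.any()
        np.testing.assert_allclose(same.diff_lo, 0, atol=1e-12)
        np.testing.assert_allclose(same.diff_hi, 0, atol=1e-12)

    def test_strong_vs_weak_edge_differs(self, rng):
        # rho=0.6 edge vs rho=0.25 edge: the difference CI should exclude 0
        theta = planted_precision(5, [(0, 1)], rho=0.6)
        theta[2, 3] = theta[3, 2] = -0.25
        assert np.linalg.eigvalsh(theta).min() > 0
        table = gaussian_table(theta, n=300, rng=rng)
        out = bootstrap_edge_difference(table, B=200, seed=4, n_points=10)
        row = out[(out.edge_a == "m0--m1") & (out.edge_b == "m2--m3")]
        assert len(row) == 1 and bool(row.significant.iloc[0])

    def test_equal_edges_rarely_differ(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            theta = planted_precision(4, [(0, 1), (2, 3)], rho=0.5)
            table = gaussian_table(theta, n=300, rng=rng)
            out = bootstrap_edge_difference(
                table, B=100, seed=seed, n_points=8
            )
            row = out[(out.edge_a == "m0--m1") & (out.edge_b == "m2--m3")]
            if len(row) == 1 and bool(row.significant.iloc[0]):
                hits += 1
        assert hits <= 2  # not significant in >= 90% of seeds

    def test_deterministic_under_seed(self, rng):
        theta = planted_precision(4, [(0, 1)], rho=0.5)
        table = gaussian_table(theta, n=120, rng=rng)
        a = bootstrap_edge_difference(table, B=100, seed=7, n_points=8)
        b = bootstrap_edge_difference(table, B=100, seed=7, n_points=8)
        assert a.equals(b)
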