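"""Phylogenetic multiple imputation: fit, conditioning, draws, pooling, LOO."""

import numpy as np
import pandas as pd
import pytest

from phylosel import (
    IncompatibleFitsError,
    PhyloMVNParams,
    UnidentifiableTraitError,
    apply_missingness,
    draw_imputations,
    fit_phylo_mvn,
    impute_moments,
    lambda_transform,
    loo_reliability,
    pool_fits,
    read_newick,
    simulate_traits,
    simulate_tree,
)
from phylosel.pgls import PGLSFit


def _dense_conditioning_oracle(X, obs, C, a, R, lam):
    """Test-only route: assemble the joint normal cell by cell and condition
    with explicit matrix inverses."""
    n, p = X.shape
    d = n * p
    Sigma = np.empty((d, d))
    C_lam = lambda_transform(C, lam)
    for i in range(n):
        for s in range(p):
            for j in range(n):
                for t in range(p):
                    Sigma[i * p + s, j * p + t] = C_lam[i, j] * R[s, t]
    mu = np.array([a[s] for _ in range(n) for s in range(p)])
    flat = X.ravel()
    o = np.flatnonzero(obs.ravel())
    m = np.flatnonzero(~obs.ravel())
    Soo_inv = np.linalg.inv(Sigma[np.ix_(o, o)])
    Smo = Sigma[np.ix_(m, o)]
    mean = mu[m] + Smo @ Soo_inv @ (flat[o] - mu[o])
    cov = Sigma[np.ix_(m, m)] - Smo @ Soo_inv @ Smo.T
    return mean, np.diag(cov)


def _dummy_fit(slope, model="y ~ x"):
    return PGLSFit(
        terms=["Intercept", "x"],
        params=np.array([0.5, slope]),
        bse=np.array([0.1, 0.2]),
        tvalues=np.array([5.0, slope / 0.2]),
        pvalues=np.array([0.01, 0.05]),
        lambda_hat=0.5,
        sigma2_ml=1.0,
        loglik=-10.0,
        adj_r2=0.3,
        n_used=10,
        df_resid=8,
        residuals=np.zeros(10),
        fitted=np.zeros(10),
        whitened_residuals=np.zeros(10),
        whitened_fitted=np.zeros(10),
        model=model,
    )


class TestFitPhyloMVN:
    def test_two_tip_closed_form(self):
        # single complete trait, 2 tips at depth 2, lambda fixed at 1:
        # a_hat = (x1+x2)/2 (GLS mean on 2I), sigma2_hat = sum (x-a)^2 / (n*T)
        tree = read_newick("(A:2,B:2);")
        tab = pd.DataFrame({"x": [1.0, 5.0]}, index=["A", "B"])
        params = fit_phylo_mvn(tab, tree, lam=1.0, min_obs_per_trait=2)
        assert params.root_means[0] == pytest.approx(3.0, abs=1e-8)
        # D' C^-1 D / n with C = 2I: ((1-3)^2 + (5-3)^2)/2 / 2 = 2
        assert params.trait_cov[0, 0] == pytest.approx(2.0, rel=1e-6)

    def test_parameter_recovery(self):
        # moderate-size recovery run; tight recovery is exercised at scale
        # by the acceptance checks
        R = np.array([[1.0, 0.7], [0.7, 1.0]])
        rel_err = []
        for rep in range(5):
            tree = simulate_tree(150, seed=40 + rep)
            tab = simulate_traits(tree, R, 0.8, [0, 0], seed=rep)
            masked = apply_missingness(tab, {"trait0": 0.3, "trait1": 0.2},
                                       seed=rep)
            p = fit_phylo_mvn(masked.data, tree)
            rel_err.append(abs(p.trait_cov[0, 0] - 1.0))
            rel_err.append(abs(p.lam - 0.8))
        assert np.mean(rel_err) < 0.15

    def test_duplicated_trait_estimates_unit_correlation(self, tree12):
        tab = simulate_traits(tree12, np.eye(1), 0.9, [0.0], seed=6,
                              trait_names=["a"])
        tab["b"] = tab["a"]
        p = fit_phylo_mvn(tab, tree12, lam=0.9)
        corr = p.trait_cov[0, 1] / np.sqrt(p.trait_cov[0, 0] * p.trait_cov[1, 1])
        assert corr > 0.999

    def test_all_missing_trait_rejected(self, tree12):
        tab = simulate_traits(tree12, np.eye(2), 0.5, [0, 0], seed=1)
        tab["trait1"] = np.nan
        with pytest.raises(UnidentifiableTraitError):
            fit_phylo_mvn(tab, tree12)


class TestImputeMoments:
    @pytest.mark.parametrize("n,p,seed", [(4, 2, 0), (3, 4, 1), (6, 2, 2), (4, 3, 3)])
    def test_matches_dense_oracle(self, n, p, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(n, seed=seed)
        A = rng.normal(size=(p, p))
        R = A @ A.T + 0.5 * np.eye(p)
        lam = float(rng.uniform(0, 1))
        a = rng.normal(size=p)
        tab = simulate_traits(tree, R, lam, a, seed=seed + 10)
        X = tab.to_numpy().copy()
        obs = np.ones_like(X, dtype=bool)
        holes = rng.choice(n * p, size=max(2, n * p // 4), replace=False)
        obs.ravel()[holes] = False
        tab_masked = tab.copy()
        tab_masked.values[~obs] = np.nan
        params = PhyloMVNParams(a, R, lam, 0.0, list(tab.columns))
        mom = impute_moments(tab_masked, tree, params)
        mean_o, var_o = _dense_conditioning_oracle(
            X, obs, tree.vcv(list(tab.index)), a, R, lam
        )
        np.testing.assert_allclose(mom.cond_mean, mean_o, atol=1e-8)
        np.testing.assert_allclose(mom.cond_var, var_o, atol=1e-8)

    def test_star_tree_hand_example(self):
        # star tree, one missing tip, root mean at its ML value (the plain
        # mean): conditional mean 2, conditional variance sigma2 * depth
        star = read_newick("(A:1,B:1,C:1,D:1);")
        tab = pd.DataFrame({"x": [1.0, 2.0, 3.0, np.nan]},
                           index=["A", "B", "C", "D"])
        sigma2 = 0.7
        params = PhyloMVNParams(np.array([2.0]), np.array([[sigma2]]), 1.0,
                                0.0, ["x"])
        mom = impute_moments(tab, star, params)
        assert mom.cond_mean[0] == pytest.approx(2.0, abs=1e-10)
        assert mom.cond_var[0] == pytest.approx(sigma2 * 1.0, abs=1e-10)

    def test_zero_distance_sister_copies_value(self):
        tree = read_newick("((A:0,B:0):2,C:2);")
        tab = pd.DataFrame({"x": [np.nan, 4.2, -1.0]}, index=["A", "B", "C"])
        params = PhyloMVNParams(np.array([0.0]), np.array([[1.3]]), 1.0,
                                0.0, ["x"])
        mom = impute_moments(tab, tree, params)
        assert mom.cond_mean[0] == pytest.approx(4.2, abs=1e-8)
        assert mom.cond_var[0] == pytest.approx(0.0, abs=1e-8)

    def test_variance_shrinkage(self, tree12):
        tab = simulate_traits(tree12, np.eye(2) + 0.5, 0.8, [0, 0], seed=3)
        masked = apply_missingness(tab, {"trait0": 0.3, "trait1": 0.3}, seed=3)
        params = fit_phylo_mvn(masked.data, tree12)
        mom = impute_moments(masked.data, tree12, params)
        assert np.all(mom.cond_var <= mom.marginal_var + 1e-10)

    def test_per_trait_lambda_conditioning(self, tree12):
        # a per-trait lambda vector with equal entries must agree with the
        # common-lambda path
        tab = simulate_traits(tree12, np.eye(2) + 0.5, 0.8, [0, 0], seed=9)
        tab.iloc[0, 0] = np.nan
        common = PhyloMVNParams(np.zeros(2), np.eye(2) + 0.5, 0.6, 0.0,
                                list(tab.columns))
        vector = PhyloMVNParams(np.zeros(2), np.eye(2) + 0.5,
                                np.array([0.6, 0.6]), 0.0, list(tab.columns))
        a = impute_moments(tab, tree12, common)
        b = impute_moments(tab, tree12, vector)
        np.testing.assert_allclose(a.cond_mean, b.cond_mean, atol=1e-10)
        np.testing.assert_allclose(a.cond_var, b.cond_var, atol=1e-10)

    def test_no_missing_cells_rejected(self, tree12):
        tab = simulate_traits(tree12, np.eye(1), 0.5, [0.0], seed=1)
        params = fit_phylo_mvn(tab, tree12, lam=0.5)
        with pytest.raises(ValueError, match="no missing"):
            impute_moments(tab, tree12, params)


class TestDrawImputations:
    def _setup(self, tree):
        tab = simulate_traits(tree, np.eye(2) + 0.5, 0.8, [0, 0], seed=8)
        masked = apply_missingness(tab, {"trait0": 0.25, "trait1": 0.25}, seed=8)
        params = fit_phylo_mvn(masked.data, tree)
        mom = impute_moments(masked.data, tree, params)
        return masked, mom

    def test_observed_cells_bitwise_identical(self, tree12):
        masked, mom = self._setup(tree12)
        imps = draw_imputations(mom, masked.data, m=5, seed=1)
        obs = ~masked.data.isna()
        for tab in imps.tables:
            assert tab.notna().all().all()
            np.testing.assert_array_equal(
                tab.to_numpy()[obs.to_numpy()],
                masked.data.to_numpy()[obs.to_numpy()],
            )

    def test_same_seed_identical(self, tree12):
        masked, mom = self._setup(tree12)
        a = draw_imputations(mom, masked.data, m=4, seed=9)
        b = draw_imputations(mom, masked.data, m=4, seed=9)
        assert a.seeds == b.seeds
        for ta, tb in zip(a.tables, b.tables):
            pd.testing.assert_frame_equal(ta, tb)

    def test_zero_variance_collapses_draws(self, tree12):
        masked, mom = self._setup(tree12)
        mom.cond_var[:] = 0.0
        imps = draw_imputations(mom, masked.data, m=3, seed=2)
        pd.testing.assert_frame_equal(imps.tables[0], imps.tables[1])
        pd.testing.assert_frame_equal(imps.tables[0], imps.tables[2])

    def test_draw_mean_matches_conditional_mean(self, tree12):
        masked, mom = self._setup(tree12)
        sp, tr = mom.species[0], mom.traits[0]
        m = 400
        imps = draw_imputations(mom, masked.data, m=m, seed=3)
        draws = np.array([t.loc[sp, tr] for t in imps.tables])
        se = np.sqrt(mom.cond_var[0] / m)
        assert abs(draws.mean() - mom.cond_mean[0]) < 3 * se

    def test_m_below_two_rejected(self, tree12):
        masked, mom = self._setup(tree12)
        with pytest.raises(ValueError):
            draw_imputations(mom, masked.data, m=1, seed=0)


class TestPoolFits:
    def test_identical_fits_zero_sd(self):
        pooled = pool_fits([_dummy_fit(2.0)] * 4)
        assert (pooled.table.filter(like="_sd").to_numpy() == 0).all()

    def test_hand_pooling(self):
        pooled = pool_fits([_dummy_fit(1.0), _dummy_fit(3.0)])
        row = pooled.table.set_index("term").loc["x"]
        assert row["estimate_mean"] == pytest.approx(2.0)
        assert row["estimate_sd"] == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_permutation_invariant(self):
        fits = [_dummy_fit(s) for s in (0.5, 2.5, -1.0)]
        a = pool_fits(fits).table
        b = pool_fits(fits[::-1]).table
        pd.testing.assert_frame_equal(a, b)

    def test_mismatched_models_rejected(self):
        with pytest.raises(IncompatibleFitsError):
            pool_fits([_dummy_fit(1.0, "y ~ x"), _dummy_fit(1.0, "y ~ z")])

    def test_rubin_rule_option(self):
        # Rubin: estimate = mean, total var = within + (1+1/m) * between
        pooled = pool_fits([_dummy_fit(1.0), _dummy_fit(3.0)], rule="rubin")
        row = pooled.table.set_index("term").loc["x"]
        within = 0.2**2
        between = 2.0
        assert row["estimate"] == pytest.approx(2.0)
        assert row["se"] == pytest.approx(np.sqrt(within + 1.5 * between), abs=1e-12)
        identical = pool_fits([_dummy_fit(2.0)] * 3, rule="rubin")
        assert identical.table.set_index("term").loc["x", "se"] == pytest.approx(0.2)


class TestLOOReliability:
    def test_exact_linear_dependence_r_one(self, tree12):
        tab = simulate_traits(tree12, np.eye(1), 0.8, [0.0], seed=4,
                              trait_names=["a"])
        tab["b"] = 2.0 * tab["a"] + 1.0
        params = fit_phylo_mvn(tab, tree12, lam=0.8)
        r = loo_reliability(tab, tree12, params)
        assert r["a"] >= 1 - 1e-6
        assert r["b"] >= 1 - 1e-6

    def test_noise_trait_uncorrelated(self):
        rs = []
        for rep in range(10):
            tree = simulate_tree(64, seed=60 + rep)
            rng = np.random.default_rng(rep)
            tab = simulate_traits(tree, np.eye(1), 0.9, [0.0], seed=rep,
                                  trait_names=["signal"])
            tab["noise"] = rng.normal(size=64)  # lambda=0, independent
            params = fit_phylo_mvn(tab, tree)
            rs.append(loo_reliability(tab, tree, params)["noise"])
        assert abs(np.mean(rs)) < 0.15

    def test_refit_mode_agrees_on_small_instance(self, tree12):
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        tab = simulate_traits(tree12, R, 0.8, [0, 0], seed=5)
        params = fit_phylo_mvn(tab, tree12, lam=0.8)
        fast = loo_reliability(tab, tree12, params)
        slow = loo_reliability(tab, tree12, params, refit=True)
        for k in fast:
            assert fast[k] == pytest.approx(slow[k], abs=0.15)

    def test_rmse_decreases_with_cross_trait_correlation(self):
        rmse = {}
        for rho in (0.0, 0.5, 0.9):
            errs = []
            for rep in range(15):
                tree = simulate_tree(40, seed=80 + rep)
                R = np.array([[1.0, rho], [rho, 1.0]])
                tab = simulate_traits(tree, R, 0.8, [0, 0], seed=rep)
                masked = apply_missingness(tab, {"trait0": 0.3}, seed=rep)
                params = fit_phylo_mvn(masked.data, tree)
                mom = impute_moments(masked.data, tree, params)
                truth = np.array([
                    masked.truth.loc[sp, tr]
                    for sp, tr in zip(mom.species, mom.traits)
                ])
                errs.append(np.sqrt(np.mean((mom.cond_mean - truth) ** 2)))
            rmse[rho] = np.mean(errs)
        assert rmse[0.9] < rmse[0.5] < rmse[0.0]
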