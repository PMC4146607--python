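import numpy as np
import pytest

from preyscale.data_io import TraitTable
from preyscale.errors import NumericalError, ParameterError
from preyscale.phylo_gls import (
    MODELS,
    aicc,
    apply_lambda,
    fit_pgls,
    gls_fit,
    loglik_at_lambda,
    phylo_covariance,
)
from preyscale.synthetic_data import SimulationConfig, simulate_dataset
from preyscale.treekit import Phylogeny

from conftest import make_frame, star_tree


def oracle_loglik(y, X, V):
    """Independent recomputation of the profiled ML log-likelihood."""
    n = len(y)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    e = y - X @ beta
    s2 = e @ Vi @ e / n
    sign, logdet = np.linalg.slogdet(V)
    assert sign > 0
    return -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * logdet - 0.5 * n


class TestPhyloCovariance:
    def test_three_tip_example(self, toy_tree):
        V = phylo_covariance(toy_tree, ["A_a", "B_b", "C_c"])
        np.testing.assert_allclose(V, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_species_order_respected(self, toy_tree):
        V = phylo_covariance(toy_tree, ["C_c", "A_a", "B_b"])
        np.testing.assert_allclose(V, [[2, 0, 0], [0, 2, 1], [0, 1, 2]])

    def test_star_tree_diagonal(self):
        t = star_tree(list("ABCD"), depth=3.0)
        V = phylo_covariance(t, list("ABCD"))
        np.testing.assert_allclose(V, 3.0 * np.eye(4))

    def test_sister_tips_share_parent_depth(self):
        t = Phylogeny.from_newick("(((A:1,B:1):2,C:3):1,D:4);")
        V = phylo_covariance(t, list("ABCD"))
        assert V[0, 1] == pytest.approx(3.0)  # parent of A,B at depth 3
        assert V[0, 2] == pytest.approx(1.0)
        assert V[0, 3] == pytest.approx(0.0)
        assert np.all(np.linalg.eigvalsh(V) > 0)

    def test_missing_species_error(self, toy_tree):
        from preyscale.errors import ValidationError

        with pytest.raises(ValidationError):
            phylo_covariance(toy_tree, ["A_a", "B_b", "Nope"])


class TestApplyLambda:
    def test_identity_at_one(self, toy_tree):
        V = phylo_covariance(toy_tree, ["A_a", "B_b", "C_c"])
        np.testing.assert_array_equal(apply_lambda(V, 1.0), V)

    def test_diagonal_at_zero(self, toy_tree):
        V = phylo_covariance(toy_tree, ["A_a", "B_b", "C_c"])
        np.testing.assert_array_equal(apply_lambda(V, 0.0), np.diag(np.diag(V)))

    def test_half(self):
        V = np.array([[2.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(
            apply_lambda(V, 0.5), [[2.0, 0.5], [0.5, 2.0]]
        )

    @pytest.mark.parametrize("lam", [-0.1, 1.1, 5.0])
    def test_out_of_range(self, lam):
        with pytest.raises(ParameterError):
            apply_lambda(np.eye(2), lam)


class TestGLSFit:
    def test_identity_covariance_matches_ols(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, p = 30, 3
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            beta, _se, _s2, _ll = gls_fit(y, X, np.eye(n))
            ols = np.linalg.lstsq(X, y, rcond=None)[0]
            np.testing.assert_allclose(beta, ols, rtol=1e-8)

    def test_intercept_only_oracle(self):
        # hand algebra: beta0 = mean, sigma2_ML = sum((y-mean)^2)/n
        beta, se, s2, ll = gls_fit(
            np.array([1.0, 2.0, 3.0]), np.ones((3, 1)), np.eye(3)
        )
        assert beta[0] == pytest.approx(2.0)
        assert s2 == pytest.approx(2.0 / 3.0)
        assert se[0] == pytest.approx(np.sqrt(s2 / 3))
        assert ll == pytest.approx(oracle_loglik(
            np.array([1.0, 2.0, 3.0]), np.ones((3, 1)), np.eye(3)
        ))

    def test_loglik_closed_form_random_psd(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 12
            A = rng.normal(size=(n, n))
            V = A @ A.T + n * np.eye(n)
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = rng.normal(size=n)
            _b, _se, _s2, ll = gls_fit(y, X, V)
            assert ll == pytest.approx(oracle_loglik(y, X, V), rel=1e-10)

    def test_duplicated_data_loglik_oracle(self):
        # duplicating (y, X) with block-diagonal identity changes loglik
        # exactly as the closed form dictates
        rng = np.random.default_rng(3)
        n = 15
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.5] + rng.normal(size=n)
        y2, X2 = np.tile(y, 2), np.vstack([X, X])
        _b, _se, _s2, ll2 = gls_fit(y2, X2, np.eye(2 * n))
        assert ll2 == pytest.approx(oracle_loglik(y2, X2, np.eye(2 * n)), rel=1e-10)

    def test_rank_deficient_design(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(NumericalError):
            gls_fit(np.arange(5.0), X, np.eye(5))

    def test_non_pd_covariance(self):
        V = np.ones((4, 4))
        with pytest.raises(NumericalError) as exc:
            gls_fit(np.arange(4.0), np.ones((4, 1)), V)
        assert "condition_number" in exc.value.diagnostics


class TestAICc:
    def test_stated_example(self):
        assert aicc(-5.0, 3, 10) == pytest.approx(20.0)

    def test_degenerate_n(self):
        with pytest.raises(ParameterError):
            aicc(-5.0, 5, 6)


@pytest.fixture(scope="module")
def sim_bundle():
    cfg = SimulationConfig(n_species=64, seed=21, lambda_true=0.7, sigma2=0.3)
    table, tree = simulate_dataset(cfg)
    return table, tree


class TestFitPGLS:
    def test_lambda_grid_oracle(self, sim_bundle):
        # the returned lambda-hat attains the profile max over a 1001-point
        # grid within 1e-3 log-units
        table, tree = sim_bundle
        fit = fit_pgls(table, tree, "min", "mass_only", effect_size=None)
        y = table.df["log_prey_min"].to_numpy()
        X = MODELS["mass_only"].design(table)
        V = phylo_covariance(tree, table.species)
        grid = np.linspace(0, 1, 1001)
        grid_best = max(loglik_at_lambda(y, X, V, g) for g in grid)
        assert fit.loglik >= grid_best - 1e-3

    def test_lambda_profile_continuity(self, sim_bundle):
        table, tree = sim_bundle
        y = table.df["log_prey_min"].to_numpy()
        X = MODELS["mass_only"].design(table)
        V = phylo_covariance(tree, table.species)
        grid = np.linspace(0, 1, 101)
        vals = np.array([loglik_at_lambda(y, X, V, g) for g in grid])
        assert np.all(np.isfinite(vals))
        # continuity: refining the steepest interval shrinks the largest
        # increment (a step discontinuity would keep it constant)
        j = int(np.argmax(np.abs(np.diff(vals))))
        worst = abs(vals[j + 1] - vals[j])
        fine = np.linspace(grid[j], grid[j + 1], 101)
        fvals = np.array([loglik_at_lambda(y, X, V, g) for g in fine])
        assert np.max(np.abs(np.diff(fvals))) < worst / 2

    def test_star_tree_lambda_has_no_effect(self):
        frame = make_frame(n=12, seed=4)
        table = TraitTable.from_frame(frame)
        star = star_tree(table.species, depth=1.0)
        f0 = fit_pgls(table, star, "min", "mass_only", lambda_mode=0.0, effect_size=None)
        f1 = fit_pgls(table, star, "min", "mass_only", lambda_mode=1.0, effect_size=None)
        np.testing.assert_allclose(f0.beta, f1.beta, atol=1e-8)
        assert f0.loglik == pytest.approx(f1.loglik, abs=1e-8)

    def test_nested_models_loglik_monotone(self, sim_bundle):
        table, tree = sim_bundle
        lls = {
            name: fit_pgls(
                table, tree, "min", name, lambda_mode=0.5, effect_size=None
            ).loglik
            for name in ("interaction", "mass_only", "null")
        }
        assert lls["interaction"] >= lls["mass_only"] - 1e-9
        assert lls["mass_only"] >= lls["null"] - 1e-9

    def test_aicc_invariant_and_k(self, sim_bundle):
        table, tree = sim_bundle
        fit = fit_pgls(table, tree, "min", "interaction", effect_size=None)
        assert fit.k == 4 + 2
        expected = -2 * fit.loglik + 2 * fit.k + 2 * fit.k * (fit.k + 1) / (
            fit.n - fit.k - 1
        )
        assert fit.aicc == pytest.approx(expected, rel=1e-12)
        fixed = fit_pgls(table, tree, "min", "interaction", lambda_mode=0.5,
                         effect_size=None)
        assert fixed.k == 4 + 1

    def test_lambda_bounds_and_se_shape(self, sim_bundle):
        table, tree = sim_bundle
        fit = fit_pgls(table, tree, "max", "interaction", effect_size=None)
        assert 0.0 <= fit.lambda_hat <= 1.0
        assert len(fit.beta) == len(fit.se) == 4

    def test_effect_size_conventions(self, sim_bundle):
        table, tree = sim_bundle
        lrt = fit_pgls(table, tree, "min", "mass_only", effect_size="lrt")
        tst = fit_pgls(table, tree, "min", "mass_only", effect_size="tstat")
        for fit in (lrt, tst):
            assert fit.effect_r is not None and 0.0 <= fit.effect_r <= 1.0
        null = fit_pgls(table, tree, "min", "null", effect_size="lrt")
        assert null.effect_r is None

    def test_zero_range_rows_excluded(self):
        frame = make_frame(n=12, seed=8, zero_range_rows=(0, 5))
        table = TraitTable.from_frame(frame)
        star = star_tree(table.species, depth=1.0)
        fit = fit_pgls(table, star, "range", "mass_only", effect_size=None)
        assert fit.n == 10
        assert len(fit.species) == 10

    def test_recovers_lambda_one(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_species=150, seed=seed, lambda_true=1.0,
                                   sigma2=0.4)
            table, tree = simulate_dataset(cfg)
            fit = fit_pgls(table, tree, "min", "mass_only", effect_size=None)
            hits += fit.lambda_hat >= 0.85
        assert hits >= 9

    def test_recovers_lambda_zero(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(n_species=150, seed=seed, lambda_true=0.0,
                                   sigma2=0.4)
            table, tree = simulate_dataset(cfg)
            fit = fit_pgls(table, tree, "min", "mass_only", effect_size=None)
            hits += fit.lambda_hat <= 0.15
        assert hits >= 9
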