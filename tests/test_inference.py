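import numpy as np
import pandas as pd
import pytest

from foodshock.experiments import run_grid, vulnerability_counts
from foodshock.inference import (
    FitError,
    build_country_table,
    build_dyadic_table,
    count_covariates,
    dyadic_covariates,
    negbin_fit,
    ols_fit,
    prune_covariates,
    standardize_coefficients,
    tobit_fit,
    _tobit_negll_olsen,
)
from foodshock.topology import node_features

from conftest import small_network


def censored_data(n=5000, seed=0, sigma=1.5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 3))
    beta = np.array([0.5, 1.0, -2.0, 0.7])
    ystar = beta[0] + X @ beta[1:] + rng.standard_normal(n) * sigma
    tab = pd.DataFrame(X, columns=["x1", "x2", "x3"])
    tab["dd"] = np.maximum(ystar, 0.0)
    return tab, beta, sigma


class TestDyadicTable:
    @pytest.fixture(scope="class")
    def chain3_parts(self):
        from foodshock.generate import fixture

        net = fixture("chain3")
        grid = run_grid(net, alphas=(0.0, 0.5, 1.0))
        feats = node_features(net)
        table = build_dyadic_table(grid, feats, net)
        return net, grid, feats, table

    def test_row_count(self, chain3_parts):
        _, _, _, table = chain3_parts
        assert len(table) == 3 * 3 * 3

    def test_distance_regimes(self, chain3_parts):
        _, _, _, table = chain3_parts
        row_ac = table.query("origin == 'A' and dest == 'C'").iloc[0]
        assert row_ac["indirect"] == 1.0  # distance 2
        assert row_ac["no_direct_link"] == 0.0
        row_ca = table.query("origin == 'C' and dest == 'A'").iloc[0]
        assert row_ca["no_direct_link"] == 1.0  # no directed path
        row_ab = table.query("origin == 'A' and dest == 'B'").iloc[0]
        assert (
            row_ab[["domestic", "indirect", "no_direct_link"]] == 0
        ).all()  # direct-link baseline
        row_aa = table.query("origin == 'A' and dest == 'A'").iloc[0]
        assert row_aa["domestic"] == 1.0

    def test_exactly_one_regime_per_row(self, chain3_parts):
        net, grid, feats, table = chain3_parts
        direct = (
            (table["domestic"] == 0)
            & (table["indirect"] == 0)
            & (table["no_direct_link"] == 0)
        )
        regimes = (
            table[["domestic", "indirect", "no_direct_link"]].sum(axis=1)
            + direct
        )
        assert (regimes == 1).all()

    def test_alpha_dummies(self, chain3_parts):
        _, _, _, table = chain3_parts
        assert table.groupby("alpha")["alpha_1"].mean().tolist() == [
            0.0,
            0.0,
            1.0,
        ]

    def test_network_hash_mismatch_rejected(self, chain3_parts):
        net, grid, feats, _ = chain3_parts
        other = small_network(0, n=8)
        with pytest.raises(FitError, match="different network"):
            build_dyadic_table(grid, node_features(other), other)


class TestTobit:
    def test_recovery_under_heavy_censoring(self):
        tab, beta, sigma = censored_data()
        assert 0.3 < (tab["dd"] == 0).mean() < 0.5
        r = tobit_fit(tab, ["x1", "x2", "x3"])
        est = r.params[["const", "x1", "x2", "x3"]].to_numpy()
        se = r.bse[["const", "x1", "x2", "x3"]].to_numpy()
        assert (np.abs(est - beta) < 3 * se).all()
        assert r.params["sigma"] == pytest.approx(sigma, rel=0.05)

    def test_uncensored_equals_least_squares(self):
        tab, *_ = censored_data()
        tab = tab.assign(dd=tab["dd"] + 10.0)  # shift off the boundary
        rt = tobit_fit(tab, ["x1", "x2", "x3"])
        ro = ols_fit(tab, ["x1", "x2", "x3"], "dd")
        np.testing.assert_allclose(
            rt.params[:-1].to_numpy(), ro.params.to_numpy(), atol=1e-6
        )

    def test_all_censored_refused(self):
        tab = pd.DataFrame({"x1": [1.0, 2.0, 3.0], "dd": [0.0, 0.0, 0.0]})
        with pytest.raises(FitError, match="censored"):
            tobit_fit(tab, ["x1"])

    def test_negative_response_refused(self):
        tab = pd.DataFrame({"x1": [1.0, 2.0], "dd": [-1.0, 2.0]})
        with pytest.raises(FitError):
            tobit_fit(tab, ["x1"])

    def test_objective_has_unique_optimum_from_multiple_starts(self):
        """The likelihood is concave in the (beta/sigma, 1/sigma) scale, so
        different starts must reach the same fit."""
        from scipy import optimize

        tab, *_ = censored_data(n=400, seed=3)
        X = np.column_stack(
            [np.ones(len(tab)), tab[["x1", "x2", "x3"]].to_numpy()]
        )
        y = tab["dd"].to_numpy()
        cens = y == 0
        rng = np.random.default_rng(0)
        sols = []
        for _ in range(4):
            theta0 = np.append(rng.standard_normal(4), rng.uniform(0.5, 3.0))
            res = optimize.minimize(
                _tobit_negll_olsen,
                theta0,
                args=(X, y, cens),
                method="Nelder-Mead",
                options={"maxiter": 20000, "fatol": 1e-12, "xatol": 1e-10},
            )
            sols.append(res.fun)
        assert np.ptp(sols) < 1e-5

    def test_pseudo_r2_in_unit_interval(self):
        tab, *_ = censored_data(n=1000, seed=5)
        r = tobit_fit(tab, ["x1", "x2", "x3"])
        assert 0 < r.stats["pseudo_r2"] < 1


class TestNegBin:
    def test_nb2_recovery(self):
        rng = np.random.default_rng(7)
        n = 516
        X = rng.standard_normal((n, 2))
        beta = np.array([1.0, 0.5, -0.3])
        mu = np.exp(beta[0] + X @ beta[1:])
        kappa = 0.5
        y = rng.negative_binomial(1 / kappa, 1 / (1 + kappa * mu))
        tab = pd.DataFrame(X, columns=["a", "b"])
        tab["count"] = y
        r = negbin_fit(tab, ["a", "b"])
        est = r.params[["const", "a", "b"]].to_numpy()
        se = r.bse[["const", "a", "b"]].to_numpy()
        assert (np.abs(est - beta) < 3 * se).all()
        assert r.stats["family"] == 1.0

    def test_poisson_data_gives_near_zero_dispersion(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((516, 2))
        mu = np.exp(1.0 + 0.4 * X[:, 0])
        tab = pd.DataFrame(X, columns=["a", "b"])
        tab["count"] = rng.poisson(mu)
        r = negbin_fit(tab, ["a", "b"])
        assert r.stats["dispersion"] < 0.05

    def test_intercept_only_mean_recovery(self):
        tab = pd.DataFrame({"count": [2] * 60})
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = negbin_fit(tab, [])
        assert np.exp(r.params["const"]) == pytest.approx(2.0, rel=1e-4)

    def test_all_zero_counts_refused(self):
        tab = pd.DataFrame({"a": [1.0, 2.0], "count": [0, 0]})
        with pytest.raises(FitError, match="zero"):
            negbin_fit(tab, ["a"])

    def test_non_integer_counts_refused(self):
        tab = pd.DataFrame({"a": [1.0, 2.0], "count": [0.5, 2.0]})
        with pytest.raises(FitError):
            negbin_fit(tab, ["a"])


class TestOLS:
    def test_noiseless_linear_r2_one(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 2))
        y = 1.0 + X @ np.array([2.0, -1.0])
        tab = pd.DataFrame(X, columns=["a", "b"])
        tab["y"] = y
        r = ols_fit(tab, ["a", "b"], "y")
        assert r.stats["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_recovery_with_noise(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((800, 2))
        beta = np.array([0.3, 1.2, -0.8])
        y = beta[0] + X @ beta[1:] + rng.standard_normal(800)
        tab = pd.DataFrame(X, columns=["a", "b"])
        tab["y"] = y
        r = ols_fit(tab, ["a", "b"], "y")
        est = r.params.to_numpy()
        assert (np.abs(est - beta) < 3 * r.bse.to_numpy()).all()

    def test_duplicated_column_named_in_error(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({"a": rng.standard_normal(50)})
        tab["a_copy"] = tab["a"]
        tab["y"] = tab["a"] * 2
        with pytest.raises(FitError, match="a_copy"):
            ols_fit(tab, ["a", "a_copy"], "y")

    def test_sandwich_close_to_classical_when_homoskedastic(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        X = rng.standard_normal((4000, 2))
        y = 1.0 + X @ np.array([1.0, -1.0]) + rng.standard_normal(4000)
        Xc = sm.add_constant(X)
        robust = sm.OLS(y, Xc).fit(cov_type="HC1").bse
        classical = sm.OLS(y, Xc).fit().bse
        np.testing.assert_allclose(robust, classical, rtol=0.1)


class TestStandardize:
    def test_slope_times_sd(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500) * 2.0
        tab = pd.DataFrame({"x": x, "y": 3.0 * x + 1.0})
        r = ols_fit(tab, ["x"], "y")
        s = standardize_coefficients(r)
        assert s["x"] == pytest.approx(3.0 * np.std(x, ddof=1), rel=1e-9)

    def test_indicator_passes_through(self):
        rng = np.random.default_rng(3)
        d = (rng.random(500) > 0.5).astype(float)
        x = rng.standard_normal(500)
        tab = pd.DataFrame({"x": x, "d": d})
        tab["y"] = x + 2.0 * d + rng.standard_normal(500) * 0.1
        r = ols_fit(tab, ["x", "d"], "y")
        s = standardize_coefficients(r)
        assert s["d"] == r.params["d"]

    def test_t_statistics_invariant(self):
        tab, *_ = censored_data(n=800, seed=9)
        r = tobit_fit(tab, ["x1", "x2", "x3"])
        s = standardize_coefficients(r)
        for c in ["x1", "x2", "x3"]:
            t_raw = r.params[c] / r.bse[c]
            t_std = s[c] / (r.bse[c] * r.exog_sd[c])
            assert t_std == pytest.approx(t_raw, rel=1e-12)

    def test_zero_variance_dropped_with_note(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        tab = pd.DataFrame({"x": x, "y": 2 * x})
        r = ols_fit(tab, ["x"], "y")
        r.exog_sd["x"] = 0.0
        r.is_indicator["x"] = False
        s = standardize_coefficients(r)
        assert "x" not in s.index
        assert s.attrs["dropped_zero_variance"] == ["x"]


class TestCountTable:
    def test_covariates_are_baseline_only(self):
        net = small_network(1, n=8)
        g = run_grid(net, alphas=(0.0, 1.0))
        feats = node_features(net)
        counts = vulnerability_counts(g, 1.0)
        tab = build_country_table(counts, feats, net, "count")
        # same country, different alpha -> identical covariates
        for cov in ["in_degree", "log_out_strength", "hub", "c4"]:
            by_alpha = tab.pivot(index="id", columns="alpha", values=cov)
            assert (by_alpha.nunique(axis=1) == 1).all()

    def test_prune_drops_constant_and_duplicate(self):
        tab = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0, 4.0],
                "b": [2.0, 4.0, 6.0, 8.0],
                "c": [1.0, 1.0, 1.0, 1.0],
            }
        )
        assert prune_covariates(tab, ["a", "b", "c"]) == ["a"]


class TestSyntheticGridSigns:
    def test_robust_tobit_signs_on_default_grid(
        self, default_net, default_grid
    ):
        """Domestic shocks raise a country's own deficit; destination
        export volume shields it (the escape-valve sign)."""
        from foodshock.inference import tobit_fit as _fit

        feats = node_features(default_net)
        table = build_dyadic_table(default_grid, feats, default_net)
        covs = prune_covariates(table, dyadic_covariates(default_grid))
        r = _fit(table, covs)
        assert r.params["domestic"] >= 0
        assert r.params["dest_log_out_strength"] <= 0
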