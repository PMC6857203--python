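"""ABC machinery: scaling, rejection, model choice, Bayes factors, and the
neural-net regression adjustment checked against a conjugate-normal oracle."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from divergesim import abc
from divergesim.simulator import LocusConfig, PriorSet, default_priors


class TestFilter:
    @pytest.mark.parametrize("fst,d,keep", [
        (0.2, 0.5, False),    # F_ST above 0.159
        (0.05, 0.5, True),
        (0.05, -0.01, False),  # D below 0
        (0.05, 1.01, False),   # D above 1
        (0.159, 0.0, True),    # boundary values retained
        (float("nan"), 0.5, False),
    ])
    def test_keep_drop(self, fst, d, keep):
        assert abc.filter_simulations(fst, d) is keep


class TestScaling:
    def test_mad_division(self, rng):
        X = rng.normal(size=(101, 3)) * np.array([1.0, 2.0, 5.0])
        Xs, obs_s, scale, keep = abc.mad_scale(X, X[0])
        from scipy.stats import median_abs_deviation
        assert np.allclose(scale, median_abs_deviation(X, axis=0, scale=1.0))
        assert np.allclose(Xs[0], obs_s)

    def test_idempotent_rescaling(self, rng):
        X = rng.normal(size=(101, 3))
        Xs, *_ = abc.mad_scale(X, X[0])
        Xss, *_ = abc.mad_scale(Xs, Xs[0])
        from scipy.stats import median_abs_deviation
        assert np.allclose(median_abs_deviation(Xss, axis=0, scale=1.0), 1.0)

    def test_distances_invariant_to_column_units(self, rng):
        X = rng.normal(size=(200, 4))
        obs = rng.normal(size=4)
        units = np.array([1.0, 3.5, 0.2, 40.0])
        d1 = np.linalg.norm(abc.mad_scale(X, obs)[0]
                            - abc.mad_scale(X, obs)[1], axis=1)
        d2 = np.linalg.norm(abc.mad_scale(X * units, obs * units)[0]
                            - abc.mad_scale(X * units, obs * units)[1], axis=1)
        assert np.allclose(d1, d2)

    def test_constant_columns_dropped(self, rng):
        X = np.hstack([rng.normal(size=(60, 2)), np.ones((60, 1))])
        with pytest.warns(UserWarning, match="constant"):
            Xs, *_ = abc.mad_scale(X, X[0])
        assert Xs.shape[1] == 2

    def test_all_constant_errors(self):
        with pytest.raises(ValueError):
            abc.mad_scale(np.ones((50, 2)), np.ones(2))


class TestWeights:
    def test_epanechnikov_bounds(self, rng):
        d = np.sort(rng.random(50))
        w = abc.epanechnikov_weights(d)
        assert np.all((0 <= w) & (w <= 1))

    def test_zero_distance_gets_weight_one(self):
        w = abc.epanechnikov_weights(np.array([0.0, 1.0, 2.0]))
        assert w[0] == 1.0

    def test_all_zero_distances(self):
        assert np.all(abc.epanechnikov_weights(np.zeros(5)) == 1.0)

    def test_weighted_quantile_median(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        q = abc.weighted_quantile(x, 0.5, np.ones(4))
        assert 2.0 <= q[0] <= 3.0


def _toy_tables(rng, n=600, separation=6.0):
    """Two models with well-separated 2-D summaries."""
    tables = {}
    for i, model in enumerate(["M0", "M1"]):
        stats = rng.normal(loc=i * separation, size=(n, 2))
        tables[model] = abc.ReferenceTable(
            model=model,
            params=pd.DataFrame({"theta": rng.uniform(1, 2, n)}),
            stats=stats, stat_names=["s1", "s2"],
            aux=pd.DataFrame(index=range(n)))
    return tables


class TestModelChoice:
    def test_separable_models_recovered(self, rng):
        tables = _toy_tables(rng)
        post = abc.abc_model_choice(np.array([0.1, -0.1]), tables,
                                    tolerance=0.1)
        assert post.best_model == "M0"
        assert post.mnlogistic["M0"] > 0.95
        assert post.rejection["M0"] > 0.95

    def test_probabilities_sum_to_one(self, rng):
        tables = _toy_tables(rng, separation=1.0)
        post = abc.abc_model_choice(np.array([0.5, 0.5]), tables, 0.2)
        assert sum(post.rejection.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(post.mnlogistic.values()) == pytest.approx(1.0, abs=1e-9)

    def test_uninformative_stats_recover_prior(self, rng):
        """Tolerance 1 with equal table sizes and exchangeable statistics
        gives rejection probabilities ~ 1/n_models."""
        tables = _toy_tables(rng, separation=0.0)
        post = abc.abc_model_choice(rng.normal(size=2), tables, tolerance=1.0)
        for p in post.rejection.values():
            assert abs(p - 0.5) < 0.05

    def test_missing_model_zero_probability(self, rng):
        tables = _toy_tables(rng, separation=50.0)
        with pytest.warns(UserWarning, match="absent"):
            post = abc.abc_model_choice(np.zeros(2), tables, tolerance=0.1)
        assert post.mnlogistic["M1"] == 0.0

    def test_sklearn_protocol(self, rng):
        tables = _toy_tables(rng)
        X, y, _ = abc.combine_tables(tables)
        est = abc.ABCModelChoice(tolerance=0.1)
        clone(est)  # get_params/set_params round trip
        est.fit(X, y)
        assert est.predict(np.array([[0.0, 0.0], [6.0, 6.0]])).tolist() \
            == ["M0", "M1"]

    def test_bayes_factors(self):
        post = abc.ModelPosterior(rejection={"a": 0.95, "b": 0.05},
                                  mnlogistic={"a": 0.95, "b": 0.05},
                                  tolerance=0.1, n_accepted=100)
        assert abc.bayes_factor(post, "a", "b") == pytest.approx(19.0)
        assert abc.bayes_factor(post, "a", "b") \
            * abc.bayes_factor(post, "b", "a") == pytest.approx(1.0)
        post.mnlogistic["b"] = 0.0
        assert math.isinf(abc.bayes_factor(post, "a", "b"))

    def test_cross_validation_identity_confusion(self, rng):
        tables = _toy_tables(rng, n=300, separation=8.0)
        conf = abc.cross_validate_model_choice(tables, n_pseudo=10,
                                               tolerance=0.2, seed=1)
        assert (conf.sum(axis=1) == 10).all()
        assert conf.loc["M0", "M0"] == 10
        assert conf.loc["M1", "M1"] == 10


class TestReferenceTable:
    def test_determinism_and_point_mass_priors(self):
        pri = PriorSet({
            "Ne_K": ("uniform", 2e5, 2e5 + 1e-9),
            "Ne_W": ("uniform", 2e5, 2e5 + 1e-9),
            "Ne_A": ("uniform", 2e5, 2e5 + 1e-9),
            "T": ("uniform", 1e6, 1e6 + 1e-9),
        })
        cfg = LocusConfig()
        kw = dict(n_loci=5, locus_config=cfg, seed=7, apply_filter=False)
        t1 = abc.build_reference_table("ISO-A", pri, 20, **kw)
        t2 = abc.build_reference_table("ISO-A", pri, 20, **kw)
        assert np.array_equal(t1.stats, t2.stats)
        assert t1.n_rows == 20
        # point-mass prior: identical parameters, varying summaries
        assert np.ptp(t1.params["Ne_K"]) < 1e-6
        assert np.std(t1.stats[:, 0]) > 0

    def test_filter_tally_reported(self):
        tab = abc.build_reference_table("SC-B", default_priors(), 60,
                                        n_loci=5, seed=3, apply_filter=True)
        assert tab.n_raw == 60
        assert tab.n_rows + tab.n_filtered == 60

    def test_incompatible_filter_errors(self):
        pri = default_priors()
        # tiny sizes force extreme differentiation: everything filtered
        for k in ("Ne_K", "Ne_W", "Ne_A"):
            pri.specs[k] = ("uniform", 1e3, 2e3)
        pri.specs["T"] = ("uniform", 1.9e6, 2.0e6)
        with pytest.raises(RuntimeError, match="filtered"):
            abc.build_reference_table("ISO-A", pri, 4000, n_loci=5, seed=1)


class TestRegressionAdjustment:
    def test_conjugate_normal_oracle(self):
        """theta ~ N(0, tau2), s = theta + eps: the rejection and adjusted
        posterior means must both sit within Monte-Carlo error of the
        analytic posterior mean tau2 s / (tau2 + sigma2)."""
        rng = np.random.default_rng(1)
        tau2, sig2, n = 1.0, 0.5, 40_000
        theta = rng.normal(0, np.sqrt(tau2), n)
        s = theta + rng.normal(0, np.sqrt(sig2), n)
        s_obs = 1.3
        analytic_mean = tau2 / (tau2 + sig2) * s_obs
        analytic_sd = np.sqrt(tau2 * sig2 / (tau2 + sig2))
        est = abc.ABCPosteriorRegressor(tolerance=0.01, n_networks=8,
                                        transform="none", random_state=3)
        est.fit(s[:, None], pd.DataFrame({"theta": theta}))
        post = est.adjust([s_obs])
        n_eff = post.weights.sum() ** 2 / (post.weights ** 2).sum()
        mc_err = 3 * analytic_sd / np.sqrt(n_eff)
        rej_mean = np.average(post.accepted["theta"], weights=post.weights)
        adj_mean = post.point_estimates["theta"]["mean"]
        assert abs(rej_mean - analytic_mean) < mc_err + 0.05
        assert abs(adj_mean - analytic_mean) < mc_err + 0.05

    def test_zero_distance_observation_passthrough(self, rng):
        stats = rng.normal(size=(500, 3))
        params = pd.DataFrame({"a": rng.uniform(1, 2, 500)})
        est = abc.ABCPosteriorRegressor(tolerance=1 / 500, n_networks=3,
                                        transform="log")
        est.fit(stats, params)
        post = est.adjust(stats[42])
        assert post.n_accepted == 1
        assert post.adjusted["a"].iloc[0] == pytest.approx(
            params["a"].iloc[42])

    def test_log_transform_requires_positive(self, rng):
        est = abc.ABCPosteriorRegressor(transform="log")
        with pytest.raises(ValueError, match="positive"):
            est.fit(rng.normal(size=(50, 2)),
                    pd.DataFrame({"a": rng.normal(size=50)}))

    def test_point_estimate_table_shape(self, rng):
        stats = rng.normal(size=(400, 2))
        params = pd.DataFrame({"a": rng.uniform(1, 2, 400),
                               "b": rng.uniform(10, 20, 400)})
        est = abc.ABCPosteriorRegressor(tolerance=0.25, n_networks=3,
                                        random_state=1)
        est.fit(stats, params)
        pe = est.adjust(np.zeros(2)).point_estimates
        assert list(pe.index) == ["median", "mean", "mode", "q2.5", "q97.5"]
        assert list(pe.columns) == ["a", "b"]
        for c in pe.columns:
            assert pe[c]["q2.5"] <= pe[c]["median"] <= pe[c]["q97.5"]

    def test_label_symmetry_of_acceptance(self, rng):
        """Swapping population labels in both observation and reference
        table swaps the two size posteriors exactly at the acceptance stage
        (same accepted rows, same weights, swapped parameter columns)."""
        n = 2000
        stats = rng.normal(size=(n, 4))  # (pi_K, pi_W, d_K, d_W)-like
        params = pd.DataFrame({
            "Ne_K": np.exp(rng.uniform(9, 16, n)),
            "Ne_W": np.exp(rng.uniform(9, 16, n)),
        })
        obs = np.array([0.3, -0.2, 0.1, 0.4])
        swap_cols = [1, 0, 3, 2]
        est = abc.ABCPosteriorRegressor(tolerance=0.05, n_networks=2,
                                        random_state=7)
        est.fit(stats, params)
        post = est.adjust(obs)
        est2 = abc.ABCPosteriorRegressor(tolerance=0.05, n_networks=2,
                                         random_state=7)
        est2.fit(stats[:, swap_cols],
                 params.rename(columns={"Ne_K": "Ne_W", "Ne_W": "Ne_K"})
                 [["Ne_K", "Ne_W"]])
        post2 = est2.adjust(obs[swap_cols])
        assert np.allclose(post.weights, post2.weights)
        assert np.allclose(post.accepted["Ne_K"], post2.accepted["Ne_W"])
        med1 = abc.weighted_quantile(post.accepted["Ne_K"].to_numpy(), 0.5,
                                     post.weights)
        med2 = abc.weighted_quantile(post2.accepted["Ne_W"].to_numpy(), 0.5,
                                     post2.weights)
        assert med1[0] == pytest.approx(med2[0])


class TestTwoStage:
    def test_two_stage_structure(self, rng):
        """Four models in two groups: winners per group, then a final."""
        tables = {}
        for i, model in enumerate(["ISO-A", "SC-A", "ISO-B", "SC-B"]):
            stats = rng.normal(loc=i * 2.0, size=(300, 2))
            tables[model] = abc.ReferenceTable(
                model=model, params=pd.DataFrame({"T": rng.uniform(1, 2, 300)}),
                stats=stats, stat_names=["s1", "s2"],
                aux=pd.DataFrame(index=range(300)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = abc.two_stage_model_choice(np.array([6.0, 6.0]), tables,
                                             tolerance=0.2)
        assert set(res["finalists"]) == {"A", "B"}
        assert res["final"].best_model in res["finalists"].values()
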