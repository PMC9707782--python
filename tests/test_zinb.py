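"""Count-model core: marginal likelihood, fitting, AICc bookkeeping.

The quadrature marginal likelihood is checked against a brute-force
trapezoid integration built directly on scipy's negative-binomial pmf, and
the fitted coefficients against a plain NB regression from statsmodels in
the degenerate (no zero inflation, no random effect) regime.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from beartrack.zinb import (ModelSpec, aicc, akaike_weights, build_design,
                            compare_sets, fit, table1_model_sets,
                            table2_model_set, zinb_nll)


def brute_force_nll(params, design, family, ngrid=4001, span=10.0):
    """Independent oracle: trapezoid integration of the random effect."""
    p = design.X.shape[1]
    beta = params[:p]
    pi = special.expit(params[p])
    disp = math.exp(params[p + 1])
    sigma = math.exp(params[p + 2])
    eta = design.X @ beta + design.offset
    z = np.linspace(-span, span, ngrid)
    total = 0.0
    for s in range(design.n_sites):
        m = design.site_idx == s
        ys, es = design.y[m], eta[m]
        mus = np.exp(es[None, :] + sigma * z[:, None])
        if family == "nb2":
            logf = stats.nbinom.logpmf(ys[None, :], disp, disp / (disp + mus))
        else:
            logf = stats.nbinom.logpmf(ys[None, :], mus / disp, 1.0 / (1.0 + disp))
        lm = np.where(ys[None, :] == 0,
                      np.logaddexp(np.log(pi), np.log1p(-pi) + logf),
                      np.log1p(-pi) + logf)
        integrand = lm.sum(axis=1) + stats.norm.logpdf(z)
        peak = integrand.max()
        total += math.log(np.trapezoid(np.exp(integrand - peak), z)) + peak
    return -total


@pytest.fixture(scope="module")
def design20(small_zinb_dataset):
    data, _ = small_zinb_dataset
    return build_design(ModelSpec("m", ("x1",), "nb2"), data)


class TestMarginalLikelihood:
    @pytest.mark.parametrize("family", ["nb2", "nb1"])
    @pytest.mark.parametrize("sigma", [0.3, 0.7, 1.2])
    def test_quadrature_matches_trapezoid(self, design20, family, sigma):
        params = np.array([-1.0, 0.5, special.logit(0.3), math.log(0.8),
                           math.log(sigma)])
        got = zinb_nll(params, design20, family)
        want = brute_force_nll(params, design20, family)
        assert abs(got - want) / abs(want) < 1e-6

    def test_degenerate_limit_is_plain_nb(self, design20):
        """pi -> 0, sigma -> 0 reduces to an unmixed NB regression."""
        params = np.array([-1.0, 0.5, -30.0, math.log(0.8), math.log(1e-12)])
        got = zinb_nll(params, design20, "nb2")
        mu = np.exp(design20.X @ params[:2] + design20.offset)
        direct = -stats.nbinom.logpmf(design20.y, 0.8, 0.8 / (0.8 + mu)).sum()
        assert got == pytest.approx(direct, rel=1e-9)

    def test_large_theta_approaches_poisson(self, design20):
        """theta -> infinity turns the count part into a Poisson within the
        same zero-inflation mixture."""
        pi_logit = -4.0
        params = np.array([-1.0, 0.5, pi_logit, math.log(1e7), math.log(1e-12)])
        got = zinb_nll(params, design20, "nb2")
        mu = np.exp(design20.X @ params[:2] + design20.offset)
        logpo = stats.poisson.logpmf(design20.y, mu)
        l1mpi = -np.logaddexp(0.0, pi_logit)
        lm = np.where(design20.y == 0,
                      np.logaddexp(pi_logit + l1mpi, l1mpi + logpo),
                      l1mpi + logpo)
        # agreement is limited by the O(1/theta) truncation of the limit
        assert got == pytest.approx(-lm.sum(), rel=1e-5)


class TestDesignBookkeeping:
    def test_table1_parameter_counts(self):
        sets = table1_model_sets()
        assert sets["conflict"][0].k == 13   # with TD*HD interaction
        assert sets["conflict"][1].k == 12   # without
        assert sets["full"][0].k == 16
        assert sets["environmental"][0].k == 8
        assert sets["null"][0].k == 4        # intercept + sigma + dispersion + zi

    def test_table2_parameter_counts(self):
        k = {s.name: s.k for s in table2_model_set()}
        assert k["conflict_x_season"] == 11
        assert k["season"] == 7
        assert k["null"] == 4
        assert len(k) == 8 and "null" in k

    def test_design_columns_and_season_reference(self, default_bundle):
        data = default_bundle.site_month
        spec = ModelSpec("s", ("season",), "nb2")
        d = build_design(spec, data)
        assert d.colnames == ["(Intercept)", "season[summer]", "season[autumn]",
                              "season[winter]"]
        # spring rows are all-zero in the dummies (reference level)
        spring = data.loc[data["effort"] > 0, "season"].to_numpy() == "spring"
        assert (d.X[spring, 1:] == 0).all()

    def test_zero_effort_rows_dropped_and_logged(self):
        data = pd.DataFrame({
            "site_id": ["A", "A", "B"], "count": [1, 0, 2],
            "effort": [10, 0, 20], "x1": [0.1, 0.2, -0.1],
        })
        d = build_design(ModelSpec("m", ("x1",), "nb2"), data)
        assert d.n == 2 and d.n_dropped == 1

    def test_missing_covariate_errors(self):
        data = pd.DataFrame({"site_id": ["A"], "count": [1], "effort": [10]})
        with pytest.raises(ValueError, match="missing"):
            build_design(ModelSpec("m", ("HD",), "nb2"), data)


class TestAicc:
    def test_example_value(self):
        assert aicc(-5.0, 3, 10) == pytest.approx(20.0)

    def test_limits(self):
        assert aicc(-7.0, 0, 50) == pytest.approx(14.0)
        big_n = aicc(-5.0, 3, 10**7)
        assert big_n == pytest.approx(16.0, abs=1e-4)  # approaches AIC
        with pytest.raises(ValueError):
            aicc(-5.0, 9, 10)


class TestAkaikeWeights:
    def test_examples(self):
        np.testing.assert_allclose(akaike_weights([100.0, 100.0]), [0.5, 0.5])
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-3)

    def test_sum_to_one_and_ratio_identity(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(50, 80, 6)
        w = akaike_weights(a)
        assert w.sum() == pytest.approx(1.0)
        # w_i / w_j = exp((a_j - a_i)/2) for every pair
        for i in range(6):
            for j in range(6):
                assert w[i] / w[j] == pytest.approx(math.exp((a[j] - a[i]) / 2))


class TestFitting:
    def test_recovers_truth_within_3se(self, small_zinb_dataset):
        data, truth = small_zinb_dataset
        res = fit(ModelSpec("m", ("x1",), "nb2"), data, seed=0)
        assert res.converged
        for est, se, tv in zip(res.coef["estimate"], res.coef["se"], truth["beta"]):
            assert abs(est - tv) < 3 * se
        assert res.k == 5 and res.n == len(data)

    def test_deterministic_refit(self, small_zinb_dataset):
        data, _ = small_zinb_dataset
        a = fit(ModelSpec("m", ("x1",), "nb2"), data, seed=3)
        b = fit(ModelSpec("m", ("x1",), "nb2"), data, seed=3)
        np.testing.assert_array_equal(a.params, b.params)

    def test_intercept_only_moment_check(self):
        """Near-Poisson data, no zeros inflation: intercept ~ log(rate)."""
        rng = np.random.default_rng(8)
        n_sites, m = 30, 13
        effort = rng.integers(20, 31, n_sites * m)
        rate = 0.4
        data = pd.DataFrame({
            "site_id": np.repeat([f"S{i}" for i in range(n_sites)], m),
            "effort": effort,
            "count": rng.poisson(rate * effort),
        })
        res = fit(ModelSpec("null", (), "nb2"), data, seed=0)
        assert res.coef.loc["(Intercept)", "estimate"] == pytest.approx(
            math.log(rate), abs=0.08)
        assert res.pi < 0.1 and res.sigma_site < 0.15

    def test_matches_statsmodels_nb_regression(self):
        """Degenerate regime cross-check against an independent fitter."""
        sm_api = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        n = 600
        x = rng.standard_normal(n)
        mu = np.exp(0.5 + 0.6 * x) * 10.0
        theta = 2.0
        y = rng.negative_binomial(theta, theta / (theta + mu))
        data = pd.DataFrame({"site_id": [f"S{i}" for i in range(n)],
                             "count": y, "effort": 10.0, "x1": x})
        ours = fit(ModelSpec("m", ("x1",), "nb2"), data, seed=0)
        X = sm_api.add_constant(x)
        ref = sm_api.NegativeBinomial(y, X, offset=np.full(n, math.log(10.0))).fit(disp=0)
        np.testing.assert_allclose(ours.coef["estimate"], ref.params[:2], atol=0.03)
        assert ours.pi < 0.05


class TestComparison:
    def _mock_fit(self, name, set_name, ll, k=5, n=200):
        spec = ModelSpec(name, ("x1",), "nb2", set_name)
        return type("F", (), {
            "spec": spec, "name": name, "family": "nb2", "k": k, "n": n,
            "loglik": ll, "aicc": aicc(ll, k, n), "converged": True})()

    def test_within_and_between_deltas(self):
        fits = {
            "A": [self._mock_fit("a1", "A", -50.0), self._mock_fit("a2", "A", -50.3)],
            "B": [self._mock_fit("b1", "B", -52.0)],
        }
        df = compare_sets(fits).set_index("model")
        assert df.loc["a1", "delta_within"] == 0.0
        assert df.loc["a2", "delta_within"] == pytest.approx(0.6)
        assert df.loc["a1", "delta_between"] == 0.0
        assert df.loc["b1", "delta_between"] == pytest.approx(4.0)
        assert df["weight"].sum() == pytest.approx(1.0)
        # at delta 0.6 the weight ratio is exp(0.3), the published-table ratio
        assert (df.loc["a1", "weight"] / df.loc["a2", "weight"]
                == pytest.approx(math.exp(0.3)))

    def test_single_model_weight_one(self):
        df = compare_sets({"A": [self._mock_fit("a", "A", -10.0)]})
        assert df["weight"].iloc[0] == pytest.approx(1.0)
        assert df["delta_within"].iloc[0] == 0.0


class TestYamlSpecs:
    def test_round_trip_published_candidate_list(self, tmp_path):
        from beartrack.zinb import specs_from_yaml
        doc = """
models:
  - name: conflict
    set: conflict
    terms: [HD, "HD^2", RD, EVI, DUrb, DAg, Ele, TD, "TD*HD"]
  - name: season_only
    set: seasonal
    family: nb1
    terms: [season]
  - name: "null"
"""
        path = tmp_path / "models.yaml"
        path.write_text(doc)
        specs = specs_from_yaml(path)
        assert [s.k for s in specs] == [13, 7, 4]
        assert specs[1].family == "nb1"
        assert specs[2].terms == ()
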