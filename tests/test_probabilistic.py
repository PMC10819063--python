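import numpy as np
import pytest
from scipy import stats

from pyrethrisk import FittedDistribution, fit_from_percentiles, run_monte_carlo
from pyrethrisk.errors import AnchorError, ConfigurationError


def _anchors_from(dist, ranks=(5, 50, 95)):
    return [(r, float(dist.ppf(r / 100))) for r in ranks]


class TestAnchorValidation:
    def test_non_monotone_values_rejected(self):
        with pytest.raises(AnchorError):
            fit_from_percentiles([(5, 2.0), (50, 1.0), (95, 3.0)])

    def test_near_degenerate_anchors_rejected(self):
        with pytest.raises(AnchorError):
            fit_from_percentiles([(5, 1.0), (50, 1.0 + 1e-9), (95, 1.0 + 2e-9)])

    def test_ranks_outside_open_interval_rejected(self):
        with pytest.raises(AnchorError):
            fit_from_percentiles([(0, 1.0), (50, 2.0), (95, 3.0)])

    def test_nonpositive_values_rejected(self):
        with pytest.raises(AnchorError):
            fit_from_percentiles([(5, -1.0), (50, 2.0), (95, 3.0)])


class TestRoundTripRecovery:
    """Fitting exact quantiles of a skewed gallery member recovers it."""

    @pytest.mark.parametrize("shape,scale", [(1.5, 2.0), (4.0, 0.5), (9.0, 1.2)])
    def test_gamma(self, shape, scale):
        fit = fit_from_percentiles(_anchors_from(stats.gamma(shape, scale=scale)))
        assert fit.family == "gamma"
        assert fit.params["shape"] == pytest.approx(shape, rel=0.01)
        assert fit.params["scale"] == pytest.approx(scale, rel=0.01)

    @pytest.mark.parametrize("mu,sigma", [(0.0, 0.8), (1.3, 0.4), (-1.0, 1.2)])
    def test_lognormal(self, mu, sigma):
        fit = fit_from_percentiles(_anchors_from(stats.lognorm(sigma, scale=np.exp(mu))))
        assert fit.family == "lognormal"
        assert fit.params["mu"] == pytest.approx(mu, abs=0.01 * max(1, abs(mu)))
        assert fit.params["sigma"] == pytest.approx(sigma, rel=0.01)

    @pytest.mark.parametrize("shape,scale", [(0.8, 1.0), (2.5, 3.0)])
    def test_weibull(self, shape, scale):
        fit = fit_from_percentiles(_anchors_from(stats.weibull_min(shape, scale=scale)))
        assert fit.family == "weibull"
        assert fit.params["shape"] == pytest.approx(shape, rel=0.01)
        assert fit.params["scale"] == pytest.approx(scale, rel=0.01)

    def test_asymmetric_triangular(self):
        a, c, b = 1.0, 2.0, 8.0
        dist = stats.triang((c - a) / (b - a), loc=a, scale=b - a)
        fit = fit_from_percentiles(_anchors_from(dist))
        assert fit.family == "triangular"
        assert fit.params["min"] == pytest.approx(a, abs=0.01 * (b - a))
        assert fit.params["mode"] == pytest.approx(c, abs=0.01 * (b - a))
        assert fit.params["max"] == pytest.approx(b, abs=0.01 * (b - a))

    def test_symmetric_anchors_select_symmetric_family(self):
        """Symmetric triples are a tie class; a symmetric family must win over lognormal."""
        fit = fit_from_percentiles([(10, 4.0), (50, 5.0), (90, 6.0)], nonnegative=False)
        assert fit.family in ("normal", "triangular", "uniform")
        assert fit.fit_error < 1e-12
        assert "lognormal" in fit.candidates
        assert fit.candidates["lognormal"][1] > fit.fit_error

    def test_normal_anchor_parameters_recovered_within_family(self):
        mu, sigma = 10.0, 2.0
        fit = fit_from_percentiles(_anchors_from(stats.norm(mu, sigma)), nonnegative=False)
        params, err = fit.candidates["normal"]
        assert err < 1e-12
        assert params["mu"] == pytest.approx(mu, rel=0.01)
        assert params["sigma"] == pytest.approx(sigma, rel=0.01)

    def test_uniform_anchor_parameters_recovered_within_family(self):
        lo, hi = 2.0, 10.0
        fit = fit_from_percentiles(_anchors_from(stats.uniform(lo, hi - lo)), nonnegative=False)
        params, err = fit.candidates["uniform"]
        assert err < 1e-12
        assert params["min"] == pytest.approx(lo, rel=0.01)
        assert params["max"] == pytest.approx(hi, rel=0.01)

    def test_fit_error_anchored_quantiles_reproduced(self):
        anchors = [(10, 20.58), (50, 61.56), (90, 85.55)]
        fit = fit_from_percentiles(anchors)
        q = fit.quantile(np.array([0.10, 0.50, 0.90]))
        rel = np.abs(q - np.array([20.58, 61.56, 85.55])) / np.array([20.58, 61.56, 85.55])
        assert np.sum(rel**2) == pytest.approx(fit.fit_error, abs=1e-12)

    def test_gallery_subset_restricts_choice(self):
        anchors = _anchors_from(stats.gamma(2.0, scale=1.0))
        fit = fit_from_percentiles(anchors, gallery=("lognormal", "normal"))
        assert fit.family in ("lognormal", "normal")


class TestMonteCarlo:
    def test_point_masses_reproduce_deterministic_pipeline(self):
        level = FittedDistribution.point_mass(3.2)
        contribs = {
            "cypermethrin": FittedDistribution.point_mass(60.0),
            "permethrin": FittedDistribution.point_mass(40.0),
        }
        gvs = {"cypermethrin": 10.0, "permethrin": 64.0}
        res = run_monte_carlo(level, contribs, gvs, n=500, seed=1, keep_samples=True)
        from pyrethrisk import attribute_measured_level, hazard_quotient

        expected = sum(
            hazard_quotient(attribute_measured_level(3.2, pct), gvs[sub])
            for sub, pct in [("cypermethrin", 60.0), ("permethrin", 40.0)]
        )
        assert (res.samples["total"] == expected).all()
        # identical draws; sd is pure floating round-off of the sample mean
        assert res.total_summary.sd == pytest.approx(0.0, abs=1e-15)
        assert res.exceedance == 0.0

    def test_lognormal_level_mean_matches_closed_form(self):
        mu, sigma, gv = 1.0, 0.5, 50.0
        level = FittedDistribution(
            family="lognormal", params={"mu": mu, "sigma": sigma}, fit_error=0.0,
            anchors=((50, np.exp(mu)),),
        )
        contribs = {"permethrin": FittedDistribution.point_mass(100.0)}
        res = run_monte_carlo(level, contribs, {"permethrin": gv}, n=10_000, seed=3,
                              keep_samples=True)
        analytic_mean = np.exp(mu + sigma**2 / 2) / gv
        se = res.total_summary.sd / np.sqrt(res.n_iterations)
        assert abs(res.total_summary.mean - analytic_mean) < 3 * se

    def test_same_seed_bit_identical_different_seeds_close(self):
        level = FittedDistribution(
            family="gamma", params={"shape": 4.0, "scale": 0.5}, fit_error=0.0,
            anchors=((50, 1.8),),
        )
        contribs = {"cypermethrin": FittedDistribution(
            family="triangular", params={"min": 20.0, "mode": 45.0, "max": 70.0},
            fit_error=0.0, anchors=((50, 45.0),),
        )}
        gvs = {"cypermethrin": 5.0}
        a = run_monte_carlo(level, contribs, gvs, n=10_000, seed=7)
        b = run_monte_carlo(level, contribs, gvs, n=10_000, seed=7)
        c = run_monte_carlo(level, contribs, gvs, n=10_000, seed=8)
        assert a.total_summary == b.total_summary
        assert a.exceedance == b.exceedance
        se = a.total_summary.sd / np.sqrt(a.n_iterations)
        assert abs(a.total_summary.mean - c.total_summary.mean) < 3 * np.sqrt(2) * se

    def test_exceedance_converges_to_analytic_value(self):
        mu, sigma, gv = 0.0, 0.8, 1.5
        level = FittedDistribution(
            family="lognormal", params={"mu": mu, "sigma": sigma}, fit_error=0.0,
            anchors=((50, 1.0),),
        )
        contribs = {"permethrin": FittedDistribution.point_mass(100.0)}
        analytic = float(stats.lognorm(sigma, scale=np.exp(mu)).sf(gv))
        small = run_monte_carlo(level, contribs, {"permethrin": gv}, n=100, seed=5, threshold=1.0)
        large = run_monte_carlo(level, contribs, {"permethrin": gv}, n=10_000, seed=5, threshold=1.0)
        assert abs(large.exceedance - analytic) < abs(small.exceedance - analytic) + 0.01
        assert abs(large.exceedance - analytic) < 0.02

    def test_contribution_clipping_rare_at_realistic_anchors(self):
        """Adult generic-metabolite contribution anchors need almost no clipping."""
        level = FittedDistribution.point_mass(1.0)
        tri = fit_from_percentiles([(10, 29.79), (50, 43.60), (90, 61.41)],
                                   gallery=("triangular",))
        logn = fit_from_percentiles([(10, 5.14), (50, 11.79), (90, 18.44)],
                                    gallery=("lognormal",))
        res = run_monte_carlo(
            level, {"a": tri, "b": logn}, {"a": 1.0, "b": 1.0}, n=20_000, seed=2
        )
        assert res.clip_fractions["a"] < 0.005
        assert res.clip_fractions["b"] < 0.005

    def test_renormalisation_restores_partition(self):
        level = FittedDistribution.point_mass(10.0)
        contribs = {
            "a": FittedDistribution(
                family="normal", params={"mu": 70.0, "sigma": 5.0}, fit_error=0.0,
                anchors=((50, 70.0),)),
            "b": FittedDistribution(
                family="normal", params={"mu": 50.0, "sigma": 5.0}, fit_error=0.0,
                anchors=((50, 50.0),)),
        }
        res = run_monte_carlo(level, contribs, {"a": 1.0, "b": 1.0}, n=2_000, seed=9,
                              renormalize=True, keep_samples=True)
        totals = res.samples["hq"]["a"] + res.samples["hq"]["b"]
        assert np.allclose(totals, 10.0)  # level * 100% / gv 1.0

    def test_invalid_inputs_rejected(self):
        level = FittedDistribution.point_mass(1.0)
        good = {"a": FittedDistribution.point_mass(100.0)}
        with pytest.raises(ConfigurationError):
            run_monte_carlo(level, good, {"a": 0.0}, n=10, seed=0)
        with pytest.raises(ConfigurationError):
            run_monte_carlo(level, good, {}, n=10, seed=0)
        with pytest.raises(ConfigurationError):
            run_monte_carlo(level, {}, {}, n=10, seed=0)
        with pytest.raises(ConfigurationError):
            run_monte_carlo(level, {"a": 42.0}, {"a": 1.0}, n=10, seed=0)
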