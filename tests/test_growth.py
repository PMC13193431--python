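"""Growth functions, Bayesian fitting, model comparison and sex contrasts."""

import numpy as np
import pytest
from scipy import stats

from raygrowth.growth import (GROWTH_FAMILIES, MCMCSettings, REDUCED_MCMC,
                              build_growth_input, compare_models,
                              fit_growth_bayes, fit_growth_lsq, predict_size,
                              sex_difference)

LOGISTIC_TRUTH = dict(dw_inf=401.70, k=0.45, t0=-0.36)


def _logistic_data(n=200, sigma=20.0, seed=0, truth=LOGISTIC_TRUTH):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 11, n)
    dw = predict_size("logistic", t, **truth) + sigma * rng.standard_normal(n)
    return t, dw


class TestPredictSize:
    def test_logistic_inflection_is_half_asymptote(self):
        assert predict_size("logistic", -0.36, **LOGISTIC_TRUTH) == \
            pytest.approx(401.70 / 2)

    def test_vbgm2_anchored_at_birth_size(self):
        assert predict_size("vbgm2", 0.0, dw_inf=400.0, k=0.4, dw0=217.0) == 217.0

    @pytest.mark.parametrize("family,kw", [
        ("vbgm3", dict(dw_inf=588.96, k=0.13, t0=-3.77)),
        ("vbgm2", dict(dw_inf=506.15, k=0.22, dw0=215.0)),
        ("gompertz", dict(dw_inf=537.03, k=0.21, t0=-0.64)),
        ("logistic", dict(dw_inf=512.22, k=0.29, t0=0.82))])
    def test_monotone_increasing_in_age(self, family, kw):
        t = np.linspace(0, 30, 200)
        assert np.all(np.diff(predict_size(family, t, **kw)) > 0)

    @pytest.mark.parametrize("family,kw", [
        ("vbgm3", dict(dw_inf=588.96, k=0.13, t0=-3.77)),
        ("logistic", dict(dw_inf=401.70, k=0.45, t0=-0.36))])
    def test_asymptote_reached(self, family, kw):
        far = predict_size(family, 1000.0 / kw["k"], **kw)
        assert abs(far - kw["dw_inf"]) < 1e-6 * kw["dw_inf"]

    def test_unknown_family_and_missing_params(self):
        with pytest.raises(ValueError):
            predict_size("richards", 1.0, dw_inf=400, k=0.3, t0=0)
        with pytest.raises(ValueError):
            predict_size("logistic", 1.0, dw_inf=400, k=0.3)
        with pytest.raises(ValueError):
            predict_size("vbgm2", 1.0, dw_inf=400, k=0.3)


class TestGrowthInput:
    def test_one_fish_three_bands(self):
        import pandas as pd
        pairs = pd.DataFrame({"fish_id": "a", "sex": "M",
                              "age": [0, 1, 2], "dw_back": [200., 280., 330.]})
        t, dw = build_growth_input(pairs, "M")
        assert len(t) == 3

    def test_sexes_partition_input(self, small_ds):
        from raygrowth.backcalc import back_calculate_all, fit_dw_vr
        fit = fit_dw_vr(small_ds.data)
        pairs = back_calculate_all(
            small_ds.data.assign(age=small_ds.data["read1"]), fit)
        tm, _ = build_growth_input(pairs, "M")
        tf, _ = build_growth_input(pairs, "F")
        assert len(tm) + len(tf) == len(pairs)
        with pytest.raises(ValueError):
            build_growth_input(pairs, "X")


class TestLeastSquares:
    def test_noise_free_recovery_to_optimizer_tolerance(self, noise_free_ds):
        from raygrowth.backcalc import back_calculate_all, fit_dw_vr
        fit = fit_dw_vr(noise_free_ds.data)
        pairs = back_calculate_all(
            noise_free_ds.data.assign(age=noise_free_ds.data["read1"]), fit)
        t, dw = build_growth_input(pairs)
        ls = fit_growth_lsq(t, dw, "logistic")
        assert ls["dw_inf"] == pytest.approx(401.70, rel=1e-4)
        assert ls["k"] == pytest.approx(0.45, rel=1e-3)
        assert ls["t0"] == pytest.approx(-0.36, abs=1e-3)
        assert ls["sigma"] < 1e-4


@pytest.fixture(scope="module")
def logistic_fit():
    # default run lengths: the convergence contract (R-hat < 1.10 and
    # ESS > 400 per parameter) is defined for the full 12,000 draws
    t, dw = _logistic_data(seed=0)
    return fit_growth_bayes(t, dw, "logistic", seed=3, sex="M")


class TestBayesFit:

    def test_parameter_recovery_within_three_posterior_sd(self, logistic_fit):
        for p, truth in (("dw_inf", 401.70), ("k", 0.45), ("t0", -0.36),
                         ("sigma", 20.0)):
            z = abs(logistic_fit.posterior.mean(p) - truth) / \
                logistic_fit.posterior.sd(p)
            assert z < 3.0, p

    def test_convergence_diagnostics_reported(self, logistic_fit):
        assert logistic_fit.converged
        assert all(r < 1.10 for r in logistic_fit.posterior.rhat.values())
        assert all(e > 400 for e in logistic_fit.posterior.ess.values())

    def test_truncation_respected_in_every_draw(self, logistic_fit):
        for p in ("dw_inf", "k", "sigma"):
            assert (logistic_fit.posterior.pooled(p) > 0).all()

    def test_posterior_sharpens_as_noise_shrinks(self):
        sds = []
        for sigma in (20.0, 10.0, 5.0):
            t, dw = _logistic_data(sigma=sigma, seed=1)
            fr = fit_growth_bayes(t, dw, "logistic", settings=REDUCED_MCMC,
                                  seed=5)
            sds.append(fr.posterior.sd("dw_inf"))
        assert sds[0] > sds[1] > sds[2]

    def test_prior_only_run_samples_the_prior(self):
        fr = fit_growth_bayes([], [], "logistic", seed=11)
        d = fr.posterior.pooled("dw_inf")
        theory = stats.halfnorm(scale=700.0)
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(d, q) == pytest.approx(theory.ppf(q), rel=0.10)
        assert (d >= 0).all()
        assert fr.posterior.pooled("t0").std() == pytest.approx(8.0, rel=0.15)

    def test_all_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            fit_growth_bayes([1.0, 2.0, 3.0, 4.0, 5.0], [-1.0] * 5,
                             "logistic")

    def test_deterministic_given_seed(self):
        t, dw = _logistic_data(n=60, seed=2)
        a = fit_growth_bayes(t, dw, "logistic", settings=REDUCED_MCMC, seed=9)
        b = fit_growth_bayes(t, dw, "logistic", settings=REDUCED_MCMC, seed=9)
        assert a.aic == b.aic
        np.testing.assert_array_equal(a.posterior.pooled("k"),
                                      b.posterior.pooled("k"))


class TestComparison:
    def test_mixed_datasets_rejected(self):
        t1, dw1 = _logistic_data(n=40, seed=3)
        t2, dw2 = _logistic_data(n=40, seed=4)
        f1 = fit_growth_bayes(t1, dw1, "logistic", settings=REDUCED_MCMC, seed=1)
        f2 = fit_growth_bayes(t2, dw2, "gompertz", settings=REDUCED_MCMC, seed=1)
        with pytest.raises(ValueError, match="different datasets"):
            compare_models([f1, f2])

    def test_ranking_orders_by_aic(self):
        t, dw = _logistic_data(n=120, seed=5)
        fits = [fit_growth_bayes(t, dw, f, settings=REDUCED_MCMC, seed=2)
                for f in ("logistic", "vbgm2")]
        comp = compare_models(fits)
        assert comp["aic"].is_monotonic_increasing
        assert comp.loc[0, "delta_aic"] == 0.0


class TestSexDifference:
    def test_identical_posteriors_not_significant(self):
        t, dw = _logistic_data(n=100, seed=6)
        fr = fit_growth_bayes(t, dw, "logistic", settings=REDUCED_MCMC, seed=4)
        for c in sex_difference(fr, fr, seed=0):
            assert not c.significant
            assert c.ci_low <= 0 <= c.ci_high

    def test_shifted_posterior_is_significant(self):
        import copy
        t, dw = _logistic_data(n=100, seed=6)
        fr = fit_growth_bayes(t, dw, "logistic", settings=REDUCED_MCMC, seed=4)
        shifted = copy.deepcopy(fr)
        sd = shifted.posterior.sd("dw_inf")
        shifted.posterior.draws["dw_inf"] = \
            shifted.posterior.draws["dw_inf"] + 10 * sd
        contrasts = {c.param: c for c in sex_difference(shifted, fr, seed=0)}
        assert contrasts["dw_inf"].significant

    def test_family_mismatch_rejected(self):
        t, dw = _logistic_data(n=60, seed=7)
        f1 = fit_growth_bayes(t, dw, "logistic", settings=REDUCED_MCMC, seed=1)
        f2 = fit_growth_bayes(t, dw, "gompertz", settings=REDUCED_MCMC, seed=1)
        with pytest.raises(ValueError, match="family"):
            sex_difference(f1, f2)
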