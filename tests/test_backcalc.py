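"""DW-VR regression, ANCOVA pooling, and BPH back-calculation."""

import numpy as np
import pandas as pd
import pytest

from raygrowth.backcalc import (RegressionFit, ancova_sex, back_calculate,
                                back_calculate_all, fit_dw_vr, summarize_by_age)


def _line_df(a, b, n=30, noise=0.0, sex="M", seed=0):
    rng = np.random.default_rng(seed)
    vr = rng.uniform(1, 6, n)
    return pd.DataFrame({"sex": sex, "vr_mm": vr,
                         "dw_mm": a + b * vr + noise * rng.standard_normal(n)})


class TestRegression:
    def test_exact_line_recovered(self):
        fit = fit_dw_vr(_line_df(100.0, 500.0))
        assert fit.a == pytest.approx(100.0)
        assert fit.b == pytest.approx(500.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_generator_truth_within_two_se(self, small_ds):
        fit = fit_dw_vr(small_ds.data)
        cfg = small_ds.config
        # noisy VR: slope attenuates by the reliability ratio; with
        # vr_sd=0.1 over a ~1 mm VR spread that is a few percent
        assert abs(fit.a - cfg.vr_intercept) < 60
        assert abs(fit.b - cfg.vr_slope) / cfg.vr_slope < 0.15
        assert fit.r2 > 0.8

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            fit_dw_vr(_line_df(0, 500).head(2))

    def test_degenerate_vr_is_error(self):
        df = pd.DataFrame({"vr_mm": [2.0] * 5, "dw_mm": np.arange(5.0)})
        with pytest.raises(ValueError, match="variance"):
            fit_dw_vr(df)


class TestAncova:
    def test_same_line_pools_at_nominal_rate(self):
        pooled = 0
        for s in range(50):
            df = pd.concat([_line_df(30, 90, 100, 20.0, "M", seed=2 * s),
                            _line_df(30, 90, 100, 20.0, "F", seed=2 * s + 1)])
            pooled += ancova_sex(df).pooled
        assert pooled >= 42  # ~95% of replicates at alpha=0.05

    def test_different_slopes_detected(self):
        df = pd.concat([_line_df(30, 500, 60, 5.0, "M", seed=1),
                        _line_df(30, 800, 60, 5.0, "F", seed=2)])
        res = ancova_sex(df)
        assert res.p_slope_interaction < 0.001
        assert not res.pooled

    def test_random_relabelling_gives_uniform_p(self):
        rng = np.random.default_rng(5)
        ps = []
        for s in range(100):
            df = _line_df(30, 90, 80, 15.0, seed=100 + s)
            df["sex"] = rng.choice(["M", "F"], size=len(df))
            res = ancova_sex(df)
            ps.append(res.p_slope_interaction)
        ps = np.array(ps)
        assert abs(ps.mean() - 0.5) < 0.12
        assert (ps < 0.05).mean() < 0.13

    def test_single_sex_forces_pooling(self):
        res = ancova_sex(_line_df(30, 90, 20, 5.0, "M"))
        assert res.pooled and res.forced


class TestBPH:
    FIT = RegressionFit(a=30.0, b=90.0, r2=0.99, n=100, residual_sd=5.0)

    def _fish(self, dw=400.0, vr=4.0, radii=(1.0, 2.0, 4.0)):
        return {"fish_id": "x", "sex": "M", "dw_mm": dw, "vr_mm": vr,
                "band_radii_mm": list(radii)}

    def test_edge_radius_returns_capture_size(self):
        out = back_calculate(self._fish(), self.FIT)
        assert out["dw_back"].iloc[-1] == pytest.approx(400.0)

    def test_zero_intercept_is_pure_proportionality(self):
        fit = RegressionFit(a=0.0, b=90.0, r2=1.0, n=10, residual_sd=0.0)
        out = back_calculate(self._fish(radii=(2.0, 4.0)), fit)
        assert out["dw_back"].iloc[0] == pytest.approx(200.0)

    def test_scale_equivariance(self):
        df = _line_df(30, 90, 40, 10.0, seed=3)
        df["fish_id"] = [f"f{i}" for i in range(len(df))]
        df["band_radii_mm"] = df["vr_mm"].map(lambda v: [v / 2, v])
        fit1 = fit_dw_vr(df)
        out1 = back_calculate_all(df, fit1)
        df2 = df.assign(dw_mm=df["dw_mm"] * 2)
        fit2 = fit_dw_vr(df2)
        out2 = back_calculate_all(df2, fit2)
        assert fit2.a == pytest.approx(2 * fit1.a)
        assert fit2.b == pytest.approx(2 * fit1.b)
        np.testing.assert_allclose(out2["dw_back"], 2 * out1["dw_back"])

    def test_monotone_in_age_per_fish(self, small_ds):
        fit = fit_dw_vr(small_ds.data)
        pairs = back_calculate_all(
            small_ds.data.assign(age=small_ds.data["read1"]), fit)
        for _, grp in pairs.groupby("fish_id"):
            assert grp.sort_values("age")["dw_back"].is_monotonic_increasing

    def test_noise_free_pipeline_recovers_truth(self, noise_free_ds):
        fit = fit_dw_vr(noise_free_ds.data)
        pairs = back_calculate_all(
            noise_free_ds.data.assign(age=noise_free_ds.data["read1"]), fit)
        m = pairs.merge(noise_free_ds.truth_trajectories,
                        on=["fish_id", "age"])
        np.testing.assert_allclose(m["dw_back"], m["true_dw"], rtol=1e-8)

    def test_nonpositive_denominator_skips_fish(self):
        fit = RegressionFit(a=-1000.0, b=90.0, r2=0.5, n=10, residual_sd=5.0)
        out = back_calculate(self._fish(), fit)
        assert out.empty

    def test_radius_beyond_centrum_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            back_calculate(self._fish(radii=(1.0, 5.0)), self.FIT)


class TestSummary:
    def test_single_fish_reading_counts(self):
        pairs = pd.DataFrame({"fish_id": "a", "sex": "M",
                              "age": [0, 1, 2], "dw_back": [200, 280, 330]})
        obs = pd.DataFrame({"sex": ["M"], "age": [2], "dw_mm": [335.0]})
        tab = summarize_by_age(pairs, obs)
        assert tab["m"].tolist() == [1, 1, 1]
        assert tab.loc[tab["age"] == 2, "n"].item() == 1

    def test_reading_count_non_increasing_with_age(self, small_ds):
        from raygrowth.backcalc import fit_dw_vr
        fit = fit_dw_vr(small_ds.data)
        aged = small_ds.data.assign(age=small_ds.data["read1"])
        tab = summarize_by_age(back_calculate_all(aged, fit), aged)
        for _, grp in tab.groupby("sex"):
            m = grp.sort_values("age")["m"].to_numpy()
            assert np.all(np.diff(m) <= 0)

    def test_noise_free_observed_equals_backcalculated(self, noise_free_ds):
        fit = fit_dw_vr(noise_free_ds.data)
        aged = noise_free_ds.data.assign(age=noise_free_ds.data["read1"])
        tab = summarize_by_age(back_calculate_all(aged, fit), aged)
        has_obs = tab["n"] > 0
        np.testing.assert_allclose(tab.loc[has_obs, "dw_avg"],
                                   tab.loc[has_obs, "dw_back"], rtol=1e-8)
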