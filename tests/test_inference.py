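import numpy as np
import pandas as pd
import pytest

from forestbeta.data_io import HabitatTable, ValidationError
from forestbeta.inference import (
    ModelSpec,
    backward_prune,
    fit_lmm,
    habitat_coordinates,
    habitat_distance,
    regime_contrasts,
    residual_correlogram,
    satterthwaite_tests,
    simulate_pair_table,
)
from forestbeta.lmm import RandomInterceptLMM, f_test, lrt_random


def habitat_row(i, elev, conv, slope, aspect, plot=1, grain=20):
    return {
        "subplot_id": f"{plot}:g{grain}:{i}:0",
        "plot_id": plot,
        "grain": grain,
        "row": i,
        "col": 0,
        "mean_elevation": elev,
        "convexity": conv,
        "slope": slope,
        "aspect": aspect,
    }


class TestHabitatDistance:
    def test_identical_subplots(self):
        h = HabitatTable(pd.DataFrame([habitat_row(0, 500, 1, 20, 90),
                                       habitat_row(1, 500, 1, 20, 90)]))
        c = habitat_coordinates(h)
        assert habitat_distance(c.index[0], c.index[1], c) == pytest.approx(0.0)

    def test_opposed_aspect_only(self):
        # same elevation/convexity/slope, aspect 0 vs 180: sin equal, cos
        # differs by 2 -> Euclidean distance exactly 2
        h = HabitatTable(pd.DataFrame([habitat_row(0, 500, 1, 20, 0),
                                       habitat_row(1, 500, 1, 20, 180)]))
        c = habitat_coordinates(h)
        assert habitat_distance(c.index[0], c.index[1], c) == pytest.approx(2.0)

    def test_metric_properties(self, rng):
        rows = [
            habitat_row(i, 400 + 50 * rng.random(), rng.normal(), 10 + 20 * rng.random(),
                        360 * rng.random())
            for i in range(12)
        ]
        c = habitat_coordinates(HabitatTable(pd.DataFrame(rows)))
        ids = list(c.index)
        for _ in range(100):
            i, j, k = rng.choice(len(ids), 3, replace=False)
            dij = habitat_distance(ids[i], ids[j], c)
            dji = habitat_distance(ids[j], ids[i], c)
            dik = habitat_distance(ids[i], ids[k], c)
            dkj = habitat_distance(ids[k], ids[j], c)
            assert dij == pytest.approx(dji)
            assert dij <= dik + dkj + 1e-12


class TestLmmFitting:
    def test_matches_statsmodels_reml(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        plots = np.repeat(np.arange(6), 40)
        x = rng.normal(size=len(plots))
        y = 1.0 + 0.5 * x + rng.normal(0, 0.3, 6)[plots] + rng.normal(size=len(plots))
        X = np.column_stack([np.ones_like(x), x])
        fit = RandomInterceptLMM(y, X, {"plot": plots}).fit()
        df = pd.DataFrame({"y": y, "x": x, "plot": plots})
        ref = sm.MixedLM.from_formula("y ~ x", groups="plot", data=df).fit(reml=True)
        assert np.allclose(fit.beta, ref.fe_params.values, atol=1e-6)
        assert fit.vc["plot"] == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=1e-6)
        assert fit.sigma2 == pytest.approx(ref.scale, abs=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)

    def test_deterministic_refit(self):
        pairs = simulate_pair_table(n_plots=6, pairs_per_plot=40, seed=0)
        spec = ModelSpec(response="y", fixed=("regime", "log_hd"), random=("group",))
        f1 = fit_lmm(spec, pairs)
        f2 = fit_lmm(spec, pairs)
        assert np.allclose(f1.fit.beta, f2.fit.beta, atol=1e-8)
        assert f1.fit.loglik == pytest.approx(f2.fit.loglik, abs=1e-8)

    def test_parameter_recovery_small(self):
        hits = 0
        n_runs = 15
        for s in range(n_runs):
            pairs = simulate_pair_table(n_plots=9, pairs_per_plot=80, beta_hd=0.08,
                                        sigma_plot=0.05, sigma=0.1, seed=s)
            spec = ModelSpec(response="y", fixed=("log_hd",), random=("group",))
            res = fit_lmm(spec, pairs)
            j = res.slices["log_hd"][0]
            hits += abs(res.fit.beta[j] - 0.08) <= 3 * res.fit.se[j]
        assert hits >= n_runs - 1

    def test_zero_variance_lands_on_boundary(self):
        boundary = 0
        for s in range(10):
            pairs = simulate_pair_table(n_plots=6, pairs_per_plot=50, sigma_plot=0.0, seed=50 + s)
            spec = ModelSpec(response="y", fixed=("log_hd",), random=("group",))
            res = fit_lmm(spec, pairs)
            boundary += res.fit.boundary.get("group", False)
        assert boundary >= 3  # ~half of REML fits hit the boundary


class TestSatterthwaite:
    def test_balanced_anova_ddf_matches_residual_df(self, rng):
        g = np.repeat(np.arange(3), 40)
        y = rng.normal(size=120) + 0.2 * (g == 2)
        X = np.column_stack([np.ones(120), (g == 1).astype(float), (g == 2).astype(float)])
        fit = RandomInterceptLMM(y, X, {}).fit()
        C = np.zeros((2, 3))
        C[0, 1] = C[1, 2] = 1.0
        res = f_test(fit, C)
        assert abs(res["ddf"] - 117) / 117 < 0.05

    def test_regime_type_one_error_reduced(self):
        """F test of a between-plot factor stays near nominal size."""
        hits = 0
        n_runs = 100
        for s in range(n_runs):
            pairs = simulate_pair_table(n_plots=9, pairs_per_plot=30,
                                        regime_effects=(0.0, 0.0, 0.0),
                                        sigma_plot=0.05, sigma=0.1, seed=1000 + s)
            spec = ModelSpec(response="y", fixed=("regime", "log_hd"), random=("group",))
            res = fit_lmm(spec, pairs)
            table = satterthwaite_tests(res)
            p = float(table.loc[table["term"] == "regime", "p"].iloc[0])
            hits += p <= 0.05
        assert 0.005 <= hits / n_runs <= 0.12  # nominal 0.05, 100-rep window

    def test_pruning_removes_least_significant_first(self):
        pairs = simulate_pair_table(n_plots=9, pairs_per_plot=60, beta_hd=0.3,
                                    regime_effects=(0.0, 0.0, 0.0),
                                    sigma_plot=0.0, sigma=0.1, seed=4)
        spec = ModelSpec(response="y", fixed=("regime", "log_hd", "log_sd"), random=("group",))
        res = backward_prune(spec, pairs)
        # strong log_hd effect survives; null terms are pruned
        assert "log_hd" in res.slices
        dropped = [step["dropped"] for step in res.pruning_log]
        assert set(dropped) <= {"regime", "log_sd", "plot_mean_elev"}
        for step in res.pruning_log:
            assert step["p"] > 0.05


class TestLrt:
    def test_identical_models_give_zero(self):
        pairs = simulate_pair_table(n_plots=6, pairs_per_plot=40, seed=9)
        spec = ModelSpec(response="y", fixed=("log_hd",), random=("group",))
        f1 = fit_lmm(spec, pairs)
        out = lrt_random(f1.fit, f1.fit)
        assert out["statistic"] == 0.0 and out["p"] == 1.0

    def test_boundary_null_mass_near_half(self):
        zeros = 0
        n_runs = 60
        for s in range(n_runs):
            pairs = simulate_pair_table(n_plots=8, pairs_per_plot=25, sigma_plot=0.0,
                                        seed=3000 + s)
            full = fit_lmm(ModelSpec(response="y", fixed=("log_hd",), random=("group",)), pairs)
            red = fit_lmm(ModelSpec(response="y", fixed=("log_hd",), random=()), pairs)
            stat = lrt_random(full.fit, red.fit)["statistic"]
            zeros += stat < 1e-8
        assert 0.3 <= zeros / n_runs <= 0.75

    def test_power_with_large_plot_variance(self):
        rejects = 0
        n_runs = 20
        for s in range(n_runs):
            pairs = simulate_pair_table(n_plots=9, pairs_per_plot=60, sigma_plot=0.5,
                                        sigma=0.1, seed=4000 + s)
            full = fit_lmm(ModelSpec(response="y", fixed=("log_hd",), random=("group",)), pairs)
            red = fit_lmm(ModelSpec(response="y", fixed=("log_hd",), random=()), pairs)
            rejects += lrt_random(full.fit, red.fit)["p"] < 0.05
        assert rejects >= 19

    def test_non_nested_rejected(self):
        pairs = simulate_pair_table(n_plots=6, pairs_per_plot=30, seed=1)
        a = fit_lmm(ModelSpec(response="y", fixed=("log_hd",), random=("group",)), pairs)
        b = fit_lmm(ModelSpec(response="y", fixed=("log_hd",), random=("regime",)), pairs)
        with pytest.raises(ValueError, match="nested"):
            lrt_random(a.fit, b.fit)


class TestContrasts:
    def test_adjusted_at_least_unadjusted(self):
        pairs = simulate_pair_table(n_plots=9, pairs_per_plot=40,
                                    regime_effects=(0.0, 0.05, 0.1), seed=2)
        res = fit_lmm(ModelSpec(response="y", fixed=("regime", "log_hd"), random=("group",)), pairs)
        ct = regime_contrasts(res)
        assert len(ct) == 3
        assert (ct["adj_p"] >= ct["p"] - 1e-12).all()

    def test_identical_regimes_not_separated(self):
        ok = 0
        n_runs = 10
        for s in range(n_runs):
            pairs = simulate_pair_table(n_plots=9, pairs_per_plot=40,
                                        regime_effects=(0.0, 0.0, 0.6),
                                        sigma_plot=0.02, sigma=0.1, seed=700 + s)
            res = fit_lmm(ModelSpec(response="y", fixed=("regime", "log_hd"),
                                    random=("group",)), pairs)
            ct = regime_contrasts(res).set_index("contrast")
            ok += ct.loc["2-1", "adj_p"] > 0.05
        assert ok >= 8

    def test_two_regimes_single_contrast_unchanged(self):
        pairs = simulate_pair_table(n_plots=6, pairs_per_plot=40,
                                    regime_effects=(0.0, 0.2), seed=3)
        res = fit_lmm(ModelSpec(response="y", fixed=("regime", "log_hd"),
                                random=("group",)), pairs)
        ct = regime_contrasts(res)
        assert len(ct) == 1
        assert ct["adj_p"].iloc[0] == pytest.approx(ct["p"].iloc[0], rel=0.15)

    def test_pruned_regime_returns_empty(self):
        pairs = simulate_pair_table(n_plots=6, pairs_per_plot=40, seed=5)
        res = fit_lmm(ModelSpec(response="y", fixed=("log_hd",), random=("group",)), pairs)
        ct = regime_contrasts(res)
        assert ct.empty and "pruned" in ct.attrs["note"]


class TestCorrelogram:
    def test_iid_residuals_rarely_significant(self):
        good = 0
        n_runs = 10
        for s in range(n_runs):
            pairs = simulate_pair_table(n_plots=6, pairs_per_plot=60, seed=800 + s)
            res = fit_lmm(ModelSpec(response="y", fixed=("log_hd",), random=("group",)), pairs)
            cg = residual_correlogram(res, n_classes=10, n_perm=199, seed=s)
            good += (cg["p"] <= 0.05).sum() <= 1
        assert good >= 8

    def test_spatial_trend_detected_in_first_class(self):
        pairs = simulate_pair_table(n_plots=6, pairs_per_plot=80, seed=6)
        res = fit_lmm(ModelSpec(response="y", fixed=("log_hd",), random=("group",)), pairs)
        # inject a smooth spatial signal into the residuals
        trend = np.sin(res.pairs["mid_x"].to_numpy() / 150.0) + np.cos(
            res.pairs["mid_y"].to_numpy() / 150.0
        )
        res.fit.residuals = res.fit.residuals + 3.0 * res.fit.residuals.std() * trend
        cg = residual_correlogram(res, n_classes=8, n_perm=199, seed=1)
        assert cg.iloc[0]["p"] <= 0.05
        assert cg.iloc[0]["morans_i"] > 0

    def test_constant_residuals_error(self):
        pairs = simulate_pair_table(n_plots=6, pairs_per_plot=30, seed=7)
        res = fit_lmm(ModelSpec(response="y", fixed=("log_hd",), random=("group",)), pairs)
        res.fit.residuals = np.zeros_like(res.fit.residuals)
        with pytest.raises(ValidationError, match="constant"):
            residual_correlogram(res, seed=1)
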