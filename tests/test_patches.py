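import numpy as np
import pandas as pd
import pytest

from socialgaze.density import DensityMap
from socialgaze.patches import (
    MODEL_TERMS,
    compare_models,
    decile_bin_summary,
    fit_mixed_model,
    patchify,
    standardize_predictors,
)
from socialgaze.roi import build_roi_set
from socialgaze.saliency import SaliencyMap
from socialgaze.simulate import generate_patch_data


def _scene(rng):
    h, w = 900, 1200
    head = np.zeros((h, w), bool)
    head[100:180, 200:290] = True
    body = np.zeros((h, w), bool)
    body[180:420, 180:310] = True
    sal = SaliencyMap(rng.random((h, w)))
    return sal, build_roi_set(head, body, sal)


def _density(values, pid="p0", sid="s0"):
    return DensityMap(np.asarray(values, float), pid, sid, 10, 3000.0)


class TestPatchify:
    def test_grid_yields_108_records(self, rng):
        sal, rs = _scene(rng)
        out = patchify(_density(rng.random((900, 1200))), sal, rs)
        assert len(out) == 108
        assert set(out["patch_row"]) == set(range(9))
        assert set(out["patch_col"]) == set(range(12))

    def test_uniform_density_all_relative_one(self, rng):
        sal, rs = _scene(rng)
        out = patchify(_density(np.full((900, 1200), 0.2)), sal, rs)
        assert np.allclose(out["rel_fix_density"], 1.0)

    def test_per_scene_means_exactly_one(self, rng):
        sal, rs = _scene(rng)
        out = patchify(_density(rng.random((900, 1200))), sal, rs)
        for col in ("rel_fix_density", "rel_saliency", "rel_head", "rel_body"):
            assert out[col].mean() == pytest.approx(1.0, rel=1e-12)

    def test_center_distance_structure(self, rng):
        sal, rs = _scene(rng)
        out = patchify(_density(rng.random((900, 1200))), sal, rs)
        dist = out["dist_center"].round(9)
        assert dist.nunique() == 27
        assert dist.min() == pytest.approx(np.hypot(50, 0))

    def test_scene_without_heads_flagged_zero(self, rng):
        # a social scene showing only body parts: head mask empty
        h, w = 900, 1200
        body = np.zeros((h, w), bool)
        body[100:400, 200:400] = True
        sal = SaliencyMap(rng.random((h, w)))
        rs = build_roi_set(np.zeros((h, w), bool), body, sal)
        with pytest.warns(UserWarning, match="no head"):
            out = patchify(_density(rng.random((900, 1200))), sal, rs)
        assert (out["rel_head"] == 0).all()

    def test_indivisible_grid_error(self, rng):
        sal = SaliencyMap(rng.random((90, 110)))
        with pytest.raises(ValueError):
            patchify(_density(rng.random((90, 110))), sal, None, n_rows=9, n_cols=12)


class TestStandardize:
    def test_columns_zero_mean_unit_sd(self, rng):
        sal, rs = _scene(rng)
        frames = [
            patchify(_density(rng.random((900, 1200)), pid=f"p{i}"), sal, rs) for i in range(3)
        ]
        design, report = standardize_predictors(pd.concat(frames, ignore_index=True))
        for col in ("dist_center", "rel_saliency", "rel_head", "rel_body"):
            assert design[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert design[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
            assert col in report
        assert {"sal_x_head", "sal_x_body"} <= set(design.columns)

    def test_idempotent(self, rng):
        sal, rs = _scene(rng)
        table = patchify(_density(rng.random((900, 1200))), sal, rs)
        d1, _ = standardize_predictors(table)
        d2, _ = standardize_predictors(d1)
        for col in ("dist_center", "rel_saliency"):
            np.testing.assert_allclose(d1[col], d2[col], atol=1e-10)

    def test_zero_variance_predictor_error(self, rng):
        sal, rs = _scene(rng)
        table = patchify(_density(rng.random((900, 1200))), sal, rs)
        table["rel_body"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_predictors(table)

    def test_cohort_row_arithmetic(self):
        # full crossing and the mean-valid-trial bookkeeping
        assert 31 * 79 * 108 == 264_492
        assert round(31 * 78.93548 * 108) == 264_276


class TestFitMixedModel:
    def test_matches_statsmodels_on_small_data(self):
        import statsmodels.formula.api as smf

        design, _ = generate_patch_data(
            5, 6, {"intercept": 1.0, "dist_center": -0.3, "rel_saliency": 0.2,
                   "rel_head": 0.5, "rel_body": 0.1},
            0.02, 0.04, 0.3, seed=11,
        )
        fit = fit_mixed_model(design, "4")
        df = design.assign(g=1)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oracle = smf.mixedlm(
                "rel_fix_density ~ dist_center + rel_saliency + rel_head + rel_body",
                df,
                groups="g",
                vc_formula={"p": "0 + C(participant_id)", "s": "0 + C(scene_id)"},
            ).fit(reml=True)
        for ours, theirs in zip(
            ["intercept", "dist_center", "rel_saliency", "rel_head", "rel_body"],
            ["Intercept", "dist_center", "rel_saliency", "rel_head", "rel_body"],
        ):
            assert fit.fixed_effects[ours]["beta"] == pytest.approx(
                oracle.params[theirs], abs=1e-3
            )

    def test_ols_limit_when_variances_vanish(self):
        design, _ = generate_patch_data(
            4, 5, {"intercept": 0.5, "dist_center": -0.4, "rel_saliency": 0.3,
                   "rel_head": 0.2, "rel_body": 0.1},
            0.0, 0.0, 0.05, seed=21,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_model(design, "4")
        X = np.column_stack(
            [np.ones(len(design))]
            + [design[t].to_numpy() for t in MODEL_TERMS["4"]]
        )
        beta_ols = np.linalg.lstsq(X, design["rel_fix_density"].to_numpy(), rcond=None)[0]
        got = [fit.fixed_effects[t]["beta"] for t in ("intercept",) + MODEL_TERMS["4"]]
        np.testing.assert_allclose(got, beta_ols, atol=1e-6)

    def test_noiseless_exact_recovery(self):
        truth = {"intercept": 1.0, "dist_center": -0.3, "rel_saliency": 0.15,
                 "rel_head": 0.5, "rel_body": 0.2}
        design, _ = generate_patch_data(4, 5, truth, 0.0, 0.0, 0.0, seed=2)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_model(design, "4")
        for term, val in truth.items():
            assert fit.fixed_effects[term]["beta"] == pytest.approx(val, abs=1e-8)

    def test_intercept_only_loglik_matches_closed_form(self):
        # iid N(mu, s2) limit: ML loglik at the variance MLE
        rng = np.random.default_rng(3)
        n = 600
        y = rng.normal(0.0, 1.3, n)
        design = pd.DataFrame(
            {
                "participant_id": ["p0"] * n,
                "scene_id": ["s0"] * n,
                "rel_fix_density": y,
            }
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mixed_model(design, "0")
        s2 = y.var()
        expected = -0.5 * n * (1 + np.log(2 * np.pi * s2))
        # a single group per factor leaves the random intercepts confounded
        # with the mean; the ML deviance still attains the iid bound
        assert fit.loglik_ml == pytest.approx(expected, abs=0.5)

    def test_parameter_recovery_within_two_se(self):
        truth = {"intercept": 1.0, "dist_center": -0.3, "rel_saliency": 0.15,
                 "rel_head": 0.5, "rel_body": 0.2, "sal_x_head": 0.1, "sal_x_body": 0.05}
        design, _ = generate_patch_data(8, 10, truth, 0.01, 0.05, 0.2, seed=5)
        fit = fit_mixed_model(design, "6")
        for term in MODEL_TERMS["6"]:
            eff = fit.fixed_effects[term]
            assert abs(eff["beta"] - truth[term]) < 2 * eff["se"]

    def test_unknown_model_id(self):
        with pytest.raises(ValueError):
            fit_mixed_model(pd.DataFrame(), "9z")


@pytest.fixture(scope="module")
def fits():
    truth = {"intercept": 1.0, "dist_center": -0.3, "rel_saliency": 0.15,
             "rel_head": 0.5, "rel_body": 0.2}
    design, _ = generate_patch_data(6, 8, truth, 0.01, 0.04, 0.2, seed=9)
    return {m: fit_mixed_model(design, m) for m in ("0", "1a", "2", "3a", "3b", "4")}


class TestCompareModels:

    def test_self_comparison_is_null(self, fits):
        out = compare_models([(fits["4"], fits["4"])])
        assert out["chi2"].item() == 0.0
        assert out["p"].item() == 1.0

    def test_true_effects_detected(self, fits):
        out = compare_models([(fits["3a"], fits["4"])])  # body effect is real
        assert out["p"].item() < 0.001
        assert out["delta_aic"].item() < 0

    def test_ladder_chi2_nonnegative_df_one(self, fits):
        ladder = [("0", "1a"), ("1a", "2"), ("2", "3a"), ("3a", "4")]
        out = compare_models([(fits[a], fits[b]) for a, b in ladder])
        assert (out["chi2"] >= 0).all()
        assert (out["df"] == 1).all()

    def test_non_nested_pair_refused(self, fits):
        with pytest.warns(UserWarning, match="not nested"):
            out = compare_models([(fits["3a"], fits["3b"])])
        assert np.isnan(out["chi2"].item())


class TestDecileBins:
    def test_uniform_response_equal_bin_means(self, rng):
        df = pd.DataFrame({"rel_saliency": rng.random(5000), "rel_fix_density": 1.0})
        out = decile_bin_summary(df, "rel_saliency")
        assert np.allclose(out["mean"], 1.0)
        assert out["n"].sum() == 5000

    def test_zero_coverage_bin_for_social_features(self, rng):
        vals = np.concatenate([np.zeros(3000), rng.random(2000)])
        df = pd.DataFrame({"rel_head": vals, "rel_fix_density": rng.random(5000)})
        out = decile_bin_summary(df, "rel_head")
        assert out.iloc[0]["bin"] == "0"
        assert out.iloc[0]["n"] == 3000
        assert out["n"].sum() == 5000
        assert len(out) == 11

    def test_distance_bins_partition_with_few_distinct_values(self, rng):
        # 27 distinct values, uneven bins
        vals = rng.choice(np.arange(27) * 13.7 + 50, size=4000)
        df = pd.DataFrame({"dist_center": vals, "rel_fix_density": rng.random(4000)})
        out = decile_bin_summary(df, "dist_center")
        assert out["n"].sum() == 4000
        fracs = out["n"] / 4000
        assert fracs.max() < 0.2 and fracs.min() > 0.03
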