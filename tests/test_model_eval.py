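import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from fdgsig.model_eval import (
    compare_models,
    external_validate,
    make_model,
    r_squared,
    repeated_cv,
    rmse,
    stability_sweep,
    summarize_resamples,
)
from fdgsig.pet_quant import outlier_fences
from fdgsig.synthetic import generate_validation_cohort


class TestMetrics:
    def test_rmse_examples(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0
        assert rmse([1, -1], [0, 0]) == 1
        assert rmse([3, 4], [0, 0]) == pytest.approx(math.sqrt(12.5))

    def test_rmse_empty(self):
        with pytest.raises(ValueError):
            rmse([], [])

    def test_r2_affine_is_one(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, 2.5 * y + 1) == pytest.approx(1.0)

    def test_r2_orthogonal_near_zero(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        yhat = np.array([1.0, 1.0, -1.0, -1.0])
        assert r_squared(y, yhat) == pytest.approx(0.0, abs=1e-12)

    def test_r2_matches_explicit_sums(self):
        y = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        yhat = np.array([0.8, 2.5, 3.1, 3.3, 4.4])
        num = ((y - y.mean()) * (yhat - yhat.mean())).sum()
        den = math.sqrt(((y - y.mean()) ** 2).sum() * ((yhat - yhat.mean()) ** 2).sum())
        assert r_squared(y, yhat) == pytest.approx((num / den) ** 2, rel=1e-12)

    def test_r2_constant_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert math.isnan(r_squared([1.0, 2.0], [3.0, 3.0]))


class TestRepeatedCV:
    def test_resample_count_is_k_times_repeats(self, small_cohort):
        model = make_model("pls", top_n=30)
        res = repeated_cv([model], small_cohort.expression, small_cohort.log2_suv,
                          k=5, repeats=3, seed=0)
        assert len(res) == 15
        assert res["error"].isna().all()

    def test_leave_one_out_count(self, small_cohort):
        n = small_cohort.expression.n_samples
        model = make_model("pls", top_n=10)
        res = repeated_cv([model], small_cohort.expression,
                          small_cohort.log2_suv, k=n, repeats=1, seed=0)
        assert len(res) == n
        assert res["r2"].isna().all()  # single-sample folds: undefined R^2
        assert res["rmse"].notna().all()

    def test_identical_specs_give_identical_resamples(self, small_cohort):
        m1 = make_model("pls", top_n=30)
        m2 = make_model("pls", top_n=30)
        m2.name = "PLS-copy"
        res = repeated_cv([m1, m2], small_cohort.expression, small_cohort.log2_suv,
                          k=5, repeats=2, seed=4)
        wide = res.pivot(index="resample", columns="model", values="rmse")
        np.testing.assert_allclose(wide["PLS-3"], wide["PLS-copy"], rtol=1e-12)

    def test_deterministic_given_seed(self, small_cohort):
        kw = dict(k=5, repeats=2, seed=9)
        r1 = repeated_cv([make_model("pls", top_n=20)], small_cohort.expression,
                         small_cohort.log2_suv, **kw)
        r2 = repeated_cv([make_model("pls", top_n=20)], small_cohort.expression,
                         small_cohort.log2_suv, **kw)
        pd.testing.assert_frame_equal(r1, r2)

    def test_summary_layout(self, small_cohort):
        res = repeated_cv([make_model("pls", top_n=30)], small_cohort.expression,
                          small_cohort.log2_suv, k=5, repeats=2, seed=0)
        summary = summarize_resamples(res)
        assert summary.loc[0, "n_resamples"] == 10
        assert summary.loc[0, "rmse_q025"] <= summary.loc[0, "rmse_mean"]
        assert summary.loc[0, "rmse_mean"] <= summary.loc[0, "rmse_q975"]


def _fake_resamples():
    rng = np.random.default_rng(0)
    base = rng.normal(0.5, 0.05, 50)
    rows = []
    for name, shift in [("A", 0.0), ("B", 0.1)]:
        for i, v in enumerate(base):
            rows.append({"model": name, "resample": i, "rmse": v + shift,
                         "r2": 0.6 - (v + shift) / 4})
    return pd.DataFrame(rows)


class TestCompareModels:
    def test_constant_shift_detected(self):
        comp = compare_models(_fake_resamples())
        assert len(comp) == 1  # 2 models -> Bonferroni factor 1
        assert comp.loc[0, "rmse_p_adj"] < 0.01
        assert comp.loc[0, "r2_p_adj"] < 0.01

    def test_model_against_itself_degenerate(self):
        df = _fake_resamples()
        df.loc[df["model"] == "B", "rmse"] = df.loc[df["model"] == "A", "rmse"].to_numpy()
        df.loc[df["model"] == "B", "r2"] = df.loc[df["model"] == "A", "r2"].to_numpy()
        comp = compare_models(df)
        assert comp.loc[0, "degenerate"]
        assert comp.loc[0, "rmse_p_adj"] == 1.0

    def test_order_invariance(self):
        df = _fake_resamples()
        swapped = df.iloc[::-1].reset_index(drop=True)
        a = compare_models(df)
        b = compare_models(swapped)
        assert a.loc[0, "rmse_p_adj"] == pytest.approx(
            b.loc[0, "rmse_p_adj"], rel=1e-12
        )

    def test_bonferroni_factor_counts_pairs(self):
        df = _fake_resamples()
        extra = df[df["model"] == "A"].assign(model="C", rmse=lambda d: d.rmse + 0.05)
        comp3 = compare_models(pd.concat([df, extra], ignore_index=True))
        assert len(comp3) == 3
        single = compare_models(df).loc[0, "rmse_p_adj"]
        triple = comp3.set_index(["model_a", "model_b"]).loc[("A", "B"), "rmse_p_adj"]
        assert triple == pytest.approx(min(1.0, single * 3), rel=1e-9)

    def test_unpaired_rejected(self):
        df = _fake_resamples()
        df.loc[3, "rmse"] = np.nan
        with pytest.raises(ValueError, match="paired"):
            compare_models(df)


class TestExternalValidation:
    @pytest.fixture()
    def fitted(self, small_cohort):
        model = make_model("pls", top_n=30)
        model.fit(small_cohort.expression, small_cohort.log2_suv)
        fences = outlier_fences(2.0 ** small_cohort.log2_suv.to_numpy())
        return model, fences

    def test_validating_on_training_reproduces_training_rmse(self, small_cohort, fitted):
        """Feeding the training cohort back in reproduces the training
        error on the retained samples (outliers on the raw SUV scale are
        excluded a priori, as in cohort curation)."""
        model, fences = fitted
        res = external_validate(model, small_cohort.expression,
                                small_cohort.log2_suv, fences)
        table = res["per_sample"]
        kept = ~table["classification"].isin(["low_outlier", "high_outlier"])
        train_rmse = rmse(table.loc[kept, "measured_log2_suv"],
                          model.predict(small_cohort.expression)[kept.to_numpy()])
        assert res["rmse_all"] == pytest.approx(train_rmse, rel=1e-12)
        assert res["n_all"] + res["n_outliers_excluded"] == len(table)

    def test_no_influential_means_equal_rmse(self, small_cohort, small_validation, fitted):
        model, fences = fitted
        res = external_validate(model, small_validation.expression,
                                small_validation.log2_suv, fences)
        assert res["n_influential"] == 0
        assert res["rmse_all"] == pytest.approx(res["rmse_excluding_influential"])

    def test_influential_counts_audit(self, small_cohort, small_config, fitted):
        model, fences = fitted
        cfg = dataclasses.replace(small_config, include_influential=True)
        val = generate_validation_cohort(small_cohort, cfg)
        res = external_validate(model, val.expression, val.log2_suv, fences)
        assert res["n_influential"] == 1
        assert res["n_all"] == cfg.validation_n - res["n_outliers_excluded"]
        assert res["n_excluding"] == res["n_all"] - 1
        table = res["per_sample"]
        infl = table[table["classification"] == "influential"]
        assert infl["pred_over_measured"].iloc[0] == pytest.approx(
            infl["predicted_suv"].iloc[0] / infl["measured_suv"].iloc[0]
        )


class TestStabilitySweep:
    def test_tiny_threshold_matches_direct_full_fit(self, small_cohort, small_validation):
        fences = outlier_fences(2.0 ** small_cohort.log2_suv.to_numpy())
        sweep = stability_sweep(
            small_cohort.expression, small_cohort.log2_suv,
            small_validation.expression, small_validation.log2_suv,
            thresholds=[0.0], sign_variants=(), fences=fences,
        )
        direct = make_model("pls", threshold=0.0)
        direct.fit(small_cohort.expression, small_cohort.log2_suv)
        ref = external_validate(direct, small_validation.expression,
                                small_validation.log2_suv, fences)
        assert sweep.loc[0, "n_probes"] == small_cohort.expression.n_probes
        assert sweep.loc[0, "rmse_with_influential"] == pytest.approx(ref["rmse_all"])

    def test_sign_variants_partition_mixed_selection(self, small_cohort, small_validation):
        theta = 0.1
        sweep = stability_sweep(
            small_cohort.expression, small_cohort.log2_suv,
            small_validation.expression, small_validation.log2_suv,
            thresholds=[theta], sign_threshold=theta,
        )
        n = sweep.set_index("sign")["n_probes"]
        assert n["positive"] + n["negative"] == n["mixed"]

    def test_variants_complete_without_errors(self, small_cohort, small_validation):
        sweep = stability_sweep(
            small_cohort.expression, small_cohort.log2_suv,
            small_validation.expression, small_validation.log2_suv,
            thresholds=[0.05, 0.1, 0.15],
        )
        assert sweep["error"].isna().all()
        assert (sweep["rmse_with_influential"] > 0).all()

    def test_impossible_variant_recorded_not_fatal(self, small_cohort, small_validation):
        sweep = stability_sweep(
            small_cohort.expression, small_cohort.log2_suv,
            small_validation.expression, small_validation.log2_suv,
            thresholds=[99.0], sign_variants=(),
        )
        assert sweep["error"].notna().all()
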