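import numpy as np
import pandas as pd
import pytest

from saliotime import (
    bayes_factor,
    bootstrap_slope_test,
    compare_models,
    contrast_from_summary,
    lmm_lr_test,
    normalized_bias,
    ols_slope_test,
    per_participant_bias,
    pool_super_subject,
    scene_contrast,
)


class TestNormalizedBias:
    def test_worked_examples(self):
        # participant mean report for 8-s videos is 10 s
        reports = np.array([10.0, 10.0, 5.0])  # third report 50% below mean? no:
        # construct cells explicitly: mean m, plus probes at 0.5m, m, 1.5m
        m = 10.0
        reports = np.array([1.5 * m - 0.5 * m, 0.5 * m, m, 1.5 * m])
        # cell mean is (10 + 5 + 10 + 15)/4 = 10 = m
        durations = np.full(4, 8.0)
        bias = normalized_bias(reports, durations)
        assert bias[1] == pytest.approx(-0.5)
        assert bias[2] == pytest.approx(0.0)
        assert bias[3] == pytest.approx(0.5)

    def test_cell_mean_exactly_zero(self):
        rng = np.random.default_rng(0)
        durations = rng.choice([8.0, 12.0, 16.0], size=60)
        reports = rng.uniform(5, 25, size=60)
        bias = normalized_bias(reports, durations)
        for d in (8.0, 12.0, 16.0):
            assert bias[durations == d].mean() == pytest.approx(0.0, abs=1e-12)

    def test_grouped_cells(self):
        reports = np.array([10.0, 20.0, 5.0, 10.0])
        durations = np.full(4, 8.0)
        groups = np.array([0, 0, 1, 1])
        bias = normalized_bias(reports, durations, groups)
        np.testing.assert_allclose(
            bias, [-1 / 3, 1 / 3, -1 / 3, 1 / 3], atol=1e-12
        )

    def test_nonpositive_cell_mean_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            normalized_bias([0.0, 0.0], [8.0, 8.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            normalized_bias([1.0, 2.0], [8.0])


class TestSuperSubject:
    @staticmethod
    def _trials(rng, n_participants=3, scale=None):
        rows = []
        for p in range(n_participants):
            s = scale[p] if scale else 1.0
            for t in range(20):
                d = [8.0, 12.0, 16.0, 20.0][t % 4]
                rows.append((p, 0, t, "office", d, s * (3 + 0.75 * d) + rng.normal()))
        return pd.DataFrame(
            rows,
            columns=["participant", "block", "trial", "scene", "duration_s", "report_s"],
        )

    def test_single_participant_round_trips(self):
        trials = self._trials(np.random.default_rng(1), n_participants=1)
        pooled = pool_super_subject(trials)
        np.testing.assert_allclose(pooled["report_pooled_s"], trials["report_s"])
        expect = per_participant_bias(trials)["bias"]
        np.testing.assert_allclose(pooled["bias"], expect)

    def test_zscores_unit_per_participant(self):
        pooled = pool_super_subject(self._trials(np.random.default_rng(2)))
        for _, grp in pooled.groupby("participant"):
            assert grp["report_z"].mean() == pytest.approx(0.0, abs=1e-10)
            assert grp["report_z"].std() == pytest.approx(1.0, abs=1e-10)

    def test_scale_differences_removed(self):
        trials = self._trials(np.random.default_rng(3), scale=[1.0, 2.0, 0.5])
        pooled = pool_super_subject(trials)
        spread = pooled.groupby("participant")["report_pooled_s"].std()
        assert spread.max() / spread.min() < 1.5

    def test_constant_reports_rejected(self):
        trials = self._trials(np.random.default_rng(4))
        trials.loc[trials["participant"] == 0, "report_s"] = 9.0
        with pytest.raises(ValueError, match=r"participant\(s\) \[0\]"):
            pool_super_subject(trials)


class TestSceneContrast:
    def test_all_zero_differences(self):
        bias = np.zeros(8)
        scenes = np.tile(["city", "office"], 4)
        parts = np.repeat([0, 1, 2, 3], 2)
        res = scene_contrast(bias, scenes, parts, unit="participant")
        assert res.stat == 0.0 and res.d == 0.0
        assert res.ci[0] <= 0.0 <= res.ci[1]

    def test_paired_oracle(self):
        # paired differences (1, 2, 3): mean 2, sd 1, t = 2/(1/sqrt 3) = 3.464,
        # d = 2.0, 95% CI 2 -/+ 4.303/sqrt(3)
        bias = np.array([1.0, 0.0, 2.0, 0.0, 3.0, 0.0])
        scenes = np.tile(["city", "office"], 3)
        parts = np.repeat([0, 1, 2], 2)
        res = scene_contrast(bias, scenes, parts, unit="participant")
        assert res.stat == pytest.approx(3.4641, abs=1e-3)
        assert res.d == pytest.approx(2.0)
        assert res.ci[0] == pytest.approx(-0.4841, abs=1e-3)
        assert res.ci[1] == pytest.approx(4.4841, abs=1e-3)

    def test_trial_mode(self):
        rng = np.random.default_rng(5)
        bias = np.concatenate([rng.normal(0.3, 1, 50), rng.normal(0.0, 1, 50)])
        scenes = np.array(["city"] * 50 + ["office"] * 50)
        res = scene_contrast(bias, scenes, unit="trial")
        assert res.analysis == "scene_contrast_trial"
        assert res.df == 98

    def test_missing_scene_rejected(self):
        with pytest.raises(ValueError, match="missing scene"):
            scene_contrast(
                [0.1, 0.2], ["city", "city"], [0, 0], unit="participant"
            )

    def test_summary_oracle(self):
        # printed summary mean 5.23, SE 1.69, n 40 -> t = 3.09, CI [1.81, 8.65]
        res = contrast_from_summary(5.23, 1.69, 40)
        assert res.stat == pytest.approx(3.0947, abs=1e-3)
        assert res.ci[0] == pytest.approx(1.812, abs=1e-2)
        assert res.ci[1] == pytest.approx(8.648, abs=1e-2)


class TestSlopeTests:
    def test_self_regression(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=100)
        res = bootstrap_slope_test(y, y, n_boot=10_000, seed=0)
        assert res.estimate == pytest.approx(1.0)
        assert res.p <= 0.001

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bootstrap_slope_test(np.arange(10.0), np.ones(10), n_boot=1000)

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_slope_test(np.arange(10.0), np.arange(10.0), n_boot=10)

    def test_p_never_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        res = bootstrap_slope_test(5 * x, x, n_boot=1000, seed=1)
        assert res.p >= 1 / 1001

    def test_ols_matches_bootstrap_slope(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        y = 0.5 * x + rng.normal(size=80)
        boot = bootstrap_slope_test(y, x, n_boot=1000, seed=2)
        ols = ols_slope_test(y, x)
        assert ols.estimate == pytest.approx(boot.estimate)
        assert ols.sidedness.startswith("one-tailed")


class TestLMM:
    @staticmethod
    def _data(rng, beta=0.5, n_p=10, n_t=30):
        pid = np.repeat(np.arange(n_p), n_t)
        x = rng.normal(size=n_p * n_t)
        y = beta * x + rng.normal(0, 0.5, n_p)[pid] + rng.normal(0, 1, n_p * n_t)
        return pd.DataFrame({"participant": pid, "x": x, "y": y})

    def test_null_model_vs_itself(self):
        data = self._data(np.random.default_rng(9))
        res = lmm_lr_test(data, "y", None)
        assert res.stat == 0.0 and res.p == 1.0

    def test_detects_fixed_effect(self):
        data = self._data(np.random.default_rng(10))
        res = lmm_lr_test(data, "y", "x")
        assert res.p < 0.001
        assert res.ci[0] <= 0.5 <= res.ci[1]

    def test_aic_identity(self):
        data = self._data(np.random.default_rng(11))
        res = lmm_lr_test(data, "y", "x")
        assert res.aic == pytest.approx(res.aic_reduced + 2 - res.stat, abs=1e-6)

    def test_single_group_rejected(self):
        data = self._data(np.random.default_rng(12), n_p=1)
        with pytest.raises(ValueError, match="grouping"):
            lmm_lr_test(data, "y", "x")


class TestCompareModels:
    def test_identical_models_tie(self):
        data = TestLMM._data(np.random.default_rng(13))
        res = lmm_lr_test(data, "y", "x")
        table = compare_models({"a": res, "b": res})
        assert (table["delta_aic"] == 0).all()

    def test_mismatched_sizes_rejected(self):
        d1 = TestLMM._data(np.random.default_rng(14))
        d2 = TestLMM._data(np.random.default_rng(15), n_t=20)
        with pytest.raises(ValueError, match="different outcome sizes"):
            compare_models(
                {"a": lmm_lr_test(d1, "y", "x"), "b": lmm_lr_test(d2, "y", "x")}
            )

    def test_signal_model_ranks_first(self):
        rng = np.random.default_rng(16)
        data = TestLMM._data(rng)
        data["junk"] = rng.normal(size=len(data))
        table = compare_models(
            {
                "signal": lmm_lr_test(data, "y", "x"),
                "junk": lmm_lr_test(data, "y", "junk"),
            }
        )
        assert table.loc[0, "model"] == "signal" and bool(table.loc[0, "best"])


class TestBayesFactor:
    def test_prior_collapse_gives_bf_one(self):
        res = bayes_factor(2.0, 1.0, prior_scale=1e-6, robustness=False)
        assert res.bf == pytest.approx(1.0, abs=1e-3)

    def test_uniform_prior_negative_effect_supports_null(self):
        res = bayes_factor(
            -8.0, 1.0, prior="uniform", prior_scale=5.0, robustness=False
        )
        assert res.bf < 1 / 3

    def test_robustness_region_contains_scale(self):
        res = bayes_factor(5.23, 1.69, prior_scale=10.5)
        lo, hi = res.bf_rr
        assert lo <= 10.5 <= hi
        assert res.bf > 3  # category: evidence for H1

    def test_t_likelihood_variant(self):
        res_n = bayes_factor(5.23, 1.69, prior_scale=10.5, robustness=False)
        res_t = bayes_factor(
            5.23, 1.69, prior_scale=10.5, likelihood_df=39, robustness=False
        )
        assert res_t.bf != pytest.approx(res_n.bf, rel=1e-3)
        assert res_t.bf > 3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bayes_factor(1.0, 0.0)
        with pytest.raises(ValueError):
            bayes_factor(1.0, 1.0, prior_scale=-1.0)
        with pytest.raises(ValueError):
            bayes_factor(1.0, 1.0, prior="cauchy")
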