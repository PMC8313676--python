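"""Behavioural preprocessing and mixed-effects machinery."""

import numpy as np
import pandas as pd
import pytest

from dichotic.stats import (
    decompose_within_between,
    error_breakdown,
    fdr_correct,
    fit_mixed_model,
    fit_mixed_models,
    fit_speed_model,
    lrt_random_slopes,
    preprocess_behaviour,
)


def _trials(n=40, rng=None, rt=2.0, accuracy="correct"):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "subject": ["s1"] * n,
        "trial": np.arange(n),
        "accuracy": [accuracy] * n,
        "correct": [accuracy == "correct"] * n,
        "rt": [rt] * n,
    })


class TestPreprocess:
    def test_speed_is_inverse_reaction_time(self):
        acc, speed = preprocess_behaviour(_trials(rt=2.0))
        assert (speed["speed"] == 0.5).all()
        assert len(acc) == len(speed) == 40

    def test_timeouts_excluded_everywhere(self):
        t = _trials(n=10)
        t.loc[3, "rt"] = 4.0
        t.loc[3, "accuracy"] = "timeout"
        t.loc[5, "rt"] = 4.5  # late response counts as timeout too
        acc, speed = preprocess_behaviour(t)
        assert len(acc) == 8 and len(speed) == 8
        assert 3 not in acc["trial"].values and 5 not in acc["trial"].values

    def test_no_correct_trials_gives_empty_speed(self, caplog):
        import logging
        t = _trials(n=6, accuracy="random_error")
        with caplog.at_level(logging.WARNING):
            acc, speed = preprocess_behaviour(t)
        assert speed.empty
        assert "empty" in caplog.text


class TestErrorBreakdown:
    @staticmethod
    def _table(conf_per_subj, rand_per_subj, n=20, total=40):
        rows = []
        for s in range(n):
            cats = (["spatial_confusion"] * conf_per_subj[s]
                    + ["random_error"] * rand_per_subj[s])
            cats += ["correct"] * (total - len(cats))
            for i, c in enumerate(cats):
                rows.append({"subject": f"s{s}", "trial": i, "accuracy": c,
                             "correct": c == "correct", "rt": 1.0})
        return pd.DataFrame(rows)

    def test_equal_proportions_give_zero_t(self):
        t = self._table([2] * 20, [2] * 20)
        out = error_breakdown(t)
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_doubled_confusions_give_positive_t(self):
        t = self._table([4] * 20, [2] * 20)
        out = error_breakdown(t)
        assert out["t"] > 0
        assert out["df"] == 19

    def test_zero_counts_stay_finite(self):
        t = self._table([0] * 20, [0] * 20)
        out = error_breakdown(t)
        assert np.isfinite(out["t"])


class TestDecomposition:
    def test_constant_within_subject_gives_zero_state(self):
        v = np.array([2.0, 2.0, 5.0, 5.0])
        s = np.array(["a", "a", "b", "b"])
        within, between = decompose_within_between(v, s)
        assert np.allclose(within, 0.0)

    def test_two_subject_between_zscore(self):
        v = np.array([1.0, 1.0, 3.0, 3.0])
        s = np.array(["a", "a", "b", "b"])
        _, between = decompose_within_between(v, s)
        # subject means 1 and 3, sample SD sqrt(2): z = -/+ 1/sqrt(2)
        assert np.allclose(between, [-0.70710678, -0.70710678,
                                     0.70710678, 0.70710678])

    def test_orthogonality(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=300)
        s = np.repeat([f"s{i}" for i in range(30)], 10)
        within, between = decompose_within_between(v, s)
        assert abs(np.cov(within, between)[0, 1]) < 1e-10

    def test_within_sums_to_zero_per_subject(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=60)
        s = np.repeat(["a", "b", "c"], 20)
        within, _ = decompose_within_between(v, s, z_within=False)
        for g in ("a", "b", "c"):
            assert abs(within[s == g].sum()) < 1e-10


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_correct([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        adj = fdr_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_all_ones_stay_one(self):
        assert np.allclose(fdr_correct([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_ranks(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(size=20))
        adj = fdr_correct(p)
        assert np.all(np.diff(adj) >= -1e-12)
        assert np.all(adj >= p - 1e-12)


def _glmm_data(n_sub=12, n_trial=40, beta=1.0, seed=0, gaussian=False):
    rng = np.random.default_rng(seed)
    sub = np.repeat(np.arange(n_sub), n_trial)
    item = np.tile(np.arange(n_trial), n_sub)
    cue = np.tile(np.r_[np.full(n_trial // 2, -0.5), np.full(n_trial // 2, 0.5)], n_sub)
    u = rng.normal(0, 0.5, n_sub)[sub]
    d = pd.DataFrame({"subject": sub, "item": item, "cue": cue})
    if gaussian:
        d["y"] = beta * cue + u + rng.normal(0, 0.8, len(d))
    else:
        lp = 0.3 + beta * cue + u
        d["y"] = (rng.random(len(d)) < 1 / (1 + np.exp(-lp))).astype(int)
    return d


class TestMixedModels:
    def test_intercept_only_on_chance_data(self):
        d = _glmm_data(beta=0.0, seed=4)
        d["y"] = np.random.default_rng(5).integers(0, 2, len(d))
        fit = fit_mixed_model(d, "y ~ 1 + (1 | subject)", "binomial")
        # intercept consistent with 0 on the logit scale up to sampling error
        assert abs(fit.coef("(Intercept)")) < 3 * fit.se("(Intercept)")

    def test_deviation_code_flip_negates_coefficient(self):
        d = _glmm_data(beta=1.2, seed=6, gaussian=True)
        d2 = d.assign(cue=-d["cue"])
        fits = fit_mixed_models([
            {"name": "a", "data": d, "formula": "y ~ cue + (1 | subject)",
             "family": "gaussian"},
            {"name": "b", "data": d2, "formula": "y ~ cue + (1 | subject)",
             "family": "gaussian"},
        ])
        assert fits["a"].coef("cue") == pytest.approx(-fits["b"].coef("cue"), abs=1e-8)
        assert fits["a"].loglik == pytest.approx(fits["b"].loglik, abs=1e-6)

    def test_zero_noise_linear_recovery(self):
        n = 200
        rng = np.random.default_rng(7)
        x = rng.normal(size=n)
        d = pd.DataFrame({"subject": np.repeat([0, 1], n // 2), "x": x})
        d["y"] = 2.0 + 1.5 * x
        fit = fit_speed_model(d, "y ~ x + (1 | subject)", zscore_outcome=False)
        assert fit.coef("x") == pytest.approx(1.5, abs=1e-6)

    def test_odds_ratio_is_exp_estimate(self):
        d = _glmm_data(beta=0.8, seed=8)
        fit = fit_mixed_model(d, "y ~ cue + (1 | subject) + (1 | item)", "binomial")
        row = fit.table.set_index("term").loc["cue"]
        assert row["odds_ratio"] == pytest.approx(np.exp(row["estimate"]))
        assert (fit.table["p_fdr"] >= fit.table["p"] - 1e-15).all()

    def test_between_only_effect_leaves_within_null(self):
        """A purely trait-level association must load on the between
        regressor, not the within regressor."""
        rng = np.random.default_rng(9)
        n_sub, n_trial = 30, 30
        sub = np.repeat(np.arange(n_sub), n_trial)
        trait = rng.normal(size=n_sub)
        measure = trait[sub] + rng.normal(size=n_sub * n_trial)
        y = 0.8 * trait[sub] + rng.normal(0, 0.5, n_sub * n_trial)
        within, between = decompose_within_between(measure, sub)
        d = pd.DataFrame({"subject": sub, "y": y, "w": within, "b": between})
        fit = fit_mixed_model(d, "y ~ w + b + (1 | subject)", "gaussian")
        assert abs(fit.coef("w")) < 0.05
        assert fit.coef("b") > 0.3

    def test_agrees_with_statsmodels_oracle(self):
        """Fixed effects match an independent Gaussian LMM implementation."""
        import statsmodels.formula.api as smf
        d = _glmm_data(n_sub=15, n_trial=30, beta=0.9, seed=10, gaussian=True)
        fit = fit_mixed_model(d, "y ~ cue + (1 | subject)", "gaussian",
                              reml=True)
        sm_fit = smf.mixedlm("y ~ cue", d, groups=d["subject"]).fit(reml=True)
        assert fit.coef("cue") == pytest.approx(sm_fit.params["cue"], abs=1e-4)
        assert fit.coef("(Intercept)") == pytest.approx(
            sm_fit.params["Intercept"], abs=1e-4)
        assert fit.se("cue") == pytest.approx(sm_fit.bse["cue"], rel=1e-3)


class TestLrt:
    def _fits(self, heterogeneity, seed):
        rng = np.random.default_rng(seed)
        n_sub, n_trial = 24, 40
        sub = np.repeat(np.arange(n_sub), n_trial)
        cue = np.tile(np.r_[np.full(n_trial // 2, -0.5), np.full(n_trial // 2, 0.5)], n_sub)
        slope = 0.8 + rng.normal(0, heterogeneity, n_sub)[sub]
        y = slope * cue + rng.normal(0, 0.4, n_sub)[sub] + rng.normal(0, 0.6, len(sub))
        d = pd.DataFrame({"subject": sub, "cue": cue, "y": y})
        return fit_mixed_models([
            {"name": "base", "data": d, "formula": "y ~ cue + (1 | subject)",
             "family": "gaussian"},
            {"name": "ext", "data": d, "formula": "y ~ cue + (1 + cue | subject)",
             "family": "gaussian"},
        ])

    def test_identical_models_retain_base(self):
        fits = self._fits(0.0, seed=11)
        out = lrt_random_slopes(fits["base"], fits["base"])
        assert out["statistic"] == 0.0
        assert not out["adopt_extension"]

    def test_strong_heterogeneity_adopts_extension(self):
        adopted = 0
        for seed in range(5):
            fits = self._fits(1.0, seed=20 + seed)
            out = lrt_random_slopes(fits["base"], fits["ext"])
            adopted += out["adopt_extension"]
        assert adopted >= 4

    def test_non_nested_rejected(self):
        fits = self._fits(0.5, seed=12)
        with pytest.raises(ValueError, match="nested"):
            lrt_random_slopes(fits["ext"], fits["base"])
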