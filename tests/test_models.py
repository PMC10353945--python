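"""Regression engine: stratification, recovery, conventions and FDR."""

import numpy as np
import pandas as pd
import pytest

import lofburden as lb
from lofburden.models import (RegressionSpec, fdr_adjust, participation_or,
                              reverse_townsend, split_lof_by_or)

from conftest import make_carrier_matrix


def synthetic_frame(n, carrier_freq=0.05, traits=None, seed=0, pgs_shift=0.0):
    rng = np.random.default_rng(seed)
    cohort = lb.build_cohort(lb.CohortSpec(max(n // 100, 10), n - max(n // 100, 10),
                                           family_fraction=0.0,
                                           pgs_shift_diagnosed=pgs_shift, seed=seed))
    ind = pd.DataFrame({"lof_high": rng.binomial(1, carrier_freq, n),
                        "lof_low": rng.binomial(1, carrier_freq, n)},
                       index=pd.Index(cohort["individual_id"], name="individual_id"))
    phen = lb.simulate_phenotypes(cohort, ind, traits, seed=seed + 1)
    return lb.prepare_model_frame(cohort, ind, phen), ind, phen


class TestSplitByOr:
    def _carriers(self, cohort):
        genes = [lb.GeneSpec(f"G{i}", "other", 0.02, 0.01, 300) for i in range(4)]
        return make_carrier_matrix(cohort, genes, seed=60)

    def test_threshold_stratification(self, small_cohort):
        cm = self._carriers(small_cohort)
        # gene ORs mirroring printed exemplars: 7.4 low, 150.1 high, exactly
        # 10 low, infinity high
        ors = pd.Series([7.4, 150.1, 10.0, np.inf], index=cm.genes)
        ind = split_lof_by_or(cm, ors)
        long = cm.to_long()
        for gene, expect_high in zip(cm.genes, [0, 1, 0, 1]):
            carriers = long.loc[long["gene_id"] == gene, "individual_id"]
            col = "lof_high" if expect_high else "lof_low"
            assert (ind.loc[carriers, col] == 1).all()

    def test_undefined_or_excluded(self, small_cohort):
        cm = self._carriers(small_cohort)
        ors = pd.Series([np.nan] * 4, index=cm.genes)
        ind = split_lof_by_or(cm, ors)
        assert ind.to_numpy().sum() == 0

    def test_carrier_on_both_sides_flagged_twice(self, small_cohort):
        cm = self._carriers(small_cohort)
        ors = pd.Series([2.0, 50.0, 2.0, 50.0], index=cm.genes)
        ind = split_lof_by_or(cm, ors)
        long = cm.to_long()
        per_ind = long.merge(ors.rename("or_"), left_on="gene_id", right_index=True)
        both = per_ind.groupby("individual_id")["or_"].agg(
            lambda s: (s <= 10).any() and (s > 10).any())
        both_ids = both[both].index
        if len(both_ids):
            assert (ind.loc[both_ids, ["lof_low", "lof_high"]] == 1).all().all()


class TestLinearRecovery:
    def test_recovers_generative_beta(self):
        traits = {"y": lb.TraitSpec("continuous", lb.EffectSpec(
            beta_lof_high=-0.37, beta_lof_low=-0.19, beta_pgs=0.05))}
        frame, _, _ = synthetic_frame(40_000, carrier_freq=0.025, traits=traits, seed=70)
        res = lb.fit_model(frame, RegressionSpec.from_preset(
            "y", "linear", "population_trait", "lof_high"))
        b = res.set_index("term")["estimate"]
        assert b["lof_high"] == pytest.approx(-0.37, abs=0.08)
        assert b["pgs"] == pytest.approx(0.05, abs=0.02)

    def test_pure_noise_covariate_barely_moves_estimates(self):
        traits = {"y": lb.TraitSpec("continuous", lb.EffectSpec(beta_lof_high=-0.3))}
        frame, _, _ = synthetic_frame(50_000, traits=traits, seed=71)
        rng = np.random.default_rng(72)
        frame["noise_cov"] = rng.standard_normal(len(frame))
        base = lb.fit_model(frame, RegressionSpec("y", "linear",
                                                  ("LoF", "pgs", "sex"), "lof_high"))
        with_noise = lb.fit_model(frame, RegressionSpec(
            "y", "linear", ("LoF", "pgs", "sex", "noise_cov"), "lof_high"))
        a = base.set_index("term")["estimate"]
        b = with_noise.set_index("term")["estimate"]
        assert abs(a["lof_high"] - b["lof_high"]) < 0.01

    def test_standardized_outcome_zero_intercept(self):
        traits = {"y": lb.TraitSpec("continuous", lb.EffectSpec())}
        frame, _, _ = synthetic_frame(5_000, traits=traits, seed=73)
        spec = RegressionSpec("y", "linear", ("pgs", "sex"))
        sub = frame.dropna(subset=["y"])
        y = sub["y"]
        y = (y - y.mean()) / y.std(ddof=0)
        import statsmodels.api as sm
        from lofburden.models import _build_design
        res = sm.OLS(y, _build_design(sub, spec)).fit()
        # binary sex stays unstandardized, so the intercept only shrinks
        # to the order of beta_sex * mean(sex); here effects are null
        assert abs(res.params["const"]) < 0.01

    def test_ci_coverage_near_nominal(self):
        # 200 small null replicates: the 95% CI for the carrier effect
        # should cover zero ~95% of the time
        rng = np.random.default_rng(74)
        covered = 0
        reps = 200
        for r in range(reps):
            n = 400
            x = rng.binomial(1, 0.2, n)
            y = rng.standard_normal(n)
            df = pd.DataFrame({"y": y, "lof_high": x,
                               "pgs": rng.standard_normal(n)})
            res = lb.fit_model(df, RegressionSpec("y", "linear", ("LoF", "pgs")))
            row = res.set_index("term").loc["lof_high"]
            covered += row["ci_low"] <= 0 <= row["ci_high"]
        assert abs(covered / reps - 0.95) < 0.05


class TestLogistic:
    def test_recovers_generative_log_or(self):
        rng = np.random.default_rng(75)
        n = 50_000
        lof = rng.binomial(1, 0.03, n)
        pgs = rng.standard_normal(n)
        logit = -2.0 + 1.5 * lof + 0.3 * pgs
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame({"diagnosed": y.astype(int), "lof_high": lof, "pgs": pgs,
                           "sex": rng.binomial(1, 0.5, n)})
        res = lb.fit_model(df, RegressionSpec("diagnosed", "binary_logistic",
                                              ("LoF", "pgs", "sex", "LoF:pgs")))
        b = res.set_index("term")["estimate"]
        assert b["lof_high"] == pytest.approx(1.5, abs=0.15)

    def test_pgs_shift_gives_positive_coefficient(self):
        frame, _, _ = synthetic_frame(30_000, seed=76, pgs_shift=0.2)
        res = lb.fit_model(frame, RegressionSpec.from_preset(
            "diagnosed", "binary_logistic", "diagnosis", "lof_high"))
        row = res.set_index("term").loc["pgs"]
        assert row["estimate"] > 0 and row["p_value"] < 0.01

    def test_separation_flagged(self):
        df = pd.DataFrame({"diagnosed": [0] * 50 + [1] * 50,
                           "lof_high": [0] * 50 + [1] * 50,
                           "pgs": np.random.default_rng(77).standard_normal(100)})
        res = lb.fit_model(df, RegressionSpec("diagnosed", "binary_logistic",
                                              ("LoF", "pgs")))
        assert res.attrs["separation"]


class TestOrdinal:
    def test_recovers_latent_beta(self):
        traits = {"band": lb.TraitSpec("ordinal", lb.EffectSpec(
            beta_lof_high=-0.5, band_thresholds=(-1.1, 0.0, 1.1, 2.4)),
            noise_dist="logistic")}
        frame, _, _ = synthetic_frame(40_000, carrier_freq=0.05, traits=traits, seed=78)
        res = lb.fit_model(frame, RegressionSpec(
            "band", "ordinal_logistic", ("LoF", "pgs", "sex"), "lof_high"))
        row = res.set_index("term").loc["lof_high"]
        assert row["estimate"] == pytest.approx(-0.5, abs=0.1)
        assert row["odds_ratio"] == pytest.approx(np.exp(row["estimate"]))

    def test_null_effect_ci_covers_one(self):
        traits = {"band": lb.TraitSpec("ordinal", lb.EffectSpec(
            band_thresholds=(-1.0, 0.0, 1.0)), noise_dist="logistic")}
        frame, _, _ = synthetic_frame(10_000, traits=traits, seed=79)
        res = lb.fit_model(frame, RegressionSpec(
            "band", "ordinal_logistic", ("LoF", "pgs"), "lof_high"))
        row = res.set_index("term").loc["lof_high"]
        assert row["or_ci_low"] <= 1 <= row["or_ci_high"]

    def test_reversed_band_order_inverts_or(self):
        traits = {"band": lb.TraitSpec("ordinal", lb.EffectSpec(
            beta_lof_high=-0.6, band_thresholds=(-1.0, 0.0, 1.0)),
            noise_dist="logistic")}
        frame, _, _ = synthetic_frame(8_000, carrier_freq=0.1, traits=traits, seed=80)
        res = lb.fit_model(frame, RegressionSpec(
            "band", "ordinal_logistic", ("LoF", "pgs"), "lof_high"))
        frame["band_rev"] = frame["band"].max() + 1 - frame["band"]
        res_rev = lb.fit_model(frame, RegressionSpec(
            "band_rev", "ordinal_logistic", ("LoF", "pgs"), "lof_high"))
        a = res.set_index("term").loc["lof_high", "estimate"]
        b = res_rev.set_index("term").loc["lof_high", "estimate"]
        assert a == pytest.approx(-b, abs=1e-3)

    def test_empty_level_raises_unless_collapsed(self):
        df = pd.DataFrame({"band": [1, 1, 3, 3] * 30,
                           "lof_high": [0, 1] * 60,
                           "pgs": np.random.default_rng(81).standard_normal(120)})
        with pytest.raises(ValueError, match="empty"):
            lb.fit_model(df, RegressionSpec("band", "ordinal_logistic", ("LoF", "pgs")))
        res = lb.fit_model(df, RegressionSpec("band", "ordinal_logistic", ("LoF", "pgs")),
                           empty_levels="collapse")
        assert len(res) == 2


class TestConventions:
    def test_townsend_reversal_is_negation(self):
        x = pd.Series([1.0, -2.0, 0.0])
        assert (reverse_townsend(x) == -x).all()
        assert (reverse_townsend(reverse_townsend(x)) == x).all()

    def test_reversal_flips_fitted_beta_exactly(self):
        traits = {"townsend_index": lb.TraitSpec("continuous", lb.EffectSpec(
            beta_lof_high=0.15))}
        frame, _, _ = synthetic_frame(20_000, traits=traits, seed=82)
        frame["townsend_reversed"] = reverse_townsend(frame["townsend_index"])
        spec = lambda out: RegressionSpec(out, "linear", ("LoF", "pgs"), "lof_high")
        raw = lb.fit_model(frame, spec("townsend_index")).set_index("term")
        rev = lb.fit_model(frame, spec("townsend_reversed")).set_index("term")
        assert raw.loc["lof_high", "estimate"] == pytest.approx(
            -rev.loc["lof_high", "estimate"], abs=1e-10)


class TestFdr:
    def test_by_hand_step_up(self):
        df = pd.DataFrame({"p_value": [0.01, 0.02, 0.03, 0.04]})
        out = fdr_adjust(df, group_cols=())
        assert out["p_fdr"].tolist() == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        out = fdr_adjust(pd.DataFrame({"p_value": [0.2]}), group_cols=())
        assert out["p_fdr"].iloc[0] == pytest.approx(0.2)

    def test_adjusted_never_below_raw_and_grouping_respected(self, rng):
        df = pd.DataFrame({"p_value": rng.random(30),
                           "term": np.tile(["a", "b", "c"], 10),
                           "outcome_group": np.repeat(["g1", "g2"], 15)})
        out = fdr_adjust(df)
        assert (out["p_fdr"] >= out["p_value"] - 1e-12).all()
        # within-group monotone step-up: order of adjusted follows order of raw
        for _, grp in out.groupby(["term", "outcome_group"]):
            srt = grp.sort_values("p_value")
            assert srt["p_fdr"].is_monotonic_increasing


class TestParticipation:
    def test_null_or_near_unity(self):
        rng = np.random.default_rng(83)
        carrier = rng.binomial(1, 0.05, 100_000).astype(bool)
        resp = rng.binomial(1, 0.85, 100_000).astype(bool)
        res = participation_or(carrier, resp)
        assert res["odds_ratio"] == pytest.approx(1.0, abs=0.1)
        assert res["ci_low"] < 1 < res["ci_high"]

    def test_zero_responding_carriers(self):
        carrier = np.array([True] * 10 + [False] * 100)
        resp = np.array([False] * 10 + [True] * 80 + [False] * 20)
        res = participation_or(carrier, resp)
        assert res["odds_ratio"] == 0.0
        assert np.isfinite(res["ci_low"]) and np.isfinite(res["ci_high"])  # Haldane

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main effect"):
            RegressionSpec("y", "linear", ("pgs", "LoF:pgs"), "lof_high")
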