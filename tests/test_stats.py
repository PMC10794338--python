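"""Statistical layer: LexTALE, arcsine, JZS Bayes factors, ex-Gaussian MLE."""

import math

import numpy as np
import pandas as pd
import pytest

from partialpress.stats import (
    arcsine_transform,
    fit_exgaussian,
    jzs_mixed_anova_bf,
    jzs_ttest_bf,
    lextale_score,
    signed_rank_bf,
)
from partialpress.stats.exgauss import fit_exgaussian_cell

from oracles import ttest_bf10_grid_oracle, ttest_bf10_oracle


class TestLextale:
    @pytest.mark.parametrize(
        "words, nonwords, score, included",
        [
            (40, 20, 100.0, True),
            (0, 0, 0.0, False),
            (30, 15, 75.0, True),
            (28, 14, 70.0, False),  # exactly 70 is excluded (> 70 includes)
        ],
    )
    def test_scores(self, words, nonwords, score, included):
        res = lextale_score(words, nonwords)
        assert res.score == score
        assert res.included is included

    @pytest.mark.parametrize("words, nonwords", [(-1, 0), (41, 0), (0, 21), (2.5, 3)])
    def test_invalid_counts_rejected(self, words, nonwords):
        with pytest.raises(ValueError):
            lextale_score(words, nonwords)


class TestArcsine:
    def test_closed_forms(self):
        assert arcsine_transform(0.0) == 0.0
        assert arcsine_transform(1.0) == pytest.approx(math.pi / 2)
        assert arcsine_transform(0.25) == pytest.approx(math.pi / 6)

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            arcsine_transform(1.1)


class TestTTestBF:
    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            jzs_ttest_bf(np.zeros(10))

    def test_null_data_favor_null(self):
        # t = 0 exactly: symmetric vector
        d = np.array([-2.0, -1.0, 1.0, 2.0])
        res = jzs_ttest_bf(d)
        assert res.extras["t"] == 0.0
        assert res.bf("H1", "H0") < 1.0

    def test_matches_g_space_oracle(self):
        rng = np.random.default_rng(42)
        for loc in (0.0, 0.4, 0.9):
            d = rng.normal(loc, 1.0, 20)
            res = jzs_ttest_bf(d, prior_scale=0.707)
            oracle = ttest_bf10_oracle(res.extras["t"], 20, 0.707)
            assert res.bf("H1", "H0") == pytest.approx(oracle, rel=1e-4)

    def test_one_sided_matches_grid_oracle(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.5, 1.0, 15)
        for direction in ("greater", "less"):
            res = jzs_ttest_bf(d, 0.707, direction)
            oracle = ttest_bf10_grid_oracle(res.extras["t"], 15, 0.707, direction)
            assert res.bf("H1", "H0") == pytest.approx(oracle, rel=1e-3)

    def test_sides_average_to_two_sided(self):
        d = np.random.default_rng(2).normal(0.3, 1.0, 12)
        two = jzs_ttest_bf(d).bf("H1", "H0")
        g = jzs_ttest_bf(d, direction="greater").bf("H1", "H0")
        l = jzs_ttest_bf(d, direction="less").bf("H1", "H0")
        assert (g + l) / 2 == pytest.approx(two, rel=1e-6)


def make_anova_table(n_per_group=10, within_effect=0.0, interaction=0.0,
                     noise=20.0, seed=0, base=500.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_group):
        cond = "low" if i < n_per_group else "high"
        subj = base + rng.normal(0, 60)
        shift = within_effect + (interaction if cond == "high" else 0.0)
        rows.append(dict(participant_id=f"p{i:02d}", condition=cond,
                         item_type="irrelevant",
                         mean_rt_ms=subj + rng.normal(0, noise)))
        rows.append(dict(participant_id=f"p{i:02d}", condition=cond,
                         item_type="probe",
                         mean_rt_ms=subj + shift + rng.normal(0, noise)))
    return pd.DataFrame(rows)


class TestAnovaBF:
    def test_strong_within_effect_detected(self):
        df = make_anova_table(n_per_group=17, within_effect=100, seed=3)
        res = jzs_mixed_anova_bf(df, samples=8000, seed=1)
        assert res.log_bf[("Main", "Fam")] > math.log(10)
        assert res.log_bf[("Full", "Main")] < 0  # no interaction injected

    def test_direction_stable_across_seeds(self):
        df = make_anova_table(n_per_group=17, within_effect=100, seed=3)
        signs = [
            jzs_mixed_anova_bf(df, samples=4000, seed=s).log_bf[("Main", "Fam")] > 0
            for s in range(5)
        ]
        assert all(signs)

    def test_no_signal_favors_simpler_models(self):
        # participants differ, but no condition/item-type/interaction effects:
        # every added effect term is penalized
        df = make_anova_table(n_per_group=10, within_effect=0.0, noise=15.0,
                              seed=4)
        res = jzs_mixed_anova_bf(df, samples=8000, seed=2)
        assert res.log_bf[("Fam", "Null")] < 0
        assert res.log_bf[("Main", "Fam")] < 0
        assert res.log_bf[("Full", "Main")] < 0

    def test_globally_constant_dv_rejected(self):
        df = make_anova_table(seed=5)
        df["mean_rt_ms"] = 7.0
        with pytest.raises(ValueError, match="constant"):
            jzs_mixed_anova_bf(df, samples=1000, seed=0)

    def test_unbalanced_table_rejected(self):
        df = make_anova_table(seed=6).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            jzs_mixed_anova_bf(df, samples=1000, seed=0)

    def test_missing_cells_rejected(self):
        df = make_anova_table(seed=6)
        df.loc[0, "mean_rt_ms"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            jzs_mixed_anova_bf(df, samples=1000, seed=0)

    def test_location_and_relabel_invariance(self):
        df = make_anova_table(n_per_group=8, within_effect=50, seed=7)
        res = jzs_mixed_anova_bf(df, samples=6000, seed=3)
        shifted = df.assign(mean_rt_ms=df["mean_rt_ms"] + 1e4)
        res_shift = jzs_mixed_anova_bf(shifted, samples=6000, seed=3)
        assert res_shift.log_bf[("Main", "Fam")] == pytest.approx(
            res.log_bf[("Main", "Fam")], abs=1e-6
        )
        relabeled = df.assign(
            participant_id=df["participant_id"].map(lambda s: "zz_" + s)
        )
        res_rel = jzs_mixed_anova_bf(relabeled, samples=6000, seed=3)
        assert res_rel.log_bf[("Main", "Fam")] == pytest.approx(
            res.log_bf[("Main", "Fam")], abs=1e-6
        )

    def test_null_simulations_favor_smaller_model(self):
        # median evidence under no within-effect must point to the simpler model
        logbfs = []
        for rep in range(20):
            df = make_anova_table(n_per_group=9, within_effect=0.0, seed=100 + rep)
            res = jzs_mixed_anova_bf(df, samples=2500, seed=rep)
            logbfs.append(res.log_bf[("Main", "Fam")])
        assert np.median(logbfs) < 0

    def test_antisymmetry_accessor(self):
        df = make_anova_table(seed=8)
        res = jzs_mixed_anova_bf(df, samples=2000, seed=1)
        assert res.log_bf_for("Fam", "Main") == -res.log_bf_for("Main", "Fam")


class TestSignedRankBF:
    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            signed_rank_bf(np.zeros(10))

    def test_one_sided_direction(self):
        d = np.abs(np.random.default_rng(5).normal(1.0, 0.3, 18))
        res = signed_rank_bf(d, "greater", n_samples=1500, burn_in=300, seed=1)
        assert res.bf("H1", "H0") > 1

    def test_sign_flip_reverses_direction(self):
        d = np.abs(np.random.default_rng(5).normal(1.0, 0.3, 18))
        res_fwd = signed_rank_bf(d, "greater", n_samples=1500, burn_in=300, seed=1)
        res_rev = signed_rank_bf(-d, "greater", n_samples=1500, burn_in=300, seed=1)
        assert res_fwd.bf("H1", "H0") > 1 > res_rev.bf("H1", "H0")

    def test_seed_consistency_within_mc_error(self):
        d = np.random.default_rng(6).normal(0.3, 1.0, 16)
        a = signed_rank_bf(d, "greater", n_samples=3000, burn_in=400, seed=1)
        b = signed_rank_bf(d, "greater", n_samples=3000, burn_in=400, seed=2)
        assert a.log_bf[("H1", "H0")] == pytest.approx(
            b.log_bf[("H1", "H0")], abs=0.5
        )

    def test_labeled_approximate(self):
        d = np.random.default_rng(7).normal(0.5, 1.0, 12)
        res = signed_rank_bf(d, n_samples=500, burn_in=100, seed=0)
        assert "approximate" in res.extras["method"]


class TestExGaussian:
    def test_moment_identities_on_converged_fit(self):
        rng = np.random.default_rng(9)
        x = 400 + 60 * rng.standard_normal(3000) + rng.exponential(150, 3000)
        p = fit_exgaussian_cell(x)
        assert p.converged
        assert p.mean_ms == pytest.approx(np.mean(x), rel=0.01)
        assert p.var_ms2 == pytest.approx(np.var(x, ddof=1), rel=0.05)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(10)
        x = 400 + 60 * rng.standard_normal(500) + rng.exponential(150, 500)
        p = fit_exgaussian_cell(x, min_n=100)
        assert p.density_integral() == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_input_flagged_not_raised(self):
        p = fit_exgaussian_cell(np.full(80, 500.0))
        assert not p.converged

    def test_negative_rts_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_exgaussian_cell(np.array([-1.0] * 60))

    def test_small_cell_rejected_by_default(self):
        with pytest.raises(ValueError, match="at least"):
            fit_exgaussian_cell(np.array([400.0, 500.0, 600.0] * 5))

    def _table(self, n=1500, seed=11):
        rng = np.random.default_rng(seed)
        item_type = rng.choice(["probe", "irrelevant"], n)
        partial = rng.random(n) < 0.15
        mu = np.where(item_type == "probe", 450, 380)
        rt = mu + 50 * rng.standard_normal(n) + rng.exponential(120, n)
        rt = rt + np.where(partial, 80, 0)
        return pd.DataFrame(
            {"rt_ms": rt, "item_type": item_type, "is_partial_error": partial,
             "participant_id": rng.choice([f"p{i}" for i in range(8)], n),
             "category": rng.choice(list("abcde"), n)}
        )

    def test_cells_structure_recovers_shift(self):
        df = self._table()
        fit = fit_exgaussian(df, structure="cells")
        assert fit.converged
        probe = fit.cells[("probe", False)]
        irr = fit.cells[("irrelevant", False)]
        assert probe.mean_ms - irr.mean_ms == pytest.approx(70, abs=35)

    def test_regression_structure_fits_partial_cost(self):
        df = self._table()
        fit = fit_exgaussian(df, structure="regression")
        assert fit.converged
        # partial trials injected 80 ms slower on mu
        assert fit.coefficients["mu_ms"]["is_partial_error[True]"] == pytest.approx(
            80, abs=40
        )

    def test_hierarchical_smoke(self):
        df = self._table(n=1200)
        fit = fit_exgaussian(df, structure="hierarchical")
        assert fit.converged
        assert set(fit.random_sd) == {"participant_id", "category"}
        assert fit.loglik > -np.inf
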