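"""Exact rank tests, effect sizes, correlations and AICc model selection."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

import molartopo as mt

from oracles import mann_whitney_p_bruteforce, signed_rank_p_bruteforce


def diffs_with_positive_ranks(pos_ranks, n=7):
    """n paired differences whose |value| ranks are 1..n and whose positive
    signs sit exactly on ``pos_ranks``."""
    return np.array([(1.0 if r in pos_ranks else -1.0) * r for r in range(1, n + 1)])


class TestSignedRank:
    @pytest.mark.parametrize("pos_ranks,stat,p", [
        ({7, 6, 1}, 14.0, 1.0),          # statistic at the null mean -> p = 1
        ({5}, 5.0, 0.15625),
        ({1}, 1.0, 0.03125),
        (set(), 0.0, 0.015625),
        ({5, 6, 7}, 18.0, 0.578125),
    ])
    def test_worked_examples_n7(self, pos_ranks, stat, p):
        res = mt.signed_rank_exact(diffs_with_positive_ranks(pos_ranks))
        assert res.method == "signed_rank_exact"
        assert res.statistic == stat
        assert np.isclose(res.p_two_sided, p, rtol=1e-12)

    def test_matches_brute_force_all_small_n(self):
        rng = np.random.default_rng(42)
        for n in range(2, 9):
            for _ in range(8):
                d = rng.normal(size=n)
                d[np.abs(d) < 1e-3] = 0.5
                stat_bf, p_bf = signed_rank_p_bruteforce(d)
                res = mt.signed_rank_exact(d)
                assert res.statistic == stat_bf
                assert np.isclose(res.p_two_sided, p_bf, rtol=1e-12), (n, d)

    def test_ties_handled_exactly(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, -3.0])  # midranks, still exact
        stat_bf, p_bf = signed_rank_p_bruteforce(d)
        res = mt.signed_rank_exact(d)
        assert np.isclose(res.p_two_sided, p_bf, rtol=1e-12)

    def test_zeros_dropped(self):
        with_zeros = mt.signed_rank_exact([0.0, 0.0, 1.0, -2.0, 3.0])
        without = mt.signed_rank_exact([1.0, -2.0, 3.0])
        assert with_zeros.n == 3
        assert with_zeros.p_two_sided == without.p_two_sided

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="zero"):
            mt.signed_rank_exact([0.0, 0.0])

    def test_large_n_uses_flagged_approximation(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.3, 1.0, 40)
        res = mt.signed_rank_exact(d)
        assert res.method == "normal_approx"
        # continuity-corrected normal approximation, as scipy/R report it
        ref = ss.wilcoxon(d, correction=True, mode="approx").pvalue
        assert np.isclose(res.p_two_sided, ref, rtol=1e-6)

    def test_null_size_is_conservative(self):
        """At alpha=0.05 the exact test rejects at most ~5% of exchangeable
        null samples (discrete support makes it conservative)."""
        rng = np.random.default_rng(2024)
        n_rep, n = 2000, 8
        rejections = sum(
            mt.signed_rank_exact(rng.normal(size=n)).p_two_sided < 0.05
            for _ in range(n_rep)
        )
        rate = rejections / n_rep
        assert rate <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_rep)


class TestMannWhitney:
    def test_complete_separation_3v3(self):
        res = mt.mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert np.isclose(res.p_two_sided, 0.1, rtol=1e-12)  # 2/C(6,3)

    def test_identical_samples(self):
        res = mt.mann_whitney_exact([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5  # n^2/2 with all ties at half credit
        assert res.p_two_sided == 1.0

    def test_exact_7v11_u11(self):
        a = np.concatenate([np.arange(6.0), [100.0]])
        b = np.arange(10.0, 21.0)
        res = mt.mann_whitney_exact(a, b)
        assert res.statistic == 11.0
        assert res.method == "rank_sum_exact"
        assert np.isclose(res.p_two_sided,
                          ss.mannwhitneyu(a, b, method="exact").pvalue, rtol=1e-9)

    def test_tied_large_sample_matches_r_fallback(self):
        """With ties at n=18 the continuity-corrected approximation is used;
        it reproduces the 0.014 printed for the U=11 OPCR sex contrast."""
        a = np.concatenate([np.arange(6.0), [100.0]])
        b = np.concatenate([np.arange(10.0, 20.0), [19.0]])
        res = mt.mann_whitney_exact(a, b)
        assert res.method == "normal_approx"
        assert round(res.p_two_sided, 3) == 0.014

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for n1, n2 in [(3, 3), (4, 5), (5, 7), (6, 6)]:
            for _ in range(5):
                a, b = rng.normal(size=n1), rng.normal(size=n2)
                stat_bf, p_bf = mann_whitney_p_bruteforce(a, b)
                res = mt.mann_whitney_exact(a, b)
                assert res.statistic == stat_bf
                assert np.isclose(res.p_two_sided, p_bf, rtol=1e-12)

    def test_ties_enumerated_exactly_when_small(self):
        a = [1.0, 2.0, 2.0, 4.0]
        b = [2.0, 3.0, 5.0]
        stat_bf, p_bf = mann_whitney_p_bruteforce(a, b)
        res = mt.mann_whitney_exact(a, b)
        assert res.method == "rank_sum_exact"
        assert np.isclose(res.p_two_sided, p_bf, rtol=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mt.mann_whitney_exact([], [1.0])


class TestEffectSizes:
    def test_identical_samples_zero(self):
        eff = mt.effect_sizes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert eff.cohens_d_pooled == 0.0
        assert eff.cohens_d_paired == 0.0

    def test_hand_computed_pooled_d(self):
        eff = mt.effect_sizes([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
        assert np.isclose(eff.cohens_d_pooled, -2.0, rtol=1e-12)
        assert eff.band == "large"

    def test_simulated_unit_effect(self):
        rng = np.random.default_rng(123)
        a = rng.normal(1.0, 1.0, 10_000)
        b = rng.normal(0.0, 1.0, 10_000)
        eff = mt.effect_sizes(a, b)
        assert abs(eff.cohens_d_pooled - 1.0) < 0.05

    def test_zero_variance_unequal_means_flagged(self):
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            eff = mt.effect_sizes([1.0, 1.0], [2.0, 2.0])
        assert math.isinf(eff.cohens_d_pooled)
        assert any("infinite" in str(w.message) for w in rec)


class TestPearson:
    def _frame(self, cols):
        n = len(next(iter(cols.values())))
        return pd.DataFrame({"individual_id": [f"i{k}" for k in range(n)],
                             "species": "A", "sex": "F", "side": "L", **cols})

    def test_exact_linear_relationships(self):
        x = np.arange(10.0)
        df = self._frame({"m1": x, "m2": 2 * x + 1, "m3": -x})
        corr = mt.pearson_matrix(df, ["m1", "m2", "m3"])
        assert np.isclose(corr.loc["m1", "m2"], 1.0)
        assert np.isclose(corr.loc["m1", "m3"], -1.0)
        assert (np.diag(corr.values) == 1.0).all()
        assert np.allclose(corr.values, corr.values.T)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        df = self._frame({"m1": rng.normal(size=10_000), "m2": rng.normal(size=10_000)})
        corr = mt.pearson_matrix(df, ["m1", "m2"])
        assert abs(corr.loc["m1", "m2"]) < 0.05

    def test_constant_column_flagged_not_zero(self):
        df = self._frame({"m1": np.arange(5.0), "m2": np.ones(5)})
        with pytest.warns(UserWarning, match="constant"):
            corr = mt.pearson_matrix(df, ["m1", "m2"])
        assert np.isnan(corr.loc["m1", "m2"])

    def test_subset_filter(self):
        x = np.arange(8.0)
        df = self._frame({"m1": x, "m2": x * 2})
        df.loc[4:, "species"] = "B"
        corr = mt.pearson_matrix(df, ["m1", "m2"], subset={"species": "A"})
        assert np.isclose(corr.loc["m1", "m2"], 1.0)

    def test_too_few_rows_rejected(self):
        df = self._frame({"m1": [1.0, 2.0], "m2": [1.0, 2.0]})
        with pytest.raises(ValueError, match=">= 3"):
            mt.pearson_matrix(df, ["m1", "m2"])


def cell_mean_records(cells):
    """Constant-valued records per (species, sex, n_individuals, value)."""
    recs = []
    for species, sex, n, value in cells:
        for i in range(n):
            for side in ("L", "R"):
                recs.append(mt.SpecimenRecord(f"{species}-{sex}-{i}", species,
                                              sex, side, {"y": value}))
    return recs


class TestModelFamily:
    def test_aicc_arithmetic(self):
        assert np.isclose(mt.aicc(-5.0, 2, 10), 14 + 12 / 7, rtol=1e-12)
        assert mt.aicc(-5.0, 0, 10) == 10.0  # k=0: correction vanishes
        assert np.isclose(mt.aicc(-5.0, 2, 10**9), 14.0, atol=1e-6)
        with pytest.raises(ValueError):
            mt.aicc(-5.0, 9, 10)

    def test_species_coefficient_is_difference_of_cell_means(self):
        recs = cell_mean_records([("sp1", "F", 7, 590.096), ("sp2", "F", 18, 472.835)])
        fits = mt.fit_model_family(recs, "y", estimator="ols")
        species_only = next(f for f in fits if f.fixed_effects == ("species",))
        coef = species_only.coefficients["species[sp2]"]
        assert round(coef, 3) == -117.261
        assert round(species_only.coefficients["intercept"], 3) == 590.096

    def test_three_cell_identities(self):
        """sex+species on three constant cells reproduces the cell-mean
        differences exactly."""
        recs = cell_mean_records([("sp1", "F", 7, 159.5), ("sp2", "F", 7, 149.894),
                                  ("sp2", "M", 11, 162.756)])
        fits = mt.fit_model_family(recs, "y", estimator="ols")
        fit = next(f for f in fits if set(f.fixed_effects) == {"sex", "species"})
        assert np.isclose(fit.coefficients["intercept"], 159.5, atol=1e-9)
        assert np.isclose(fit.coefficients["species[sp2]"], 149.894 - 159.5, atol=1e-9)
        assert np.isclose(fit.coefficients["sex[M]"], 162.756 - 149.894, atol=1e-9)

    def test_no_signal_prefers_intercept_only(self):
        rng = np.random.default_rng(17)
        recs = []
        for i in range(12):
            for side in ("L", "R"):
                recs.append(mt.SpecimenRecord(
                    f"i{i}", "sp1" if i < 6 else "sp2", "F" if i % 2 else "M",
                    side, {"y": rng.normal()}))
        fits = mt.fit_model_family(recs, "y", estimator="ols")
        assert fits[0].fixed_effects == ()

    def test_eight_models_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(10):
            for side in ("L", "R"):
                recs.append(mt.SpecimenRecord(
                    f"i{i}", "sp1" if i < 5 else "sp2", "F" if i % 2 else "M",
                    side, {"y": rng.normal()}))
        fits = mt.fit_model_family(recs, "y", estimator="random_intercept")
        assert len(fits) == 8
        assert np.isclose(sum(f.akaike_weight for f in fits), 1.0, atol=1e-9)
        assert min(f.delta_aicc for f in fits) == 0.0

    def test_planted_effects_recovered_unbiased(self):
        """Known side/sex/species effects with individual random intercepts:
        over simulations the full model's estimates centre on the truth and
        the REML standard errors describe their spread."""
        rng = np.random.default_rng(99)
        true = {"side[R]": 0.8, "sex[M]": -1.2, "species[sp2]": 2.0}
        ests = {k: [] for k in true}
        ses = {k: [] for k in true}
        for _ in range(50):
            rows = []
            for i in range(16):
                species = "sp1" if i < 8 else "sp2"
                sex = "F" if i % 2 == 0 else "M"
                u = rng.normal(0, 0.7)
                for side in ("L", "R"):
                    y = (10.0 + true["side[R]"] * (side == "R")
                         + true["sex[M]"] * (sex == "M")
                         + true["species[sp2]"] * (species == "sp2")
                         + u + rng.normal(0, 0.5))
                    rows.append({"individual_id": f"i{i}", "species": species,
                                 "sex": sex, "side": side, "y": y})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = mt.fit_model(pd.DataFrame(rows), "y",
                                   ("side", "sex", "species"),
                                   estimator="random_intercept", reml=True)
            for k in true:
                ests[k].append(fit.coefficients[k])
                ses[k].append(fit.stderr[k])
        for k, v in true.items():
            est = np.array(ests[k])
            # mean estimate within 3 monte-carlo SEs of the truth
            assert abs(est.mean() - v) <= 3 * est.std(ddof=1) / np.sqrt(len(est))
            # reported SE on the scale of the empirical spread
            assert 0.6 <= np.mean(ses[k]) / est.std(ddof=1) <= 1.6

    def test_duplicate_record_rejected(self):
        recs = [mt.SpecimenRecord("i1", "sp", "F", "L", {"y": 1.0}),
                mt.SpecimenRecord("i1", "sp", "F", "L", {"y": 2.0})]
        with pytest.raises(ValueError, match="duplicate"):
            mt.records_to_frame(recs)
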