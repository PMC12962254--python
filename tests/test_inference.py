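import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genjust.cohort import (CohortConfig, matrix_to_trials_frame,
                            simulate_cohort, simulate_rating_matrix,
                            trials_frame)
from genjust.inference import (gg_epsilon, oneway_between_anova,
                               paired_t_bonferroni, rm_ancova, rm_anova,
                               welch_t, _helmert)


def long_from_matrix(Y, factor="level"):
    n, m = Y.shape
    return pd.DataFrame({
        "participant_id": np.repeat([f"p{i}" for i in range(n)], m),
        factor: np.tile([f"l{j}" for j in range(m)], n),
        "rating": Y.ravel(),
    })


class TestRmAnova:
    def test_two_level_factor_equals_squared_paired_t(self, rng):
        Y = rng.normal(0, 1, (20, 2)) + [0.0, 0.4]
        res = rm_anova(long_from_matrix(Y), within=("level",))
        t = stats.ttest_rel(Y[:, 0], Y[:, 1])
        assert res.loc["level", "F"] == pytest.approx(t.statistic ** 2, abs=1e-10)
        assert res.loc["level", "epsilon"] == 1.0
        assert res.loc["level", "p"] == pytest.approx(t.pvalue, abs=1e-12)

    def test_matches_reference_three_factor_f_values(self, clean_frames):
        statsmodels = pytest.importorskip("statsmodels.stats.anova")
        trials, _ = clean_frames
        res = rm_anova(trials)
        df = trials.rename(columns={"dangerous": "danger"})
        ref = statsmodels.AnovaRM(
            df, "rating", "participant_id",
            within=["abs_level", "rel_level", "danger"]).fit().anova_table
        mapping = {
            "abs_level": "abs_level", "rel_level": "rel_level",
            "danger": "dangerous",
            "abs_level:rel_level": "abs_level:rel_level",
            "abs_level:danger": "abs_level:dangerous",
            "rel_level:danger": "rel_level:dangerous",
            "abs_level:rel_level:danger": "abs_level:rel_level:dangerous",
        }
        for ref_name, eff in mapping.items():
            assert res.loc[eff, "F"] == pytest.approx(
                ref.loc[ref_name, "F Value"], rel=1e-8)
            assert res.loc[eff, "df1_uncorrected"] == ref.loc[ref_name, "Num DF"]
            assert res.loc[eff, "df2_uncorrected"] == ref.loc[ref_name, "Den DF"]

    def test_recovers_generating_factor(self):
        ratings = simulate_rating_matrix(
            "absolute", 40, noise_sd=1.85, rng=np.random.default_rng(17))
        res = rm_anova(matrix_to_trials_frame(ratings))
        etas = res["partial_eta_sq"]
        assert etas.idxmax() == "abs_level"
        assert etas["abs_level"] > 3 * etas.drop("abs_level").max()

    def test_sum_of_squares_conservation(self, clean_frames):
        trials, _ = clean_frames
        res = rm_anova(trials)
        total = res.attrs["ss_subjects"] + res["ss_effect"].sum() + \
            res["ss_error"].sum()
        assert total == pytest.approx(res.attrs["ss_total"], rel=1e-8)

    def test_missing_cell_rejected(self, clean_frames):
        trials, _ = clean_frames
        broken = trials[~((trials["participant_id"] == "p0000")
                          & (trials["abs_level"] == "low"))]
        with pytest.raises(ValueError, match="missing"):
            rm_anova(broken)


class TestGGEpsilon:
    def test_two_measures_always_one(self, rng):
        S = np.cov(rng.normal(0, 1, (2, 30)))
        assert gg_epsilon(S) == pytest.approx(1.0)

    @pytest.mark.parametrize("m", [3, 4, 6])
    def test_compound_symmetry_gives_one(self, m):
        S = 0.7 * np.ones((m, m)) + 0.9 * np.eye(m)
        assert gg_epsilon(S) == pytest.approx(1.0, abs=1e-12)

    def test_fixed_matrix_against_closed_form(self):
        # eigenvalue evaluation of the double-centred covariance, by hand
        S = np.array([[2.0, 0.5, 0.3], [0.5, 1.5, 0.2], [0.3, 0.2, 1.0]])
        assert gg_epsilon(S) == pytest.approx(0.9894991922455572, abs=1e-10)

    def test_matches_reference_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(0, 1, (15, 3))
        Y[:, 2] += rng.normal(0, 1.5, 15)
        eps_ref = float(pg.epsilon(pd.DataFrame(Y), correction="gg"))
        assert gg_epsilon(np.cov(Y, rowvar=False)) == pytest.approx(eps_ref, abs=1e-12)
        # contrast form agrees with the double-centred form
        assert gg_epsilon(np.cov(Y, rowvar=False), contrast=_helmert(3)) == \
            pytest.approx(eps_ref, abs=1e-12)

    def test_bounds(self, rng):
        for m in (3, 4, 5):
            Y = rng.normal(0, 1, (20, m)) * np.arange(1, m + 1)
            eps = gg_epsilon(np.cov(Y, rowvar=False))
            assert 1 / (m - 1) - 1e-12 <= eps <= 1 + 1e-12

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.ones((2, 3)))


class TestPairedT:
    def test_d_is_t_over_sqrt_n(self, rng):
        wide = pd.DataFrame({"a": rng.normal(0, 1, 30),
                             "b": rng.normal(0.5, 1, 30)})
        res = paired_t_bonferroni(wide)[0]
        assert res.d == pytest.approx(res.t / np.sqrt(30))
        assert res.df == 29

    def test_hand_computed_t(self):
        # diffs [1, 2, 3, 2]: mean 2, sd sqrt(2/3), t = 2 / (sd/2)
        wide = pd.DataFrame({"a": [2.0, 4.0, 6.0, 5.0],
                             "b": [1.0, 2.0, 3.0, 3.0]})
        res = paired_t_bonferroni(wide)[0]
        assert res.t == pytest.approx(4.898979485566356, abs=1e-12)

    def test_identical_columns(self):
        wide = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        res = paired_t_bonferroni(wide)[0]
        assert res.t == 0.0 and res.p_adj == 1.0

    def test_bonferroni_family_and_cap(self, rng):
        wide = pd.DataFrame(rng.normal(0, 1, (12, 3)), columns=list("abc"))
        results = paired_t_bonferroni(wide)
        assert len(results) == 3
        for r in results:
            assert r.p_adj == min(1.0, r.p * 3)
            assert r.p_adj >= r.p


class TestWelch:
    def test_hand_computed(self):
        res = welch_t([1.0, 2.0, 3.0], [2.0, 4.0, 9.0])
        assert res.t == pytest.approx(-1.3887301496588274, abs=1e-12)
        assert res.df == pytest.approx(2.3058823529411763, abs=1e-12)

    def test_equal_variance_limit_df(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(0.2, 1, 200)
        res = welch_t(a, b)
        assert res.df == pytest.approx(398, abs=5)

    def test_equal_means_zero_t(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert welch_t(x, x).t == 0.0

    def test_both_constant_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [1.0, 1.0])


class TestOnewayAnova:
    def test_constant_groups_zero_f(self):
        res = oneway_between_anova([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
        assert res["F"] == 0.0

    def test_two_groups_equals_squared_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.7, 1, 12)
        res = oneway_between_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res["F"] == pytest.approx(t.statistic ** 2, rel=1e-10)

    def test_hand_computed_three_groups(self):
        res = oneway_between_anova([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0],
                                    [6.0, 5.0, 7.0]])
        assert res["F"] == pytest.approx(13.0, abs=1e-12)
        assert res["partial_eta_sq"] == pytest.approx(0.8125, abs=1e-12)
        assert (res["df1"], res["df2"]) == (2, 6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_between_anova([[1.0, 2.0]])


@pytest.fixture(scope="module")
def cohort_frames():
    cfg = CohortConfig(n_participants=30, bad_fractions={}, seed=23)
    records = simulate_cohort(cfg)
    from genjust.cohort import participants_frame
    return trials_frame(records), participants_frame(records)


class TestRmAncova:
    def test_covariate_shift_invariance(self, cohort_frames):
        trials, participants = cohort_frames
        cov = participants.set_index("participant_id")["humanness"]
        res1 = rm_ancova(trials, cov)
        res2 = rm_ancova(trials, cov + 5.0)
        within = res1.index != "covariate"
        assert np.allclose(res1.loc[within, "F"], res2.loc[within, "F"],
                           atol=1e-10)

    def test_uninformative_covariate_close_to_anova(self, cohort_frames):
        trials, _ = cohort_frames
        rng = np.random.default_rng(99)
        ids = trials["participant_id"].unique()
        cov = pd.Series(rng.normal(0, 1, len(ids)), index=ids)
        plain = rm_anova(trials)
        adj = rm_ancova(trials, cov)
        for eff in plain.index:
            assert adj.loc[eff, "F"] == pytest.approx(plain.loc[eff, "F"],
                                                      rel=0.15)
        # and the error dfs lose exactly one participant worth of df
        assert np.all(adj.loc[plain.index, "df2_uncorrected"].to_numpy()
                      == plain["df2_uncorrected"].to_numpy()
                      - plain["df1_uncorrected"].to_numpy())

    def test_informative_covariate_absorbs_between_variance(self, cohort_frames):
        trials, _ = cohort_frames
        subj_mean = trials.groupby("participant_id")["rating"].mean()
        res = rm_ancova(trials, subj_mean)
        assert res.loc["covariate", "partial_eta_sq"] == pytest.approx(1.0)

    def test_constant_covariate_rejected(self, cohort_frames):
        trials, _ = cohort_frames
        ids = trials["participant_id"].unique()
        with pytest.raises(ValueError, match="constant"):
            rm_ancova(trials, pd.Series(1.0, index=ids))
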