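"""Statistics: t-tests, Holm, repeated-measures ANOVA with sphericity
correction, Dunnett and Tukey corrections, rating analyses, and type-I-error
calibration of the adjusted procedures."""

import numpy as np
import pandas as pd
import pytest

from facevalence import stats as st
from facevalence.synthetic import simulate_raters

POSITIONS = np.arange(-6, 7) * 0.5


class TestTTest:
    def test_all_at_chance_gives_t0_p1(self):
        r = st.ttest_vs_chance([0.5, 0.5, 0.5])
        assert r.statistic == 0.0 and r.p_raw == 1.0
        assert r.flag is not None

    def test_hand_computed_value(self):
        # mean 0.7, sd 0.1, n 3: t = 0.2 / (0.1/sqrt(3)) = 2 sqrt(3) = 3.464
        r = st.ttest_vs_chance([0.6, 0.7, 0.8])
        assert r.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert r.df == 2

    def test_two_sidedness(self):
        hi = st.ttest_vs_chance([0.6, 0.7, 0.8])
        lo = st.ttest_vs_chance([0.4, 0.3, 0.2])
        assert lo.statistic == pytest.approx(-hi.statistic)
        assert lo.p_raw == pytest.approx(hi.p_raw)

    def test_zero_variance_off_chance_flagged(self):
        r = st.ttest_vs_chance([0.8, 0.8])
        assert np.isinf(r.statistic) and r.flag is not None


class TestHolm:
    def test_single_p_unchanged(self):
        p_adj, rej = st.holm_bonferroni([0.03])
        assert p_adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_two_p_step_down_by_hand(self):
        # sorted (0.01, 0.04): adjusted = (2*0.01, max(0.02, 1*0.04)) = (0.02, 0.04)
        p_adj, rej = st.holm_bonferroni([0.01, 0.04])
        np.testing.assert_allclose(p_adj, [0.02, 0.04])
        assert rej.all()

    def test_adjusted_monotone_in_raw_rank(self, rng):
        p = rng.uniform(0, 1, 15)
        p_adj, _ = st.holm_bonferroni(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.holm_bonferroni([0.5, 1.2])


def _brute_force_rm_anova(X):
    """Sums-of-squares oracle computed with explicit loops."""
    n, k = X.shape
    grand = X.sum() / (n * k)
    ss_subj = sum(k * (X[i].mean() - grand) ** 2 for i in range(n))
    ss_eff = sum(n * (X[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((X[i, j] - grand) ** 2
                 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_subj - ss_eff
    return (ss_eff / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))


class TestRmAnova:
    def test_identical_columns_give_f0_p1(self, rng):
        col = rng.random(8)
        r = st.rm_anova_gg(np.tile(col[:, None], (1, 4)))
        assert r.F == 0.0 and r.p == 1.0

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            X = rng.normal(0.8, 0.1, (rng.integers(4, 10),
                                      rng.integers(2, 6)))
            r = st.rm_anova_gg(X)
            assert r.F == pytest.approx(_brute_force_rm_anova(X), rel=1e-8)

    def test_matches_pingouin(self, rng):
        import pingouin as pg
        X = rng.normal(0.8, 0.1, (12, 4))
        r = st.rm_anova_gg(X)
        long = pd.DataFrame({
            "y": X.ravel(),
            "subject": np.repeat(np.arange(12), 4),
            "model": np.tile(np.arange(4), 12)})
        aov = pg.rm_anova(data=long, dv="y", within="model",
                          subject="subject", correction=True, detailed=True)
        assert r.F == pytest.approx(float(aov.loc[0, "F"]), rel=1e-6)
        assert r.epsilon == pytest.approx(float(aov.loc[0, "eps"]), rel=1e-6)
        assert r.p == pytest.approx(float(aov.loc[0, "p_GG_corr"]), rel=1e-6)

    def test_epsilon_within_bounds_on_fuzz(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            k = int(rng.integers(2, 7))
            X = rng.normal(size=(int(rng.integers(3, 12)), k))
            r = st.rm_anova_gg(X)
            assert 1.0 / (k - 1) - 1e-9 <= r.epsilon <= 1.0 + 1e-9
            assert 0.0 <= r.eta_squared <= 1.0
            assert 0.0 <= r.generalized_eta_squared <= 1.0
            assert 0.0 <= r.p <= 1.0

    def test_missing_cells_rejected(self):
        X = np.ones((4, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            st.rm_anova_gg(X)


class TestDunnett:
    def test_single_comparison_close_to_paired_t(self, rng):
        X = rng.normal(0.8, 0.1, (12, 2))
        r = st.dunnett_contrasts(X, control=0, n_sim=200000, seed=1)[0]
        assert r.p_adj == pytest.approx(r.p_raw, abs=0.01)

    def test_adjusted_never_below_raw(self, rng):
        X = rng.normal(0.8, 0.1, (10, 4))
        for r in st.dunnett_contrasts(X, control=0, seed=2):
            assert r.p_adj >= r.p_raw - 1e-12

    def test_three_contrasts_for_four_models(self, rng):
        X = rng.normal(0.8, 0.1, (10, 4))
        assert len(st.dunnett_contrasts(X, control=0)) == 3


class TestTukey:
    def test_six_comparisons_for_four_models(self, rng):
        X = rng.normal(0.8, 0.1, (10, 4))
        assert len(st.tukey_pairwise(X)) == 6

    def test_symmetric_under_column_permutation(self, rng):
        X = rng.normal(0.8, 0.1, (10, 3))
        base = {r.label: r.p_adj for r in st.tukey_pairwise(X)}
        perm = st.tukey_pairwise(X[:, [2, 0, 1]],
                                 labels=["m2", "m0", "m1"])
        for r in perm:
            a, _, b = r.label.partition(" vs ")
            key = f"{a} vs {b}" if f"{a} vs {b}" in base else f"{b} vs {a}"
            assert r.p_adj == pytest.approx(base[key], rel=1e-9)

    def test_adjusted_never_below_raw(self, rng):
        X = rng.normal(0.8, 0.1, (10, 4))
        for r in st.tukey_pairwise(X):
            assert r.p_adj >= r.p_raw - 1e-12


class TestFamilywiseCalibration:
    """Null simulations (reduced replicate counts; the acceptance suite runs
    the full calibration) checking the FWER of each adjusted procedure."""

    N_REPS = 300

    def _fwer(self, procedure):
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(self.N_REPS):
            X = rng.normal(0.8, 0.05, (10, 4))
            hits += procedure(X)
        return hits / self.N_REPS

    def test_holm_fwer_near_alpha(self):
        def proc(X):
            ps = [st.ttest_vs_chance(X[:, j] - X[:, 0] + 0.5).p_raw
                  for j in range(1, 4)]
            _, rej = st.holm_bonferroni(ps)
            return rej.any()
        assert 0.02 <= self._fwer(proc) <= 0.08

    def test_dunnett_fwer_near_alpha(self):
        def proc(X):
            res = st.dunnett_contrasts(X, control=0, n_sim=2000, seed=7)
            return any(r.p_adj < 0.05 for r in res)
        assert 0.02 <= self._fwer(proc) <= 0.08

    def test_tukey_fwer_near_alpha(self):
        def proc(X):
            return any(r.p_adj < 0.05 for r in st.tukey_pairwise(X))
        assert 0.02 <= self._fwer(proc) <= 0.08


class TestRatings:
    def test_noiseless_raters_correlate_perfectly(self):
        rec = simulate_raters(POSITIONS, n_raters=3, n_blocks=4,
                              response_noise=0.0)
        out = st.rating_analysis(rec)
        assert np.allclose(out["r"], 1.0)
        assert (out["p_adj"] < 0.001).all()

    def test_negative_gain_gives_r_minus_one(self):
        rec = simulate_raters(POSITIONS, 2, 4, response_noise=0.0, gain=-1.0)
        out = st.rating_analysis(rec)
        assert np.allclose(out["r"], -1.0)

    def test_moderate_noise_r_within_precomputed_band(self):
        # Monte-Carlo oracle (10,000 reps, run separately with the closed
        # formula below) for sigma = 0.25, 4 blocks, 13 positions:
        # responses average to position/3 + noise/sqrt(4); expected r =
        # 1/sqrt(1 + var_noise_eff/var_signal), var_signal = var(s/3) =
        # 0.3403, var_noise_eff = 0.25^2/4 = 0.015625 -> r ~ 0.978 +- 0.02
        rec = simulate_raters(POSITIONS, 10, 4, response_noise=0.25, seed=5)
        out = st.rating_analysis(rec)
        assert 0.95 < out["r"].mean() < 0.995

    def test_constant_responses_flagged_undefined(self):
        rec = simulate_raters(POSITIONS, 1, 2, response_noise=0.0, gain=0.0)
        out = st.rating_analysis(rec)
        assert out.loc[0, "flag"] == "undefined"
        assert np.isnan(out.loc[0, "r"])


class TestInterRater:
    def test_duplicated_rater_correlates_perfectly(self):
        rec = simulate_raters(POSITIONS, 1, 2, response_noise=0.1, seed=1)
        dup = rec.assign(rater="r2")
        out = st.inter_rater_reliability(pd.concat([rec, dup]))
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_pure_noise_raters_average_near_zero(self):
        rec = simulate_raters(np.linspace(-3, 3, 40), 6, 2,
                              response_noise=0.3, gain=0.0, seed=8)
        out = st.inter_rater_reliability(rec)
        assert abs(out["r"].mean()) < 0.15

    def test_five_raters_give_ten_pairs(self):
        rec = simulate_raters(POSITIONS, 5, 2, response_noise=0.1, seed=2)
        assert len(st.inter_rater_reliability(rec)) == 10

    def test_mismatched_image_sets_rejected(self):
        a = simulate_raters(POSITIONS, 1, 1, seed=1)
        b = simulate_raters(POSITIONS[:5], 1, 1, seed=2).assign(rater="r9")
        with pytest.raises(ValueError, match="matching"):
            st.inter_rater_reliability(pd.concat([a, b]))
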