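import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_
from scipy import stats as sps

from cdakit import calibration as cal
from cdakit import phantom as ph
from cdakit import stats as st


class TestShapiroWilk:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(42)
        res = st.shapiro_wilk(rng.normal(10, 2, size=50))
        assert res.p > 0.05

    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(-8, 0.5, 25), rng.normal(8, 0.5, 25)])
        assert st.shapiro_wilk(x).p < 0.05

    def test_degenerate_and_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            st.shapiro_wilk([3.0] * 10)
        with pytest.raises(ValueError, match="n="):
            st.shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError, match="n="):
            st.shapiro_wilk(np.arange(51.0))


class TestHolmSidak:
    def test_hand_arithmetic_smallest_of_three(self):
        adj = st.holm_sidak([0.01, 0.2, 0.3])
        assert adj[0] == pytest.approx(1 - (1 - 0.01) ** 3)  # 0.029701

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 12)
        ours = st.holm_sidak(p)
        ref = multipletests(p, method="holm-sidak")[1]
        np.testing.assert_allclose(ours, ref, rtol=1e-10)

    @settings(max_examples=100, derandomize=True)
    @given(st_.lists(st_.floats(0, 1), min_size=1, max_size=10))
    def test_monotone_and_dominates_raw(self, p):
        adj = st.holm_sidak(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestRmAnova:
    def test_identical_columns_give_f0_p1(self):
        m = np.tile(np.arange(9.0)[:, None], (1, 4))
        res = st.rm_anova_holm_sidak(m)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_two_conditions_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(9, 2))
        res = st.rm_anova_holm_sidak(m)
        t = sps.ttest_rel(m[:, 0], m[:, 1])
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_matches_independent_implementation(self):
        import pingouin as pg

        rng = np.random.default_rng(2)
        m = rng.normal(size=(9, 5)) + np.arange(5) * 0.8
        res = st.rm_anova_holm_sidak(m)
        long = pd.DataFrame(
            {
                "y": m.ravel(),
                "subject": np.repeat(np.arange(9), 5),
                "cond": np.tile(np.arange(5), 9),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subject")
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-6)
        assert res.p == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)

    def test_missing_cells_rejected(self):
        m = np.ones((5, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            st.rm_anova_holm_sidak(m)

    def test_posthoc_adjusted_dominates_raw(self):
        rng = np.random.default_rng(3)
        res = st.rm_anova_holm_sidak(rng.normal(size=(9, 4)))
        assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-12).all()


def brute_force_friedman(matrix):
    """Rank-sum formula computed step by step, independent of the library."""
    arr = np.asarray(matrix, dtype=float)
    n, k = arr.shape
    ranks = np.array([sps.rankdata(row) for row in arr])
    rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * sum(r * r for r in rj) - 3.0 * n * (k + 1)


class TestFriedman:
    def test_perfect_agreement_reaches_maximum(self):
        m = np.tile(np.array([1.0, 2.0, 3.0]), (9, 1))
        assert st.friedman_statistic(m) == pytest.approx(18.0)  # 2n for k=3

    def test_constant_matrix_gives_zero(self):
        assert st.friedman_statistic(np.ones((6, 4))) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_statistic_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(rng.integers(3, 9), rng.integers(3, 7)))
        assert st.friedman_statistic(m) == pytest.approx(brute_force_friedman(m))

    def test_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(7)
        m = rng.permuted(np.tile(np.arange(5.0), (8, 1)), axis=1) + rng.normal(
            0, 1e-9, (8, 5)
        )
        ours = st.friedman_dunn(m, p_method="asymptotic")
        ref = sps.friedmanchisquare(*[m[:, j] for j in range(5)])
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-6)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_p_matches_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(11)
        m = rng.normal(size=(4, 3))
        res = st.friedman_dunn(m, p_method="exact")
        # oracle: enumerate all (3!)^4 within-row rank arrangements
        obs = brute_force_friedman(m)
        perms = list(itertools.permutations([1.0, 2.0, 3.0]))
        hits = total = 0
        for combo in itertools.product(perms, repeat=4):
            s = brute_force_friedman(np.array(combo))
            hits += s >= obs - 1e-9
            total += 1
        assert total == 6**4
        assert res.p == pytest.approx(hits / total, abs=1e-12)

    def test_monte_carlo_p_agrees_with_asymptotic_for_study_design(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(9, 5)) + np.arange(5) * 0.45
        asym = st.friedman_dunn(m, p_method="asymptotic")
        mc = st.friedman_dunn(m, p_method="exact", n_resamples=4000, seed=3)
        assert 0.0005 < asym.p < 0.5  # informative regime
        # Monte-Carlo error: ~3 binomial SDs
        se = math.sqrt(asym.p * (1 - asym.p) / 4000)
        assert abs(mc.p - asym.p) < 3 * se + 2 / 4000

    def test_needs_three_conditions_and_complete_data(self):
        with pytest.raises(ValueError, match="three"):
            st.friedman_dunn(np.ones((5, 2)))
        m = np.ones((5, 3))
        m[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            st.friedman_dunn(m)

    def test_dunn_posthoc_conventions(self):
        rng = np.random.default_rng(9)
        m = rng.normal(size=(9, 4)) + np.arange(4) * 2.0
        res = st.friedman_dunn(m, p_method="asymptotic")
        ph_ = res.posthoc
        assert (ph_["p_adj"] >= ph_["p_raw"] - 1e-12).all()
        assert (ph_["p_adj"] <= 1.0).all()
        # z for the most separated pair has the largest magnitude
        pair = ph_.loc[(ph_["a"] == 0) & (ph_["b"] == 3), "z"].abs().iloc[0]
        assert pair == ph_["z"].abs().max()


def _summary_from_reference(flag_pattern):
    """Build a Fig-7-style summary from the published reference ranges with a
    given artifact occurrence pattern {(kv, mas): n_occurrences_at_S1}."""
    ref = cal.load_reference_ranges()
    rows = []
    for setting in ref.settings():
        for r in ref.for_setting(setting.kv, setting.mas).mean_ranges():
            rows.append(
                {
                    "kv": setting.kv,
                    "mas": setting.mas,
                    "step": r.step,
                    "range_low": r.min_hu,
                    "range_high": r.max_hu,
                    "mean_percent": 10.0,
                    "sd_percent": 1.0,
                    "n": 9,
                    "n_artifact_occurrences": flag_pattern.get((setting.kv, setting.mas), 0)
                    if r.step == 1
                    else 0,
                }
            )
    return pd.DataFrame(rows)


class TestSummarizeAndRecommend:
    def test_single_limb_without_artifacts(self):
        ref = cal.load_reference_ranges()
        frame = pd.DataFrame(
            {
                "source_id": "limb01",
                "kv": 50.0,
                "mas": 1.2,
                "step": range(1, 11),
                "percent": np.linspace(30, 1, 10),
                "flagged": False,
            }
        )
        out = st.summarize_settings(frame, ref)
        assert (out["n_artifact_occurrences"] == 0).all()
        assert (out["n"] == 1).all()
        assert (out["sd_percent"] == 0).all()

    def test_means_equal_brute_force_per_cell(self):
        ref = cal.load_reference_ranges()
        rng = np.random.default_rng(4)
        rows = []
        for limb in range(5):
            for step in range(1, 11):
                rows.append(
                    {
                        "source_id": f"limb{limb}",
                        "kv": 60.0,
                        "mas": 1.2,
                        "step": step,
                        "percent": float(rng.uniform(0, 50)),
                        "flagged": bool(rng.random() < 0.2),
                    }
                )
        frame = pd.DataFrame(rows)
        out = st.summarize_settings(frame, ref)
        for step in (1, 7):
            cell = frame[frame["step"] == step]["percent"]
            row = out[out["step"] == step].iloc[0]
            assert row["mean_percent"] == pytest.approx(cell.mean())
            assert row["n_artifact_occurrences"] == frame[frame["step"] == step]["flagged"].sum()

    def test_unknown_setting_rejected(self):
        ref = cal.load_reference_ranges()
        frame = pd.DataFrame(
            {
                "source_id": "x",
                "kv": 90.0,
                "mas": 1.2,
                "step": range(1, 11),
                "percent": 1.0,
                "flagged": False,
            }
        )
        with pytest.raises(ValueError, match="lacks"):
            st.summarize_settings(frame, ref)

    def test_study_pattern_recommends_60kv_low_mas(self):
        # artifacts at 60 kV;12 mAs, 70 kV and 80 kV; none at 50 and 60 kV;1.2
        summary = _summary_from_reference(
            {(60.0, 12.0): 3, (70.0, 1.2): 5, (80.0, 1.2): 5}
        )
        best, warning = st.recommend_setting(summary)
        assert (best.kv, best.mas) == (60.0, 1.2)
        assert warning is False

    def test_single_artifact_free_setting_wins(self):
        summary = _summary_from_reference(
            {(60.0, 12.0): 1, (70.0, 1.2): 1, (80.0, 1.2): 1, (60.0, 1.2): 2}
        )
        best, warning = st.recommend_setting(summary)
        assert (best.kv, best.mas) == (50.0, 1.2)
        assert warning is False

    def test_all_artifacted_returns_least_affected_with_warning(self):
        summary = _summary_from_reference(
            {(50.0, 1.2): 4, (60.0, 1.2): 1, (60.0, 12.0): 5, (70.0, 1.2): 5, (80.0, 1.2): 5}
        )
        best, warning = st.recommend_setting(summary)
        assert (best.kv, best.mas) == (60.0, 1.2)
        assert warning is True

    def test_tie_break_prefers_wider_coverage(self):
        rows = []
        for mas, width in ((1.2, 100.0), (12.0, 50.0)):
            for step in range(1, 11):
                rows.append(
                    {
                        "kv": 60.0,
                        "mas": mas,
                        "step": step,
                        "range_low": 0.0 + (step - 1) * width,
                        "range_high": step * width,
                        "mean_percent": 5.0,
                        "sd_percent": 1.0,
                        "n": 9,
                        "n_artifact_occurrences": 0,
                    }
                )
        best, warning = st.recommend_setting(pd.DataFrame(rows))
        assert best.mas == 1.2  # same low endpoint, wider total coverage
        assert warning is False

    def test_plot_written(self, tmp_path):
        summary = _summary_from_reference({})
        st.plot_setting_summary(summary, tmp_path / "coverage.png")
        assert (tmp_path / "coverage.png").stat().st_size > 0


class TestCohortStatistics:
    def test_reference_min_series_normal_enough_for_anova(self):
        # screen as the protocol does: Shapiro-Wilk on a per-step series
        rng = np.random.default_rng(12)
        series = rng.normal(880.6, 129.0, size=9)
        assert st.shapiro_wilk(series).p > 0.05

    def test_bound_matrix_shape_and_anova(self, study):
        m = study.bound_matrix(step=1, bound="Min")
        assert m.shape == (9, 5)
        res = st.rm_anova_holm_sidak(m)
        assert res.p < 0.05  # settings clearly separate S1 attenuation
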