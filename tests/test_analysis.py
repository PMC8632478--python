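"""Block summaries, AUC, PTA, group curves, contrasts and correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from speech_coged import analysis, design_engine as de
from speech_coged.simulator import AgentParams, simulate_choice

H, E = de.HARDER, de.EASIER


def block_amounts(choices):
    state = de.init_titration()
    amounts = []
    for c in choices:
        amounts.append(state.easy_offer if c == E else state.hard_offer)
        if state.trial_index < 6:
            state = de.next_offer(state, c)
    return amounts


class TestLowestSelection:
    def test_all_harder_block(self):
        assert analysis.lowest_selection(block_amounts([H] * 6)) == 2.0

    def test_all_easier_block_ends_at_terminal_offer(self):
        assert analysis.lowest_selection(block_amounts([E] * 6)) == 0.03125

    def test_mixed_block_from_offer_path(self):
        # offers: 1.00 E, 0.50 E, 0.25 H, 0.375 H, 0.4375 H, 0.46875 E
        assert analysis.lowest_selection(block_amounts([E, E, H, H, H, E])) == 0.46875

    def test_invariant_to_trial_order(self):
        amounts = block_amounts([E, H, E, H, E, H])
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = list(rng.permutation(amounts))
            assert analysis.lowest_selection(shuffled) == analysis.lowest_selection(amounts)

    def test_wrong_trial_count_rejected(self):
        with pytest.raises(ValueError, match="6 trials"):
            analysis.lowest_selection([2.0] * 5)


class TestAUC:
    def test_extremes_and_arithmetic(self):
        assert analysis.compute_auc([2.0] * 5) == 1.0
        assert analysis.compute_auc([0.0] * 5) == 0.0
        assert analysis.compute_auc([2.0, 2.0, 1.5, 1.0, 0.5]) == pytest.approx(0.70)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="condition means"):
            analysis.compute_auc([2.0] * 4)

    def test_equals_half_of_mean_of_means(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            means = rng.uniform(0, 2, 5)
            assert analysis.compute_auc(means) == pytest.approx(np.mean(means) / 2, abs=1e-12)


class TestPTA:
    def test_per_ear_average_and_better_ear(self):
        thresholds = {
            "left": {500: 10.0, 1000: 15.0, 2000: 20.0},
            "right": {500: 30.0, 1000: 30.0, 2000: 30.0},
        }
        res = analysis.compute_pta(thresholds)
        assert res.left_pta == 15.0
        assert res.right_pta == 30.0
        assert res.better_ear_pta == 15.0

    def test_symmetric_ears(self):
        thresholds = {e: {500: 5.0, 1000: 5.0, 2000: 5.0} for e in ("left", "right")}
        assert analysis.compute_pta(thresholds).better_ear_pta == 5.0

    def test_missing_frequency_rejected(self):
        with pytest.raises(ValueError, match="missing frequencies"):
            analysis.compute_pta({"left": {500: 5.0, 1000: 5.0}, "right": {500: 5.0, 1000: 5.0, 2000: 5.0}})


class TestGroupCurves:
    @staticmethod
    def frame(values_by_subject):
        rows = [
            (sid, snr, v)
            for sid, vals in values_by_subject.items()
            for snr, v in vals.items()
        ]
        return pd.DataFrame(rows, columns=["subject_id", "snr_db", "mean_lowest"])

    def test_identical_subjects_have_zero_width_ci(self):
        cm = self.frame({"a": {-8.0: 1.0}, "b": {-8.0: 1.0}, "c": {-8.0: 1.0}})
        groups = pd.DataFrame({"subject_id": ["a", "b", "c"], "age_group": ["young"] * 3})
        out = analysis.group_curves(cm, groups)
        assert out.loc[0, "mean"] == 1.0
        assert out.loc[0, "ci_low"] == out.loc[0, "ci_high"] == 1.0

    def test_two_subject_mean(self):
        cm = self.frame({"a": {-8.0: 1.0}, "b": {-8.0: 2.0}})
        groups = pd.DataFrame({"subject_id": ["a", "b"], "age_group": ["young"] * 2})
        out = analysis.group_curves(cm, groups)
        assert out.loc[0, "mean"] == 1.5

    def test_single_subject_group_is_flagged(self):
        cm = self.frame({"a": {-8.0: 1.0}})
        groups = pd.DataFrame({"subject_id": ["a"], "age_group": ["older"]})
        with pytest.warns(UserWarning, match="single subject"):
            out = analysis.group_curves(cm, groups)
        assert not out.loc[0, "ci_defined"]
        assert np.isnan(out.loc[0, "ci_low"])

    def test_simulated_cohort_shows_age_ordering(self, block_frame, profile_frame):
        cm = analysis.condition_means(block_frame)
        curves = analysis.group_curves(cm, profile_frame)
        wide = curves.pivot(index="snr_db", columns="age_group", values="mean")
        for snr in (-8.0, -12.0):
            assert wide.loc[snr, "older"] < wide.loc[snr, "young"]


def permutation_oracle(x, y):
    """Exhaustive rank-sum null: tail probabilities of W = rank sum of x."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[: len(x)].sum()
    sums = [
        sum(ranks[i] for i in idx)
        for idx in itertools.combinations(range(len(pooled)), len(x))
    ]
    sums = np.asarray(sums)
    p_greater = np.mean(sums >= w_obs - 1e-9)
    p_less = np.mean(sums <= w_obs + 1e-9)
    return p_less, p_greater, min(1.0, 2 * min(p_less, p_greater))


class TestGroupContrast:
    def test_extreme_separation_one_sided(self):
        res = analysis.group_contrast([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.method == "exact permutation"
        assert res.pvalue == pytest.approx(0.05)

    def test_identical_groups_central(self):
        res = analysis.group_contrast([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.pvalue == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_permutation_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 7, size=2)
        # discrete values force ties in some draws
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        p_less, p_greater, p_two = permutation_oracle(x, y)
        assert analysis.group_contrast(x, y, "less").pvalue == pytest.approx(p_less)
        assert analysis.group_contrast(x, y, "greater").pvalue == pytest.approx(p_greater)
        assert analysis.group_contrast(x, y).pvalue == pytest.approx(p_two)

    def test_large_shift_has_high_power(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0.8, 0.25, 50)
        y = rng.normal(1.5, 0.25, 50)
        res = analysis.group_contrast(x, y)
        assert res.method == "normal approximation"
        assert res.pvalue < 1e-3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            analysis.group_contrast([], [1.0])


class TestCorrelations:
    def test_pearson_agrees_with_covariance_ratio(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=20)
            y = 0.3 * x + rng.normal(size=20)
            r_lib = analysis.pearsonr(x, y)[0]
            r_def = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
            assert r_lib == pytest.approx(r_def, abs=1e-12)

    def test_bonferroni_threshold(self):
        assert analysis.bonferroni_threshold() == pytest.approx(0.01)

    @staticmethod
    def make_inputs(auc, profiles):
        return pd.DataFrame(auc), pd.DataFrame(profiles)

    def test_perfect_linear_relationship(self):
        n = 10
        wm = np.linspace(0.2, 0.8, n)
        summary = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)], "auc": wm})
        profiles = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "age_group": ["young"] * n,
                "wm_score": wm,
                "better_ear_pta": np.full(n, 10.0),
                "hhie_score": [np.nan] * n,
            }
        )
        with pytest.warns(UserWarning):
            out = analysis.correlation_battery(summary, profiles)
        row = out[(out.age_group == "young") & (out.covariate == "wm_score")].iloc[0]
        assert row.r == pytest.approx(1.0)
        # flat PTA: correlation undefined and flagged
        pta = out[(out.age_group == "young") & (out.covariate == "better_ear_pta")].iloc[0]
        assert np.isnan(pta.r) and not pta.significant

    def test_battery_on_simulated_cohort(self, block_frame, profile_frame):
        summary = analysis.discounting_summary(block_frame)
        out = analysis.correlation_battery(summary, profile_frame)
        assert len(out) == 5
        assert out.attrs["threshold"] == pytest.approx(0.01)
        older = out[out.age_group == "older"].set_index("covariate")
        assert older.loc["better_ear_pta", "r"] < 0
        assert older.loc["wm_score", "r"] > 0
        assert older.loc["hhie_score", "r"] < 0


class TestIntelligibility:
    def test_fillers_excluded_from_intelligibility(self):
        fam = pd.DataFrame(
            {
                "subject_id": ["a"] * 4,
                "snr_db": [-8.0] * 4,
                "is_filler": [False, False, True, True],
                "keywords_correct": [4, 2, 0, 0],
            }
        )
        out = analysis.intelligibility_by_condition(fam)
        assert out.loc[0, "intelligibility"] == pytest.approx(0.75)

    def test_block_summary_and_wide_summary(self, choice_log):
        blocks = analysis.block_summary(choice_log)
        assert (blocks.groupby("subject_id").size() == 20).all()
        wide = analysis.discounting_summary(blocks)
        assert set(wide.columns) == {"subject_id", 4.0, 0.0, -4.0, -8.0, -12.0, "auc"}
        assert wide["auc"].between(0, 1).all()
        # AUC identity with the long condition means
        cm = analysis.condition_means(blocks)
        for sid, g in cm.groupby("subject_id"):
            expect = analysis.compute_auc(g["mean_lowest"].tolist())
            got = float(wide.loc[wide.subject_id == sid, "auc"].iloc[0])
            assert got == pytest.approx(expect, abs=1e-12)
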