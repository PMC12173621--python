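"""Instrument scoring, Likert summaries, ANOVA, and Spearman correlation
with its exact permutation null."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from delimech.sensory_stats import (
    FEATURES,
    MEAT_ATTACHMENT,
    NEOPHOBIA,
    Instrument,
    LikertTable,
    feature_anova,
    score_instrument,
    spearman,
    stiffness_texture_correlations,
    summarize_features,
)


def responses_frame(instrument, fill):
    """All participants answer every item with `fill(participant, item)`."""
    rows = [
        (p, i, fill(p, i))
        for p in (1, 2)
        for i in range(1, instrument.n_items + 1)
    ]
    return pd.DataFrame(rows, columns=["participant", "item", "response"])


def likert_from_matrix(scores_by_product):
    rows = [
        (part + 1, product, "brittle", int(s))
        for product, scores in scores_by_product.items()
        for part, s in enumerate(scores)
    ]
    return LikertTable(pd.DataFrame(rows, columns=["participant", "product", "feature", "score"]))


class TestInstruments:
    def test_floor_without_reverse_items(self):
        inst = Instrument("plain", 10, 7)
        totals = score_instrument(responses_frame(inst, lambda p, i: 1), inst)
        assert (totals == 10).all()

    def test_neophobia_maximum_is_70(self):
        # scored maximum: raw 7 on straight items, raw 1 on reverse-keyed ones
        fill = lambda p, i: 1 if i in NEOPHOBIA.reverse_items else 7
        totals = score_instrument(responses_frame(NEOPHOBIA, fill), NEOPHOBIA)
        assert (totals == 70).all()
        assert NEOPHOBIA.score_range == (10, 70)
        assert MEAT_ATTACHMENT.score_range == (16, 80)

    def test_reverse_coding_reflection(self):
        inst = Instrument("one", 1, 7, frozenset({1}))
        df = pd.DataFrame({"participant": [1], "item": [1], "response": [2]})
        assert score_instrument(df, inst).iloc[0] == 6

    def test_out_of_scale_rejected(self):
        df = responses_frame(NEOPHOBIA, lambda p, i: 8)
        with pytest.raises(ValueError, match="outside"):
            score_instrument(df, NEOPHOBIA)

    def test_incomplete_participant_rejected(self):
        df = responses_frame(NEOPHOBIA, lambda p, i: 3).iloc[:-1]
        with pytest.raises(ValueError, match="answered"):
            score_instrument(df, NEOPHOBIA)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_totals_always_inside_score_range(self, seed):
        rng = np.random.default_rng(seed)
        for inst in (NEOPHOBIA, MEAT_ATTACHMENT):
            fill = lambda p, i: int(rng.integers(1, inst.scale_points + 1))
            totals = score_instrument(responses_frame(inst, fill), inst)
            lo, hi = inst.score_range
            assert totals.between(lo, hi).all()


class TestSummaries:
    def test_constant_scores(self):
        t = likert_from_matrix({"A": [3, 3], "B": [3, 3]})
        s = summarize_features(t)
        assert s.loc["A", ("brittle", "mean")] == 3.0
        assert s.loc["A", ("brittle", "std")] == 0.0

    def test_two_point_sample_std(self):
        t = likert_from_matrix({"A": [1, 5]})
        s = summarize_features(t)
        assert s.loc["A", ("brittle", "mean")] == 3.0
        assert s.loc["A", ("brittle", "std")] == pytest.approx(2.8284271, abs=1e-6)

    def test_planted_ordering_recovered(self):
        t = likert_from_matrix({"A": [1, 1, 2], "B": [3, 3, 3], "C": [5, 4, 5]})
        s = summarize_features(t)
        means = s[("brittle", "mean")]
        assert list(means.sort_values().index) == ["A", "B", "C"]


class TestAnova:
    def test_hand_computed_three_groups(self):
        # brute-force sums-of-squares oracle on a small worked example
        groups = {"A": [1, 2, 2], "B": [3, 3, 4], "C": [5, 5, 4]}
        t = likert_from_matrix(groups)
        res = feature_anova(t, "brittle")
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups.values())
        ss_within = sum(np.sum((np.array(g) - np.mean(g)) ** 2) for g in groups.values())
        F = (ss_between / 2) / (ss_within / 6)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.significant

    def test_separated_groups_tiny_p(self):
        t = likert_from_matrix(
            {"A": [1, 1, 1, 1, 1, 2], "B": [5, 5, 5, 5, 5, 4], "C": [3, 3, 3, 3, 3, 2]}
        )
        res = feature_anova(t, "brittle")
        assert res.p_value < 1e-6

    def test_zero_variance_degenerate(self):
        t = likert_from_matrix({"A": [2, 2], "B": [2, 2]})
        res = feature_anova(t, "brittle")
        assert res.degenerate and not res.significant

    def test_shift_invariance(self):
        base = {"A": [1, 2, 3], "B": [2, 3, 3], "C": [1, 1, 2]}
        shifted = {k: [v + 2 for v in g] for k, g in base.items()}
        F0 = feature_anova(likert_from_matrix(base), "brittle").F
        F1 = feature_anova(likert_from_matrix(shifted), "brittle").F
        assert F0 == pytest.approx(F1, rel=1e-12)

    def test_type_one_error_rate(self):
        # 500 null panels: identical population means, iid discrete scores
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            groups = [rng.integers(1, 6, 18) for _ in range(8)]
            _, p = stats.f_oneway(*groups)
            rejections += p < 0.05
        rate = rejections / n_sim
        assert 0.03 <= rate <= 0.07


class TestSpearman:
    def test_perfect_concordance(self):
        res = spearman(np.arange(8), np.arange(8) * 3.0)
        assert res.rho == pytest.approx(1.0)

    def test_published_coefficients_at_n8(self):
        # sum d^2 = 12 -> rho = 1 - 72/504 = 6/7; sum d^2 = 6 -> 0.92857
        x = np.arange(1, 9)
        y12 = next(
            p for p in permutations(x) if np.sum((x - np.array(p)) ** 2) == 12
        )
        res = spearman(x, np.array(y12, dtype=float))
        assert res.rho == pytest.approx(6 / 7)
        assert res.rho == pytest.approx(0.857142857)
        y6 = next(p for p in permutations(x) if np.sum((x - np.array(p)) ** 2) == 6)
        res6 = spearman(x, np.array(y6, dtype=float))
        assert res6.rho == pytest.approx(1 - 36 / 504)
        assert res6.method == "exact_permutation"
        assert res6.p_value < 0.05

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_brute_force_enumeration(self, n, rng):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = spearman(x, y, method="exact_permutation")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        hits = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            hits += abs(r) >= abs(res.rho) - 1e-12
        assert res.p_value == pytest.approx(hits / math.factorial(n))

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        base = spearman(x, y)
        warped = spearman(np.exp(x), y**3)
        assert warped.rho == pytest.approx(base.rho)
        assert warped.p_value == pytest.approx(base.p_value)

    def test_t_approximation_for_large_n(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = spearman(x, y)
        assert res.method == "t_approximation"
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref_rho)
        assert res.p_value == pytest.approx(ref_p, rel=1e-6)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(5), np.arange(5))


class TestCorrelationMatrix:
    @staticmethod
    def summaries_from_means(means_by_feature, products):
        cols = {}
        for f, means in means_by_feature.items():
            cols[(f, "mean")] = means
            cols[(f, "std")] = np.zeros(len(products))
        return pd.DataFrame(cols, index=products)

    def test_identical_ranking_flagged(self):
        products = list("ABCDEFGH")
        stiffness = {p: float(i + 1) for i, p in enumerate(products)}
        summaries = self.summaries_from_means(
            {"brittle": np.arange(8, dtype=float)}, products
        )
        out = stiffness_texture_correlations(stiffness, summaries, ["brittle"])
        pairs = {tuple(p["pair"]): p for p in out["significant_pairs"]}
        assert ("stiffness", "brittle") in pairs
        assert pairs[("stiffness", "brittle")]["rho"] == pytest.approx(1.0)

    def test_null_feature_rarely_flagged(self, rng):
        products = list("ABCDEFGH")
        stiffness = {p: float(i + 1) for i, p in enumerate(products)}
        flags = 0
        n_sim = 200
        for _ in range(n_sim):
            summaries = self.summaries_from_means(
                {"gummy": rng.normal(size=8)}, products
            )
            out = stiffness_texture_correlations(stiffness, summaries, ["gummy"])
            flags += len(out["significant_pairs"]) > 0
        assert 0.01 <= flags / n_sim <= 0.10

    def test_missing_product_errors(self):
        summaries = self.summaries_from_means({"brittle": np.arange(3.0)}, ["A", "B", "C"])
        with pytest.raises(ValueError, match="missing"):
            stiffness_texture_correlations(
                {"A": 1.0, "B": 2.0, "D": 3.0}, summaries, ["brittle"]
            )
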