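from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hashchat as hc
from hashchat.content_coding import SUBTHEMES, THEMES

from conftest import ct


def oracle_agreement_stats(a, b):
    """Independent contingency-table oracle for kappa and pi (pure dict
    arithmetic, exact fractions, no shared code with the implementation)."""
    n = len(a)
    table = Counter(zip(a, b))
    p_o = Fraction(sum(c for (x, y), c in table.items() if x == y), n)
    row = Counter(a)
    col = Counter(b)
    labels = set(row) | set(col)
    pe_kappa = sum(
        Fraction(row.get(l, 0), n) * Fraction(col.get(l, 0), n) for l in labels
    )
    pe_pi = sum(
        (Fraction(row.get(l, 0) + col.get(l, 0), 2 * n)) ** 2 for l in labels
    )
    kappa = None if pe_kappa == 1 else float((p_o - pe_kappa) / (1 - pe_kappa))
    pi = None if pe_pi == 1 else float((p_o - pe_pi) / (1 - pe_pi))
    return kappa, pi


labels2 = st.lists(st.sampled_from("AB"), min_size=1, max_size=12)


class TestPercentAgreement:
    def test_identical(self):
        assert hc.percent_agreement(list("ABAB"), list("ABAB")) == 100.0

    def test_three_of_four(self):
        assert hc.percent_agreement(list("AABB"), list("ABBB")) == 75.0

    def test_disjoint(self):
        assert hc.percent_agreement(list("AAA"), list("BBB")) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hc.percent_agreement(["A"], ["A", "B"])


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert hc.cohen_kappa(list("AABB"), list("AABB")) == 1.0

    def test_hand_worked_two_by_two(self):
        # p_o = 3/4; marginals a=(2,2)/4, b=(1,3)/4; p_e = 1/2; kappa = 1/2
        assert hc.cohen_kappa(list("AABB"), list("ABBB")) == pytest.approx(0.5)

    def test_single_label_both_coders(self):
        # p_e == 1 with perfect observed agreement is defined as 1
        assert hc.cohen_kappa(["A", "A"], ["A", "A"]) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hc.cohen_kappa([], [])

    def test_against_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(2, 40))
            a = list(rng.choice(list("ABC"), n))
            b = list(rng.choice(list("ABC"), n))
            try:
                ours = hc.cohen_kappa(a, b)
            except ZeroDivisionError:
                continue
            assert ours == pytest.approx(sklearn_metrics.cohen_kappa_score(a, b))

    def test_null_distribution_centered_at_zero(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, size=10_000)
        b = rng.integers(0, 2, size=10_000)
        assert abs(hc.cohen_kappa(list(a), list(b))) < 0.05


class TestScottPi:
    def test_perfect_agreement(self):
        assert hc.scott_pi(list("AABB"), list("AABB")) == 1.0

    def test_hand_worked_pooled_marginal(self):
        # pooled A:3 B:5 of 8 -> p_e = 9/64 + 25/64 = 0.53125
        assert hc.scott_pi(list("AABB"), list("ABBB")) == pytest.approx(
            (0.75 - 0.53125) / 0.46875
        )

    @given(labels2, labels2)
    def test_kappa_dominates_pi(self, a, b):
        if len(a) != len(b):
            return
        try:
            kappa = hc.cohen_kappa(a, b)
            pi = hc.scott_pi(a, b)
        except ZeroDivisionError:
            return
        assert kappa >= pi - 1e-12
        if Counter(a) == Counter(b):
            assert kappa == pytest.approx(pi)

    @given(labels2)
    def test_label_renaming_invariance(self, a):
        b = a[::-1]
        rename = {"A": "info", "B": "affect"}
        try:
            k1, p1 = hc.cohen_kappa(a, b), hc.scott_pi(a, b)
        except ZeroDivisionError:
            return
        k2 = hc.cohen_kappa([rename[x] for x in a], [rename[x] for x in b])
        p2 = hc.scott_pi([rename[x] for x in a], [rename[x] for x in b])
        assert k1 == pytest.approx(k2) and p1 == pytest.approx(p2)


class TestCodedTweet:
    def test_subtheme_required_for_information_sharing(self):
        with pytest.raises(hc.CodingError):
            hc.CodedTweet("t1", "c1", "information_sharing")

    def test_subtheme_forbidden_elsewhere(self):
        with pytest.raises(hc.CodingError):
            hc.CodedTweet("t1", "c1", "action_activism_advocacy", "asking")

    def test_unknown_theme(self):
        with pytest.raises(hc.CodingError):
            hc.CodedTweet("t1", "c1", "sentiment")


def make_original_tweets(n):
    return [hc.Tweet(f"t{i}", "a", f"tweet {i}", ct(12, 0, i % 60)) for i in range(n)]


class TestThemeDistribution:
    def test_all_one_theme(self):
        tweets = make_original_tweets(4)
        coded = [
            hc.CodedTweet(t.tweet_id, "reconciled", "positive_affect_interpersonal_closeness")
            for t in tweets
        ]
        dist = hc.theme_distribution(coded, tweets).set_index("theme")
        row = dist[dist["subtheme"].isna()]
        pa = row.loc["positive_affect_interpersonal_closeness"]
        assert pa["count"] == 4 and pa["percent"] == 100.0
        assert row.loc["information_sharing", "percent"] == 0.0

    def test_retweet_reference_rejected(self):
        tweets = [
            hc.Tweet("t0", "a", "RT @b: echo", ct(12)),
            hc.Tweet("t1", "a", "fresh content", ct(12, 1)),
        ]
        coded = [hc.CodedTweet("t0", "reconciled", "unable_to_determine")]
        with pytest.raises(hc.CodingError):
            hc.theme_distribution(coded, tweets)

    def test_percents_sum_and_subthemes_nest(self, default_sim):
        tweets, ledger = default_sim
        coded = [
            hc.CodedTweet(tid, "reconciled", theme, sub)
            for tid, (theme, sub) in ledger.themes.items()
        ]
        dist = hc.theme_distribution(coded, tweets)
        themes_only = dist[dist["subtheme"].isna()]
        # truncation at one decimal can shed up to 0.1 per theme row
        assert themes_only["percent"].sum() == pytest.approx(100.0, abs=0.4)
        assert themes_only["percent"].sum() <= 100.0
        subs = dist[dist["subtheme"].notna()]
        info = themes_only.set_index("theme").loc["information_sharing", "count"]
        assert subs["count"].sum() == info


class TestCodingReliability:
    def test_perfect_agreement_all_statistics_one(self):
        coded = []
        for coder in ("c1", "c2"):
            coded += [
                hc.CodedTweet("t1", coder, "information_sharing", "asking"),
                hc.CodedTweet("t2", coder, "action_activism_advocacy"),
            ]
        res = hc.coding_reliability(coded, "c1", "c2", level="theme")
        assert res.percent_agreement == 100.0
        assert res.cohen_kappa == 1.0 and res.scott_pi == 1.0

    def test_subtheme_level_collapses_other_themes(self):
        coded = [
            hc.CodedTweet("t1", "c1", "information_sharing", "asking"),
            hc.CodedTweet("t2", "c1", "action_activism_advocacy"),
            hc.CodedTweet("t1", "c2", "information_sharing", "health_opinion"),
            hc.CodedTweet("t2", "c2", "unable_to_determine"),
        ]
        res = hc.coding_reliability(coded, "c1", "c2", level="subtheme")
        # t2 agrees (both "other"); t1 disagrees on subtheme
        assert res.percent_agreement == 50.0 and res.n_items == 2

    def test_exhaustive_small_vectors_match_oracle(self):
        for n in range(1, 6):
            for code_a in range(2**n):
                for code_b in range(2**n):
                    a = [("A", "B")[(code_a >> i) & 1] for i in range(n)]
                    b = [("A", "B")[(code_b >> i) & 1] for i in range(n)]
                    ok, opi = oracle_agreement_stats(a, b)
                    if ok is None:
                        continue
                    assert hc.cohen_kappa(a, b) == pytest.approx(ok)
                    assert hc.scott_pi(a, b) == pytest.approx(opi)
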