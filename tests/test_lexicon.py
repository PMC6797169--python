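"""Rating pooling, skewness, and against-the-rest valence classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fmnet.errors import InputError, StatisticalError
from fmnet.io import RatingForm
from fmnet.lexicon import (
    ValenceLexicon,
    build_lexicon,
    classify_word_valence,
    cross_validate,
    pearson_skewness,
    pool_ratings,
    two_group_kruskal,
)

from oracles import brute_tau_b, kw_two_group_statistic


def _rating_forms(table):
    """table: {participant: {word: rating-or-None}} -> list of RatingForm."""
    return [
        RatingForm(pid, tuple(words.items()), source="test")
        for pid, words in table.items()
    ]


class TestPooling:
    def test_single_rating(self):
        pooled = pool_ratings(_rating_forms({"p1": {"w": 5}}))
        assert pooled == {"w": [5]}

    def test_blank_contributes_neutral_three(self):
        pooled = pool_ratings(_rating_forms({"p1": {"w": None}}))
        assert pooled == {"w": [3]}

    def test_rating_and_blank_compose(self):
        pooled = pool_ratings(_rating_forms({"p1": {"w": 2}, "p2": {"w": None}}))
        assert sorted(pooled["w"]) == [2, 3]

    def test_duplicate_rating_by_same_participant_rejected(self):
        forms = [RatingForm("p1", (("w", 2), ("w", 4)), source="t")]
        with pytest.raises(InputError, match="rated 'w' twice"):
            pool_ratings(forms)


class TestPearsonSkewness:
    def test_symmetric_distribution_is_zero(self):
        assert pearson_skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # mean 2, median 1, population sd sqrt(3): 3*(2-1)/sqrt(3)
        assert pearson_skewness([1, 1, 1, 5]) == pytest.approx(math.sqrt(3))

    def test_degenerate_distribution_signalled(self):
        with pytest.raises(StatisticalError, match="zero standard deviation"):
            pearson_skewness([2, 2, 2])

    @given(
        st.lists(st.integers(min_value=1, max_value=5), min_size=3, max_size=20),
        st.floats(min_value=0.1, max_value=5),
        st.floats(min_value=-10, max_value=10),
    )
    def test_affine_equivariance(self, scores, a, b):
        if len(set(scores)) == 1:
            return
        base = pearson_skewness(scores)
        scaled = pearson_skewness([a * s + b for s in scores])
        assert scaled == pytest.approx(base, abs=1e-8)
        flipped = pearson_skewness([-a * s + b for s in scores])
        assert flipped == pytest.approx(-base, abs=1e-8)


class TestClassification:
    def test_identical_constant_groups_are_neutral(self):
        attr, result = classify_word_valence([3] * 4, [3] * 4)
        assert attr == "neutral"
        assert result.p_value == 1.0

    def test_clearly_higher_word_is_positive(self):
        word, rest = [5] * 8, [3] * 8
        attr, result = classify_word_valence(word, rest)
        assert attr == "positive"
        assert result.p_value < 0.1
        assert result.statistic == pytest.approx(
            kw_two_group_statistic(word, rest), abs=1e-10
        )

    def test_clearly_lower_word_is_negative(self):
        attr, result = classify_word_valence([1] * 8, [4] * 8)
        assert attr == "negative"
        assert result.p_value < 0.1

    def test_empty_group_is_an_error(self):
        with pytest.raises(StatisticalError):
            classify_word_valence([], [3, 3])

    @given(
        st.lists(st.integers(min_value=1, max_value=5), min_size=6, max_size=15),
        st.lists(st.integers(min_value=1, max_value=5), min_size=6, max_size=15),
    )
    def test_label_symmetry_under_scale_reflection(self, word, rest):
        """Mapping every rating r -> 6-r swaps positive and negative."""
        attr, _ = classify_word_valence(word, rest)
        mirrored, _ = classify_word_valence(
            [6 - r for r in word], [6 - r for r in rest]
        )
        expected = {"positive": "negative", "negative": "positive", "neutral": "neutral"}
        assert mirrored == expected[attr]

    @given(
        st.lists(st.integers(min_value=1, max_value=5), min_size=5, max_size=12),
        st.lists(st.integers(min_value=1, max_value=5), min_size=5, max_size=12),
    )
    def test_decision_set_monotone_in_alpha(self, word, rest):
        """Decreasing alpha never turns a neutral word positive/negative."""
        attr_strict, _ = classify_word_valence(word, rest, alpha=0.01)
        attr_loose, _ = classify_word_valence(word, rest, alpha=0.2)
        if attr_loose == "neutral":
            assert attr_strict == "neutral"


class TestTwoGroupKruskal:
    def test_exact_p_used_for_tiny_groups(self):
        # 3 fives vs 5 ones: of the C(8,3)=56 relabellings only the observed
        # one (all three top ranks in one group) reaches the observed rank-sum
        # deviation, so the exact two-sided p is 1/56
        stat, p = two_group_kruskal([5, 5, 5], [1, 1, 1, 1, 1])
        assert p == pytest.approx(1 / 56)

    def test_all_identical_values(self):
        assert two_group_kruskal([3, 3], [3, 3, 3]) == (0.0, 1.0)


class TestBuildLexicon:
    def test_constant_ratings_give_all_neutral_and_zero_skew(self):
        forms = _rating_forms(
            {f"p{i}": {"w1": 3, "w2": None, "w3": 3} for i in range(5)}
        )
        lexicon, skew = build_lexicon(forms)
        assert {wv.attribute for wv in lexicon.words.values()} == {"neutral"}
        assert skew.pearson_skewness == 0.0

    def test_two_opposite_words_recovered(self):
        forms = _rating_forms(
            {f"p{i}": {"good": 5, "bad": 1} for i in range(20)}
        )
        lexicon, _ = build_lexicon(forms)
        assert lexicon.attribute("good") == "positive"
        assert lexicon.attribute("bad") == "negative"

    def test_single_word_is_an_error(self):
        with pytest.raises(InputError, match=">= 2 distinct rated words"):
            build_lexicon(_rating_forms({"p1": {"w": 3}}))

    def test_unrated_word_defaults_to_neutral(self):
        forms = _rating_forms({f"p{i}": {"a": 5, "b": 1} for i in range(10)})
        lexicon, _ = build_lexicon(forms)
        assert "zzz" not in lexicon
        assert lexicon.attribute("zzz") == "neutral"

    def test_csv_round_trip(self, tmp_path):
        forms = _rating_forms(
            {f"p{i}": {"università": 5, "morte": 1, "pane": 3} for i in range(12)}
        )
        lexicon, _ = build_lexicon(forms)
        lexicon.to_csv(tmp_path / "lex.csv")
        reread = ValenceLexicon.from_csv(tmp_path / "lex.csv")
        assert set(reread.words) == set(lexicon.words)
        for word, wv in lexicon.words.items():
            back = reread[word]
            assert back.attribute == wv.attribute
            assert back.n_raters == wv.n_raters
            assert back.mean == wv.mean
            assert back.median == wv.median
            assert back.statistic == wv.statistic
            assert back.p_value == wv.p_value


class TestCrossValidation:
    def test_identical_rankings_give_tau_one(self):
        means = {f"w{i}": float(i) / 2 + 1 for i in range(10)}
        lexicon = _patched_lexicon(means)
        norms = _norm_table({w: m for w, m in means.items()})
        tau, p, n = cross_validate(lexicon, norms)
        assert tau == pytest.approx(1.0)
        assert n == 10

    def test_reversed_rankings_give_tau_minus_one(self):
        means = {f"w{i}": 1.0 + i * 0.4 for i in range(8)}
        lexicon = _patched_lexicon(means)
        norms = _norm_table({w: -m for w, m in means.items()})
        tau, _, _ = cross_validate(lexicon, norms)
        assert tau == pytest.approx(-1.0)

    def test_tied_case_matches_pair_counting_oracle(self):
        means = {"a": 1.0, "b": 2.0, "c": 2.0, "d": 4.0, "e": 5.0}
        external = {"a": 1.5, "b": 2.5, "c": 3.0, "d": 3.0, "e": 4.9}
        lexicon = _patched_lexicon(means)
        norms = _norm_table(external)
        tau, _, n = cross_validate(lexicon, norms)
        words = sorted(means)
        expected = brute_tau_b([means[w] for w in words], [external[w] for w in words])
        assert tau == pytest.approx(expected, abs=1e-12)
        assert n == 5

    def test_insufficient_overlap_is_an_error(self):
        lexicon = _patched_lexicon({"a": 2.0, "b": 3.0})
        norms = _norm_table({"zzz": 1.0})
        with pytest.raises(StatisticalError, match="overlap"):
            cross_validate(lexicon, norms)


def _patched_lexicon(means):
    """A lexicon whose per-word mean ratings equal the requested values."""
    from fmnet.lexicon import WordValence

    words = {
        w: WordValence(
            word=w, n_raters=1, mean=m, median=m, attribute="neutral",
            statistic=0.0, p_value=1.0,
        )
        for w, m in means.items()
    }
    return ValenceLexicon(words=words)


def _norm_table(valence):
    from fmnet.io import ExternalNormTable

    return ExternalNormTable(valence=valence, arousal={}, source="test")
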