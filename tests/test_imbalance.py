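"""Levenshtein-ratio similarity and the five imbalance strategies."""

import sys
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teratext.corpus_io import Corpus, LabeledTweet
from teratext.imbalance import (
    SamplingPlan,
    SMOTEOverSampler,
    levenshtein_distance,
    levenshtein_ratio,
    oversample_replacement,
    undersample_random,
    undersample_similarity_all,
    undersample_similarity_fn,
)

from conftest import make_corpus

sys.setrecursionlimit(50_000)


@lru_cache(maxsize=None)
def edit_distance_oracle(a: str, b: str) -> int:
    """Brute-force recursive edit distance (memoized on suffixes)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = a[0] != b[0]
    return min(
        edit_distance_oracle(a[1:], b[1:]) + cost,
        edit_distance_oracle(a[1:], b) + 1,
        edit_distance_oracle(a, b[1:]) + 1,
    )


class TestLevenshteinRatio:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("abc", "abc", 1.0),
            ("kitten", "sitting", (13 - 3) / 13),
            ("", "a", 0.0),
            ("", "", 1.0),  # documented convention for the undefined case
        ],
    )
    def test_examples(self, a, b, expected):
        assert levenshtein_ratio(a, b) == pytest.approx(expected)

    @settings(max_examples=300, deadline=None)
    @given(
        st.text(alphabet="abc", max_size=6), st.text(alphabet="abc", max_size=6)
    )
    def test_agrees_with_recursive_oracle(self, a, b):
        assert levenshtein_distance(a, b) == edit_distance_oracle(a, b)

    @settings(max_examples=200, deadline=None)
    @given(
        st.text(alphabet="abcxyz", max_size=10),
        st.text(alphabet="abcxyz", max_size=10),
    )
    def test_symmetric_and_bounded(self, a, b):
        lr = levenshtein_ratio(a, b)
        assert lr == levenshtein_ratio(b, a)
        assert 0.0 <= lr <= 1.0
        if a == b:
            assert lr == 1.0


def _majority_corpus(texts, minority=()):
    rows = [(t, "non_defect") for t in texts]
    rows += [(t, "defect") for t in minority]
    return make_corpus(rows)


class TestSimilarityAll:
    def test_identical_pair_second_removed(self):
        c = _majority_corpus(["same headline here", "same headline here"])
        out = undersample_similarity_all(c, k=0.9)
        assert len(out) == 1

    def test_all_distinct_nothing_removed(self):
        c = _majority_corpus(["alpha beta", "totally different words", "qqq zz"])
        assert len(undersample_similarity_all(c, k=0.99)) == 3

    def test_near_duplicate_cluster_keeps_one(self):
        base = "new study links chd to genetic factors"
        dups = [base, base + " x", base + " yy", base + " z", base + " today"]
        assert all(
            levenshtein_ratio(base, d) > 0.8 for d in dups
        )  # fixture sanity via the LR oracle
        out = undersample_similarity_all(_majority_corpus(dups), k=0.8)
        assert len(out) == 1
        assert out[0].text == base  # keep-first

    def test_minority_multiset_preserved(self, synthetic_corpus):
        sub = synthetic_corpus[:400]
        out = undersample_similarity_all(sub, k=0.7)
        for label in ("defect", "possible_defect"):
            assert sorted(
                t.text for t in out if t.label == label
            ) == sorted(t.text for t in sub if t.label == label)

    def test_majority_output_subset_of_input(self, synthetic_corpus):
        sub = synthetic_corpus[:400]
        out = undersample_similarity_all(sub, k=0.8)
        in_ids = {t.tweet_id for t in sub}
        assert all(t.tweet_id in in_ids for t in out)

    def test_k_monotonicity_on_synthetic_clusters(self, synthetic_corpus):
        # stricter thresholds remove fewer tweets; removal sets need not
        # nest exactly under the keep-first rule, but counts are monotone
        # on near-duplicate cluster structure
        sub = synthetic_corpus[:400]
        sizes = [
            len(undersample_similarity_all(sub, k=k)) for k in (0.7, 0.8, 0.9)
        ]
        assert sizes == sorted(sizes)

    def test_invalid_k(self, synthetic_corpus):
        with pytest.raises(ValueError):
            undersample_similarity_all(synthetic_corpus, k=1.5)


class TestSimilarityFN:
    def test_anchor_equal_to_majority_tweet_removed(self):
        c = _majority_corpus(["the exact headline", "unrelated text"])
        out = undersample_similarity_fn(c, ["the exact headline"], k=0.9)
        assert [t.text for t in out] == ["unrelated text"]

    def test_empty_anchor_list_is_identity(self, synthetic_corpus):
        out = undersample_similarity_fn(synthetic_corpus, [], k=0.5)
        assert out.tweets == synthetic_corpus.tweets

    def test_near_anchor_tweet_removed_at_k07(self):
        anchor = "she may have chd the doctors are not sure"
        near = "she may have chd the doctors are not syre"
        far = "completely different fundraiser message"
        assert levenshtein_ratio(anchor, near) > 0.7 > levenshtein_ratio(anchor, far)
        c = _majority_corpus([near, far])
        out = undersample_similarity_fn(c, [anchor], k=0.7)
        assert [t.text for t in out] == [far]

    def test_minority_never_removed(self):
        c = _majority_corpus(["majority text"], minority=["anchor text"])
        out = undersample_similarity_fn(c, ["anchor text"], k=0.5)
        assert any(t.label == "defect" for t in out)


class TestRandomUnder:
    def test_identity_at_current_size(self, synthetic_corpus):
        out = undersample_random(synthetic_corpus, len(synthetic_corpus), seed=1)
        assert out.tweets == synthetic_corpus.tweets

    def test_seed_reproducible(self, synthetic_corpus):
        a = undersample_random(synthetic_corpus, 400, seed=5)
        b = undersample_random(synthetic_corpus, 400, seed=5)
        assert a.tweets == b.tweets
        assert len(a) == 400

    def test_target_below_minority_total_errors(self, synthetic_corpus):
        minority = sum(
            v for k, v in synthetic_corpus.class_counts().items()
            if k != "non_defect"
        )
        with pytest.raises(ValueError):
            undersample_random(synthetic_corpus, minority - 1, seed=0)

    def test_minority_untouched(self, synthetic_corpus):
        out = undersample_random(synthetic_corpus, 500, seed=2)
        for label in ("defect", "possible_defect"):
            assert sum(1 for t in out if t.label == label) == sum(
                1 for t in synthetic_corpus if t.label == label
            )


class TestOversampleReplacement:
    def _corpus(self, n_min, n_maj, n_pos=0):
        rows = [(f"minority text {i}", "defect") for i in range(n_min)]
        rows += [(f"possible text {i}", "possible_defect") for i in range(n_pos)]
        rows += [(f"majority text {i}", "non_defect") for i in range(n_maj)]
        return make_corpus(rows)

    def test_exact_multiple(self):
        out = oversample_replacement(self._corpus(5, 50), seed=0)
        assert out.class_counts()["defect"] == 50

    def test_floor_rule_nearly_equal(self):
        out = oversample_replacement(self._corpus(7, 50), seed=0)
        assert out.class_counts()["defect"] == 49  # m = floor(50/7) = 7

    def test_majority_count_unchanged(self):
        out = oversample_replacement(self._corpus(5, 50, n_pos=6), seed=0)
        assert out.class_counts()["non_defect"] == 50


class TestSMOTE:
    def test_identical_minority_points_give_identical_synthetics(self):
        X = np.vstack([np.ones((6, 3)), np.zeros((20, 3))])
        y = ["defect"] * 6 + ["non_defect"] * 20
        Xr, yr = SMOTEOverSampler(seed=0).fit_resample(X, y)
        new = Xr[26:]
        assert np.allclose(new, 1.0)
        assert (np.asarray(yr)[26:] == "defect").all()

    def test_synthetics_inside_minority_bounding_box(self):
        rng = np.random.default_rng(3)
        Xmin = rng.random((10, 4))
        Xmaj = rng.random((40, 4)) + 5
        X = np.vstack([Xmin, Xmaj])
        y = ["defect"] * 10 + ["non_defect"] * 40
        Xr, yr = SMOTEOverSampler(seed=1).fit_resample(X, y)
        new = Xr[50:]
        lo, hi = Xmin.min(axis=0), Xmin.max(axis=0)
        assert (new >= lo - 1e-12).all() and (new <= hi + 1e-12).all()

    def test_majority_rows_unchanged_and_balanced(self):
        rng = np.random.default_rng(7)
        X = rng.random((30, 2))
        y = ["defect"] * 8 + ["non_defect"] * 22
        Xr, yr = SMOTEOverSampler(seed=2).fit_resample(X, y)
        assert np.allclose(Xr[:30], X)
        yr = np.asarray(yr)
        assert (yr == "defect").sum() == (yr == "non_defect").sum()

    def test_too_small_minority_errors(self):
        X = np.random.default_rng(0).random((10, 2))
        y = ["defect"] * 3 + ["non_defect"] * 7
        with pytest.raises(ValueError):
            SMOTEOverSampler(seed=0).fit_resample(X, y)


class TestSamplingPlan:
    def test_k_required_for_similarity(self):
        with pytest.raises(ValueError):
            SamplingPlan(method="similarity_all")

    def test_k_forbidden_elsewhere(self):
        with pytest.raises(ValueError):
            SamplingPlan(method="smote", k=0.5)

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            SamplingPlan(method="bogus")
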