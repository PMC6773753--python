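"""Splitting, metrics, PR curves and the experiment harnesses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teratext.corpus_io import CLASS_ORDER
from teratext.evaluation import (
    ConfusionMatrix,
    SplitSpec,
    auc_pr,
    binary_metrics,
    collapse_two_class,
    confusion,
    heldout_size,
    metrics_from_confusion,
    pr_curve,
    round2,
    stratified_split,
)

from conftest import make_corpus

# The benchmark three-class confusion matrix used across several checks:
# rows actual (defect, possible_defect, non_defect), columns predicted.
BENCHMARK_CM = ConfusionMatrix(
    counts=np.array([[163, 12, 64], [18, 109, 113], [81, 68, 3974]])
)


class TestStratifiedSplit:
    def test_reference_class_counts_ceiling(self):
        # per-class 20% ceiling of (1192, 1196, 20611) gives the reference
        # 4602-tweet test partition
        sizes = [heldout_size(n, 0.2) for n in (1192, 1196, 20611)]
        assert sizes == [239, 240, 4123]
        assert sum(sizes) == 4602

    def test_balanced_ten_per_class(self):
        rows = []
        for cls in CLASS_ORDER:
            rows += [(f"text {cls} {i}", cls) for i in range(10)]
        train, dev, test = stratified_split(make_corpus(rows), SplitSpec(seed=0))
        assert all(v == 2 for v in test.class_counts().values())
        assert all(v == 2 for v in dev.class_counts().values())
        assert all(v == 6 for v in train.class_counts().values())

    def test_same_seed_identical_partitions(self, synthetic_corpus):
        a = stratified_split(synthetic_corpus, SplitSpec(seed=4))
        b = stratified_split(synthetic_corpus, SplitSpec(seed=4))
        for pa, pb in zip(a, b):
            assert pa.tweets == pb.tweets

    def test_disjoint_and_exhaustive(self, synthetic_corpus):
        train, dev, test = stratified_split(synthetic_corpus, SplitSpec(seed=1))
        ids = [t.tweet_id for part in (train, dev, test) for t in part]
        assert len(ids) == len(set(ids)) == len(synthetic_corpus)

    def test_proportions_within_ceiling(self, synthetic_corpus):
        _, _, test = stratified_split(synthetic_corpus, SplitSpec(seed=1))
        for cls, n in synthetic_corpus.class_counts().items():
            assert test.class_counts()[cls] == heldout_size(n, 0.2)

    def test_class_too_small_errors(self):
        rows = [("only one defect", "defect")]
        rows += [(f"t {i}", "non_defect") for i in range(10)]
        rows += [(f"p {i}", "possible_defect") for i in range(10)]
        with pytest.raises(ValueError, match="too small"):
            stratified_split(make_corpus(rows), SplitSpec())


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = ["defect", "possible_defect", "non_defect"]
        cm = confusion(y, y)
        assert np.array_equal(cm.counts, np.eye(3, dtype=int))

    def test_all_wrong_zero_diagonal(self):
        actual = ["defect", "possible_defect", "non_defect"]
        predicted = ["possible_defect", "non_defect", "defect"]
        assert np.trace(confusion(actual, predicted).counts) == 0

    def test_shuffle_invariant(self):
        rng = np.random.default_rng(0)
        actual = rng.choice(CLASS_ORDER, 50).tolist()
        predicted = rng.choice(CLASS_ORDER, 50).tolist()
        perm = rng.permutation(50)
        cm1 = confusion(actual, predicted)
        cm2 = confusion([actual[i] for i in perm], [predicted[i] for i in perm])
        assert np.array_equal(cm1.counts, cm2.counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(counts=-np.eye(3, dtype=int))


class TestMetrics:
    def test_benchmark_matrix_reproduces_reference_row(self):
        m = metrics_from_confusion(BENCHMARK_CM)
        assert m["defect"].rounded() == (0.62, 0.68, 0.65)
        assert m["possible_defect"].rounded() == (0.58, 0.45, 0.51)
        assert round2(m["non_defect"].f1) == 0.96

    def test_identity_matrix_all_ones(self):
        m = metrics_from_confusion(ConfusionMatrix(counts=np.eye(3, dtype=int) * 5))
        for cls in CLASS_ORDER:
            assert m[cls].precision == m[cls].recall == m[cls].f1 == 1.0

    def test_all_one_class_prediction(self):
        actual = ["defect", "possible_defect", "non_defect", "non_defect"]
        predicted = ["non_defect"] * 4
        m = metrics_from_confusion(confusion(actual, predicted))
        assert m["non_defect"].recall == 1.0
        assert m["defect"].recall == 0.0 and m["defect"].undefined
        assert m["possible_defect"].f1 == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from(CLASS_ORDER),
                              st.sampled_from(CLASS_ORDER)),
                    min_size=1, max_size=50))
    def test_agrees_with_per_instance_counting(self, pairs):
        actual = [a for a, _ in pairs]
        predicted = [p for _, p in pairs]
        m = metrics_from_confusion(confusion(actual, predicted))
        for cls in CLASS_ORDER:
            tp = sum(1 for a, p in pairs if a == cls and p == cls)
            fp = sum(1 for a, p in pairs if a != cls and p == cls)
            fn = sum(1 for a, p in pairs if a == cls and p != cls)
            expected = binary_metrics(tp, fp, fn)
            assert m[cls].precision == pytest.approx(expected.precision)
            assert m[cls].recall == pytest.approx(expected.recall)
            assert m[cls].f1 == pytest.approx(expected.f1)


class TestTwoClassCollapse:
    def test_reference_counts(self):
        m = binary_metrics(tp=289, fp=129, fn=190)
        assert (round2(m.precision), round2(m.recall), round2(m.f1)) == (
            0.69, 0.60, 0.64,
        )

    def test_collapse_merges_minority_labels(self):
        actual = ["defect", "possible_defect", "non_defect"]
        predicted = ["possible_defect", "defect", "non_defect"]
        cm, pos = collapse_two_class(actual, predicted)
        # cross-minority confusion becomes correct in the collapsed view
        assert pos.precision == pos.recall == pos.f1 == 1.0
        assert cm.total == 3

    def test_all_positive_prediction_recall_one(self):
        actual = ["defect", "non_defect", "possible_defect"]
        predicted = ["defect", "defect", "defect"]
        _, pos = collapse_two_class(actual, predicted)
        assert pos.recall == 1.0


class TestPRCurve:
    def test_perfect_scorer_auc_one(self):
        actual = ["defect", "defect", "non_defect", "non_defect"]
        scores = [0.9, 0.8, 0.2, 0.1]
        assert auc_pr(pr_curve(actual, scores, "defect")) == pytest.approx(1.0)

    def test_precision_at_full_recall_is_prevalence(self):
        actual = ["defect", "non_defect", "non_defect", "non_defect"]
        scores = [0.4, 0.3, 0.2, 0.1]
        curve = pr_curve(actual, scores, "defect")
        full = [p for r, p in curve if r == 1.0]
        assert min(full) == pytest.approx(0.25)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        actual = rng.choice(["defect", "non_defect"], 40).tolist()
        if "defect" not in actual:
            actual[0] = "defect"
        scores = rng.random(40)
        a1 = auc_pr(pr_curve(actual, scores, "defect"))
        a2 = auc_pr(pr_curve(actual, np.exp(5 * scores), "defect"))
        assert a1 == pytest.approx(a2)

    def test_random_scores_auc_near_prevalence(self):
        rng = np.random.default_rng(42)
        n = 4000
        actual = (["defect"] * (n // 2)) + (["non_defect"] * (n // 2))
        scores = rng.random(n)
        auc = auc_pr(pr_curve(actual, scores, "defect"))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            pr_curve(["non_defect"], [0.5], "defect")


class TestHarnesses:
    @pytest.fixture(scope="class")
    @staticmethod
    def split(synthetic_corpus):
        small = synthetic_corpus[:600]
        return stratified_split(small, SplitSpec(seed=2))

    def test_ablation_all_row_equals_standard_run(self, split, synthetic_resources):
        from teratext.evaluation import ablation, evaluate_pipeline
        from teratext.pipeline import TweetPipeline

        train, _, test = split
        results = ablation(
            train, test, synthetic_resources,
            subsets={"all": dict(use_ngrams=True, use_clusters=True,
                                 use_lengths=True)},
            seed=7,
        )
        pipe = TweetPipeline(resources=synthetic_resources, classifier="svm",
                             seed=7).fit(train)
        _, standard = evaluate_pipeline(pipe, test)
        for cls in CLASS_ORDER:
            assert results["all"][cls].f1 == pytest.approx(standard[cls].f1)

    def test_ablating_empty_feature_group_changes_nothing(
        self, split, synthetic_resources
    ):
        from teratext.evaluation import ablation
        from teratext.pipeline import Resources

        train, _, test = split
        # no cluster table -> the cluster feature group is empty
        res = Resources(
            patterns=synthetic_resources.patterns,
            names=synthetic_resources.names,
            clusters=None,
        )
        results = ablation(
            train, test, res,
            subsets={
                "all": dict(use_ngrams=True, use_clusters=True, use_lengths=True),
                "wo_clusters": dict(use_ngrams=True, use_clusters=False,
                                    use_lengths=True),
            },
            seed=3,
        )
        for cls in CLASS_ORDER:
            assert results["all"][cls].f1 == pytest.approx(
                results["wo_clusters"][cls].f1
            )

    def test_sampling_comparison_none_plan_is_baseline(
        self, split, synthetic_resources
    ):
        from teratext.evaluation import (
            evaluate_pipeline,
            sampling_comparison,
        )
        from teratext.imbalance import SamplingPlan
        from teratext.pipeline import TweetPipeline

        train, dev, test = split
        rows = sampling_comparison(
            train, dev, test, synthetic_resources,
            plans=[SamplingPlan(method="none")],
            classifiers=("svm",), seed=5,
        )
        pipe = TweetPipeline(resources=synthetic_resources, classifier="svm",
                             seed=5).fit(train)
        _, baseline = evaluate_pipeline(pipe, test)
        assert rows[0]["train_size"] == len(train)
        for cls in CLASS_ORDER:
            assert rows[0]["metrics"][cls].f1 == pytest.approx(baseline[cls].f1)

    def test_random_under_inherits_similarity_size(
        self, split, synthetic_resources
    ):
        from teratext.evaluation import sampling_comparison
        from teratext.imbalance import SamplingPlan

        train, dev, test = split
        rows = sampling_comparison(
            train, dev, test, synthetic_resources,
            plans=[
                SamplingPlan(method="similarity_all", k=0.8),
                SamplingPlan(method="random_under"),
            ],
            classifiers=("nb",), seed=5,
        )
        assert rows[1]["plan"].target_size == rows[0]["train_size"]
        assert rows[1]["train_size"] == rows[0]["train_size"]
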