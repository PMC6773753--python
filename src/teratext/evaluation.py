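"""Evaluation harness: stratified splitting, confusion matrices, per-class
precision/recall/F1, the two-class collapse, precision-recall curves with
trapezoidal AUC, feature ablation and the sampling-strategy comparison.

Display values round half-up to 2 decimals (matching the convention of the
benchmark tables); raw values are retained on every metrics object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .corpus_io import CLASS_ORDER, Corpus


def round2(x: float) -> float:
    """Round half-up to 2 decimals (display convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# --- splitting --------------------------------------------------------------


@dataclass
class SplitSpec:
    """Fractions held out for test and (of the remainder) for development;
    per-class ceiling rounding on the held-out side."""

    test_fraction: float = 0.2
    dev_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for f in (self.test_fraction, self.dev_fraction):
            if not (0.0 < f < 1.0):
                raise ValueError("fractions must lie in (0, 1)")


def heldout_size(n: int, fraction: float) -> int:
    """Per-class held-out count: ceiling of fraction * n."""
    return math.ceil(fraction * n)


def stratified_split(
    corpus: Corpus, spec: SplitSpec
) -> tuple[Corpus, Corpus, Corpus]:
    """Split into (train, dev, test), stratified per class.

    Per class: ceil(test_fraction * n) tweets to test; of the remainder,
    ceil(dev_fraction * m) to dev. Shuffling within class is seeded (one
    deterministic substream per class), partitions are disjoint and
    exhaustive, and each partition keeps corpus order.
    """
    labels = corpus.labels
    if any(l is None for l in labels):
        raise ValueError("stratified_split requires a fully labeled corpus")
    assign = np.zeros(len(corpus), dtype=int)  # 0=train 1=dev 2=test
    present = [c for c in CLASS_ORDER if c in set(labels)] + sorted(
        set(labels) - set(CLASS_ORDER)
    )
    for ci, cls in enumerate(present):
        idx = np.array([i for i, l in enumerate(labels) if l == cls])
        n = len(idx)
        n_test = heldout_size(n, spec.test_fraction)
        n_dev = heldout_size(n - n_test, spec.dev_fraction)
        if n - n_test - n_dev < 1 or n_test < 1 or n_dev < 1:
            raise ValueError(f"class {cls!r} too small to populate all partitions")
        rng = np.random.default_rng([spec.seed, ci])
        perm = rng.permutation(n)
        assign[idx[perm[:n_test]]] = 2
        assign[idx[perm[n_test : n_test + n_dev]]] = 1
    parts = tuple(
        Corpus(
            [t for t, a in zip(corpus.tweets, assign) if a == part],
            corpus.provenance,
        )
        for part in (0, 1, 2)
    )
    return parts


# --- confusion and metrics --------------------------------------------------


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = actual, columns = predicted, fixed class order."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts shape does not match class list")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def diagonal_total(self) -> int:
        return int(np.trace(self.counts))

    def row_sum(self, cls: str) -> int:
        return int(self.counts[self.classes.index(cls)].sum())

    def col_sum(self, cls: str) -> int:
        return int(self.counts[:, self.classes.index(cls)].sum())


@dataclass
class OneClassMetrics:
    precision: float
    recall: float
    f1: float
    undefined: bool = False  # flagged when a denominator was zero

    def rounded(self) -> tuple[float, float, float]:
        return round2(self.precision), round2(self.recall), round2(self.f1)


@dataclass
class ClassMetrics:
    """Per-class one-vs-rest precision/recall/F1."""

    per_class: dict[str, OneClassMetrics]

    def __getitem__(self, cls: str) -> OneClassMetrics:
        return self.per_class[cls]

    def macro_f1(self) -> float:
        return float(np.mean([m.f1 for m in self.per_class.values()]))


def confusion(
    actual: Sequence[str],
    predicted: Sequence[str],
    classes: tuple[str, ...] = CLASS_ORDER,
) -> ConfusionMatrix:
    counts = _sk_confusion(actual, predicted, labels=list(classes))
    return ConfusionMatrix(counts=counts, classes=classes)


def binary_metrics(tp: int, fp: int, fn: int) -> OneClassMetrics:
    """Precision/recall/F1 from one-vs-rest counts; zero denominators give
    0 with the undefined flag set."""
    undefined = False
    if tp + fp == 0:
        precision, undefined = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, undefined = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        undefined = undefined or tp > 0
    else:
        f1 = 2 * recall * precision / (recall + precision)
    return OneClassMetrics(precision, recall, f1, undefined)


def metrics_from_confusion(cm: ConfusionMatrix) -> ClassMetrics:
    out = {}
    for i, cls in enumerate(cm.classes):
        tp = int(cm.counts[i, i])
        fp = int(cm.counts[:, i].sum()) - tp
        fn = int(cm.counts[i, :].sum()) - tp
        out[cls] = binary_metrics(tp, fp, fn)
    return ClassMetrics(per_class=out)


POSITIVE = "positive"


def collapse_labels(labels: Sequence[str]) -> list[str]:
    return [POSITIVE if l in ("defect", "possible_defect") else l for l in labels]


def collapse_two_class(
    actual: Sequence[str], predicted: Sequence[str]
) -> tuple[ConfusionMatrix, OneClassMetrics]:
    """Collapse defect + possible_defect into one positive class and score
    the (2-class) prediction set for the positive class."""
    classes = (POSITIVE, "non_defect")
    cm = confusion(collapse_labels(actual), collapse_labels(predicted), classes)
    metrics = metrics_from_confusion(cm)
    return cm, metrics[POSITIVE]


# --- precision-recall curves ------------------------------------------------


def pr_curve(
    actual: Sequence[str], positive_scores: Sequence[float], positive_label: str
) -> list[tuple[float, float]]:
    """Precision-recall points sweeping thresholds over the unique scores
    in descending order, with the conventional (recall 0, precision 1)
    anchor prepended."""
    y = np.asarray([1 if a == positive_label else 0 for a in actual])
    s = np.asarray(positive_scores, dtype=float)
    if y.sum() == 0:
        raise ValueError("no positive instances to score")
    points = [(0.0, 1.0)]
    for thr in sorted(np.unique(s))[::-1]:
        pred = s >= thr
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        fn = int((~pred & (y == 1)).sum())
        m = binary_metrics(tp, fp, fn)
        points.append((m.recall, m.precision))
    return points


def auc_pr(curve: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area over recall.

    Where several thresholds reach the same recall, the best precision at
    that recall defines the curve height.
    """
    best: dict[float, float] = {}
    for r, p in curve:
        best[r] = max(best.get(r, 0.0), p)
    recall = np.asarray(sorted(best))
    precision = np.asarray([best[r] for r in recall])
    return float(np.trapezoid(precision, recall))


# --- experiment harnesses ---------------------------------------------------

ABLATION_SUBSETS = {
    "all": dict(use_ngrams=True, use_clusters=True, use_lengths=True),
    "wo_ngrams": dict(use_ngrams=False, use_clusters=True, use_lengths=True),
    "wo_clusters": dict(use_ngrams=True, use_clusters=False, use_lengths=True),
    "wo_lengths": dict(use_ngrams=True, use_clusters=True, use_lengths=False),
    "ngrams_only": dict(use_ngrams=True, use_clusters=False, use_lengths=False),
    "clusters_only": dict(use_ngrams=False, use_clusters=True, use_lengths=False),
}


def evaluate_pipeline(pipeline, test: Corpus) -> tuple[ConfusionMatrix, ClassMetrics]:
    predicted = pipeline.predict(test)
    cm = confusion(test.labels, list(predicted))
    return cm, metrics_from_confusion(cm)


def ablation(
    train: Corpus,
    test: Corpus,
    resources,
    subsets: dict[str, dict] | None = None,
    classifier: str = "svm",
    seed: int = 0,
) -> dict[str, ClassMetrics]:
    """Retrain and evaluate one pipeline per feature subset."""
    from .pipeline import TweetPipeline

    subsets = subsets or ABLATION_SUBSETS
    results = {}
    for name, toggles in subsets.items():
        pipe = TweetPipeline(
            resources=resources, classifier=classifier, seed=seed, **toggles
        ).fit(train)
        _, metrics = evaluate_pipeline(pipe, test)
        results[name] = metrics
    return results


def misclassified_anchors(pipeline, dev: Corpus) -> list[str]:
    """Normalized texts of dev-set minority tweets a preliminary classifier
    misclassifies as non-defect (the anchors of similarity method 2)."""
    predicted = pipeline.predict(dev)
    return [
        pipeline.normalized_text(t)
        for t, p in zip(dev.tweets, predicted)
        if t.label in ("defect", "possible_defect") and p == "non_defect"
    ]


def sampling_comparison(
    train: Corpus,
    dev: Corpus,
    test: Corpus,
    resources,
    plans: Sequence,
    classifiers: Sequence[str] = ("nb", "svm"),
    seed: int = 0,
) -> list[dict]:
    """One row per (classifier, sampling plan), all evaluated on the same
    test set. A ``random_under`` plan without a target size inherits the
    resulting training size of the most recent similarity-based plan."""
    from .imbalance import SamplingPlan
    from .pipeline import TweetPipeline

    anchors = None
    if any(p.method == "similarity_fn" for p in plans):
        prelim = TweetPipeline(resources=resources, classifier="svm", seed=seed).fit(train)
        anchors = misclassified_anchors(prelim, dev)

    rows = []
    last_similarity_size: int | None = None
    for clf in classifiers:
        for plan in plans:
            plan_used = plan
            if plan.method == "random_under" and plan.target_size is None:
                if last_similarity_size is None:
                    raise ValueError(
                        "random_under without target_size needs a preceding "
                        "similarity plan to control"
                    )
                plan_used = SamplingPlan(
                    method="random_under",
                    target_size=last_similarity_size,
                    seed=plan.seed,
                )
            pipe = TweetPipeline(
                resources=resources, classifier=clf, sampling_plan=plan_used, seed=seed
            ).fit(train, anchors=anchors)
            if plan.method in ("similarity_all", "similarity_fn"):
                last_similarity_size = pipe.train_size_
            _, metrics = evaluate_pipeline(pipe, test)
            rows.append(
                {
                    "classifier": clf,
                    "plan": plan_used,
                    "train_size": pipe.train_size_,
                    "metrics": metrics,
                }
            )
    return rows
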