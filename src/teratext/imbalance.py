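"""Data-level class-imbalance strategies built on the Levenshtein-ratio
(LR) lexical similarity.

LR(a, b) = (lensum - lendist) / lensum, where lensum = |a| + |b| and
lendist is the Levenshtein edit distance (insertions, deletions,
substitutions). LR is symmetric, lies in [0, 1], and equals 1 iff the
strings are identical.

Five strategies:

1. ``similarity_all`` — scan majority-class tweets in corpus order and drop
   a tweet when its LR to any *retained earlier* majority tweet exceeds a
   threshold k (near-duplicate head-line removal).
2. ``similarity_fn`` — drop a majority tweet when its LR to any anchor
   string (development-set minority tweets misclassified as majority)
   exceeds k.
3. ``random_under`` — uniform under-sampling of the majority class down to
   a target total corpus size.
4. ``oversample_replacement`` — whole-set duplication of each minority
   class floor(majority/minority) times.
5. ``smote`` — synthetic minority interpolation in feature space
   (x + u * (nn - x), u ~ U(0, 1), among 5 minority nearest neighbours).

All under-sampling methods preserve the minority classes exactly. Methods
1-2 are O(n^2) with a provable length-gap prefilter: LR <= 2*min(|a|,|b|) /
(|a|+|b|), so pairs whose length gap already forces LR <= k are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .corpus_io import CLASS_ORDER, Corpus

MAJORITY = "non_defect"
MINORITY = ("defect", "possible_defect")

_METHODS = (
    "similarity_all",
    "similarity_fn",
    "random_under",
    "oversample_replacement",
    "smote",
    "none",
)


@dataclass
class SamplingPlan:
    """Which imbalance method to run and its parameters."""

    method: str = "none"
    k: float | None = None
    target_size: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"unknown sampling method {self.method!r}")
        if self.method in ("similarity_all", "similarity_fn"):
            if self.k is None or not (0.0 < self.k < 1.0):
                raise ValueError(f"method {self.method} requires k in (0, 1)")
        elif self.k is not None:
            raise ValueError(f"k is only valid for similarity methods")
        if self.method == "random_under" and self.target_size is None:
            # filled in later from a similarity run's output size
            pass
        if self.method != "random_under" and self.target_size is not None:
            raise ValueError("target_size is only valid for random_under")


# --- Levenshtein ratio ------------------------------------------------------


def levenshtein_distance(a: str, b: str) -> int:
    """Classic dynamic-programming edit distance (insert/delete/substitute)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ca != cb),
            )
        prev = cur
    return prev[-1]


def levenshtein_ratio(a: str, b: str) -> float:
    """LR = (lensum - lendist) / lensum in [0, 1]; 1 iff identical.

    Both-empty input is undefined by the formula; returns 1.0 by convention
    (identical strings).
    """
    lensum = len(a) + len(b)
    if lensum == 0:
        return 1.0
    return (lensum - levenshtein_distance(a, b)) / lensum


def _lr_upper_bound(la: int, lb: int) -> float:
    # editdist >= |la - lb|  =>  LR <= 2 * min(la, lb) / (la + lb)
    if la + lb == 0:
        return 1.0
    return 2.0 * min(la, lb) / (la + lb)


def _texts_for(corpus: Corpus, text_fn: Callable[[object], str] | None) -> list[str]:
    if text_fn is None:
        return [t.text for t in corpus]
    return [text_fn(t) for t in corpus]


# --- under-sampling ---------------------------------------------------------


def undersample_similarity_all(
    train: Corpus,
    k: float,
    text_fn: Callable[[object], str] | None = None,
    majority_label: str = MAJORITY,
) -> Corpus:
    """Method 1: drop majority tweets near-duplicating a retained earlier
    majority tweet (LR > k); minority classes untouched.

    ``text_fn`` maps a tweet to the string compared (e.g. its
    classic-normalized join); defaults to the raw text.
    """
    if not (0.0 < k < 1.0):
        raise ValueError("k must lie in (0, 1)")
    texts = _texts_for(train, text_fn)
    kept: list[bool] = []
    retained_idx: list[int] = []
    for i, tweet in enumerate(train):
        if tweet.label != majority_label:
            kept.append(True)
            continue
        ti = texts[i]
        drop = False
        for j in retained_idx:
            tj = texts[j]
            if _lr_upper_bound(len(ti), len(tj)) <= k:
                continue
            if levenshtein_ratio(ti, tj) > k:
                drop = True
                break
        kept.append(not drop)
        if not drop:
            retained_idx.append(i)
    return Corpus(
        [t for t, keep in zip(train.tweets, kept) if keep], train.provenance
    )


def undersample_similarity_fn(
    train: Corpus,
    anchors: Sequence[str],
    k: float,
    text_fn: Callable[[object], str] | None = None,
    majority_label: str = MAJORITY,
) -> Corpus:
    """Method 2: drop majority tweets whose max LR to any anchor string
    (misclassified dev-set minority tweets) exceeds k."""
    if not (0.0 < k < 1.0):
        raise ValueError("k must lie in (0, 1)")
    if not anchors:
        return Corpus(list(train.tweets), train.provenance)
    texts = _texts_for(train, text_fn)
    out = []
    for tweet, text in zip(train, texts):
        if tweet.label == majority_label and any(
            _lr_upper_bound(len(text), len(a)) > k
            and levenshtein_ratio(text, a) > k
            for a in anchors
        ):
            continue
        out.append(tweet)
    return Corpus(out, train.provenance)


def undersample_random(
    train: Corpus,
    target_size: int,
    seed: int = 0,
    majority_label: str = MAJORITY,
) -> Corpus:
    """Method 3: uniform without-replacement sampling of the majority class
    so the total corpus size equals ``target_size``; order otherwise stable."""
    minority_n = sum(1 for t in train if t.label != majority_label)
    majority_idx = [i for i, t in enumerate(train) if t.label == majority_label]
    keep_majority = target_size - minority_n
    if keep_majority < 0:
        raise ValueError(
            f"target_size {target_size} smaller than minority total {minority_n}"
        )
    if keep_majority > len(majority_idx):
        raise ValueError("target_size exceeds corpus size")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(majority_idx, size=keep_majority, replace=False).tolist())
    out = [
        t for i, t in enumerate(train)
        if t.label != majority_label or i in chosen
    ]
    return Corpus(out, train.provenance)


# --- over-sampling ----------------------------------------------------------


def oversample_replacement(
    train: Corpus, seed: int = 0, majority_label: str = MAJORITY
) -> Corpus:
    """Method 4: duplicate each minority class whole-set m times,
    m = floor(majority_count / class_count) ("nearly equal"), then shuffle."""
    counts = train.class_counts()
    majority_n = counts[majority_label]
    out = []
    for t in train:
        if t.label == majority_label or t.label is None:
            out.append(t)
    for label in CLASS_ORDER:
        if label == majority_label or counts.get(label, 0) == 0:
            continue
        m = majority_n // counts[label]
        members = [t for t in train if t.label == label]
        for _ in range(max(m, 1)):
            out.extend(members)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(out))
    return Corpus([out[i] for i in order], train.provenance)


class SMOTEOverSampler(BaseEstimator):
    """Method 5: synthetic minority interpolation in feature space.

    For each minority class, synthetic rows x + u * (x_nn - x) with
    u ~ U(0, 1) and x_nn among the ``k_neighbors`` nearest same-class
    neighbours are added until the class nearly balances the majority.
    Majority rows are unchanged. Requires every minority class to have at
    least ``k_neighbors + 1`` members.
    """

    def __init__(self, k_neighbors: int = 5, seed: int = 0,
                 majority_label: str = MAJORITY):
        self.k_neighbors = k_neighbors
        self.seed = seed
        self.majority_label = majority_label

    def fit_resample(self, X, y):
        import scipy.sparse as sp

        y = np.asarray(y, dtype=object)
        dense = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        counts = {c: int((y == c).sum()) for c in np.unique(y)}
        n_major = counts.get(self.majority_label, max(counts.values()))
        rng = np.random.default_rng(self.seed)
        new_rows, new_labels = [], []
        for label, n_c in counts.items():
            if label == self.majority_label or n_c >= n_major:
                continue
            if n_c < self.k_neighbors + 1:
                raise ValueError(
                    f"class {label!r} has {n_c} members; SMOTE needs at least "
                    f"{self.k_neighbors + 1}"
                )
            idx = np.flatnonzero(y == label)
            Xc = dense[idx]
            nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1).fit(Xc)
            neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]
            n_new = n_major - n_c
            base = rng.integers(0, n_c, size=n_new)
            pick = rng.integers(0, self.k_neighbors, size=n_new)
            u = rng.random(size=n_new)
            for b, p, uu in zip(base, pick, u):
                xb = Xc[b]
                xn = Xc[neigh[b, p]]
                new_rows.append(xb + uu * (xn - xb))
                new_labels.append(label)
        if new_rows:
            X_out = np.vstack([dense, np.vstack(new_rows)])
            y_out = np.concatenate([y, np.asarray(new_labels, dtype=object)])
        else:
            X_out, y_out = dense, y
        if sp.issparse(X):
            X_out = sp.csr_matrix(X_out)
        return X_out, y_out


def smote_oversample(X, labels, seed: int = 0, k_neighbors: int = 5):
    """Functional wrapper over :class:`SMOTEOverSampler`."""
    return SMOTEOverSampler(k_neighbors=k_neighbors, seed=seed).fit_resample(X, labels)


def apply_plan(
    train: Corpus,
    plan: SamplingPlan,
    anchors: Sequence[str] | None = None,
    text_fn: Callable[[object], str] | None = None,
) -> Corpus:
    """Apply a corpus-level sampling plan (methods 1-4 / none).

    SMOTE operates in feature space and is handled by the model pipeline,
    not here.
    """
    if plan.method == "none":
        return train
    if plan.method == "similarity_all":
        return undersample_similarity_all(train, plan.k, text_fn=text_fn)
    if plan.method == "similarity_fn":
        return undersample_similarity_fn(
            train, anchors or [], plan.k, text_fn=text_fn
        )
    if plan.method == "random_under":
        if plan.target_size is None:
            raise ValueError("random_under needs a target_size")
        return undersample_random(train, plan.target_size, seed=plan.seed)
    if plan.method == "oversample_replacement":
        return oversample_replacement(train, seed=plan.seed)
    raise ValueError(f"plan {plan.method} is not corpus-level")
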