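"""Feature engineering: word n-grams, word-cluster indicators and length
features, with train-fitted min-max scaling and information-gain ranking.

Features are namespaced by column name (``ngram:``, ``cluster:``, ``len:``)
and ordered lexicographically, so the matrix layout is deterministic and
invariant to instance order. N-gram values are raw counts by default (a
``binary`` toggle is provided); scaling is min-max fitted on training data
only, with zero-range columns mapping to 0 and out-of-range values clipped
to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .corpus_io import ClusterTable
from .preprocess import _PLACEHOLDER_RE


@dataclass
class FeatureMatrix:
    """Sparse instance x feature matrix with named columns and optional
    per-column scaling bounds (fitted on training data)."""

    X: sp.csr_matrix
    feature_names: list[str]
    scaling_bounds: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def shape(self):
        return self.X.shape

    def toarray(self) -> np.ndarray:
        return self.X.toarray()


class TweetFeaturizer(BaseEstimator, TransformerMixin):
    """Build the sparse feature matrix from (raw_text, tokens) pairs.

    Parameters
    ----------
    use_ngrams, use_clusters, use_lengths : bool
        Feature-group toggles (the ablation axes).
    ngram_range : tuple
        Inclusive (min_n, max_n); default (1, 3).
    binary : bool
        If True, n-gram/cluster values are presence indicators, not counts.
    min_df : int
        Minimum document frequency for n-grams (default 1: keep all).
    cluster_table : ClusterTable or None
        Word -> cluster-path lookup; placeholders are skipped.
    """

    def __init__(
        self,
        use_ngrams: bool = True,
        use_clusters: bool = True,
        use_lengths: bool = True,
        ngram_range: tuple[int, int] = (1, 3),
        binary: bool = False,
        min_df: int = 1,
        cluster_table: ClusterTable | None = None,
    ):
        self.use_ngrams = use_ngrams
        self.use_clusters = use_clusters
        self.use_lengths = use_lengths
        self.ngram_range = ngram_range
        self.binary = binary
        self.min_df = min_df
        self.cluster_table = cluster_table

    # -- helpers -----------------------------------------------------------

    def _doc_features(self, raw: str, tokens: Sequence[str]) -> dict[str, float]:
        feats: dict[str, float] = {}
        if self.use_ngrams:
            lo, hi = self.ngram_range
            for n in range(lo, hi + 1):
                for i in range(len(tokens) - n + 1):
                    name = "ngram:" + "_".join(tokens[i : i + n])
                    feats[name] = feats.get(name, 0.0) + 1.0
        if self.use_clusters and self.cluster_table is not None:
            for tok in tokens:
                if _PLACEHOLDER_RE.match(tok):
                    continue
                path = self.cluster_table.lookup(tok)
                if path is not None:
                    name = f"cluster:{path}"
                    feats[name] = feats.get(name, 0.0) + 1.0
        if self.binary:
            feats = {k: 1.0 for k in feats}
        if self.use_lengths:
            feats["len:chars"] = float(len(raw))
            feats["len:words"] = float(len(tokens))
        return feats

    @staticmethod
    def _split_input(X):
        # X is a sequence of (raw_text, tokens) pairs
        raws, token_lists = [], []
        for raw, tokens in X:
            raws.append(raw)
            token_lists.append(list(tokens))
        return raws, token_lists

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        raws, token_lists = self._split_input(X)
        df_count: dict[str, int] = {}
        names: set[str] = set()
        for raw, tokens in zip(raws, token_lists):
            feats = self._doc_features(raw, tokens)
            for name in feats:
                df_count[name] = df_count.get(name, 0) + 1
                names.add(name)
        if self.min_df > 1:
            names = {
                n for n in names
                if n.startswith("len:") or df_count[n] >= self.min_df
            }
        self.feature_names_ = sorted(names)
        self.vocabulary_ = {n: i for i, n in enumerate(self.feature_names_)}
        return self

    def transform(self, X) -> sp.csr_matrix:
        check_is_fitted(self, "vocabulary_")
        raws, token_lists = self._split_input(X)
        rows, cols, vals = [], [], []
        for i, (raw, tokens) in enumerate(zip(raws, token_lists)):
            for name, v in self._doc_features(raw, tokens).items():
                j = self.vocabulary_.get(name)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(v)
        return sp.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(raws), len(self.feature_names_)),
            dtype=np.float64,
        )

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)


def fit_ngrams(
    corpus_tokens: Sequence[Sequence[str]], n_values=(1, 2, 3)
) -> dict[str, int]:
    """Vocabulary of all contiguous n-grams observed in training tokens."""
    if not corpus_tokens:
        raise ValueError("empty corpus")
    lo, hi = min(n_values), max(n_values)
    fz = TweetFeaturizer(
        use_clusters=False, use_lengths=False, ngram_range=(lo, hi)
    ).fit([("", t) for t in corpus_tokens])
    return fz.vocabulary_


def cluster_features(
    tokens: Sequence[str], table: ClusterTable
) -> dict[str, float]:
    """Counts over cluster-paths for one token list; unknown words and
    placeholders contribute nothing."""
    fz = TweetFeaturizer(use_ngrams=False, use_lengths=False, cluster_table=table)
    return {
        k: v for k, v in fz._doc_features("", list(tokens)).items()
    }


def length_features(text: str, tokens: Sequence[str]) -> tuple[int, int]:
    """(character length of raw text, token count)."""
    return len(text), len(tokens)


# --- scaling ----------------------------------------------------------------


class BoundedScaler(BaseEstimator, TransformerMixin):
    """Min-max scaler fitted on training data with clipping to [0, 1].

    Zero-range (constant) columns map to 0. Implemented sparse-aware: the
    common all-count columns (train min 0) stay sparse; only columns whose
    minimum is non-zero densify their offset.
    """

    def fit(self, X, y=None):
        X = sp.csr_matrix(X)
        self.min_ = np.asarray(X.min(axis=0).todense()).ravel()
        self.max_ = np.asarray(X.max(axis=0).todense()).ravel()
        rng = self.max_ - self.min_
        self.scale_ = np.where(rng > 0, 1.0 / np.where(rng > 0, rng, 1.0), 0.0)
        return self

    def transform(self, X) -> sp.csr_matrix:
        check_is_fitted(self, "scale_")
        X = sp.csr_matrix(X, dtype=np.float64)
        Xs = X @ sp.diags(self.scale_)
        nz = np.flatnonzero(self.min_ != 0)
        if nz.size:
            Xs = sp.lil_matrix(Xs)
            for j in nz:
                col = np.asarray(Xs[:, j].todense()).ravel()
                Xs[:, j] = (col - self.min_[j] * self.scale_[j]).reshape(-1, 1)
            Xs = sp.csr_matrix(Xs)
        Xs.data = np.clip(Xs.data, 0.0, 1.0)
        Xs.eliminate_zeros()
        return sp.csr_matrix(Xs)


def scale_fit_transform(train: FeatureMatrix) -> tuple[FeatureMatrix, BoundedScaler]:
    scaler = BoundedScaler().fit(train.X)
    return (
        FeatureMatrix(
            X=scaler.transform(train.X),
            feature_names=train.feature_names,
            scaling_bounds=(scaler.min_.copy(), scaler.max_.copy()),
        ),
        scaler,
    )


def scale_transform(other: FeatureMatrix, scaler: BoundedScaler) -> FeatureMatrix:
    return FeatureMatrix(
        X=scaler.transform(other.X),
        feature_names=other.feature_names,
        scaling_bounds=(scaler.min_.copy(), scaler.max_.copy()),
    )


# --- information gain -------------------------------------------------------


def _entropy(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    if counts.size == 0:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(
    X: sp.spmatrix | np.ndarray | FeatureMatrix,
    labels: Sequence[str],
    feature_names: Sequence[str] | None = None,
) -> list[tuple[str, float]]:
    """Rank features by information gain with presence/absence binarization.

    IG(f) = H(label) - sum_v p(f=v) H(label | f=v), v in {absent, present}.
    Descending by IG, ties broken by feature name.
    """
    if isinstance(X, FeatureMatrix):
        feature_names = X.feature_names
        X = X.X
    Xb = sp.csr_matrix(X)
    Xb = (Xb != 0).astype(np.int8).tocsc()
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    n, m = Xb.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(m)]
    total = np.bincount(y_idx, minlength=len(classes)).astype(float)
    h_label = _entropy(total)
    out = []
    Xcsc = Xb
    for j in range(m):
        col = Xcsc.getcol(j)
        present_rows = col.indices
        present = np.bincount(y_idx[present_rows], minlength=len(classes)).astype(float)
        absent = total - present
        n_p, n_a = present.sum(), absent.sum()
        cond = (n_p / n) * _entropy(present) + (n_a / n) * _entropy(absent)
        out.append((feature_names[j], max(0.0, h_label - cond)))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
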