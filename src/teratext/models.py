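"""The three classifiers behind a uniform fit/predict/predict_proba
contract, with the hyperparameters used throughout the pipeline:
Multinomial Naive Bayes (add-one smoothing), an RBF-kernel SVM with cost
c = 100 and minority-upweighted classes, and an LSTM sequence classifier.

Class order is fixed as (defect, possible_defect, non_defect) everywhere;
``predict_proba`` columns follow it. Models pickle round-trip via
:func:`save_model` / :func:`load_model`.
"""

from __future__ import annotations

import logging
import pickle
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from ._lstm import AdamState, LSTMNetwork, softmax
from .corpus_io import CLASS_ORDER
from .features import FeatureMatrix

logger = logging.getLogger("teratext")


def _canonical_classes(observed) -> list[str]:
    ordered = [c for c in CLASS_ORDER if c in observed]
    extras = [c for c in observed if c not in CLASS_ORDER]
    return ordered + sorted(extras)


def _as_matrix(X):
    if isinstance(X, FeatureMatrix):
        return X.X
    return X


class NaiveBayesTweetClassifier(BaseEstimator, ClassifierMixin):
    """Multinomial Naive Bayes over non-negative count features
    (add-one smoothing, log-priors from class frequencies)."""

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def fit(self, X, y):
        X = _as_matrix(X)
        self._nb = MultinomialNB(alpha=self.alpha).fit(X, y)
        self.classes_ = np.asarray(_canonical_classes(self._nb.classes_))
        self._order = [list(self._nb.classes_).index(c) for c in self.classes_]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        return self._nb.predict_proba(_as_matrix(X))[:, self._order]

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class SVMTweetClassifier(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM, cost c = 100, per-class weights defaulting to
    inverse frequency (N / (K * N_c)), one-vs-one multiclass.

    Refuses unscaled features: a :class:`FeatureMatrix` must carry scaling
    bounds, a raw matrix must already lie in [0, 1]. ``predict`` follows
    the SVM decision rule; ``predict_proba`` comes from pairwise-coupled
    sigmoid calibration and may (rarely) disagree with ``predict``.
    """

    def __init__(
        self,
        c: float = 100.0,
        class_weight="balanced",
        gamma="scale",
        probability: bool = True,
        seed: int = 0,
        check_scaling: bool = True,
    ):
        self.c = c
        self.class_weight = class_weight
        self.gamma = gamma
        self.probability = probability
        self.seed = seed
        self.check_scaling = check_scaling

    def _validate_scaled(self, X):
        if isinstance(X, FeatureMatrix):
            if X.scaling_bounds is None:
                raise ValueError(
                    "SVM requires scaled features: FeatureMatrix has no "
                    "scaling bounds (run scale_fit_transform first)"
                )
            return
        M = _as_matrix(X)
        lo = M.min() if not sp.issparse(M) else M.data.min(initial=0.0)
        hi = M.max() if not sp.issparse(M) else M.data.max(initial=0.0)
        if lo < -1e-9 or hi > 1.0 + 1e-9:
            raise ValueError(
                f"SVM requires features scaled to [0, 1]; got range "
                f"[{lo:.3g}, {hi:.3g}]"
            )

    def fit(self, X, y):
        if self.check_scaling:
            self._validate_scaled(X)
        kwargs = dict(
            kernel="rbf",
            C=self.c,
            gamma=self.gamma,
            class_weight=self.class_weight,
            random_state=self.seed,
        )
        if self.probability:
            # libsvm's pairwise-coupled sigmoid calibration; sklearn 1.9
            # deprecates the flag in favour of CalibratedClassifierCV, but
            # the pairwise coupling is the behaviour wanted here
            kwargs["probability"] = True
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message=".*probability.*", category=FutureWarning
            )
            self._svc = SVC(**kwargs).fit(_as_matrix(X), y)
        self.classes_ = np.asarray(_canonical_classes(self._svc.classes_))
        self._order = [list(self._svc.classes_).index(c) for c in self.classes_]
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self._svc.predict(_as_matrix(X))

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        if not self.probability:
            raise ValueError("fit with probability=True for predict_proba")
        return self._svc.predict_proba(_as_matrix(X))[:, self._order]


class LSTMTweetClassifier(BaseEstimator, ClassifierMixin):
    """Embedding(embed_dim) -> LSTM(hidden_dim, tanh, last state only) ->
    dropout(0.5) -> dense softmax; sequences right-zero-padded to
    ``seq_len`` (longer sequences truncated, count logged); 15 epochs of
    Adam on categorical cross-entropy, batch 32. Pretrained embeddings
    (word -> vector) seed known rows; out-of-vocabulary words start as zero
    vectors; all embeddings are fine-tuned.
    """

    def __init__(
        self,
        embeddings: dict | None = None,
        embed_dim: int = 100,
        hidden_dim: int = 128,
        seq_len: int = 800,
        dropout: float = 0.5,
        epochs: int = 15,
        batch_size: int = 32,
        learning_rate: float = 0.01,
        seed: int = 0,
    ):
        self.embeddings = embeddings
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.seq_len = seq_len
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def _encode(self, token_lists):
        n_trunc = 0
        out = np.zeros((len(token_lists), self.seq_len), dtype=np.int64)
        for r, tokens in enumerate(token_lists):
            if len(tokens) > self.seq_len:
                n_trunc += 1
                tokens = tokens[: self.seq_len]
            for t, tok in enumerate(tokens):
                out[r, t] = self.vocab_.get(tok, 0)
        if n_trunc:
            logger.warning("truncated %d sequences to %d tokens", n_trunc, self.seq_len)
        return out

    def fit(self, token_lists: Sequence[Sequence[str]], y):
        y = np.asarray(y, dtype=object)
        self.classes_ = np.asarray(_canonical_classes(np.unique(y)))
        class_idx = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_idx[c] for c in y])

        # index 0 is the pad/OOV id
        vocab: dict[str, int] = {}
        for tokens in token_lists:
            for tok in tokens:
                if tok not in vocab:
                    vocab[tok] = len(vocab) + 1
        self.vocab_ = vocab

        rng = np.random.default_rng(self.seed)
        pretrained = {}
        if self.embeddings:
            for word, idx in vocab.items():
                vec = self.embeddings.get(word)
                if vec is not None:
                    pretrained[idx] = np.asarray(vec, dtype=float)
        self.net_ = LSTMNetwork(
            vocab_size=len(vocab) + 1,
            embed_dim=self.embed_dim,
            hidden_dim=self.hidden_dim,
            n_classes=len(self.classes_),
            rng=rng,
            pretrained=pretrained,
        )
        X = self._encode(token_lists)
        onehot = np.eye(len(self.classes_))[y_idx]
        opt = AdamState(self.net_.params, lr=self.learning_rate)
        n = len(X)
        keep = 1.0 - self.dropout
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                mask = None
                if self.dropout > 0:
                    mask = (
                        rng.random((len(idx), self.hidden_dim)) < keep
                    ).astype(float) / keep
                probs, cache = self.net_.forward(X[idx], dropout_mask=mask, cache=True)
                grads = self.net_.backward(probs, onehot[idx], cache)
                opt.step(self.net_.params, grads)
        return self

    def predict_proba(self, token_lists):
        check_is_fitted(self, "net_")
        X = self._encode(token_lists)
        return self.net_.forward(X)

    def predict(self, token_lists):
        proba = self.predict_proba(token_lists)
        return self.classes_[np.argmax(proba, axis=1)]


# --- functional wrappers and persistence ------------------------------------


def train_nb(train: FeatureMatrix | sp.spmatrix, labels) -> NaiveBayesTweetClassifier:
    return NaiveBayesTweetClassifier().fit(train, labels)


def train_svm(
    train: FeatureMatrix | sp.spmatrix,
    labels,
    c: float = 100.0,
    class_weights="balanced",
    seed: int = 0,
    probability: bool = True,
) -> SVMTweetClassifier:
    return SVMTweetClassifier(
        c=c, class_weight=class_weights, seed=seed, probability=probability
    ).fit(train, labels)


def train_lstm(
    train_tokens: Sequence[Sequence[str]],
    labels,
    embeddings: dict | None = None,
    seed: int = 0,
    **kwargs,
) -> LSTMTweetClassifier:
    return LSTMTweetClassifier(embeddings=embeddings, seed=seed, **kwargs).fit(
        train_tokens, labels
    )


def predict(model, instances):
    return model.predict(instances)


def predict_proba(model, instances):
    return model.predict_proba(instances)


def save_model(model, path: str | Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path):
    with open(path, "rb") as fh:
        return pickle.load(fh)
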