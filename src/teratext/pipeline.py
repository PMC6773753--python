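"""End-to-end tweet-classification pipeline as a single estimator.

``TweetPipeline.fit(train_corpus)`` applies the configured sampling plan,
runs the appropriate normalization track, fits the featurizer (and, for the
SVM, the bounded scaler), optionally applies SMOTE in feature space, and
trains the chosen classifier. ``predict`` / ``predict_proba`` run the same
fitted transformations on new tweets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .corpus_io import ClusterTable, Corpus, NameLexicon
from .features import BoundedScaler, TweetFeaturizer
from .imbalance import SamplingPlan, SMOTEOverSampler, apply_plan
from .models import (
    LSTMTweetClassifier,
    NaiveBayesTweetClassifier,
    SVMTweetClassifier,
)
from .preprocess import DeixisWordlists, classic_normalize, embed_normalize
from .retrieval import LexiconPattern


@dataclass
class Resources:
    """External inputs shared across pipeline stages."""

    patterns: list[LexiconPattern] | None = None
    names: NameLexicon | None = None
    clusters: ClusterTable | None = None
    wordlists: DeixisWordlists = field(default_factory=DeixisWordlists)
    embeddings: dict | None = None


class TweetPipeline(BaseEstimator):
    """Sampling plan -> normalization -> features (-> scaling) -> classifier."""

    def __init__(
        self,
        resources: Resources | None = None,
        classifier: str = "svm",
        sampling_plan: SamplingPlan | None = None,
        use_ngrams: bool = True,
        use_clusters: bool = True,
        use_lengths: bool = True,
        binary: bool = False,
        min_df: int = 1,
        svm_c: float = 100.0,
        class_weight="balanced",
        probability: bool = False,
        lstm_params: dict | None = None,
        seed: int = 0,
    ):
        self.resources = resources
        self.classifier = classifier
        self.sampling_plan = sampling_plan
        self.use_ngrams = use_ngrams
        self.use_clusters = use_clusters
        self.use_lengths = use_lengths
        self.binary = binary
        self.min_df = min_df
        self.svm_c = svm_c
        self.class_weight = class_weight
        self.probability = probability
        self.lstm_params = lstm_params
        self.seed = seed

    # -- shared helpers ------------------------------------------------------

    def normalized_text(self, tweet) -> str:
        """Classic-normalized join of one tweet (the LR comparison string)."""
        res = self.resources or Resources()
        return classic_normalize(
            tweet, res.names, res.patterns, res.wordlists
        ).joined()

    def _classic_pairs(self, corpus: Corpus):
        res = self.resources or Resources()
        return [
            (
                t.text,
                classic_normalize(t, res.names, res.patterns, res.wordlists).tokens,
            )
            for t in corpus
        ]

    def _embed_tokens(self, corpus: Corpus):
        return [embed_normalize(t).tokens for t in corpus]

    # -- estimator API -------------------------------------------------------

    def fit(self, train: Corpus, anchors: list[str] | None = None):
        res = self.resources or Resources()
        plan = self.sampling_plan or SamplingPlan(method="none")
        if plan.method not in ("smote", "none"):
            train = apply_plan(
                train, plan, anchors=anchors, text_fn=self.normalized_text
            )
        self.train_size_ = len(train)
        y = np.asarray(train.labels, dtype=object)

        if self.classifier == "lstm":
            tokens = self._embed_tokens(train)
            params = dict(self.lstm_params or {})
            self.model_ = LSTMTweetClassifier(
                embeddings=res.embeddings, seed=self.seed, **params
            ).fit(tokens, y)
            return self

        pairs = self._classic_pairs(train)
        self.featurizer_ = TweetFeaturizer(
            use_ngrams=self.use_ngrams,
            use_clusters=self.use_clusters,
            use_lengths=self.use_lengths,
            binary=self.binary,
            min_df=self.min_df,
            cluster_table=res.clusters,
        ).fit(pairs)
        X = self.featurizer_.transform(pairs)

        self.scaler_ = None
        if self.classifier == "svm":
            self.scaler_ = BoundedScaler().fit(X)
            X = self.scaler_.transform(X)

        if plan.method == "smote":
            X, y = SMOTEOverSampler(seed=plan.seed).fit_resample(X, y)
            self.train_size_ = X.shape[0]

        if self.classifier == "nb":
            self.model_ = NaiveBayesTweetClassifier().fit(X, y)
        elif self.classifier == "svm":
            self.model_ = SVMTweetClassifier(
                c=self.svm_c,
                class_weight=self.class_weight,
                probability=self.probability,
                seed=self.seed,
                check_scaling=False,  # scaled in-pipeline just above
            ).fit(X, y)
        else:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        return self

    def _transform(self, corpus: Corpus):
        if self.classifier == "lstm":
            return self._embed_tokens(corpus)
        X = self.featurizer_.transform(self._classic_pairs(corpus))
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return X

    def predict(self, corpus: Corpus):
        return self.model_.predict(self._transform(corpus))

    def predict_proba(self, corpus: Corpus):
        return self.model_.predict_proba(self._transform(corpus))

    @property
    def classes_(self):
        return self.model_.classes_
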