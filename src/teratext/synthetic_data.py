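"""Seeded generator of synthetic labeled tweet corpora.

The generator emulates the statistical and linguistic structure the
classifiers exploit: a ~5%/5%/90% three-class imbalance, lexicon terms in
every tweet, possessive + child references in "defect" tweets, ambiguous
names/pronouns and hedging in "possible defect" tweets, reported speech,
fundraisers and near-duplicate headline clusters in "non defect" tweets,
plus hashtag-fused references, usernames, URLs and retweets at configurable
rates. Templates are data (a bundled slot-bearing pattern file), not code.

It makes no claim of realistic language: performance on this corpus
demonstrates signal flow through the pipeline, not real-tweet accuracy.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import ClusterTable, Corpus, LabeledTweet, Lexicon, NameLexicon
from .corpus_io import read_lexicon, read_names
from .preprocess import classic_normalize, _PLACEHOLDER_RE
from .retrieval import build_patterns

_DATA = importlib.resources.files("teratext") / "data"

#: planted misspelling pairs (canonical word -> misspelled surface form);
#: the synthetic cluster table assigns both the same cluster path
MISSPELLING_PAIRS = {
    "surgery": "surgerey",
    "doctors": "docters",
    "hospital": "hostpital",
}

_HASHTAGS = ("#blessed", "#nicu", "#love", "#momlife", "#awareness")
_DUP_EXTRAS = ("today", "tonight", "again", "update")


def bundled_lexicon() -> Lexicon:
    return read_lexicon(
        str(_DATA / "lexicon.txt"), str(_DATA / "lexicon_variants.txt")
    )


def bundled_names() -> NameLexicon:
    return read_names(str(_DATA / "names.txt"))


def load_templates() -> dict[str, dict[str, list[str]]]:
    """label -> category -> template strings, from the bundled pattern file."""
    out: dict[str, dict[str, list[str]]] = {}
    for line in (_DATA / "templates.txt").read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        label, category, template = line.split("\t", 2)
        out.setdefault(label, {}).setdefault(category, []).append(template)
    return out


@dataclass
class GeneratorSpec:
    """The stated world of the synthetic corpus.

    Class proportions default to the natural retrieval imbalance
    (~5.2% / 5.2% / 89.6%). Phenomenon knobs are fractions of their class;
    the per-class categorical remainder goes to the plain templates.
    """

    n_tweets: int = 1000
    proportions: tuple[float, float, float] = (0.052, 0.052, 0.896)
    seed: int = 0
    # defect-class phenomena
    implicit_having_frac: float = 0.25
    hashtag_fused_frac: float = 0.15
    modifier_interrupted_frac: float = 0.10
    # possible-defect phenomena
    name_only_frac: float = 0.50
    # non-defect phenomena
    reported_speech_frac: float = 0.25
    fundraiser_frac: float = 0.20
    near_duplicate_frac: float = 0.15
    duplicate_cluster_size: int = 5
    # surface decorations
    username_rate: float = 0.10
    url_rate: float = 0.15
    hashtag_rate: float = 0.10
    retweet_rate: float = 0.0
    misspelling_rate: float = 0.05
    label_noise: float = 0.0
    lexicon: Lexicon | None = None

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        fracs = (
            self.implicit_having_frac, self.hashtag_fused_frac,
            self.modifier_interrupted_frac, self.name_only_frac,
            self.reported_speech_frac, self.fundraiser_frac,
            self.near_duplicate_frac, self.username_rate, self.url_rate,
            self.hashtag_rate, self.retweet_rate, self.misspelling_rate,
            self.label_noise,
        )
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if (
            self.implicit_having_frac
            + self.hashtag_fused_frac
            + self.modifier_interrupted_frac
            > 1.0
        ):
            raise ValueError("defect-class phenomenon fractions exceed 1")


def largest_remainder_counts(n: int, proportions) -> list[int]:
    """Integer class counts summing to n, by largest-remainder rounding."""
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(short):
        base[order[i]] += 1
    return base.tolist()


class SyntheticCorpusGenerator:
    """Deterministic corpus factory for one :class:`GeneratorSpec`."""

    def __init__(self, spec: GeneratorSpec):
        self.spec = spec
        self.lexicon = spec.lexicon or bundled_lexicon()
        self.names = bundled_names()
        self.templates = load_templates()
        self._name_list = sorted(self.names.names)

    # -- slot filling --------------------------------------------------------

    def _fill(self, template: str, rng) -> str:
        term = self.lexicon.terms[rng.integers(len(self.lexicon.terms))]
        fused = re.sub(r"[\s\-]+", "", term)
        text = template.format(
            term=term,
            fused_term=fused,
            name=self._name_list[rng.integers(len(self._name_list))].capitalize(),
            fppron=("My" if rng.random() < 0.7 else "Our"),
            child=("son", "daughter", "baby", "child", "kid")[rng.integers(5)],
        )
        if rng.random() < self.spec.misspelling_rate:
            canon = list(MISSPELLING_PAIRS)[rng.integers(len(MISSPELLING_PAIRS))]
            text = re.sub(
                rf"\b{canon}\b", MISSPELLING_PAIRS[canon], text, count=1
            )
        return text

    def _decorate(self, text: str, rng) -> str:
        s = self.spec
        if rng.random() < s.hashtag_rate:
            text += " " + _HASHTAGS[rng.integers(len(_HASHTAGS))]
        if rng.random() < s.username_rate:
            text += f" @user{rng.integers(1000):03d}"
        if rng.random() < s.url_rate:
            text += f" http://t.co/{rng.integers(10**6):06x}"
        if rng.random() < s.retweet_rate:
            text = f"RT @user{rng.integers(1000):03d}: " + text
        return text

    def _pick(self, label: str, category_probs: list[tuple[str, float]], rng) -> str:
        u = rng.random()
        acc = 0.0
        chosen = None
        for cat, p in category_probs:
            acc += p
            if u < acc:
                chosen = cat
                break
        if chosen is None:
            chosen = category_probs[-1][0]
        options = self.templates[label][chosen]
        return options[rng.integers(len(options))]

    # -- generation ----------------------------------------------------------

    def generate(self) -> Corpus:
        s = self.spec
        rng = np.random.default_rng(s.seed)
        n_def, n_pos, n_neg = largest_remainder_counts(s.n_tweets, s.proportions)

        n_dup = int(round(s.near_duplicate_frac * n_neg))
        if 0 < n_dup < s.duplicate_cluster_size and n_dup != 0:
            raise ValueError(
                "near-duplicate fraction too small for one duplicate cluster"
            )

        texts_labels: list[tuple[str, str]] = []
        for _ in range(n_def):
            rest = 1.0 - (
                s.implicit_having_frac
                + s.hashtag_fused_frac
                + s.modifier_interrupted_frac
            )
            tpl = self._pick(
                "defect",
                [
                    ("implicit", s.implicit_having_frac),
                    ("hashtag_fused", s.hashtag_fused_frac),
                    ("modifier", s.modifier_interrupted_frac),
                    ("plain", rest),
                ],
                rng,
            )
            texts_labels.append((self._decorate(self._fill(tpl, rng), rng), "defect"))
        for _ in range(n_pos):
            rest = 1.0 - s.name_only_frac
            tpl = self._pick(
                "possible_defect",
                [("name", s.name_only_frac), ("pronoun", rest / 2), ("hedge", rest / 2)],
                rng,
            )
            texts_labels.append(
                (self._decorate(self._fill(tpl, rng), rng), "possible_defect")
            )
        # near-duplicate headline clusters first, then singleton negatives
        n_made = 0
        while n_made + s.duplicate_cluster_size <= n_dup:
            tpl = self._pick("non_defect", [("headline", 1.0)], rng)
            base = self._fill(tpl, rng)
            for _ in range(s.duplicate_cluster_size):
                variant = base
                if rng.random() < 0.8:
                    variant = base + " " + _DUP_EXTRAS[rng.integers(len(_DUP_EXTRAS))]
                texts_labels.append((self._decorate(variant, rng), "non_defect"))
                n_made += 1
        for _ in range(n_neg - n_made):
            rest = 1.0 - (s.reported_speech_frac + s.fundraiser_frac)
            tpl = self._pick(
                "non_defect",
                [
                    ("reported", s.reported_speech_frac),
                    ("fundraiser", s.fundraiser_frac),
                    ("headline", rest / 2),
                    ("other", rest / 2),
                ],
                rng,
            )
            texts_labels.append(
                (self._decorate(self._fill(tpl, rng), rng), "non_defect")
            )

        order = rng.permutation(len(texts_labels))
        n_users = max(1, s.n_tweets // 3)
        tweets = []
        labels_pool = ("defect", "possible_defect", "non_defect")
        for new_id, i in enumerate(order):
            text, label = texts_labels[i]
            if s.label_noise > 0 and rng.random() < s.label_noise:
                others = [l for l in labels_pool if l != label]
                label = others[rng.integers(2)]
            tweets.append(
                LabeledTweet(
                    tweet_id=f"t{new_id:06d}",
                    user_id=f"u{rng.integers(n_users):05d}",
                    text=text,
                    label=label,
                )
            )
        return Corpus(tweets, provenance=f"synthetic(seed={s.seed}, n={s.n_tweets})")

    # -- fixture counterparts of the external resources ----------------------

    def normalized_vocabulary(self, corpus: Corpus | None = None) -> list[str]:
        corpus = corpus or self.generate()
        patterns = build_patterns(self.lexicon)
        vocab: set[str] = set()
        for tweet in corpus:
            for tok in classic_normalize(tweet, self.names, patterns).tokens:
                if not _PLACEHOLDER_RE.match(tok):
                    vocab.add(tok)
        return sorted(vocab)

    def generate_cluster_table(self, corpus: Corpus | None = None) -> ClusterTable:
        """Cluster table covering the classic-normalized vocabulary of the
        generated corpus; planted misspellings share the canonical path."""
        vocab = self.normalized_vocabulary(corpus)
        if not vocab:
            raise ValueError("empty vocabulary")
        # stem pairs through the same normalizer used at lookup time
        stemmed_pairs = {}
        for canon, missp in MISSPELLING_PAIRS.items():
            c = classic_normalize(canon).tokens
            m = classic_normalize(missp).tokens
            if c and m:
                stemmed_pairs[m[0]] = c[0]
        paths: dict[str, str] = {}
        canon_words = [w for w in vocab if w not in stemmed_pairs]
        for i, word in enumerate(canon_words):
            paths[word] = format(i, "012b")
        for missp, canon in stemmed_pairs.items():
            if canon in paths:
                paths[missp] = paths[canon]
        return ClusterTable(paths=paths)

    def generate_names(self) -> NameLexicon:
        return self.names


def generate(spec: GeneratorSpec) -> Corpus:
    """Generate a seeded synthetic corpus (functional wrapper)."""
    return SyntheticCorpusGenerator(spec).generate()


def generate_cluster_table(spec: GeneratorSpec) -> ClusterTable:
    return SyntheticCorpusGenerator(spec).generate_cluster_table()


def generate_names(spec: GeneratorSpec) -> NameLexicon:
    return SyntheticCorpusGenerator(spec).generate_names()
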