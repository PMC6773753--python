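"""Two tweet-normalization tracks.

The *classic* track feeds the sparse-feature (Naive Bayes / SVM) models:
usernames, URLs, lexicon-matched birth-defect spans, given names and
personal-deixis words become protected placeholder tokens
(``_username_, _url_, _malformation_, _name_, _fppron_, _child_,
_tppron_``), then text is lowercased, stripped of non-alphabetic characters
(underscore whitelisted so placeholders survive) and Porter-stemmed.

The *embedding* track feeds the sequence model and mirrors the conventions
of pretrained tweet embeddings: ``<USER> <URL> <NUMBER> <REPEAT> <ELONG>
<HASHTAG>`` markers, slash spacing, repeated-punctuation marking, trimming
letters repeated more than three times, then PTB-style tokenization and
lowercasing (markers stay verbatim).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

from sklearn.base import BaseEstimator, TransformerMixin

from ._stem import porter_stem
from .corpus_io import Corpus, LabeledTweet, NameLexicon
from .retrieval import LexiconPattern

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_USERNAME_RE = re.compile(r"@\w+")
_PLACEHOLDER_RE = re.compile(r"^_[a-z]+_$")

PLACEHOLDERS = (
    "_username_", "_url_", "_malformation_", "_name_",
    "_fppron_", "_child_", "_tppron_",
)


@dataclass(frozen=True)
class DeixisWordlists:
    """Word sets collapsed to generalized deixis placeholders.

    Defaults cover the common possessives, child references and third-person
    pronouns; all three are configurable.
    """

    fppron: frozenset[str] = frozenset({"my", "our"})
    child: frozenset[str] = frozenset({"son", "daughter", "child", "baby", "kid"})
    tppron: frozenset[str] = frozenset({"she", "he", "her", "him", "his", "hers"})


@dataclass
class ClassicNormText:
    """Output of the classic track: lowercase stemmed tokens + placeholders."""

    tokens: list[str]

    def joined(self) -> str:
        return " ".join(self.tokens)


@dataclass
class EmbedNormText:
    """Output of the embedding track: lowercase tokens with <MARKER> tokens."""

    tokens: list[str]


def stem(token: str) -> str:
    """Porter-stem one lowercase token; placeholders pass through unchanged."""
    if _PLACEHOLDER_RE.match(token):
        return token
    return porter_stem(token)


def _word_alternation(words, hashtag_blind: bool = True) -> re.Pattern | None:
    if not words:
        return None
    alts = "|".join(re.escape(w) for w in sorted(words, key=len, reverse=True))
    lookbehind = r"(?<![\w#])" if hashtag_blind else r"(?<!\w)"
    return re.compile(rf"{lookbehind}(?:{alts})(?!\w)", re.IGNORECASE)


def classic_normalize(
    tweet: LabeledTweet | str,
    names: NameLexicon | None = None,
    patterns: list[LexiconPattern] | None = None,
    wordlists: DeixisWordlists | None = None,
) -> ClassicNormText:
    """Apply the classic normalization pipeline to one tweet.

    Order: usernames/URLs -> lexicon spans -> names -> deixis words ->
    lowercase -> strip non-alphabetic (keep underscores) -> stem.
    Name matching is whole-word and skipped inside hashtag-fused tokens.
    """
    text = tweet.text if isinstance(tweet, LabeledTweet) else tweet
    text = unicodedata.normalize("NFC", text)
    wordlists = wordlists or DeixisWordlists()

    text = _URL_RE.sub(" _url_ ", text)
    text = _USERNAME_RE.sub(" _username_ ", text)
    if patterns:
        for p in patterns:
            text = p.pattern.sub(" _malformation_ ", text)
    if names is not None:
        name_rx = _word_alternation(names.names)
        if name_rx is not None:
            text = name_rx.sub(" _name_ ", text)
    for words, placeholder in (
        (wordlists.fppron, " _fppron_ "),
        (wordlists.child, " _child_ "),
        (wordlists.tppron, " _tppron_ "),
    ):
        rx = _word_alternation(words)
        if rx is not None:
            text = rx.sub(placeholder, text)
    text = text.lower()
    text = re.sub(r"[^a-z_\s]", "", text)
    tokens = [stem(tok) for tok in text.split()]
    return ClassicNormText(tokens=tokens)


# --- embedding track -------------------------------------------------------

_NUMBER_RE = re.compile(r"(?<![\w.])\d+(?:[.,:]\d+)*(?![\w.])")
# repeated punctuation; angle brackets excluded so inserted markers survive
_PUNCT_REPEAT_RE = re.compile(r"([!?.,;:'\"*&%$^~`|\\)(\[\]{}_+=-])\1+")
_ELONG_WORD_RE = re.compile(r"\w*(\w)\1{3,}\w*")
_TOKEN_RE = re.compile(r"<[A-Z]+>|\w+(?:'\w+)?|[^\w\s]")


def embed_normalize(tweet: LabeledTweet | str) -> EmbedNormText:
    """Apply the embedding-track normalization to one tweet.

    Order: usernames/URLs -> slash spacing -> numbers -> repeated
    punctuation -> elongation trimming -> hashtag replacement -> tokenize ->
    lowercase.
    """
    text = tweet.text if isinstance(tweet, LabeledTweet) else tweet
    text = unicodedata.normalize("NFC", text)
    text = _URL_RE.sub(" <URL> ", text)
    text = _USERNAME_RE.sub(" <USER> ", text)
    text = text.replace("/", " / ")
    text = _NUMBER_RE.sub(" <NUMBER> ", text)
    text = _PUNCT_REPEAT_RE.sub(r"\1 <REPEAT> ", text)

    def _trim(m: re.Match) -> str:
        return re.sub(r"(\w)\1{3,}", r"\1\1\1", m.group(0)) + " <ELONG> "

    text = _ELONG_WORD_RE.sub(_trim, text)
    text = text.replace("#", " <HASHTAG> ")
    tokens = [
        tok if tok.startswith("<") and tok.endswith(">") else tok.lower()
        for tok in _TOKEN_RE.findall(text)
    ]
    return EmbedNormText(tokens=tokens)


# --- sklearn-style transformers --------------------------------------------


class ClassicNormalizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: tweets -> classic-track token lists."""

    def __init__(self, names=None, patterns=None, wordlists=None):
        self.names = names
        self.patterns = patterns
        self.wordlists = wordlists

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[list[str]]:
        items = X.tweets if isinstance(X, Corpus) else X
        return [
            classic_normalize(t, self.names, self.patterns, self.wordlists).tokens
            for t in items
        ]


class EmbedNormalizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: tweets -> embedding-track token lists."""

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[list[str]]:
        items = X.tweets if isinstance(X, Corpus) else X
        return [embed_normalize(t).tokens for t in items]
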