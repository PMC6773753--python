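"""Lexicon-based retrieval of tweets that mention a birth defect.

Each lexicon term (with its lexical variants) compiles to one word-boundary
anchored, case-insensitive pattern. Multi-word terms tolerate whitespace or
hyphens between words, and also match hashtag-fused forms (``#clubfoot`` for
"club foot"). An optional trailing plural ``s`` is accepted. Retrieved
tweets are post-filtered: retweets are dropped, and matches that fall inside
a username (``@...``) or URL token do not count.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

from .corpus_io import Corpus, LabeledTweet, Lexicon

_RT_RE = re.compile(r"^RT @")
_USERNAME_TOKEN_RE = re.compile(r"@\w")
_URL_TOKEN_RE = re.compile(r"^(?:https?://|www\.)", re.IGNORECASE)


@dataclass
class LexiconPattern:
    """A compiled matcher for one lexicon term and its variants."""

    source_term: str
    pattern: re.Pattern

    def matches(self, text: str) -> bool:
        return self.pattern.search(text) is not None


@dataclass
class RetrievalHit:
    """A retrieved tweet with the character spans that matched (0-based,
    end-exclusive)."""

    tweet: LabeledTweet
    matched_spans: list[tuple[int, int, str]]


def _term_alternative(surface: str) -> str:
    """Regex alternative for one surface form (term or variant)."""
    words = [re.escape(w) for w in re.split(r"[\s\-]+", surface.strip()) if w]
    if not words:
        raise ValueError(f"term {surface!r} compiles to an empty pattern")
    spaced = r"[\s\-]+".join(words)
    if len(words) == 1:
        return spaced
    # fused form: the words collapsed, preceded by '#' or '@'
    # ('#clubfoot', '@downsyndromeorg'); the '@' case exists so the
    # username post-filter sees the match and can reject the tweet
    fused = "".join(words)
    return f"(?:{spaced}|(?<=[#@]){fused})"


def build_patterns(lexicon: Lexicon) -> list[LexiconPattern]:
    """Compile one :class:`LexiconPattern` per term, folding variants in."""
    patterns = []
    seen_terms = set(lexicon.terms)
    for term in lexicon.terms:
        surfaces = [term] + lexicon.variants.get(term, [])
        alts = "|".join(_term_alternative(s) for s in surfaces)
        rx = re.compile(rf"(?<!\w)(?:{alts})s?(?!\w)", re.IGNORECASE)
        if rx.search(term) is None:
            raise ValueError(f"pattern for {term!r} does not match its own term")
        patterns.append(LexiconPattern(source_term=term, pattern=rx))
    # variants whose key term is not in the lexicon stand alone
    for term, variants in lexicon.variants.items():
        if term in seen_terms:
            continue
        alts = "|".join(_term_alternative(s) for s in variants)
        rx = re.compile(rf"(?<!\w)(?:{alts})s?(?!\w)", re.IGNORECASE)
        patterns.append(LexiconPattern(source_term=term, pattern=rx))
    return patterns


def find_spans(
    text: str, patterns: list[LexiconPattern]
) -> list[tuple[int, int, str]]:
    """All pattern matches in NFC-normalized ``text``, sorted by position."""
    spans = []
    for p in patterns:
        for m in p.pattern.finditer(text):
            spans.append((m.start(), m.end(), p.source_term))
    return sorted(spans)


def is_retweet(text: str) -> bool:
    return _RT_RE.match(text.lstrip()) is not None


def _excluded_token_spans(text: str) -> list[tuple[int, int]]:
    """Character spans of username and URL tokens (whitespace-delimited)."""
    spans = []
    for m in re.finditer(r"\S+", text):
        tok = m.group()
        if _USERNAME_TOKEN_RE.match(tok) or _URL_TOKEN_RE.match(tok):
            spans.append((m.start(), m.end()))
    return spans


def retrieve(corpus: Corpus, patterns: list[LexiconPattern]) -> list[RetrievalHit]:
    """Select tweets mentioning a lexicon term, excluding retweets and
    matches that overlap username/URL tokens.

    Deterministic; output order follows corpus order.
    """
    hits = []
    for tweet in corpus:
        text = unicodedata.normalize("NFC", tweet.text)
        if is_retweet(text):
            continue
        spans = find_spans(text, patterns)
        if not spans:
            continue
        bad = _excluded_token_spans(text)
        kept = [
            s for s in spans
            if not any(s[0] < e and b < s[1] for (b, e) in bad)
        ]
        if kept:
            hits.append(RetrievalHit(tweet=tweet, matched_spans=kept))
    return hits
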