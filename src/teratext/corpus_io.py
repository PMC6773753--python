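"""Readers and writers for corpora, lexicons, word-cluster tables and name
lists, plus the run configuration shared by the CLI and the experiment
harness.

The corpus format is tab-separated UTF-8 with a header row naming the four
columns ``tweet_id, user_id, text, label``. Labels are case-folded on read;
the three recognised classes are ``defect``, ``possible_defect`` and
``non_defect``. Malformed rows (empty text, unknown label) are counted and
reported in the load summary rather than silently dropped.
"""

from __future__ import annotations

import logging
import unicodedata
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("teratext")

#: fixed class order used everywhere (confusion matrices, probabilities)
CLASS_ORDER: tuple[str, str, str] = ("defect", "possible_defect", "non_defect")

_LABEL_ALIASES = {
    "defect": "defect",
    "+": "defect",
    "possible_defect": "possible_defect",
    "possible defect": "possible_defect",
    "?": "possible_defect",
    "non_defect": "non_defect",
    "non-defect": "non_defect",
    "nondefect": "non_defect",
    "-": "non_defect",
}


def normalize_label(raw: str) -> str:
    """Case-fold a label string to one of the three canonical classes.

    Raises ``ValueError`` for unrecognised labels.
    """
    key = raw.strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unknown label {raw!r}")
    return _LABEL_ALIASES[key]


@dataclass(frozen=True)
class LabeledTweet:
    """One tweet: opaque ids, raw text and an optional 3-way label."""

    tweet_id: str
    user_id: str
    text: str
    label: str | None = None

    def __post_init__(self):
        if not self.text.strip():
            raise ValueError("tweet text is empty")
        if self.label is not None and self.label not in CLASS_ORDER:
            raise ValueError(f"label must be one of {CLASS_ORDER}, got {self.label!r}")


@dataclass
class Corpus:
    """An ordered collection of tweets with a provenance tag."""

    tweets: list[LabeledTweet]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.tweets)

    def __iter__(self):
        return iter(self.tweets)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Corpus(self.tweets[i], self.provenance)
        return self.tweets[i]

    @property
    def labels(self) -> list[str | None]:
        return [t.label for t in self.tweets]

    @property
    def texts(self) -> list[str]:
        return [t.text for t in self.tweets]

    def class_counts(self) -> dict[str, int]:
        c = Counter(t.label for t in self.tweets if t.label is not None)
        return {k: c.get(k, 0) for k in CLASS_ORDER}

    def subset(self, labels: Iterable[str]) -> "Corpus":
        keep = set(labels)
        return Corpus([t for t in self.tweets if t.label in keep], self.provenance)


@dataclass
class LoadSummary:
    """Bookkeeping produced by :func:`read_corpus`."""

    n_rows: int
    n_loaded: int
    n_rejected: int
    rejected_reasons: dict[str, int]
    class_counts: dict[str, int]


@dataclass
class Lexicon:
    """Birth-defect terms plus per-term lexical variants (misspellings etc.)."""

    terms: list[str]
    variants: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.terms:
            raise ValueError("lexicon has no terms")
        if any(not t for t in self.terms):
            raise ValueError("lexicon contains an empty term")


@dataclass
class ClusterTable:
    """Word -> hierarchical cluster-path (bit-string) lookup, case-normalized."""

    paths: dict[str, str]
    counts: dict[str, int] = field(default_factory=dict)

    def lookup(self, word: str) -> str | None:
        return self.paths.get(word.lower())

    def __len__(self) -> int:
        return len(self.paths)


@dataclass
class NameLexicon:
    """Set of lowercase given names used for the ``_name_`` normalization."""

    names: frozenset[str]

    def __post_init__(self):
        if not self.names:
            raise ValueError("name lexicon is empty")

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.names

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class RunConfig:
    """Flat configuration for an end-to-end run; every stochastic stage
    derives its substream from the single ``seed``."""

    corpus_path: str = ""
    lexicon_path: str = ""
    variants_path: str | None = None
    clusters_path: str | None = None
    names_path: str | None = None
    test_fraction: float = 0.2
    dev_fraction: float = 0.2
    seed: int = 42
    sampling_method: str = "none"
    sampling_k: float | None = None
    sampling_target_size: int | None = None
    classifier: str = "svm"
    svm_c: float = 100.0
    use_ngrams: bool = True
    use_clusters: bool = True
    use_lengths: bool = True

    def __post_init__(self):
        for f in (self.test_fraction, self.dev_fraction):
            if not (0.0 < f < 1.0):
                raise ValueError("split fractions must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers


def read_corpus(
    path: str | Path,
    delimiter: str = "\t",
    labeled: bool = True,
) -> tuple[Corpus, LoadSummary]:
    """Read a delimited tweet file into a :class:`Corpus`.

    The header must name ``tweet_id, user_id, text`` and, for labeled data,
    ``label``. Rows with empty text or unrecognised labels are rejected and
    counted in the returned :class:`LoadSummary`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    required = {"tweet_id", "user_id", "text"} | ({"label"} if labeled else set())
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"corpus file missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"corpus file {path} has no rows")

    tweets: list[LabeledTweet] = []
    reasons: Counter[str] = Counter()
    for row in df.itertuples(index=False):
        text = unicodedata.normalize("NFC", str(row.text))
        if not text.strip():
            reasons["empty_text"] += 1
            continue
        label = None
        if labeled:
            raw = str(getattr(row, "label"))
            try:
                label = normalize_label(raw)
            except ValueError:
                reasons["unknown_label"] += 1
                continue
            if raw.strip() != label:
                logger.warning("label %r normalized to %r", raw, label)
        tweets.append(LabeledTweet(str(row.tweet_id), str(row.user_id), text, label))

    corpus = Corpus(tweets, provenance=str(path))
    summary = LoadSummary(
        n_rows=len(df),
        n_loaded=len(tweets),
        n_rejected=len(df) - len(tweets),
        rejected_reasons=dict(reasons),
        class_counts=corpus.class_counts(),
    )
    if summary.n_rejected:
        logger.warning("rejected %d malformed rows: %s", summary.n_rejected, dict(reasons))
    return corpus, summary


def write_corpus(corpus: Corpus, path: str | Path, delimiter: str = "\t") -> None:
    """Write a corpus back to the tab-separated format (round-trips read_corpus)."""
    df = pd.DataFrame(
        {
            "tweet_id": [t.tweet_id for t in corpus],
            "user_id": [t.user_id for t in corpus],
            "text": [t.text for t in corpus],
            "label": [t.label if t.label is not None else "" for t in corpus],
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


def read_lexicon(
    term_path: str | Path, variants_path: str | Path | None = None
) -> Lexicon:
    """Read one-term-per-line lexicon, lowercased and deduplicated in file
    order, with an optional tab-separated ``term<TAB>variant`` file merged in.

    A variant line whose term is not in the lexicon stands alone as an extra
    pattern (recorded under its own term).
    """
    terms: list[str] = []
    seen: set[str] = set()
    for line in Path(term_path).read_text(encoding="utf-8").splitlines():
        term = line.strip().lower()
        if term and term not in seen:
            terms.append(term)
            seen.add(term)
    if not terms:
        raise ValueError(f"lexicon file {term_path} is empty")
    variants: dict[str, list[str]] = {}
    if variants_path is not None:
        for line in Path(variants_path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 2:
                term, var = parts[0].strip().lower(), parts[1].strip().lower()
            else:
                term = var = parts[0].strip().lower()
            if var and var not in variants.setdefault(term, []):
                variants[term].append(var)
    return Lexicon(terms=terms, variants=variants)


def read_clusters(path: str | Path) -> ClusterTable:
    """Read a TSV of ``cluster-path<TAB>word[<TAB>count]`` rows.

    Duplicate words keep their first path.
    """
    paths: dict[str, str] = {}
    counts: dict[str, int] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            continue
        cpath, word = parts[0].strip(), parts[1].strip().lower()
        if word and word not in paths:
            paths[word] = cpath
            if len(parts) > 2:
                try:
                    counts[word] = int(parts[2])
                except ValueError:
                    pass
    if not paths:
        raise ValueError(f"cluster file {path} is empty")
    return ClusterTable(paths=paths, counts=counts)


def read_names(path: str | Path) -> NameLexicon:
    """Read a one-name-per-line given-names list (lowercased, deduplicated)."""
    names = {
        line.strip().lower()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }
    if not names:
        raise ValueError(f"names file {path} is empty")
    return NameLexicon(names=frozenset(names))
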