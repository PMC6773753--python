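import pytest

from teratext.corpus_io import Corpus, LabeledTweet, Lexicon, NameLexicon
from teratext.pipeline import Resources
from teratext.retrieval import build_patterns
from teratext.synthetic_data import GeneratorSpec, SyntheticCorpusGenerator


@pytest.fixture(scope="session")
def tiny_lexicon():
    return Lexicon(
        terms=[
            "chd", "club foot", "down syndrome", "dwarfism", "gastroschisis",
            "hydrocephalus", "microcephaly", "trisomy 18", "spina bifida",
            "craniosynostosis",
        ],
        variants={"hydrocephalus": ["hydrocephalis"]},
    )


@pytest.fixture(scope="session")
def patterns(tiny_lexicon):
    return build_patterns(tiny_lexicon)


@pytest.fixture(scope="session")
def names():
    return NameLexicon(frozenset({"emma", "liam", "olivia", "noah", "ava"}))


def make_corpus(rows):
    """rows: list of (text, label) -> Corpus with sequential ids."""
    return Corpus(
        [
            LabeledTweet(f"t{i}", f"u{i % 7}", text, label)
            for i, (text, label) in enumerate(rows)
        ]
    )


@pytest.fixture(scope="session")
def generator():
    return SyntheticCorpusGenerator(GeneratorSpec(n_tweets=1200, seed=11))


@pytest.fixture(scope="session")
def synthetic_corpus(generator):
    return generator.generate()


@pytest.fixture(scope="session")
def synthetic_resources(generator, synthetic_corpus):
    return Resources(
        patterns=build_patterns(generator.lexicon),
        names=generator.names,
        clusters=generator.generate_cluster_table(synthetic_corpus),
    )
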