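# teratext

Tools for detecting, among tweets that mention birth defects, those in
which the user reports their **own child's** birth-defect outcome. This is
the tweet-level filtering step of social-media cohort studies in birth-defect
epidemiology: given posts retrieved by a lexicon of congenital-anomaly
terms, separate genuine self-reports from the ~90% of posts that merely
mention a defect (news, fundraisers, reported speech).

Tweets fall into three classes:

- **defect** — the tweet indicates the user's child has the mentioned
  anomaly (*"My son has hydrocephalus"*),
- **possible_defect** — the referent or diagnosis is ambiguous (*"Emma was
  diagnosed with craniosynostosis"* — whose child is Emma?),
- **non_defect** — a mere mention (headlines, awareness days, fundraisers).

## What is in the box

- **Retrieval** (`teratext.retrieval`) — word-boundary, case-insensitive
  patterns compiled from a term lexicon plus lexical variants, tolerant of
  hyphen/whitespace variation and hashtag-fused mentions (`#clubfoot`);
  post-filters drop retweets and matches inside usernames/URLs.
- **Preprocessing** (`teratext.preprocess`) — two tracks. The *classic*
  track (for sparse-feature models) replaces usernames, URLs,
  lexicon-matched spans, given names and personal-deixis words with
  protected placeholders (`_username_, _url_, _malformation_, _name_,
  _fppron_, _child_, _tppron_`), then lowercases, strips non-alphabetic
  characters and Porter-stems. The *embedding* track (for the sequence
  model) emits `<USER> <URL> <NUMBER> <REPEAT> <ELONG> <HASHTAG>` markers.
- **Features** (`teratext.features`) — word 1–3-grams, word-cluster
  indicators, character/word lengths; train-fitted min-max scaling with
  clipping; information-gain feature ranking.
- **Class imbalance** (`teratext.imbalance`) — five data-level strategies
  built on the Levenshtein ratio LR(a,b) = (lensum − lendist)/lensum:
  similarity under-sampling against the training set itself, similarity
  under-sampling against misclassified development-set anchors, random
  under-sampling, whole-set minority over-sampling, and SMOTE.
- **Models** (`teratext.models`) — Multinomial Naive Bayes, an RBF-kernel
  SVM (cost c = 100, minority-upweighted classes, pairwise-coupled
  probability calibration) and a pure-numpy LSTM (embedding → LSTM(128,
  tanh, last state) → dropout 0.5 → softmax; right-padding to 800 tokens,
  15 epochs).
- **Evaluation** (`teratext.evaluation`) — stratified splitting with
  per-class ceiling rounding, confusion matrices, per-class P/R/F1, the
  two-class collapse, PR curves with trapezoidal AUC, feature ablation and
  a sampling-strategy comparison harness.
- **Synthetic data** (`teratext.synthetic_data`) — a seeded template-based
  corpus generator (class imbalance, deixis phenomena, near-duplicate
  headlines, hashtag-fused mentions) with fixture cluster tables and name
  lists, so every stage is testable offline.

Everything is organised as sklearn-style estimators (`fit` / `predict` /
`transform`, `get_params`); module-level functions are thin wrappers.

## Worked example

```python
from teratext.synthetic_data import GeneratorSpec, SyntheticCorpusGenerator
from teratext.retrieval import build_patterns
from teratext.evaluation import (SplitSpec, stratified_split, confusion,
                                 metrics_from_confusion)
from teratext.pipeline import Resources, TweetPipeline

gen = SyntheticCorpusGenerator(GeneratorSpec(n_tweets=1000, seed=7))
corpus = gen.generate()
print(corpus.class_counts())
# {'defect': 52, 'possible_defect': 52, 'non_defect': 896}

res = Resources(patterns=build_patterns(gen.lexicon), names=gen.names,
                clusters=gen.generate_cluster_table(corpus))
train, dev, test = stratified_split(corpus, SplitSpec(seed=7))
pipe = TweetPipeline(resources=res, classifier="svm", seed=7).fit(train)
cm = confusion(test.labels, list(pipe.predict(test)))
for cls, m in metrics_from_confusion(cm).per_class.items():
    print(cls, m.rounded())
# defect (0.79, 1.0, 0.88)
# possible_defect (1.0, 0.73, 0.84)
# non_defect (1.0, 1.0, 1.0)
```

The class counts reproduce the natural ~5/5/90 retrieval imbalance; the
per-class (precision, recall, F1) rows show the weighted SVM recovering the
minority classes on held-out synthetic data — high here because templated
tweets are far easier than real ones.

The normalizer and the similarity primitive at the core:

```python
from teratext.preprocess import classic_normalize
from teratext.imbalance import levenshtein_ratio, undersample_similarity_all

classic_normalize("My son has hydrocephalus... so proud!",
                  names=gen.names, patterns=res.patterns).tokens
# ['_fppron_', '_child_', 'ha', '_malformation_', 'so', 'proud']

levenshtein_ratio("kitten", "sitting")   # 0.7692... = (13 - 3) / 13
len(undersample_similarity_all(corpus, k=0.8))   # 1000 -> 133
```

The under-sampling pass removes majority-class tweets whose LR to an
already-retained majority tweet exceeds k, collapsing the generator's
near-duplicate headline clusters while preserving every minority tweet.

There is also a CLI (`teratext simulate|retrieve|preprocess|sample|train|
evaluate|ablate`) over the same library; run `teratext --help`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic world from the seed, runs retrieval and the full
weighted-SVM pipeline on a stratified split, recomputes the confusion
matrix and per-class metrics from scratch, and writes the results JSON.

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
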