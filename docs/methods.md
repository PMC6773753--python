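# Methods

This note documents the models and procedures implemented in `teratext`,
the defaults chosen where the design was genuinely open, and what the test
suite does and does not establish.

## Task and data model

The unit of analysis is a single tweet known to mention a birth-defect
term. The classifier assigns one of three labels: `defect` (the user
reports their own child's anomaly), `possible_defect` (ambiguous referent
or unconfirmed diagnosis) and `non_defect` (mere mention). The natural
class distribution after lexicon retrieval is heavily imbalanced
(roughly 5% / 5% / 90%), and every design choice below follows from the
need to recover the two minority classes under that imbalance.

Corpora are tab-separated UTF-8 with a header
(`tweet_id, user_id, text, label`); labels case-fold on read and malformed
rows are counted, never silently dropped. Text is stored raw (NFC
normalized); both preprocessing tracks read from the same source.

## Retrieval

Each lexicon term and its lexical variants compile into one
case-insensitive pattern: words joined by `[\s-]+`, word-boundary anchored,
with an optional trailing plural `s`. Multi-word terms additionally match
their collapsed form after `#` or `@` so hashtag-fused mentions are found
and username-borne matches can be rejected by the post-filter. Post-filters:
a tweet is dropped when it is a retweet (left-stripped text matching
`^RT @`) or when every matched span overlaps a whitespace-delimited
username (`@...`) or URL (`http(s)://`, `www.`) token.

Whether the original retrieval allowed word-internal matches is unknown;
word-boundary anchoring with optional plural is this package's choice and
is configurable only by editing the pattern builder.

## Preprocessing

Classic track order: (1) usernames/URLs to `_username_`/`_url_`; (2)
lexicon-matched spans to `_malformation_` (hiding the specific anomaly so
the model cannot learn incidental term–class associations); (3) given
names to `_name_` (whole word, case-insensitive, skipped inside
hashtag-fused tokens); (4) deixis words to `_fppron_` {my, our},
`_child_` {son, daughter, child, baby, kid}, `_tppron_` {she, he, her,
him, his, hers} — all three sets configurable; (5) lowercase; (6) strip
everything but `[a-z_]` and whitespace (the underscore whitelist protects
placeholders; removal rather than space-splitting mirrors how hashtag-fused
tokens behave as single tokens); (7) Porter-stem non-placeholder tokens.

The relative order of (2)–(4) is not externally fixed; this package fixes
lexicon → names → deixis. "me" is deliberately not in the `_fppron_`
default (it marks first person but not possession); it can be added via
`DeixisWordlists`.

The Porter stemmer is implemented in-package (no stemmer library is
available in the runtime environment) following the classic five-step
algorithm, with words of length ≤ 2 passed through. Porter is not
idempotent (`agree → agre → agr`, `diagnosed → diagnos → diagno`), so
re-normalizing normalized text is equivalent to re-stemming each token;
the substitution and stripping stages are identity on their own output.
This is the precise form of the pipeline's idempotence property and is
what the test suite asserts.

Embedding track order (mirroring the conventions of pretrained tweet
embeddings): usernames/URLs → slash spacing → numbers → repeated
punctuation (`!!!` → `! <REPEAT>`) → elongation trimming (letters repeated
more than three times trimmed to three, `<ELONG>` appended) → hashtag
character to `<HASHTAG>` → PTB-style tokenization → lowercase (markers
verbatim). The tokenizer is a simplified PTB-style regex (markers, words
with internal apostrophes, single punctuation); it does not split
contractions.

## Features

Sparse features are namespaced and lexicographically ordered, so the
matrix layout is deterministic and instance-order invariant:

- `ngram:*` — contiguous word 1/2/3-grams over classic-track tokens, raw
  counts by default (a `binary` toggle exists; whether the original
  features were binary is unknown), minimum document frequency 1.
- `cluster:*` — counts over word-cluster paths (hierarchical bit-string
  labels grouping distributionally similar words, so misspellings share a
  feature); lookups use classic-normalized tokens with placeholders
  skipped, since placeholders exist in no external cluster table.
- `len:chars`, `len:words` — raw-text character length and token count.

Scaling is min-max fitted on training data only; constant columns map to
0 and out-of-range test values clip to [0, 1], keeping SVM inputs bounded.
Information gain uses presence/absence binarization:
IG(f) = H(y) − Σ_v p(f=v) H(y|f=v), ranked descending with name
tie-breaks; it equals mutual information in bits and is cross-checked
against an independent MI implementation in the tests.

## Class-imbalance strategies

Lexical similarity is the Levenshtein ratio
LR(a, b) = (lensum − lendist) / lensum with lensum = |a| + |b| and lendist
the classic insert/delete/substitute edit distance; LR is symmetric, lies
in [0, 1], is 1 exactly for identical strings, and is defined as 1 for the
degenerate both-empty input. LR is computed on classic-normalized text by
the pipeline (near-duplicates usually differ in usernames/URLs, which
normalization collapses); the samplers accept any text function.

1. **similarity_all** — scan majority tweets in corpus order; drop a tweet
   when its LR to any *retained earlier* majority tweet exceeds k
   (keep-first greedy). This removes repeated headlines/fundraisers
   without discarding distinct majority language. Note: under the
   keep-first rule the *set* of removed tweets need not shrink
   monotonically as k grows (a dropped tweet changes the retained
   reference set); on near-duplicate cluster structure the removed *count*
   is monotone, and that is what the tests assert.
2. **similarity_fn** — drop a majority tweet when its LR to any anchor
   exceeds k, where anchors are development-set minority tweets a
   preliminary classifier misclassified as majority (pruning the majority
   side of the linguistic boundary).
3. **random_under** — uniform without-replacement majority sampling to a
   target total size; used as the control for 1–2 at matched sizes (the
   comparison harness fills a missing target size from the most recent
   similarity run).
4. **oversample_replacement** — each minority class duplicated whole-set
   floor(majority/minority) times ("nearly equal"), order then shuffled.
5. **SMOTE** — synthetic minority rows x + u·(x_nn − x), u ~ U(0, 1), with
   x_nn among the 5 nearest same-class neighbours, generated until each
   minority class matches the majority count; implemented in-package (no
   imbalanced-learn in the environment) on sklearn's NearestNeighbors.

Methods 1–2 are O(n²) in the majority class with an exact length-gap
prefilter: LR ≤ 2·min(|a|,|b|)/(|a|+|b|), so pairs whose length gap
already bounds LR below k skip the DP entirely. The thresholds that
produce any particular under-sampled size are corpus-dependent parameters,
not targets.

## Classifiers

- **Naive Bayes** — multinomial with add-one smoothing over the raw count
  features (no scaling).
- **SVM** — RBF kernel, cost c = 100, per-class weights defaulting to
  inverse frequency N/(K·N_c), one-vs-one multiclass, trained on the
  scaled features (the estimator refuses unscaled input). Probabilities
  come from pairwise-coupled sigmoid calibration and may rarely disagree
  with the decision-rule prediction; PR curves use these calibrated
  scores.
- **LSTM** — trainable embedding (100-d; pretrained vectors seed known
  rows, out-of-vocabulary words start as zero vectors, all rows
  fine-tuned) → one LSTM layer (128 units, tanh), last hidden state only →
  dropout 0.5 → dense softmax; sequences right-zero-padded to 800 tokens
  (longer ones truncated and counted); 15 training epochs. The
  environment ships no neural-network framework, so forward and BPTT
  passes are implemented in numpy; training is deterministic given the
  seed. Optimizer choices are not externally fixed: Adam with learning
  rate 0.01 (chosen once for reliable convergence on short-sequence toy
  problems), batch size 32, categorical cross-entropy — all exposed as
  parameters.

Class order is fixed everywhere as (defect, possible_defect, non_defect).

## Evaluation

Stratified splitting holds out ceil(fraction · n) per class (test first,
then development from the remainder), with one seeded shuffle substream
per class. Ceiling rounding is the convention that maps per-class counts
(1192, 1196, 20611) at 20% to a 239 + 240 + 4123 = 4602-tweet test set.
Per-class precision/recall/F1 come from the one-vs-rest counts of the
confusion matrix (rows actual, columns predicted); undefined ratios
(empty denominator) report 0 with an explicit flag. Display rounding is
2-decimal half-up; raw values are retained. The two-class collapse merges
the minority classes into one positive class and evaluates a 2-class
prediction set — note this is not the same as collapsing a 3-class
confusion matrix, since a retrained 2-class model redistributes errors.
PR curves sweep thresholds over unique scores descending with a
(recall 0, precision 1) anchor; AUC is trapezoidal over recall, using the
best precision where several thresholds reach the same recall.

## Synthetic world

The generator emulates: the natural 5.2/5.2/89.6 class split (largest
remainder rounding); defect tweets built from possessive + child-reference
templates with a lexicon term, with knobs for implicit "having" relations
(0.25), hashtag-fused references (0.15) and modifier-interrupted
possessives (0.10); possible-defect tweets with name-only deixis (0.50)
or pronoun/hedging otherwise; non-defect tweets as reported speech (0.25),
fundraisers (0.20) and headlines, with near-duplicate headline clusters
(0.15 of the class, clusters of 5) for the similarity under-sampler to
collapse; usernames (0.10), URLs (0.15), hashtags (0.10), retweets (0 by
default) and planted misspellings (0.05) as surface decorations; label
noise 0. Knob defaults are fixed once from the qualitative error-analysis
inventory of the underlying study; where no rate is stated anywhere they
are single plausible choices, not fitted quantities.

Templates are data (a bundled slot-bearing pattern file). The fixture
cluster table assigns one bit-string path per classic-normalized
vocabulary word, with planted misspellings sharing their canonical word's
path; the name list is a bundled 40-name sample standing in for a
popular-given-names list.

What a green test establishes: that lexical signal placed in the corpus
flows through retrieval, normalization, features and the weighted SVM to
held-out minority-class F1 far above a label-shuffled control. What it
does not establish: performance on real tweets — templated language is
vastly easier than real social-media text (near-perfect synthetic F1
carries no claim about real-corpus scores).

## Numerical and degenerate-input conventions

- LR of two empty strings: 1.0 (documented convention; the formula is
  undefined at lensum = 0).
- Min-max scaling: zero-range columns → 0; out-of-range values clip.
- Undefined precision/recall → 0 with an `undefined` flag, never NaN.
- All randomness flows from a single integer seed; per-stage substreams
  derive deterministically (e.g. per-class seed sequences in splitting).
- Stemmer: words of length ≤ 2 unchanged; placeholders never stemmed.

## Known limitations

- No dependency parsing, coreference or cross-tweet deixis resolution;
  user-timeline aggregation is out of scope.
- The PTB-style tokenizer is a simplified contract, not the reference
  implementation.
- SMOTE densifies minority rows, so it is intended for desk-scale corpora.
- The LSTM is CPU-only numpy; at the default 800-token padding it is slow
  on large corpora (use shorter `seq_len` where tweets are short).
- Name detection is list-based; names outside the list are not normalized
  (the same recall gap the error analysis of the underlying task reports).
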