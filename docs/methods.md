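# Methods

This note documents the models implemented in `clinner`, the design of
the synthetic corpora, the numerical choices, and what the package's
tests do and do not demonstrate about real clinical data.

## Task and data model

The task is sentence-level named-entity recognition: every token gets an
IOB2 tag (`B-<type>` opens a mention, `I-<type>` continues it, `O` is
outside), and entity mentions are contiguous, non-overlapping token
spans with a type from a fixed inventory. Coordinates are 0-based,
half-open, at token level. Overlapping or discontinuous mentions are
rejected by the data model; tokenization of the synthetic corpora is
whitespace-based and case is preserved throughout (abbreviations such as
"DM" are case-bearing). An `I-X` tag not preceded by `B-X` or `I-X` —
possible in raw model output — is repaired to `B-X` before span
decoding, the standard IOB2 repair; this makes the tag-to-span decoder
total.

## Embedding spaces and combination operators

Word-form and lemma embedding spaces are trained separately on raw
(unannotated) token streams. Lookup is total: units outside the
vocabulary map to the all-zero vector, so downstream code never
branches on vocabulary membership. The three combination operators —
concatenation `(e_w(w), e_l(l))`, sum `e_w(w)+e_l(l)` and difference
`e_w(w)−e_l(l)` (the latter two requiring equal dimensions) — plus the
two single-space features give five input descriptors (W, L, (W,L),
W+L, W−L) selectable at run time. Two consequences of the zero-vector
rule are load-bearing and tested: `sum + subtract = 2·e_w(w)` for every
pair, and combining an OOV word under `sum` degrades gracefully to the
pure lemma vector.

Three trainers produce the same `EmbeddingSpace` container and are
interchangeable downstream:

* **word2vec** — skip-gram with negative sampling (5 negatives,
  unigram^0.75 noise distribution), mini-batched at 128 pairs with
  linearly decaying learning rate from 0.025. Small batches matter:
  with large batches, a word recurring many times per batch receives a
  summed update that acts like a multiplied learning rate and collapses
  small-vocabulary embeddings to rank one.
* **glove** — weighted least-squares factorisation of log co-occurrence
  counts (distance-weighted counts, weight `min(1, (x/100)^0.75)`),
  fitted by Adagrad; the exported vector is the sum of the word and
  context matrices.
* **fasttext** — the skip-gram objective with the centre word
  represented as the sum of its word vector and its character 3–5-gram
  vectors; exported vectors are the composed ones. OOV lookup still
  returns the zero vector (no subword inference at lookup time): the
  zero-vector rule is applied uniformly across algorithms.

Defaults are dimension 300 and window 5; the vocabulary cut-off
defaults to minimum count 1 because the synthetic corpora are small.
Similarities are reported rounded half-up to two decimals. 2-D
projections for inspection use scikit-learn PCA; nearest-neighbour
queries rank by cosine with lexicographic tie-breaks and exclude the
query term.

## The tagger

The sequence model is a character-aware bidirectional LSTM-CRF,
implemented in NumPy with explicit backpropagation (verified against
central-difference numerical gradients in the test suite):

1. **Character encoder** — each token's characters (unknown characters
   map to a reserved symbol; the character inventory comes from the
   training part only) pass through a character-level bi-LSTM; the
   final forward and backward states concatenate to a `2·h_char`
   vector. This supplies subword evidence: derivational suffixes that
   mark entity classes, and robustness to single-character misspellings.
2. **Input** — the character representation is concatenated with the
   word-level embedding feature chosen by the input descriptor; the
   word part is the zero vector for OOV units.
3. **Context encoder** — a word-level bi-LSTM (forward and backward
   runs over the padded, masked batch; state carries through padding so
   the last timestep holds the final real state).
4. **Decoder** — a linear projection to per-tag emission scores and a
   linear-chain CRF with transition, start and stop scores. The
   log-partition uses the forward recursion in log space; gradients use
   forward-backward marginals; decoding is Viterbi with ties broken
   toward the lower tag index.

**Training.** Mini-batch Adam (the optimiser is fixed here for
reproducibility) on the mean negative log-likelihood, gradient clipping
at global norm 5.0, inverted dropout on the word-LSTM input. Sentences
are bucketed by length once and batch order is shuffled per epoch. All
randomness — initialisation, shuffling, dropout — derives from the
single config seed, so reports are bit-reproducible. Defaults follow
the tuned values for this architecture: 300 LSTM hidden units, 100
character hidden units, character embedding dimension 100, learning
rate 0.005, dropout 0.5, batch size 30.

**Early stopping.** After each epoch the model is scored by exact-match
micro F1 on the development set; training stops after `patience = 3`
consecutive epochs without improvement (or at `max_epochs`), and the
parameters of the best dev epoch are restored. Two refinements:

* Ties keep the *latest* epoch's parameters. Dev F1 often plateaus
  exactly while training loss is still falling; among equally good dev
  scores the longer-trained model fits the training data better. A tie
  still counts as "no improvement" for the patience counter.
* `min_epochs` (default 1) is an optional burn-in before the stopping
  rule may fire. At small scale the dev score can sit at 0 for the
  first few epochs (the initialised model predicts all `O`), and
  patience would otherwise kill the run before lift-off. The scripted
  experiments use `min_epochs = 8`.

`grid_search` evaluates a finite config list exhaustively by best dev
F1 with ties toward the earlier entry.

## Evaluation

Entity-level scoring supports four criteria: exact (span and type both
exact), partial (any token overlap, any type), span-only and type-only.
Counting under relaxed criteria follows a MUC-style convention, fixed
here because prose descriptions of "partial match" rarely pin it down:
a predicted mention is a true positive iff it overlaps at least one
gold mention satisfying the type criterion; a gold mention is a false
negative iff no acceptable prediction overlaps it. Precision is
measured over predicted mentions and recall over gold mentions, so
relaxing criteria is monotone: partial F1 ≥ exact F1 on every input (a
tested invariant). Micro averages pool TP/FP/FN counts over types —
the convention under which a table's "Avg." row is not the arithmetic
mean of the per-type F1s. Per-type rows are reported only under
type-exact matching, where each true positive is attributable to one
type. A 0/0 precision or recall is reported as 0 with an `undefined`
flag rather than an error, and metrics are displayed on the 0–100 scale
with two decimals. Token-level confusion matrices over the full BIO
alphabet (including `O`) complement the entity scores.

## Error analysis

Test token types are partitioned by aggregate outcome (always correct /
always incorrect / both), where token correctness means the full BIO
tag including the B/I distinction matches gold. Error-source sets are
computed from the training data and the embedding vocabulary only,
never from predictions:

* **OOEV** — test token types absent from the embedding vocabulary;
* **OOTV** — test token types absent from the training tokens;
* **AAV** — token types with more than one distinct gold tag in
  training. The `O` tag counts: a word seen both inside an entity and
  as plain text is ambiguously annotated under this definition, which
  also covers cross-type ambiguity (`B-Body part` in one sentence,
  `I-Disorder` in another);
* **NEA** — training mention token sequences that also occur in a
  training sentence uncovered by any mention (exact, case-sensitive
  token-sequence matching).

The token-level table reports `100·|group ∩ source|/|group|` per outcome
group and source; sources overlap, so rows need not sum to 100, and
empty groups yield undefined (NaN) cells rather than zeros. The
entity-level table does the same for exact-match TP/FP/FN classes
against NEA/AAV/OOTV, judging false positives on the predicted
mention's tokens and false negatives on the gold mention's; an entity
is OOTV if its surface token sequence never occurs as a training
mention of any type, and AAV if any of its tokens is ambiguously
annotated. The unseen-correct rate is the fraction of exact-match true
positives whose (type, token sequence) pair never occurs in training —
the package's measure of generalization beyond memorised mentions.
Percentages are over token *types*, not occurrences, matching the
outcome-grouping definition.

## Synthetic corpora

Real clinical corpora are confidential, so the generator builds
pseudo-language corpora that reproduce the properties the experiments
depend on, without any claim of linguistic realism:

* **Lexicons.** Each entity type gets a lexicon of 1–3-word terms
  (multiword fraction 0.3 by default) built from syllable pseudo-words;
  the final word of each term carries a type-indicative suffix pool
  (e.g. "-itis/-osis/-algia" for one type, "-olol/-icin/-pril" for
  another) so a character encoder has honest subword signal. Words are
  globally unique across terms and positions, which makes an
  unambiguous corpus provably free of ambiguously-annotated vocabulary.
* **Lemma map.** Some surfaces are inflections of their lemma;
  misspelled variants (one single-character edit: delete, swap,
  substitute, insert) share the canonical word's lemma, and
  abbreviations (initial-letter contraction for multiword terms,
  truncation + "." otherwise) share the full term's joined lemma —
  mirroring how "DM" lemmatises to *diabetes mellitus*. Variant
  creation rates default to 0.1 each; when a term has variants, a
  mention realises as a variant with probability 0.25.
* **Sentences.** Templates place 0–2 neutral fillers, a type-indicative
  trigger word, the term tokens, an optional post-trigger and trailing
  fillers; ~10% of sentences carry no mention and ~20% carry two.
  Planted per-type counts are recorded and recoverable exactly from the
  corpus statistics.
* **Ambiguity.** A configurable fraction of single-word term types
  (default 0.05) also appears as plain `O` context in mention-free
  sentences, creating AAV and NEA instances on demand;
  `ambiguity_rate = 0` guarantees both sets are empty.
* **Unseen mentions.** A quota of dev and test mentions equal to
  `target_test_oov_fraction` (default 0.3) is drawn from held-out terms
  that never occur in training — from *disjoint* halves of the held-out
  pool, so model selection on dev never sees the test part's unseen
  terms. Train-part terms are assigned round-robin so every training
  term actually occurs. Giving dev the same unseen quota as test is
  essential: both parts emulate draws from the same record collection,
  and early stopping can only select for generalization if dev measures
  it.
* **Raw corpora.** Unannotated streams for embedding training share a
  controllable Jaccard vocabulary overlap with the annotated corpus
  (shared-subset and fresh-word counts are solved exactly for the
  requested overlap, and a coverage pass guarantees every planned word
  occurs). Overlap 1 emulates an in-domain health-record corpus;
  overlap near 0 an out-of-domain general corpus. Entity terms retained
  by the overlap filter co-occur with their usual triggers so
  distributional similarity stays learnable.

Every operation draws from its own pseudo-random stream split from the
config seed, so corpora are byte-reproducible and adding an option does
not perturb unrelated draws. Two preset profiles mirror a two-language
setup: profile A with {Disease, Drug}, profile B with {Body part,
Disorder, Finding}.

What the generator does **not** emulate: real morphology or syntax,
sentence-length and frequency distributions of clinical prose,
annotation disagreement, discontinuous entities, or document structure.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that its qualitative orderings (in-domain ≥ out-of-domain
embeddings; partial ≥ exact F1; OOTV dominating errors) are recoverable
under controlled conditions — not that any particular F1 level would be
attained on real records.

## Scripted experiment conditions

`scripts/acceptance.py` fixes two desk-scale experiments (sizes chosen
so the full script is about a minute on one CPU):

* **Memorization/recovery** — profile A, 300/100/100 sentences,
  `ambiguity_rate = 0`, unseen-mention fraction 0.3, an in-domain raw
  corpus of 4000 sentences (several times the annotated size, mirroring
  the usual record-corpus-to-annotated-set ratio) with 300-d skip-gram
  vectors (5 epochs), and default tagger hyperparameters
  (`max_epochs = 30`, `min_epochs = 8`). Expected behaviour: train F1
  ≈ 100, test F1 well above 90, and a substantial unseen-correct rate
  (~25–30%) demonstrating generalization.
* **Domain trend** — three runs per condition on profile A at a
  deliberately scarce scale: 120/60/100 sentences, unseen fraction 0.5,
  variant rates 0.15, batch size 10, 100 LSTM / 30 character hidden
  units, embeddings of dimension 50 trained on 2000-sentence raw
  corpora with vocabulary overlap 1.0 (in-domain) vs 0.1
  (out-of-domain). At this scale the input representation matters; at
  the 300-sentence default both conditions saturate near F1 99 and the
  comparison is uninformative. The reported quantity is the ordering
  (mean in-domain minus mean out-of-domain test F1), not an absolute
  level.

## Known limitations

* Pure-NumPy training is desk-scale: hundreds of sentences, not the
  hundreds of thousands of a real record corpus.
* The CRF, LSTM and trainers are float64 single-threaded
  implementations built for verifiability (enumeration oracles,
  numerical gradient checks), not throughput.
* Partial-match counting follows one declared convention; other
  conventions (per-gold partial credit, weighted overlap) would give
  different partial scores on the same predictions.
* The fasttext-style trainer composes subwords during training only;
  OOV lookup is the zero vector by design, so subword generalisation at
  inference time is deliberately out of scope.
* Absolute scores on the synthetic corpora say nothing quantitative
  about real clinical text; only the tested identities, invariants and
  orderings transfer.
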