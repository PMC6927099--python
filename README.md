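# clinner — clinical named-entity recognition with word/lemma embeddings and a bi-LSTM-CRF

`clinner` is a self-contained pipeline for medical named-entity
recognition (NER) in clinical text: finding mentions of entities such as
*Disease*, *Drug*, *Body part*, *Disorder* and *Finding* in notes from
electronic health records, where misspellings, ad-hoc abbreviations
("DM" for *diabetes mellitus*) and out-of-vocabulary terms are the norm.
It is aimed at clinical NLP researchers who want to study how the
**source and combination of input embeddings** affects a neural tagger —
in particular in-domain (health-record-like) versus out-of-domain
embedding corpora — without access to confidential clinical data: a
synthetic-corpus generator reproduces the statistical structure of such
corpora (noisy entity variants, lemma maps, ambiguous tokens, a
controllable fraction of test entities unseen in training).

## The model

Tokens are tagged with the IOB2 scheme (`B-<type>`, `I-<type>`, `O`).
Two embedding spaces feed the tagger: `e_w : Σ_W → R^n` over surface
word-forms and `e_l : Σ_L → R^m` over lemmas, with out-of-vocabulary
units mapped to the zero vector. Per token they are combined by one of

* concatenation (W,L): `(e_w(w), e_l(l)) ∈ R^{n+m}`
* sum (W+L): `e_w(w) + e_l(l)` (requires n = m)
* subtraction (W−L): `e_w(w) − e_l(l)` (requires n = m)

or used alone (W or L). The tagger is a character-aware bidirectional
LSTM-CRF:

1. a character-level bi-LSTM turns each token's characters into a
   subword representation (final forward + backward states), capturing
   clinically meaningful affixes ("-itis", "-algia", "hypo-") and making
   misspelled or unseen words representable;
2. the character representation is concatenated with the word-level
   embedding feature and fed to a word-level bi-LSTM context encoder;
3. a linear projection produces per-token emission scores and a
   linear-chain CRF decodes the tag sequence with Viterbi; training
   minimises the CRF negative log-likelihood with Adam, dropout, and
   early stopping on development-set exact-match micro F1.

Evaluation is entity-level precision/recall/F1 (micro and per type)
under **exact** match (type and span both exact) and relaxed **partial**
match (any token overlap, any type), plus token-level confusion
matrices. An error-analysis module attributes errors to out-of-
embedding-vocabulary (OOEV), out-of-training-vocabulary (OOTV),
ambiguously-annotated (AAV) and non-entity-annotation (NEA) sources, and
measures the fraction of correctly tagged entities never seen in
training.

Everything is NumPy: the LSTMs (with hand-written backpropagation
through time), the CRF forward/backward/Viterbi recursions, and the
embedding trainers (skip-gram with negative sampling, a GloVe-style
co-occurrence factorisation, and a subword-composition variant).

## Worked example

```python
from clinner import EmbeddingSpace, combine, cosine_similarity, lookup, nearest_neighbours
from clinner.embedding_spaces import display_similarity

word = EmbeddingSpace.from_mapping({
    "DM": (6.5, 2.0), "diabetesmellitus": (6.8, 2.7),
    "hiperglucemia": (5.0, 2.5), "diarrea": (1.5, 5.0), "fiebre": (1.7, 7.1),
})
lemma = EmbeddingSpace.from_mapping({"diabetes mellitus": (0.6, 23.2)})

print("concat  :", combine(word, lemma, "DM", "diabetes mellitus", "concatenate"))
print("sum     :", combine(word, lemma, "DM", "diabetes mellitus", "sum"))
print("subtract:", combine(word, lemma, "DM", "diabetes mellitus", "subtract"))
dm = lookup(word, "DM")
print("cos(DM, fiebre)           =", display_similarity(cosine_similarity(dm, lookup(word, "fiebre"))))
for term, sim in nearest_neighbours(word, "DM", 3):
    print(f"  {term:<18} {sim:.2f}")
```

prints

```
concat  : [ 6.5  2.   0.6 23.2]
sum     : [ 7.1 25.2]
subtract: [  5.9 -21.2]
cos(DM, fiebre)           = 0.51
  diabetesmellitus   1.00
  hiperglucemia      0.99
  diarrea            0.56
```

The abbreviation `DM` sits next to the run-together misspelling
`diabetesmellitus` (cosine ≈ 1.00) and far from the unrelated `fiebre`
(0.51) — the behaviour that makes embedding features useful for noisy
clinical text. The three combination operators show how a word-form
vector and its lemma vector are merged into a single tagger input.

## Command line

One console script covers the pipeline:

```bash
clinner generate --profile A --seed 5 --out data --raw-overlap 1.0
clinner embed --algo word2vec --dim 50 --epochs 5 --seed 5 \
        --in data/raw_overlap1.txt --out word.vec
clinner train --train data/train.conll --dev data/dev.conll \
        --feature W --wordvec word.vec --out model
clinner predict --model model --in data/test.conll --out pred.conll
clinner evaluate --gold data/test.conll --pred pred.conll --match exact
clinner analyze --train data/train.conll --gold data/test.conll \
        --pred pred.conll --vec word.vec --out analysis
```

Profile A generates a two-type ({Disease, Drug}) pseudo-language corpus,
profile B a three-type one ({Body part, Disorder, Finding}). Corpus
files are CoNLL-style columns `TOKEN<TAB>LEMMA<TAB>BIOTAG`; embeddings
use the word2vec text format.

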