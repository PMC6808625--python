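# Methods

## Model

The tagger is a linear-chain CRF over neural emission scores.  For a
sentence of tokens `x_1..x_n`, each token is represented by the
concatenation of

1. a token-embedding lookup (`d_token`, default 100; lowercased lookup so
   that case information is carried by the character channel, where the
   original surface is used);
2. the final forward and backward states of a character-level BiLSTM over
   the token's characters (`2·d_char_lstm`, default 2×25, character
   embeddings `d_char`=25);
3. optional lexical channels, concatenated as raw untrainable values:
   a one-hot POS vector (dimension |POS inventory|+1, the extra slot for
   unseen/missing tags), a {0,1} gazetteer-membership flag, and a {0,1}
   affix flag.

A token-level BiLSTM (`d_token_lstm` per direction, default 100) reads the
sequence, an affine projection yields per-tag emissions, and the CRF
contributes trainable transition, start and stop scores.  The training
loss is the exact negative log-likelihood (forward algorithm in log
space); decoding is Viterbi with ties broken toward the lowest tag index.
Transitions that violate the tagging scheme's grammar (e.g. `O → I-X`)
are masked with a large negative constant (−10⁴) by default, so decoded
sequences always map back to entity spans without repair; the mask can be
disabled, in which case a repair pass ("stray `I-X` becomes `B-X`") makes
the span decoder total.

Spans are encoded in BIOES by default (BIO selectable); the richer
boundary marks give the CRF more to work with on multi-token mentions.

Dropout (default rate 0.5, inverted scaling) is applied to the
concatenated embedding and to the BiLSTM output.  The default optimizer is
SGD with learning rate 0.005 and global gradient-norm clipping at 5.0;
Adam is available through the training configuration and is what the
desk-scale experiments use (learning rate 0.01), since it converges in a
handful of epochs on the synthetic corpora.  All randomness — parameter
initialization, dropout masks, batch shuffling — flows from explicit
integer seeds.

The network and its gradients run on a small reverse-mode autodiff tape
over numpy float64 arrays (`pharmaconer._autodiff`): broadcast-aware
arithmetic, matmul, sigmoid/tanh, concatenation/stacking, fancy indexing
and a stable log-sum-exp.  Sentences in a minibatch are padded and run
through the recurrent layers together with a carry-through mask (masked
steps propagate the previous state), and the CRF forward recursion is
batched the same way; the batched loss equals the sum of per-sentence
losses to float64 round-off, which the tests assert.  Gradient
correctness is established by finite-difference comparison (relative
agreement better than 1e-4), and CRF inference by exhaustive path
enumeration on small instances (≤ 1e-6 in log space).

## Feature channels

- **Gazetteer** — one term per line; terms are NFC-normalized and
  lowercased (accents preserved: they are lexically meaningful in
  Spanish; an accent-stripping flag exists for noisy corpora).  Because
  the membership test is per token, multi-word entries are additionally
  exploded into their component words of length ≥ 3, so an entry like
  "ácido acetilsalicílico" can still fire.  Lookup is a hash-set probe.
- **Affixes** — 5-column TSV of which the type (prefix/suffix/root) and
  the Spanish affix are consumed; anchoring hyphens are stripped.
  Prefixes match anchored at the start, suffixes at the end, roots
  anywhere; matching is case-insensitive and accent-sensitive.  A token
  equal to the bare affix matches (the simplest total rule), and tokens
  shorter than 3 characters never match roots, which caps false positives
  on fragments.  One combined flag is emitted for "any entry matched".
- **POS** — consumed from the input annotations, never computed; the tag
  inventory is frozen at training time and serialized with the model, and
  unseen tags map to the UNK slot at prediction time.

Disabled channels contribute zero *width* (not zero values), so the base
configuration reproduces the plain character-enhanced BiLSTM-CRF, and a
disabled channel's resource file is never read.

## Vocabulary and embeddings

The token vocabulary is the union of training-corpus tokens and the words
of an optional pretrained embedding file, so pretrained coverage survives
gaps in the training vocabulary.  Pretrained vectors are copied verbatim;
uncovered tokens are initialized uniformly in `[-r, r]` with
`r = sqrt(3/d)`; UNK is the mean of the pretrained vectors (random when
none are given) and PAD is zero.  The loader accepts word2vec text with a
`count dim` header as well as headerless GloVe/fastText `.vec`, skips
malformed lines (rejecting the file if they dominate), and reads gzip
transparently.  Out-of-vocabulary tokens map to UNK; no subword
composition is attempted.

## Splitting and training protocol

Documents are split 80/10/10 (train/dev/test) by greedy iterative
stratification over entity-mention counts: documents carrying the
currently rarest label are placed first, each into the split whose
remaining need — summed over all labels the document carries, weighted by
relative need — is greatest, with remaining capacity as tie-break.  The
procedure is deterministic under the split seed.  On the default
two-class imbalanced corpus (ratio ≈ 4398:3009, 200 documents) per-split
label proportions land within ~1.5 percentage points of the corpus-wide
proportions.

Training iterates minibatches (default 16 sentences, reshuffled each
epoch under the seed) and evaluates entity-level micro-F1 on the dev set
after every epoch.  Early stopping uses strict improvement (tolerance
1e-6) with a patience of 10 epochs by default; the parameters of the best
dev epoch are restored before returning.  Rare entity classes can be
discarded up front (their mentions become O tokens; documents, text and
offsets are untouched) — the desk-scale benchmark drops the two rare
classes and targets the two frequent ones.

## Evaluation

Scoring is strict CoNLL-style: an entity counts as a true positive only
when label and exact character span both match; precision, recall and F1
are micro-averaged over labels, and token accuracy counts every token
including O.  Matching is on character offsets rather than token indices,
so externally produced predictions with a different tokenization can be
scored (token accuracy is then reported as absent).  Swapping gold and
predicted swaps precision and recall exactly; the suite checks this, and
checks equivalence with an independently coded set-comparison matcher on
randomized corpora.

## Synthetic corpus generator

No suitable annotated Spanish clinical corpus can be redistributed, so the
generator produces a corpus with the statistical shape the toolchain
needs to be exercised against, and the experiments in this repository run
on it end to end:

- four entity classes with heavily imbalanced target mention counts
  (proportions 4398 : 50 : 3009 : 167), allocated to mention slots by
  largest-remainder apportionment so realized counts track the targets to
  ±1 before shuffling;
- entity surfaces drawn from three per-class pools: gazetteer terms
  (emitted to `gazetteer.txt`), affix-bearing words built around real INN
  drug-class affixes (*-caína*, *-cilina*, *-micina*, *-olol*, *cef-*,
  *-tiaz-*; emitted to `affixes.tsv`), and cue-free words; multi-token
  protein mentions of the shape "receptores de X";
- background text from a disjoint vocabulary, with sentence-initial
  capitalization, attached commas and sentence-final periods so the
  tokenizer's punctuation rules are genuinely exercised; all surfaces are
  built from Spanish-like syllables including accented vowels and ñ;
- a 10-tag POS inventory with class-correlated distributions (entity
  tokens are nouns, `de` is a preposition, punctuation is tagged as such);
- distractors: gazetteer terms inserted in non-entity context, which is
  what forces a model to combine context with the gazetteer flag rather
  than copy it.

Pool sizes default to 120 terms per class: large enough that entity
surfaces are individually rare, so the lexical flags carry signal that
pure token-embedding memorization cannot replace — the regime a real
nomenclator-derived gazetteer serves.  The separability dial fixes three
study conditions: **trivial** (every mention is a gazetteer term, no
distractors, no multi-token mentions — a dictionary rule is Bayes-optimal
at F1 100, which ceiling-checks the model), **easy** (90% of mentions
carry a cue, 5% of sentences contain a distractor), and **hard** (50%
cue-bearing, 20% distractor sentences).  The emitted gazetteer/affix
files are consistent with generation, so features recomputed from the
files agree with the generator's intent; the tests verify this, as well
as byte-identical regeneration under a fixed seed.

What the generator does **not** emulate: real Spanish morphology and
syntax, discourse structure, abbreviations/acronyms, spelling noise,
annotation disagreement, and nested or discontinuous mentions.  Passing
the synthetic benchmark therefore demonstrates that the architecture,
features, optimization and toolchain work as specified — not that any
particular F1 carries over to real clinical text.

## Problem sizes used in tests and the acceptance script

The desk-scale benchmark uses 200 documents of ~15 sentences (~2,100
mentions), small model dimensions (`d_char`=`d_char_lstm`=8, `d_token`=16,
`d_token_lstm`=24, dropout 0.25), Adam at 0.01, batch size 16, patience
10 with a 12-epoch cap for the trivial-level run and a matched 3-epoch
budget for the easy-level feature-ablation comparison.  These sizes train
in a few minutes on one CPU while leaving the conclusions qualitatively
unchanged from larger configurations.  CRF oracle checks enumerate all
paths for n ≤ 5 tokens and ≤ 4 tags (500 instances); feature oracles
compare 1,000 tokens against brute-force scans.

A caveat the ablation surfaces rather than hides: at this corpus scale
training covers most entity surfaces, so the measured benefit of the
gazetteer/affix channels on the easy level is small relative to
seed-to-seed training variance — single-seed comparisons can go either
way, and at some seeds the feature-equipped model settles into copying
the cues (a dev-F1 plateau near the cued-mention fraction) while the
featureless model is forced to learn the vocabulary.  The ablation
example and the acceptance script print the comparison they actually ran;
the regime where dictionary knowledge is structurally irreplaceable —
surfaces absent from training — grows with corpus vocabulary and is
under-represented at desk scale.

## Known limitations

- Recurrent layers are exact but CPU-bound; the implementation favors
  auditability over throughput and is not meant for corpora orders of
  magnitude beyond the desk scale.
- Nested, overlapping and discontinuous entities are out of scope; BRAT
  relation/event annotations are ignored on read.
- No fuzzy gazetteer matching or entity normalization to database
  identifiers; class labels are opaque strings.
- fastText subword composition is not implemented: unseen tokens share
  one UNK embedding row.
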