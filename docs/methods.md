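# Methods

## Task and data model

Chemical–protein interaction extraction is treated as sentence-level
classification of candidate pairs. A ChemProt-style corpus is three
headerless TSV files (abstracts; entity mentions with character
offsets; relation annotations). Offsets are 0-based half-open over
`full_text = title + "\t" + abstract`; the separator is configurable
but a single tab is the convention read and written here. Candidate
generation enumerates every within-sentence (chemical, gene) pair; the
label is the evaluated CPR class of a gold relation linking the pair
(one instance per class for multi-labeled pairs), otherwise NEG. Gold
relations of the non-evaluated classes (CPR:1,2,7,8,10) are treated as
NEG, matching the shared-task evaluation. Cross-sentence gold relations
are dropped and counted in a report — the official corpus's printed
per-class supports fall slightly short of its total evaluated-CPI
count, consistent with a small number of such pairs — and an entity
overlapping a sentence boundary skips its instances with a warning.
The chemical argument is normalized into the `chem` slot regardless of
file order, since the task is defined on (chemical, gene) pairs.

Sentence splitting is a pluggable function; the default is rule-based
(`.?!` + whitespace, abbreviation and single-initial guards, tab forces
a boundary). Tokenization is mention-boundary-aware: a gold mention is
always a single token, so annotation offsets map cleanly to token
positions. The POS tagger is injected; the default is a deterministic
regex/lexicon coarse tagger (no model downloads). Both are deliberately
simple — for real corpora a biomedical tokenizer/tagger can be passed
in.

## Features

Each instance becomes four aligned integer sequences: token ids, POS
ids, and two position channels holding signed token distances to the
chemical and the gene (0 on the mention, negative before, positive
after; head-of-span convention), clipped to ±D and shifted by +D.
Defaults: D = 30 with 50-dimensional position and POS embeddings at
reference scale; the desk-scale experiment configuration uses D = 10
and 8-dimensional embeddings. Target entities are anonymized to
`CHEM_ENT`/`GENE_ENT` by default (policies: `none`, `targets`, `all`)
so the classifier cannot memorize entity surfaces.

## Contextual representations

A small bidirectional LSTM language model supplies per-token vectors.
Forward and backward factorizations are trained jointly (the objective
is exactly the sum of the two per-token log-likelihood sums; causality
of each direction is enforced by construction and by perturbation
tests). The representation stack has L+1 layers of one width 2H: layer
0 duplicates the static embedding; layer l concatenates the layer-l
forward and backward hidden states. The classifier mixes the stack with
softmax-normalized scalars and a global scale. Protocol decisions made
here: the LM is trained separately on the corpus sentences and frozen;
the mixing weights and scale train with the task loss. A provider
interface (in-process or precomputed-file) means externally computed
contextual vectors of any origin can be substituted without touching
the classifier.

LM specifics: embedding width equals hidden width (so the stack is
rectangular); embeddings are unit-scale at initialization — with
0.1-scale initialization the frozen context features carry token
identity too weakly and the downstream classifier cannot lift off
within a 20-epoch budget. Input/output embedding tying is available.
Training uses RMSProp, default 3 epochs at lr 5e-3, batches bucketed
and padded with a carry-through state mask.

## Classifier

Input vector per token: mixed context ⊕ distance-to-chemical ⊕
distance-to-gene ⊕ POS embeddings. Dropout (0.5) is applied to this
concatenation and to the pooled sentence vector, the two places the
protocol prescribes. The Bi-LSTM uses the standard gate equations with
h_t = o_t ⊙ tanh(c_t); a `literal` variant h_t = o_t ⊙ tanh(c_{t−1})
is kept behind a flag for fidelity experiments (the two agree exactly
whenever c_t = c_{t−1}). The backward direction consumes each sequence
reversed within its true length; padded rows are zeroed and padded
steps carry state through, so padding cannot influence any output (a
tested invariant: scribbling on PAD slots leaves logits bit-identical).

Multihead self-attention uses three per-head projections (Q, K, V) of
the Bi-LSTM output, per-head scaling √(d/h) by default (a `literal`
√d flag exists; per-head scaling keeps logits unit-scale per head),
−∞ masking of padded keys (weights exactly zero), concatenation and an
output projection. Reference geometry: 600-wide encoder output, 6 heads
of width 100; desk-scale default: 48 wide, 4 heads.

**Residual connection.** The attention block is wrapped in a residual
skip (`attention_residual`, default on; the plain stack remains
available). This was a measured necessity, not ornament: with the plain
stack, trained self-attention drives every position toward the same
attended mixture, the pooling layer then sees nearly identical rows,
its weights stay near uniform (max weight ≈ 1.3× uniform), and the
attention-keyword report degenerates to token frequency. With the skip,
per-position identity survives the attention layer, pooling
concentrates (≈ 7.6× uniform) and the planted triggers emerge as the
top-weighted keywords of their classes.

Attention pooling scores a_t = vᵀtanh(W h_t), softmaxed over unmasked
positions; the pooled vector feeds a 6-class softmax. The pooling
weight vector v is initialized from N(0, 1) — zero initialization
leaves pooling uniform with a vanishing early gradient. The output
layer is Glorot-initialized (zero initialization blocks all gradient
flow into the encoder), and LSTM forget-gate biases start at 1.

## Training protocol

Categorical cross-entropy; RMSProp lr 0.001 (decay 0.9, ε 1e-7 — the
common defaults, chosen here); batch 64; dropout 0.5; validation split
10% by uniform instance-level sampling; early stopping on validation
micro-F with patience 5 (the stopping metric is a choice — the protocol
names the validation set but not the metric), best checkpoint = highest
validation micro-F, earliest epoch on ties, restored on return.
Experiments repeat over 5 seeds, each seed resampling the validation
split, with arithmetic-mean micro metrics reported and per-seed values
retained. No class re-weighting by default (NEG dominance is part of
the task); a class-weight hook exists. Training is bit-reproducible
given a seed; a non-finite loss aborts with a diagnostic.

## Scoring

The 6×6 confusion matrix (rows gold, columns predicted, fixed order
NEG, CPR:3, CPR:4, CPR:5, CPR:6, CPR:9) supports per-class and micro
metrics. Micro pools TP/FP/FN over the five positive classes; NEG is
excluded from the positive set but contributes false positives and
negatives. Zero denominators score 0. Reports round half-even to three
decimals. The scorer is validated two ways: against an independent
library scorer on random inputs, and against a published reference
matrix whose printed micro (0.706/0.618/0.659) and per-class rows it
reproduces exactly at printed precision. Confusion matrices round-trip
through TSV so published tables can be scored directly. The scorer
operates per candidate instance; an abstract-level (pair, class)
aggregation hook is deliberately left out of scope.

Attention keywords: tokens ranked by pooling weight per predicted
class, summed by default (mean available; with uniform weights the sum
reduces to token frequency, which is the documented degenerate case),
lowercased, placeholders and PAD excluded, stopwords kept — published
keyword lists include ordinary words, so fidelity beats tidiness.

## Synthetic corpora

The generator emits the exact three-file dialect plus ground-truth
instance labels. Each sentence hosts one (chemical, gene) pair with a
class drawn from a configurable mixture (default: 50% NEG, 10% each
positive class); with probability `trigger_strength` the class's
trigger keyword is planted by the pair (lexicons follow the attention
keywords characteristic of each CPR class: inhibitor-variants for
CPR:4, agonist/antagonist for CPR:5/6, expression/increased/induced for
CPR:3, metabolism/uptake/enzyme for CPR:9), otherwise a neutral verb.
Templates are slot-filling frames (active, passive, multi-clause) over
a Zipf-distributed filler vocabulary with synthetic entity surfaces
(CHM####/GEN####); distractor clauses add unrelated entities (more NEG
candidates, same gold), and a confound dial makes CPR:3 and CPR:4
sentences use a shared ambiguous regulation trigger (regulates,
modulates, ...) instead of their class-specific one, so the two classes
genuinely collide. Distractor noise draws from an
independent RNG stream, so planted relations are invariant to the
distractor rate at fixed seed, and generation is byte-deterministic.

At trigger strength 1 with no distractors/confounds, the label is a
deterministic function of the planted trigger, so a keyword-matching
baseline (provided) is Bayes-optimal at micro-F 1.0 — which is what
makes end-to-end recovery a sharp test. What passing those tests shows:
the architecture, features, optimization and scoring machinery work and
can extract a lexical-contextual signal. What it does not show:
performance on real biomedical prose, whose entity ambiguity,
anaphora, nested mentions and genuine linguistic variation the
templates do not emulate; corpus-level benchmark scores require the
real ChemProt data and full-scale training.

## Problem sizes and experiment defaults

Synthetic experiments use desk-scale settings chosen once: contextual
width 24 (LM hidden 12/direction), Bi-LSTM 24/direction (48-wide
encoder), 4 heads, pooling dim 16, D = 10; easy-corpus recovery uses
~550 documents (~3000 instances) for up to 20 epochs; the difficulty
sweep uses ~300 documents (~1600 instances) for up to 30 epochs —
below ~700 optimizer updates the loss is still in its plateau phase, so
smaller sweeps under-train and say nothing about difficulty. In the
confound experiment, the ambiguous shared trigger makes CPR:3 vs CPR:4
irreducibly uncertain for the affected sentences (an early clause-based
confound design failed here: an appended "consistent with <other
trigger>" clause is positionally distinguishable, so the model simply
learned it as an inverted cue), and the CPR:3/CPR:4 share of
off-diagonal confusion rises sharply relative to the unconfounded run.

## Numerical choices and degenerate inputs

Float64 throughout. Softmax/log-softmax are max-shifted; masked
attention logits use an additive −1e30 so masked weights underflow to
exact zero. Sigmoid inputs are clipped at ±500. Ties in early stopping
break to the earliest epoch; vocabulary lookup of unseen tokens when
frozen yields OOV (index 1); PAD is index 0. Empty sentences, empty
corpora for LM training, fully-masked pooling inputs, out-of-vocabulary
LM ids, label values outside the 6-class set, non-divisible
head counts and mask/sequence shape mismatches all raise early with
specific messages. Finite-difference gradient checks hold every
parameterized block to relative error < 1e-4.

## Known limitations

- The bi-LM is a word-level toy compared to large pretrained contextual
  encoders; the provider interface is the intended escape hatch.
- The coarse POS tagger is rule-based; its tags are deterministic
  rather than linguistically accurate.
- Document-level (cross-sentence) relations are out of scope by design;
  they are counted, not classified.
- The scorer is instance-level; official shared-task tooling aggregates
  differently at the abstract level.
- Desk-scale defaults are tuned for synthetic corpora; applying the
  package to real ChemProt data would use the reference dimensions and
  substantially more compute.
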