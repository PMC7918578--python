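# Methods

## Problem and data model

The unit of classification is a *segment*: one silence-delimited,
transcribed utterance of the operating surgeon, labelled with one of 8
classes — the seven ordered phases of laparoscopic cholecystectomy
(LC) plus an "extra" pseudo-phase (label 8) for speech unrelated to
any phase (normal OR conversation). A corpus groups segments by video
and preserves temporal order (0-based consecutive indices per video).
Splitting is always at video granularity: a surgical video is one
temporal sequence, and letting segments of the same video appear on
both sides of a split would leak near-duplicate vocabulary and
temporal context into the test set.

The study corpus this design targets (15 Spanish educational videos,
611 segments, 58 of them in the two held-out test videos) is not
publicly available. Its per-video, per-phase sample counts are
packaged as a fixture (`corpus.table2_fixture`), and
`synthetic.corpus_from_counts` rebuilds a corpus with exactly those
counts from synthetic text. Note the published version of that count
table carries three row totals (videos 3, 8, 15) that disagree with
the sums of their own cells, while the column totals and the 611 grand
total are cell-consistent; this package always computes marginals from
cells, so those three video totals are reported as 63, 161 and 56.

## Synthetic corpus generator

The generator emulates the structural properties the method relies on,
not Spanish prose:

* **Timelines.** Each video is a monotone walk over phases 1..7: each
  phase is absent with probability `phase_skip_prob` (default 0.05 —
  the study's count table contains zero cells), otherwise contributes
  a contiguous block of `1 + Poisson(mean − 1)` segments. Extra
  segments are *inserted* into gaps (probability
  `extra_insertion_prob`, default 0.3, matching the extra class's
  ~30% share of segments), not modelled as a state of the walk —
  conversation is not part of the surgical sequence.
* **Vocabularies.** Each phase owns `vocab_size_per_phase` abstract
  keywords (`p4_kw_07`); an `overlap[(a, b)] = f` entry makes a
  fraction `f` of phase-b's inventory identical to phase-a keywords,
  reproducing lexical confusability (both dissection phases say
  "dissect"). Keywords are swapped for same-phase synonym tokens with
  probability `synonym_rate`; generic filler tokens stand in for
  function words; the pseudo-phase draws from its own conversational
  vocabulary only.
* Tokens are abstract rather than fabricated clinical Spanish: the
  pipeline is language-agnostic after tokenization, and stemming is
  exercised separately on real-word fixtures.

With zero overlap a keyword lookup classifies every segment perfectly,
which is the separability ground truth for the recovery tests. What
passing on such corpora does *not* show: robustness to transcription
errors, paraphrase, genuine synonymy across phases, or annotator
disagreement — none of which the generator emulates.

## Preprocessing

Normalization lowercases, strips markup tags, punctuation and special
characters, keeps letters (with accents), digits and word-internal
underscores, and collapses whitespace. Accents are preserved (the
Spanish Snowball stemmer handles and finally removes them itself);
digits are kept because port sizes and counts are informative. Stop
lists and stemmers are pluggable: empty list + identity stemmer for
synthetic corpora, the bundled Spanish list + in-repo Snowball Spanish
stemmer for real transcripts. The Spanish and English (Porter2)
stemmers are implemented from the published Snowball algorithm
definitions and verified against hand-traced reference outputs.

## Features

* **BOW** — raw term counts over the training vocabulary (terms sorted
  lexicographically for reproducibility).
* **TF-iDF** — `tf · (ln((1+n)/(1+df)) + 1)` with L2 row
  normalization; the smoothed-idf dialect is recorded in the feature
  matrix provenance and cross-checked against an independent
  implementation in the tests.
* **Word2Vec** — skip-gram with negative sampling (the "predict the
  context of the word" direction), trained on the training split
  itself; defaults d=100, window=5, 5 negatives, 50 epochs,
  min_count=1 — small-corpus settings chosen because the corpora here
  are hundreds, not millions, of tokens. Training in-corpus (rather
  than loading pre-trained vectors) keeps the artifact download-free
  and leakage-free; pre-trained Spanish embeddings are the obvious
  alternative for real deployments.
* **GloVe** — symmetric windowed co-occurrence counts (unit-weighted;
  no 1/distance decay) factorized under the weighted least-squares
  objective with `f(x) = (x/x_max)^0.75` capped at 1, AdaGrad updates,
  final vector = target + context vector.
* **Segment vectors** are unweighted means of in-vocabulary word
  vectors — order-invariant and the standard baseline aggregation; a
  segment with no known tokens maps to the zero vector.

All fitting happens on training token sequences only; transforming
unseen segments never mutates fitted state.

## Balancing

Class imbalance is severe (extra 178 vs phase 7 just 22 segments in
the study counts). SVM-SMOTE oversamples every class to an explicit
`target_per_class`: seed points are the class's support vectors of an
RBF-SVM (C=1) fitted on the training features, and each synthetic
sample is `x_i + u·(x_nn − x_i)` with `u ~ U(0,1)` toward one of the
k=5 nearest same-class neighbours (k reduced to class size − 1 for
tiny classes; a singleton class is duplicated with a warning). Only
the interpolation branch is implemented — extrapolation beyond the
seed can leave the class's convex hull, and boundary focus is already
provided by support-vector seeding. The balanced-study target (178
per class, 1424 total) uses the majority-class count over the *full*
corpus even though the training split holds only 163 extra-phase
segments; `target_per_class` is therefore an explicit parameter, not
inferred. Test data are never oversampled: test videos must keep
their real temporal composition.

## Classifiers

The four back-ends and their searched domains: one-vs-all logistic
regression with ridge penalty (strength 1); RBF-SVM with C=1 and
pairwise-coupling posterior calibration; random forest with
entropy/Gini criterion (100 trees, unlimited depth, tree-vote
posteriors); MLP with activation ∈ {logistic, tanh, relu} ×
optimizer ∈ {adam, lbfgs} (one hidden layer of 100). Unlisted
hyperparameters take the library defaults and are recorded in the
model metadata. All posterior rows are renormalized onto the simplex
to absorb tiny calibration drift.

Cross-validation is stratified by phase at the segment level (the
per-sample view; sequence-aware evaluation is the temporal module's
job) with shuffling under the run seed — the exact fold assignment is
a documented assumption. Every fold refits vocabulary/embeddings and
the oversampler on its own training portion; per-fold metadata records
the fitted sizes so tests can audit the absence of leakage. An
overfitting flag marks mean train − validation macro-F1 > 0.15.

## Temporal model

Because training sequences are fully labelled, the HMM is estimated by
supervised counting (no Baum–Welch): additive smoothing α (default
0.01) on transitions and initial probabilities; with α = 0, rows of
states never left are set uniform with a warning. An optional
`extra_boost` adds transition mass into and out of the pseudo-phase
before renormalization — loosening the restriction on entering
conversation from any phase, the natural remedy for the pseudo-phase
decoding errors discussed below.

Classifier posteriors enter as emission scores in one of two modes,
recorded in provenance: `posterior` (floored posteriors) and the
default `scaled_likelihood` (posterior divided by training class
prior, the standard hybrid coupling; emission floor 1e−6 keeps log
scores finite and lets the decoder traverse classes the classifier
never saw). Each test video is decoded independently with Viterbi in
log space; ties break toward the lowest state index at every
backtracking step, so decoded paths are exactly reproducible. Viterbi
(MAP sequence) rather than forward–backward posterior decoding: the
deliverable is one coherent timeline, not per-segment marginals.

**When smoothing helps and when it cannot.** If the per-segment
classifier is already confident and correct, the MAP path can only tie
or — at genuine temporal incoherencies — overrule it: a singleton
conversation segment inside a phase block is *correctly* smoothed away
by a well-estimated HMM whenever the transition cost of entering and
leaving the pseudo-phase exceeds the one-segment emission advantage.
This is a property of the model, not a defect of the decoder, and it
is exactly the pseudo-phase behaviour observed in practice. The
smoothing-benefit tests therefore use temporally coherent timelines
(contiguous monotone blocks) for the no-harm property at noise
ε = 0.4 — where the noisy argmax is still always correct and Viterbi
must merely not break it — and show the positive benefit at ε = 0.8,
where the argmax degrades below 60% accuracy and smoothing recovers
~40 points.

## Evaluation

Macro (unweighted) F1 over classes present in the ground truth is the
headline score; accuracy is reported alongside. Error rates come in
three forms because they answer different questions on imbalanced
sets: per-phase (1 − recall of that phase), average (unweighted mean
over phases present), and total (pooled misclassification fraction =
1 − accuracy). Cohen's kappa serves inter-annotator agreement checks.
The timeline disruption count formalizes "workflow-implausible
decoding" as the number of positions whose predicted non-extra phase
is strictly below the running maximum non-extra phase — a backward
jump; pseudo-phase predictions are exempt since conversation
legitimately interleaves everywhere. The formal rule is this
package's definition; narrative descriptions of disruptions do not fix
one.

## Problem sizes and numerical choices

The default test/acceptance runs use 15-video corpora (hundreds of
segments), embedding dimensions 50 and ~20 epochs, and 5-fold CV in
tests — sizes chosen to keep the full suite in tens of seconds while
leaving every statistical check comfortably powered. Seeds derive
from one root seed per run (+1 features, +2 oversampling,
+3 classifier), so stages are independently reproducible. Degenerate
inputs are defined throughout: empty token sequences become zero
feature rows; zero TF-iDF rows stay zero under L2; fully
out-of-vocabulary segments embed to the zero vector; empty corpora
are valid but unfittable.

## Known limitations

* Synthetic text has no morphology, so stemming and stop-word removal
  are exercised on word fixtures, not end-to-end.
* Embeddings are trained on a few hundred segments; absolute embedding
  quality is far below pre-trained vectors, which is acceptable here
  because phases are lexically separable by construction.
* The HMM assumes first-order dynamics and stationary transitions; it
  has no phase-duration model.
* The pseudo-phase remains the structurally hard case: it breaks the
  monotone phase walk, and MAP decoding will smooth away brief
  conversation under confident transitions. `extra_boost` mitigates
  but does not remove this.
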