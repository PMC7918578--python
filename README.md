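# surgspeech

Speech-based surgical workflow analysis: recognizing the phases of a
laparoscopic cholecystectomy (LC) from what the surgeon *says*.

In surgical-education operating rooms, the trainee verbally discloses
each action while operating. Transcribing that speech and classifying
every silence-delimited utterance into a surgical phase yields a
recognized workflow timeline that can be compared against the expected
procedure — a non-intrusive basis for assessing procedural and
decision-making skills.

`surgspeech` implements that recognition pipeline end to end for the
8-class LC scheme — seven ordered phases (1 preparation, 2 Calot's
triangle dissection, 3 cystic duct/artery clipping and cutting,
4 gallbladder dissection, 5 gallbladder extraction, 6 cleaning and
coagulation, 7 suturing and port removal) plus an "extra" pseudo-phase
(8) for ordinary OR conversation:

1. **Corpus handling** — ordered, video-grouped transcript segments in a
   JSON-lines format, video-level train/test splitting, and the study's
   per-video phase count table as a packaged fixture.
2. **Synthetic corpora** — a seeded generator emulating the statistical
   structure of the (non-public) study corpus: monotone phase walks,
   interleaved conversation, phase-specific vocabularies with
   controllable cross-phase lexical overlap.
3. **Preprocessing** — normalize → tokenize → stop words → stemming
   (in-repo Snowball Spanish and English/Porter2 stemmers).
4. **Features** — bag-of-words; TF-iDF with smoothed idf,
   `idf(t) = ln((1+n)/(1+df(t))) + 1`, and L2 row normalization;
   Word2Vec (skip-gram with negative sampling) and GloVe embeddings
   trained in-corpus, with segment vectors as word-vector means.
5. **Balancing** — SVM-SMOTE: synthetic minority samples interpolated
   from support-vector seed points toward same-class neighbours,
   applied to training features only.
6. **Classifiers** — one-vs-all ridge logistic regression, RBF-kernel
   SVM (C = 1), random forest (entropy/Gini), and an MLP
   (logistic/tanh/relu × adam/lbfgs), all exposing posterior
   probabilities; stratified 10-fold cross-validation with per-fold
   refitting of features and oversampling.
7. **Temporal model** — a classifier-coupled hidden Markov model:
   transition matrix and initial distribution estimated by supervised
   counting with additive smoothing,
   `A[s,s'] = (c(s→s') + α) / (c(s→·) + 8α)`,
   classifier posteriors converted to emission scores (optionally
   scaled by class priors), and per-video Viterbi decoding in log space.
8. **Evaluation** — 8×8 confusion matrix, per-class precision/recall/F1,
   macro-F1, accuracy, per-phase / average / total error rates, Cohen's
   kappa for inter-annotator agreement, and timeline comparison with a
   workflow-disruption count (backward jumps in the phase progression).

## Worked example

Generate a synthetic 15-video corpus, then train an SVM on in-corpus
Word2Vec features and decode the two held-out videos with the coupled
HMM:

```bash
surgspeech simulate --seed 3 --out sim
# wrote 680 segments over 15 videos to sim/corpus.jsonl

cat > run.yaml <<'YAML'
feature: word2vec
classifier:
  kind: svm
test_video_ids: ["v01", "v02"]
feature_params: {d: 50, epochs: 20}
YAML

surgspeech run --corpus sim/corpus.jsonl --config run.yaml --seed 7 --out results
# test macro-F1 0.980, accuracy 0.986 (with HMM)
```

`results/report.json` holds the full evaluation. For this run the raw
per-segment classifier is perfect (macro-F1 1.0 — the synthetic
vocabularies are separable), while the HMM-smoothed timeline scores
macro-F1 0.980 / accuracy 0.986 with per-video results

```text
v01: macro-F1 0.987, accuracy 0.972, 0 disruptions (36 segments)
v02: macro-F1 1.000, accuracy 1.000, 0 disruptions (38 segments)
```

The one smoothed-away segment in v01 is a singleton conversation
(pseudo-phase) utterance that the decoder relabels as the surrounding
phase: conversation interleaves arbitrarily with the surgical sequence
and is the known hard case for the temporal model. The HMM earns its
keep when the classifier is noisy — under heavy injected posterior
noise, Viterbi smoothing raises segment accuracy by roughly 40 points
(see `tests/test_acceptance.py`). Other outputs: `timelines.csv`
(truth vs predicted per segment, for timeline plots),
`transitions.csv` (the estimated transition matrix), and
`resolved_config.json` (full configuration and seed). Add `--grid` to
score all 4 features × 4 classifiers × ±HMM (32 rows).

## Layout

```
src/surgspeech/     corpus, synthetic, preprocess, features, embeddings,
                    balance, classify, temporal, evaluate, experiment, cli
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     models, assumptions, parameter choices, limitations
scripts/acceptance.py
```
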