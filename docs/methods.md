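# Methods

This note records the models, defaults, and numerical choices behind
`rarescreen`, and what the synthetic-corpus tests do and do not establish.

## Problem framing

The screening target, AADC deficiency, is too rare to train on cases: the
package therefore models ten proxy concepts per sentence (autonomic
dysfunction, cerebral palsy, developmental delay, epilepsy/seizures,
feeding issues, hypotonia, insomnia, mood disturbance, movement
disorders, oculogyric crisis) and ranks patients by how many of these
co-occur in their chart. Direct mentions of the disease itself are
ingested but never modeled — a chart that already names the disease needs
no flagging.

## Corpus model

- Offsets are 0-based, half-open character indices on raw note text (the
  BRAT convention). Every `.ann` entity is verified against
  `note_text[start:end]` on read; a mismatch is an integrity error, not a
  warning, because silent offset drift corrupts labels downstream.
- Sentence segmentation is a deterministic rule-based splitter (terminal
  punctuation with an abbreviation guard, plus hard newline boundaries).
  A model-based segmenter can be substituted; the exact spans produced by
  any particular pretrained parser are not reproducible across versions,
  and deterministic spans are worth more to a testable pipeline than
  marginally better boundaries.
- A sentence is labeled for a concept iff its span overlaps an annotation
  by at least one character; an annotation crossing a boundary marks all
  overlapped sentences, each inheriting the annotation's modifiers. The
  three modifiers (negated, not-patient, hypothetical) collapse into one
  *negative-qualified* class — separately they are too rare to model.
- When one sentence holds both an unqualified and a qualified mention of
  the same concept, positive wins: an asserted mention evidences presence
  regardless of an accompanying negation, and screening favors recall.
- Splits are by patient (80/10/10, nearest-integer rounding with the
  remainder to train, keeping training as large as possible because
  several concepts are rare); partitioning is a seeded shuffle with
  round-robin assignment, sizes differing by at most one.

## Synthetic corpus generator

The generator emulates the *statistical* structure the pipeline assumes:
patients with latent concept truths drawn at configurable prevalences
(defaults mirror the development study's annotated validation cohort,
e.g. developmental delay 0.54, oculogyric crisis 0.045), 2–4 notes per
patient of 4–8 sentences, mentions of true concepts at `mention_rate`
0.3 per sentence, modifier phrasings at `modifier_rate` 0.15, and
qualified-only distractor mentions on negative patients at
`distractor_rate` 0.02. Modifier cues sit in the same sentence as the
phrase so the qualified class is learnable from local context. A
`case_fraction` knob plants multi-symptom patients (6–9 of the 9
non-epilepsy concepts) — the patients screening must surface — and a
Gaussian-copula correlation knob is available because the ranking model's
value depends on symptom co-occurrence.

What it does **not** emulate: real clinical language (section headers,
boilerplate, abbreviation soup, typos), annotator disagreement, or
concept phrasings outside its lexicon. Passing tests on synthetic corpora
therefore demonstrate that the pipeline's machinery is correct and that
the method recovers multi-symptom patients when concepts are detectable;
they say nothing about detection difficulty on real notes, where reported
sentence-level performance varies widely by concept.

## Features

- N-gram block: binary presence of uni- and bi-grams over lowercased
  alphanumeric tokens, document frequency computed per training
  *sentence* (the classification unit), retained iff
  `min_df ≤ df < max_df` with defaults 0.05/0.95 — boundary semantics
  chosen so that exactly-5% survives and exactly-95% is removed. Binary
  rather than counts or tf-idf: sentences are short enough that presence
  and count nearly coincide, and presence is the simplest faithful
  encoding. Tri-grams are excluded (no measured gain in development).
- Embedding block: 768 dimensions by default. The default backend hashes
  word-boundary-aware character 3–5-grams into the slots with alternating
  signs, applies a seeded slot permutation/sign flip, and L2-normalizes.
  It is deterministic, offline, and gives sub-token robustness that the
  n-gram block lacks; a pretrained clinical transformer can be plugged in
  through the same `embed` contract where weights are available.
- Blocks are concatenated n-grams first, layout recorded.

## Sentence classifiers

Per concept: optional negative downsampling (keep `round(rate · n_neg)`
negatives, all other classes untouched), then a 2/3–1/3 class-stratified
split; a one-vs-rest SVM (LinearSVC for linear, SVC for rbf) fits the 2/3
portion and per-class isotonic regressions map its margins to
probabilities on the 1/3 portion, renormalized to the simplex (uniform
fallback when every calibrator returns 0). Downsampling happens *before*
the calibration split so the calibrator sees the same class mix as the
base model. One-vs-rest (rather than one-vs-one) keeps one margin and one
calibrator per class. Model selection is 5×2 cross-validation with
patient-disjoint halves scored by multiclass log-loss (probabilities
clipped at 1e-15); ties prefer the smaller penalty, then linear over rbf.
The per-concept settings selected in the development study (kernel,
penalty C, downsampling, reduction) ship as the `reference` classifier
configuration; both SVM knobs (C and the rbf width γ) are exposed.

## Reduction

Closed-form reductions on the positive-probability stream: max, min,
mean, noisy-or `1 − ∏(1 − p)`. Empty evidence reduces to 0 for every
kind — a patient with no relevant sentences cannot be ranked up. Trained
combiners (linear SVM with isotonic output scaling, small MLP) operate on
fixed-length summaries — count, max, mean, and top-3 order statistics of
each of the three class-probability streams — so variable sentence counts
feed a fixed input width. The patient gold standard is positive iff at
least one unqualified annotation of the concept exists for the patient.
Per-concept selection maximizes validation average precision; ties break
noisy-or > max > mean > min > trained, preferring closed-form,
evidence-accumulating reducers. Noisy-or is implemented leak-free (no
background-cause term): nothing in the design calls for a leak
probability, and a leak term would bound every patient away from 0.

## Ranking

The target is the count of gold-positive concepts excluding
epilepsy/seizures (0–9); epilepsy remains one of the ten predictors. The
fit is maximum-likelihood log-link Poisson via IRLS (statsmodels GLM,
tolerance 1e-10), plain Poisson rather than quasi-Poisson — the count
target is bounded and the score is used only for ordering, so dispersion
correction would change nothing that matters. D² = 1 − residual/null
deviance. Ranking sorts by descending score with lexicographic
patient-id tie-breaks. The reference coefficient vector from the
development cohort ships with intercept 0: the intercept was not
published, the ordering is invariant to it, and absolute score values are
site-specific (so the development cohort's score distribution — mean
5.136, top-200 threshold 17.260 — is not reproducible, by design).

## Evaluation

- Average precision uses the stable-sort step-function definition (ties
  keep input order, no interpolation), which is exactly checkable against
  a brute-force oracle; AUC is the Mann-Whitney formulation with ties at
  1/2.
- The review endpoint selects top-k and bottom-k ranked patients and
  emits a seeded shuffled review list with no group labels (blinding).
  Significance on the resulting 2×2 uses two-sided Fisher exact
  (probability ordering) and Yates-corrected chi-square.
- The cluster diagnostic runs spectral clustering (default 5 clusters,
  nearest-neighbor affinity) and a 2-component PCA on the patient
  concept-probability matrix only — never the rank score — so cluster
  concentration of top-ranked patients is an independent consistency
  check on the ranking.

## Pipeline defaults and problem sizes

Stages communicate only through files with per-stage manifests (seeds,
config echo, input hashes); re-running a stage with the same config is
byte-identical. Synthetic end-to-end runs (tests and
`scripts/acceptance.py`) use 2000 patients with 2% planted multi-symptom
cases, 10 partitions with partition 0 as the annotated development set,
and train all concepts with the generic linear C=1.0, no downsampling
configuration, selecting reductions on the validation split. The
development study's per-concept reference settings are deliberately not
used on synthetic text: they were tuned to a specific hospital corpus
(e.g. rbf with C=1e-4 for insomnia) and are meaningless against the
generator's lexicon, though they remain the shipped defaults for
real-corpus use. Problem sizes were chosen as the smallest corpora at
which planted-case recovery and prevalence control are stable across
seeds.

## Known limitations

- The rule-based segmenter under-splits prose with unusual punctuation;
  swap in a model-based segmenter for production notes.
- Isotonic calibration is coarse for concepts with very few qualified
  examples; per-class probabilities remain rank-correct but can be
  step-shaped.
- The generator's lexicon separability inflates patient-level AP/AUC to
  near 1; treat synthetic metrics as machinery checks, not performance
  estimates.
- Note-type filtering is a metadata filter; cohort construction from a
  clinical data warehouse is out of scope.
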