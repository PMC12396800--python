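# Methods

## Problem and model

`nidphen` classifies individual clinical notes as describing an active
neuroinfectious disease (NID) or not. The design assumption is that NID
status is expressed in a note through a relatively small set of clinical
phrase patterns — affirmative findings ("CSF positive for …"), negations
("no evidence of meningitis"), antimicrobial therapy, and suggestive
symptoms — and that the informative content of a long note is
concentrated in the neighborhoods of such phrases. The pipeline therefore
restricts each note to lexicon-match context windows before building a
bag-of-words representation, and classifies the resulting sparse n-gram
count vector with a gradient-boosted tree ensemble.

The model is discriminative and order-agnostic beyond trigrams: negation
is handled lexically (negation phrases produce their own n-grams, e.g.
"evidence meningitis" from "no evidence of meningitis" after stopword
removal), not by syntactic negation-scope detection.

## Pipeline parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `min_chars` | 5000 | characters | notes shorter than this rarely carry enough clinical detail; boundary is inclusive (length ≥ 5000 kept) |
| `buffer` | 100 | characters | context captured on each side of a lexicon match |
| n-gram range | 1–3 | words | unigrams through trigrams; joined by single spaces |
| `min_doc_freq` | 2 | documents | drops hapax n-grams; the initial pool size is corpus-dependent |
| `reg_strength` | 10 | inverse penalty (C) | L1 logistic selection; larger = weaker penalty, matching the dominant convention in L1 tooling |
| `max_iterations` | 1000 | solver iterations | selection-fit budget |
| `n_rounds` | 10 | bootstrap rounds | stability selection; a term must be nonzero in ≥ ⌈n_rounds/2⌉ rounds |
| `train_fraction` | 0.8 | proportion | note-level stratified split |
| `k_folds` | 5 | folds | patient-grouped, label-stratified CV for family comparison |
| `threshold` | 0.5 | probability | decision cutoff for threshold metrics; neutral default, configurable |
| `bootstrap_iterations` | 1000 | resamples | percentile-bootstrap CIs |

XGBoost hyperparameters (300 trees, depth 6, learning rate 0.1, `hist`
tree method, positive-class weight n_neg/n_pos) are conventional
defaults, exposed via `params`; nothing in the method constrains them.

## Procedure details and numerical choices

**Matching and windows.** Matching is case-insensitive because
lowercasing happens only after window extraction; otherwise capitalized
clinical terms ("CSF", "Meningitis") would be missed. Overlapping
matches from different patterns are all reported and deduplicated by the
interval merge, which also merges *touching* expansions. Zero-length
regex matches are discarded.

**Normalization order.** Lowercase; non-alphabetic characters are
replaced by spaces (not deleted) so "HSV-1" yields `hsv` rather than
fusing neighbors; whitespace collapses; tokens shorter than 3 characters
are dropped; stopwords are removed before lemmatization; the stopword
and length filters are re-applied to the lemmas so normalization is
idempotent (a lemma such as "other" from "others" can itself be a
stopword). The lemmatizer is a small dictionary-less rule lemmatizer in
the morphy style: an irregular-form table plus ordered suffix rules with
guards for Latinate clinical suffixes (-is, -us, -ss), noun-only, no POS
tagging. It trades linguistic completeness for determinism and
consistency — both inflections of a term map to one feature column,
which is all bag-of-words requires.

**Window blocking.** N-grams are formed strictly within windows. Merged
windows are textually discontiguous regions of a note, so a cross-window
n-gram would be an artifact of concatenation; blocking is the
conservative choice.

**Selection.** "Stability selection with majority vote": the L1 fit is
repeated on bootstrap resamples of the training rows and a term is kept
when its coefficient magnitude exceeds 1e−8 (solver slack) in at least
half the rounds. With `n_rounds=1` this degenerates to a single
full-sample L1 support. Class weights are n/(2·n_c). Resamples missing a
class are redrawn. The curation list is a versioned plain-text artifact
so the manual-review step is reproducible; removal is exact string match
on the space-joined n-gram, and absent terms are logged as no-ops.

**Split and CV.** The split is note-level with stratification on the ICD
flag, after which test notes sharing a patient with the training set are
moved to a `pruned` bucket (training is untouched, so the train size is
exactly what the fraction dictates and the evaluated test set may be
smaller). CV folds are patient-grouped *and* label-stratified; a fold
containing one class raises an error advising fewer folds. A tie in mean
AUPRC is broken by family-name order and logged.

**Metrics.** AUROC uses the tie-corrected rank formula, exactly equal to
the pairwise P(pos > neg) + ½ P(tie) definition. AUPRC is step-wise
average precision over distinct thresholds; trapezoidal interpolation in
PR space is deliberately avoided (it overestimates). Threshold calls use
`score ≥ threshold`. Undefined ratios (precision with no predicted
positives) are reported as `None`, never as 0. Bootstrap CIs are the
2.5/50/97.5 percentiles over resamples of note indices; single-class (or
metric-undefined) resamples are redrawn and counted, keeping the number
of effective draws fixed. Notes with zero lexicon matches are scored on
an all-zero feature row and flagged `no_windows` in the prediction
output rather than being silently dropped.

## The synthetic generator

`nidphen.synth` emulates the structure of a lumbar-puncture-enriched
hospital cohort; its defaults are the study-regime conditions: 2469
patients contributing 1 + Poisson(0.215) notes each (capped at 6,
~3000 notes), patient-level disease probability 0.16 (all of a patient's
notes inherit the status, so leakage pruning and grouped CV are
meaningfully exercised), notes padded with neutral boilerplate to
≥ 5000 characters, and per-note ICD flags drawn at sensitivity 0.97 /
specificity 0.59 against truth — a regime in which roughly half the
corpus ends up ICD-flagged.

Positive notes embed Poisson(`signal_strength`=4) affirmative-NID
phrases plus Poisson(2) drug and Poisson(2) keyword phrases; negative
notes embed Poisson(1.5) negation and Poisson(2) keyword phrases, with
occasional (Poisson(0.7)) empiric-antibiotic mentions so drug terms are
not trivially separating. `signal_strength`=4 was chosen as realistic
for a ≥ 5000-character note documenting an active CNS infection: such
notes restate the diagnosis and findings several times. Phrases are
literal surface realizations paired with each lexicon regex (a regex is
not a generator); the filler-sentence bank is screened against the
lexicon at test time so every lexicon hit in generated text is a planted
phrase.

**Planted-signal recovery** is assessed per pattern: tokens planted by
one phrase are perfectly collinear count columns, so an L1 fit keeps an
arbitrary representative among them; a pattern counts as recovered when
*any* n-gram of its normalized match core survives selection.

**What passing tests do not show.** The generator's language is
lexically trivial — real notes paraphrase, misspell, hedge, copy
forward, and mention historical rather than active infections (the
dominant error sources in real chart review). Near-perfect synthetic
AUROC therefore validates the machinery (windowing, blocking, selection,
weighting, evaluation), not expected real-world accuracy; published
results on real cohorts of this kind report hold-out AUROC near 0.98
with AUPRC near 0.89 internally and 0.78 externally.

## Open design decisions

* The "iterative" L1 reduction is operationalized as bootstrap stability
  selection; the alternative (a single fit, or recursive refitting on
  the surviving support) is not what gives majority-vote robustness.
* Whether the published feature reduction included a frequency
  pre-filter is unknown; here the pool is defined by `min_doc_freq` and
  the reduction by L1 survival plus curation.
* The regularization constant is read as the *inverse* penalty (larger =
  weaker), the dominant convention in L1 logistic tooling; it is a
  config knob so the opposite reading can be tested.
* Counts, not binary indicators, populate the matrix; no TF-IDF — plain
  bag-of-words.
* Chart-review count arithmetic: with 465 + 14 confirmed cases,
  specificity computed from the 2×2 is 1486/2521 = 58.9%; the package
  reports the arithmetic value.

## Known limitations

* Regex dialect is Python `re`; no word-boundary anchoring is imposed on
  lexicon patterns beyond what each pattern declares itself.
* The rule lemmatizer over- and under-stems rare forms ("lens" → "len");
  consistency, not correctness, is what featurization needs.
* No sentence segmentation, negation-scope detection, temporal
  reasoning, or structured-lab integration.
* The decision threshold (0.5) is not calibrated; threshold metrics are
  reported at the configured cutoff and the bootstrap quantifies their
  sampling noise, not calibration error.
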