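# Methods

## Problem and pipeline

The package discovers a cohort of pregnant social-media users from a stream
of short posts and mines their timelines for gestational-age and
medication-mention information. The pipeline is a narrowing funnel:

    posts → seed prefilter → 14 query patterns → supervised PIT filter
          → cohort roster → timeline analyses (trimesters, drug mentions)

A *pregnancy-indicating post* (PIT) is a first-person statement by the
author about her own current pregnancy; third-person ("my sister is five
weeks pregnant"), figurative ("having a baby JB day") and hypothetical
("one day I am going to have a baby") posts are retrieval false positives
that the classifier must remove.

## Pattern retrieval

Collection APIs track broad keywords, not regular expressions, so retrieval
is two-staged: a substring prefilter on five seed terms (which also catches
hashtag forms such as `#pregnant`), then 14 case-insensitive regular
expressions over normalized text (lowercased, Unicode apostrophes mapped to
`'`, whitespace collapsed). Realization conventions for the published
simplified forms: terms joined by "and" become an unordered conjunction of
lookaheads; "exact sequence with whitespace or punctuations in between"
becomes the terms in order separated by `\W+` (any non-word characters —
the exact punctuation class is not specified upstream, and `\W+` is the
broadest reading consistent with the examples).

Two realization choices deserve note for pattern 1, the first-person
time-phrase pattern. Retrieved sample posts include ones where the
first-person marker *follows* the time phrase and ones using "days" as the
unit, so the default realization requires `(im|i am|i'm)` anywhere in the
post (not strictly before the time phrase) and includes day/days in the
time class. No digit is required before the unit — the original
hand-written pattern had none. Both choices are encoded in the shipped,
auditable pattern config (`pregcohort dump-patterns`) and can be
overridden.

Every realization embeds at least one seed term, making the prefilter a
necessary condition for any match (property-tested). Duplicate posts (same
user and text) collapse to the earliest timestamp to suppress
retweet-style noise. An optional Latin-printable filter (≥80% of
characters) approximates the upstream manual removal of encoding-broken
and non-Latin posts; it is off by default.

## Feature representation

A post maps to five concatenated blocks in fixed order; any subset can be
disabled, which is how the ablation rows are produced.

* **n-grams** — counts of 1–3-grams over Porter-stemmed lowercase tokens,
  stopwords kept, restricted to a vocabulary fitted on training data with
  `min_count = 2` (controls sparsity; indices assigned lexicographically
  for platform-independent layouts). The Porter stemmer is implemented
  in-package from the published algorithm (five rule steps over the
  consonant-vowel measure, words of ≤2 letters unchanged) and validated
  against the algorithm's worked examples.
* **embeddings** — the elementwise sum of per-token dense vectors (default
  dimension 400 to match public Twitter-trained tables; fixtures use
  smaller dimensions). All tokens contribute, including stopwords; tokens
  absent from the table contribute nothing.
* **clusters** — binary presence indicators over a fixed hierarchical
  clustering (default 1000 base clusters), read from
  `bitstring-path<TAB>token<TAB>frequency` files with cluster index = rank
  of the distinct path in file order.
* **sentiment** — six slots: positive-term count, negative-term count, sum
  and mean of prior-polarity scores, sums of subjectivity polarity and
  strength. The upstream description names three lexicon families but not
  the exact statistics; this fixed six-slot summary is frozen for
  reproducibility and configurable lexicon files are the extension point.
* **structural** — six slots: word count, character count, sentence count
  (split on `.!?` runs), mean sentence length in words,
  punctuation-character count, uppercase ratio. Ratios are 0 on empty
  text.

The tokenizer splits on whitespace and strips surrounding punctuation,
keeping contractions whole ("i'm" stays one token, preserving the pattern
vocabulary) and hashtags/@-mentions as single tokens with the marker
recorded. Embedding and cluster lookups use raw tokens; stems are used
only for n-grams, matching how public embedding and cluster resources are
keyed.

## Classification

Defaults: linear SVM with C = 1.0 and inverse-class-frequency weighting
(the annotated class balance upstream was roughly 2:1); random forest with
100 trees and √p features per split; Gaussian Naive Bayes on the dense
vector as the baseline (the dense blocks may be negative, ruling out a
multinomial event model). The ensemble takes any odd number ≥3 of fitted
members and votes by strict majority; the default trio is {NB, SVM, RF}.
Because margin-based training is scale-sensitive, the embedding, sentiment
and structural blocks are standardized with training-set statistics;
count-valued blocks are left raw. Scores are oriented so larger means more
PIT-like (signed margin for the SVM, PIT probability otherwise); no
probability calibration is performed — ROC curves sweep raw scores.

All fits are seed-deterministic end to end, and a model archive
(estimator + scaler + hyperparameters + training digest + seed) reloads to
bit-identical predictions.

## Evaluation protocol

Stratified 80–20 splits; stratified k-fold cross-validation (default
k = 10) with metrics computed by pooling held-out predictions across folds
(each instance predicted exactly once), which is also how the per-pattern
breakdown attributes pooled predictions to source patterns (multi-pattern
posts count once per pattern). The accuracy interval is the Wilson score
interval at 95% (the method is a package choice; upstream reports an
unnamed 95% CI). Learning curves train on nested stratified subsets
(10%…100% under one seed — nesting mirrors a growing annotation effort and
reduces between-point variance) against a fixed test set, with ROC/AUC per
point. Ablations report the all-blocks row, leave-one-out rows and
single-block rows from the same pooled-CV procedure.

## Annotation operations

Consensus labels are resolved by strict majority with a configurable tie
policy (default: discard with a warning). Fleiss' kappa is computed via
statsmodels' implementation behind the package surface; tests cross-check
it against a direct evaluation of the published formula, and the uniform
null simulation recovers κ ≈ 0. A single-category matrix yields NaN with a
warning (chance agreement is 1, so kappa is undefined) rather than a
crash.

## Trimester inference

Rules: seed terms "pregnant"/"pregnancy"; a symmetric context window of 6
tokens on each side of the seed (the upstream description says "window of
size 6" without specifying the convention; per-side is the default and
"6 total" is selectable); a mention requires a temporal unit
(week/month/day) and a number (digits, ordinals, number words one–forty)
in the window, paired by nearest-preceding-number. Unit priority when a
window holds several pairs: weeks are primary, with a co-occurring day
pair added as days/7 ("39 weeks and 6 days" → 39.86); months are used only
when no week pair exists, at 4.345 weeks per month (365.25/12/7); day-only
mentions are accepted only in "since"-style phrasings, at days/7.
Conversions outside [1, 45] gestational weeks are rejected as implausible.

Start-date estimation takes the median of per-mention candidates
(timestamp − 7·w days) and reports the median absolute deviation in days;
the median makes the estimate robust to jokes and quoted speech, and the
dispersion lets callers drop unreliable timelines — extensions motivated
by the roughly 50% categorization accuracy reported for the simplest
version of this rule set upstream. Trimester boundaries: week ≤ 12 → 1,
≤ 27 → 2, else 3; post phases use elapsed weeks from the estimated start
(< 1 week → pre, > 40-week term → post; term length configurable).
Optional, off by default: hashtag segmentation (digit/letter splits plus
greedy dictionary segmentation, enabling `#37weekspregnant`) and countdown
phrasings ("10 weeks to go" → term − 10).

## Medication mentions

Token-equality matching (case-insensitive) against a
`canonical: variant, variant` lexicon with cross-drug variant collisions
rejected at load. Only posts labeled T1/T2/T3 are counted. The shipped
dozen-drug lexicon is an example fixture; the real analysis set is a user
input. Counts are mentions, not intake events — no intake claim is made.

## Synthetic data: what it does and does not show

The generator is the package's falsification harness, not a realism claim.
Corpora mix announcement templates (each co-designed to match ≥1 stock
pattern — verified by running the matcher) with three confounder families
(third-person, figurative, hypothetical) at configurable weights
(defaults 0.40/0.35/0.25); announcement and confounder fillers come from
disjoint pools, with a `vocabulary_overlap` knob and a 10% lexical-noise
rate (appended hashtags/interjections, filler typos that never touch
pattern-bearing tokens). Timelines plant progress statements at integer
gestational weeks timestamped exactly at start + 7w days, filler posts in
every phase, and drug mentions per a phase schedule; mention-carrying
users number exactly `round(prevalence × n_users)` (stratified rather than
Bernoulli, so the planted rate is exact and recovery assertions test the
detector, not binomial noise). The default prevalence of 0.44 mirrors the
detectable-fraction regime reported for real timelines.

Because templates are linearly separable by construction, held-out F1 ≈ 1
on synthetic corpora demonstrates that featurization, training and the
funnel compose correctly — not real-data performance, where reported
pregnancy-class F1 is in the high 0.80s. Likewise exact start-date and
phase recovery shows the arithmetic is self-consistent; real progress
statements are noisier (jokes, countdowns, conflicting mentions). What the
synthetic suite *can* falsify: pattern-template co-design, prefilter
necessity, funnel monotonicity, seed determinism, metric formulas against
brute-force oracles, and exact ground-truth recovery.

## Numerical and degenerate-input choices

Lexicographic n-gram indexing and sorted JSON/JSONL output make reruns
byte-identical. Empty texts featurize to zero blocks with ratio slots 0.
Equal classifier scores give AUC 0.5 (trapezoid over the two-point ROC).
Zero-variance columns standardize with scale 1 to avoid division by zero.
Timestamps are UTC; naive inputs are assumed UTC. Problem sizes in the
acceptance script (2000-post corpus, 1000 timelines, fixture embedding
dimension 24 and 32 clusters) are the package's standard desk-scale study
conditions.

## Known limitations

* Pattern realizations are one reading of printed simplified forms; the
  original deployed expressions are not public. The config file is the
  audit/override path.
* The lexicon files shipped for tests are synthetic fixtures, not the
  published sentiment resources; results on real data require the real
  resources (word2vec-text embeddings, cluster paths, lexicons).
* The deep-learning member of the original ensemble is out of scope; the
  ensemble generalizes to any odd set of provided models.
* Trimester inference trusts explicit progress statements; outcome events
  (births, losses) are not detected, so late-timeline phases may be wrong
  for ended pregnancies.
* Token-equality drug matching misses misspellings by design.
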