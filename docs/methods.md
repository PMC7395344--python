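# Methods

## The computable phenotype

A patient is a **presumptive case** if, during the half-open study window
[2016-01-01, 2018-01-01), their record contains any occurrence of a
sarcopenia / cachexia / frailty text term or phenotype ICD code
(ICD-9 797, 799.4; ICD-10 R54, R64, M62.84; exact string match on the
normalized code — "797" does not match "797.0"; a prefix mode exists but is
off by default). A presumptive case is **confirmed** if at least one
occurrence is positive after classification (and, where two reviewer label
streams exist, after adjudication); a presumptive with only
negative/uncertain occurrences is **rejected**. Adults with an in-window
encounter and no occurrences at all are **control-eligible**. Uncertain
occurrences do not confirm a case but do exclude a patient from the control
pool — a deliberate, conservative reading; the opposite choice would only
add borderline cases.

The index date is the earliest in-window positive occurrence for cases and
the earliest in-window encounter for controls; all index-anchored variables
(closest lab, post-index medications) hang off it.

### Text rules

Sentence segmentation splits on `.;!?` followed by whitespace and on
newlines (clinical notes are newline-heavy). Negation uses a NegEx-style
trigger set (`no, not, without, denies, no evidence of, ruled out,
negative for`; post-triggers `was not present, is absent`) within five
tokens of the term, bounded by the sentence. Third-person attribution is
resolved lexically: a kinship/caregiver cue in the same sentence ("her
frail mother") marks the mention negative-for-the-patient; no coreference
is attempted. Hedges (`possible, questionable, may have, ?`) adjacent to
the term give *uncertain*. Precedence: negation → third person → hedge →
positive. Classification is a pure function of the sentence.

The lexicon holds the grammatical variants of the three terms plus all
single-edit (substitution / deletion / insertion / adjacent transposition)
misspellings of forms longer than five characters, dropping variants that
collide with a stop-list of common English words or with another
condition's neighbourhood. Matching is case-insensitive at word
boundaries; because every form is one alphabetic token, detection scans
maximal word tokens against a hash set — equivalent to boundary-anchored
regex matching but linear-time.

## The synthetic cohort

The generator emulates the statistical structure a multi-system EHR
extract would present to this pipeline:

* **Condition mix.** Cases draw a nonempty subset of {S, C, F} from an
  explicit 7-cell joint distribution. The default mix (frailty-dominant,
  with a large C∩F overlap cell and ~15.6% of cases multi-condition) is
  patterned on a published statewide validation cohort; the subset
  probabilities are 89/2607/5402/33/57/1273/133 over 9594.
* **Term use.** Each case-condition receives a geometric number of planted
  mentions (mean 2 — the within-case mention-count distribution is not an
  emulated quantity, just a dial). Mentions are positive with the
  per-condition positive-use rate (0.97 / 0.90 / 0.95), with at least one
  positive forced per case-condition; non-positive mentions split evenly
  between negation and third-person templates. A configurable 6.7% of
  presumptive patients are planted fully rejected (only non-positive
  uses). These two dials cannot both be met exactly together with the
  per-condition rates — the implied patient-level positive-use rates land
  at roughly (0.98, 0.92, 0.96) — because the real rejected population had
  condition overlaps that are not published; the explicit rejected-rate
  dial wins and the deviation is ≤ 2 points.
* **Misspellings.** Each planted surface form is perturbed with one random
  single-character edit (rate 0.05 by default), resampled until the edited
  form is still in the lexicon, so planted mentions remain detectable by
  construction. Five-letter "frail" is never misspelled.
* **Codes.** 13.6% of cases (a patient-level probability) receive an ICD
  code for one of their conditions, plus each additional condition at rate
  0.031 (the published multi-code share among coded cases). Codes are
  planted only alongside text, so `code_only` detection never occurs on
  defaults — the pipeline still handles it.
* **Comorbidities.** Each category has a control prevalence and a target
  odds ratio; the case probability is the exact odds-ratio inversion
  p₁ = OR·p₀ / (1 − p₀ + OR·p₀). CKD stages 3/4/5 are one mutually
  exclusive categorical so the nested stage flags stay consistent; the
  stage-3 odds ratio (~2.42) is derived so the stages-3–5 aggregate hits
  its target (3.96) given the stage-4 and stage-5 targets. Flag draws
  materialise as ICD-10 codes chosen so that both the comorbidity flagger
  and the Charlson index respond (plus non-Charlson fillers such as I25.10
  and G62.9 so control Charlson stays low, and benign noise codes Z00.00 /
  J06.9).
* **Demographics, labs, utilization.** Age ~ Normal(74.9, 16.8) clipped to
  [18, 102] for cases *and* controls (same distribution, so exact matching
  is feasible); sex 59% female; race 10/69/21% black/white/other. Labs are
  normal (albumin, prealbumin) or lognormal (BMI, weight, HbA1c) with
  location/scale solved from target median and quartiles per arm, and
  per-arm measurement probabilities reproducing differential missingness
  (prealbumin is measured in only ~1% of controls). Height is planted
  consistent with weight and BMI so BMI recomputation agrees with the
  recorded value. Hospitalization counts are Poisson (means 2.5 / 0.15);
  medication dispensings are Bernoulli per class per arm with dates in
  [index, window end).
* **Prevalence.** The eligible-population case prevalence is not a
  published quantity (the source database denominator is in the millions);
  the default 0.05 is a realistic choice for an adult multi-system
  population and leaves a deep control pool for exact matching.

What the generator does **not** emulate: realistic clinical language
(notes are ~30 fixed sentence templates with slots), correlation between
comorbidities, secular coding trends, within-patient lab trajectories, or
imperfect reviewer behaviour. Consequently the NLP-fidelity tests
demonstrate internal consistency of detector and generator — 100% recovery
on template text — not performance on real clinical prose.

## Matching

Exact keys (birth year, sex, race), 1:1, without replacement. Within each
stratum min(#cases, #controls) pairs form, with uniform-random control
selection under a recorded seed; surplus cases are reported unmatched and
excluded from paired analyses. For exact-key matching the per-stratum
greedy count equals the maximum bipartite matching (verified against a
Hopcroft-Karp oracle in the tests). No caliper: "year of birth" is taken
literally, which also makes the result order-independent.

## Statistics

* **Signed-rank** (paired continuous): differences case − control, zeros
  discarded (classical Wilcoxon, not Pratt), midranks for ties. Exact
  two-sided p (2·min(lower, upper) tail, capped at 1) by convolution over
  sign assignments when the effective n ≤ 25; otherwise normal
  approximation with tie correction and 0.5 continuity correction.
* **Matched-pair OR** (paired binary): OR = n₁₀/n₀₁, the conditional-ML
  estimate for 1:1 pairs (equal to univariate conditional logistic
  regression); Wald 95% CI on the log scale; continuity-corrected McNemar
  p. Boundary counts (n₁₀ or n₀₁ = 0) return 0/∞ with a one-sided
  Haldane-corrected interval, flagged; no discordant pairs → flagged
  undefined.
* **Rank-sum** (unpaired continuous): midranks; exact by enumeration of
  rank splits when n₁+n₂ ≤ 12, else normal approximation with tie and
  continuity corrections.
* **2×2 categorical**: Fisher's exact (two-sided, summing hypergeometric
  probabilities ≤ observed) when any expected cell < 5, else Pearson
  chi-square without continuity correction; a zero margin gives p = 1,
  flagged degenerate. The rule applied is recorded in the result.
* Missing continuous values drop the pair (pairwise-complete); per-variable
  analyzable n is reported. No multiple-testing correction by default
  (two-sided p < 0.05), with a Benjamini-Hochberg helper available.

The exact-enumeration thresholds (25 / 12) keep the exact branches well
under a second while the approximate branches agree with the exact p to
< 0.02 just above the cutoffs (tested).

## Charlson index

Quan (2005) ICD-9/ICD-10 coding algorithms, shipped as editable JSON
package data, with the original weights (MI 1 … metastatic 6, AIDS 6) and
hierarchy (diabetes-with-complication over diabetes, metastatic over any
malignancy, moderate/severe over mild liver). The analysis-table
comorbidity categories use a separate documented prefix mapping in the same
format, since the source study's own code lists are not available.

## Problem sizes and determinism

Default runs use 20 000 patients (~1 000 cases); the test suite uses 2 000
for pipeline fixtures, 20 000 for the convergence and determinism checks,
2 000 null replicates per test for type-I calibration, and 500 replicates
of 2 000 pairs for CI coverage. All randomness flows through seeded
numpy generators; a config plus seed reproduces every output file
byte-identically.

## Known limitations

* Detection quality claims are bounded by the template corpus; no claim is
  made about recall on free clinical text.
* Reviewer adjudication runs on simulated label streams; real dual review
  would disagree in ways the simulation does not model.
* Only univariate paired tests are provided (multivariable conditional
  logistic regression is out of scope).
* The albumin/prealbumin unit label is stored as configured ("mg/dl",
  following the emulated table) and is not corrected to g/dl.
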