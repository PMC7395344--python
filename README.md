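# ehrpheno

Computable phenotyping of **sarcopenia, cachexia and frailty** from
electronic health records, with a matched case-control analysis — exercised
end to end on a synthetic EHR generator so that no patient data is needed.

Muscle-health syndromes are widely under-coded: clinicians write "cachectic"
or "appears frail" in notes far more often than they assign the
corresponding ICD codes (797/R54 for frailty, 799.4/R64 for cachexia,
M62.84 for sarcopenia). `ehrpheno` implements a rule-based computable
phenotype that fuses both signals:

1. **Text detection.** A lexicon of grammatical variants and
   single-edit misspellings of the three condition terms is matched at word
   boundaries in clinical notes. Each mention is classified as *positive*,
   *negative* or *uncertain* using NegEx-style sentence-bounded triggers:
   negation within a 5-token window ("not sarcopenic", "no evidence of
   cachexia"), third-person attribution ("her frail mother"), and hedges
   ("possible sarcopenia").
2. **Code detection.** Exact-match ICD-9/ICD-10 phenotype codes, always
   counted as positive occurrences.
3. **Status assignment.** Adults with an in-window encounter partition into
   *confirmed cases* (≥1 positive occurrence), *rejected presumptives*
   (occurrences, none positive) and *control-eligibles* (no occurrences).
   The dual-reviewer adjudication rule (positive ∧ uncertain → positive,
   etc.) is implemented for reviewer label streams.
4. **Matching.** Controls are matched 1:1 to cases exactly on birth year,
   sex and race, without replacement; per-stratum greedy assignment attains
   the maximum bipartite matching.
5. **Analysis.** Per-patient variables (comorbidity flags, Quan-coded
   Charlson index, index-anchored labs and BMI, hospitalizations, post-index
   medications) are compared with the matched-pair battery: Wilcoxon
   signed-rank for continuous variables and the 1:1 conditional odds ratio
   OR = n₁₀/n₀₁ over discordant pairs (the conditional-ML estimate, with
   Wald CI and McNemar p). Unpaired subgroup contrasts use the rank-sum and
   chi-square/Fisher tests.

The synthetic generator plants ground truth — condition sets with a
realistic overlap pattern, positive/negated/third-person term usage,
ICD-coding probability ~13.6%, and case-control contrasts in comorbidities,
labs and medications — so every stage is testable against known answers.

## Worked example

```bash
ehrpheno run-all --seed 1 --outdir out/
```

runs the whole pipeline on a 20 000-patient synthetic cohort and writes
every intermediate artifact (`notes.jsonl`, `mentions.csv`,
`phenotypes.csv`, `pairs.csv`, `variables.csv`, `results.json`, TSV/JSON
tables). From `out/summary.json` and `out/results.json` of that run:

```text
confirmed cases            958 / 1031 presumptive  (92.9% confirmation)
text terms only            85.1%   |  with ICD code  14.9%
positive term use          sarcopenia 100.0%, cachexia 93.6%, frailty 93.9%
>=2 conditions             17.3% of cases
matched pairs              958
hypertension               65.2% cases vs 34.8% controls, OR 3.58, p ~ 2e-37
BMI (median, Q1-Q3)        22.3 (19.0-26.2) vs 28.2 (24.6-32.4), p ~ 1e-36
Charlson index             3 (1, 4) vs 1 (0, 2), p ~ 2e-92
```

Interpretation: the detector confirms ~93% of presumptive patients (the
rest used the terms only negatively or about another person); most cases
carry no phenotype ICD code; and cases show the planted excess of
comorbidity burden and the planted BMI deficit, recovered through the full
detection → matching → paired-testing chain. Library use without the CLI:

```python
from ehrpheno import GeneratorConfig, generate_cohort, build_phenotypes

dataset, truth = generate_cohort(GeneratorConfig(n_patients=5000, rng_seed=7))
phenotypes, mentions, occurrences = build_phenotypes(dataset)
```

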