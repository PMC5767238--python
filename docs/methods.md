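# Methods

## What the package models

`langsample` analyzes *connected language* — continuous spontaneous speech
elicited by a picture-description task (the "Cookie Theft" scene) — as a
longitudinal marker of very early cognitive decline. The pipeline has four
stages, each a module:

1. **Transcripts** (`chat_io`). Samples are represented as ordered
   *C-units* (an independent clause plus all its modifiers), read from a
   documented subset of the CHAT transcription format: main participant
   lines, examiner-prompt lines, a morphology tier (`%mor`, one
   `pos|lemma` entry per non-maze word), a grammatical-relation tier
   (`%gra`), and disfluency ("maze") coding — filled pauses (`&-um`),
   unfilled pauses (`(.)`), repetition (`[/]`), revision (`[//]`) and
   false-start (`[/-]`) retraces. Maze material is flagged and excluded
   from all content measures; examiner prompts are counted (they occupy
   sample time) but contribute no tokens. Tokens are lower-cased and
   terminators are not tokens. `parse_chat` and `write_chat` are exact
   inverses on every transcript the generator produces, which the test
   suite exercises as a round-trip property.

2. **Discourse measures** (`features`). Ten analysis measures in four
   groups plus five descriptive measures, computed over non-maze words
   only:

   - Semantic: percent nouns, percent verbs (of total words), pronoun
     index = pronouns / (nouns + pronouns);
   - Syntax: verb index = verbs / utterances, proposition density =
     (verbs + adjectives + adverbs + prepositions + conjunctions) / words,
     grammatical complexity = embedding relations / all relations;
   - Lexical: type-token ratio = unique words / words, number of unique
     words, semantic-unit count (distinct scene content units mentioned,
     against a configurable checklist shipped as YAML);
   - Fluency: maze index = (filled pauses + false starts + revisions +
     repetitions) / utterances;
   - Descriptive: total words, total semantic units, MLU (words per
     C-unit), words per minute, semantic units per minute (durations
     include examiner-prompt time).

   Ratios with zero denominators are reported as missing, never as 0. The
   maze index follows its stated definition and omits unfilled pauses by
   default; `include_unfilled_pauses=True` adds them, since transcription
   practice codes both. Unique words count distinct lower-cased surfaces,
   the usual type-token convention.

3. **Factor scores** (`factors`). Four latent constructs — Semantic,
   Syntax, Lexical, Fluency — are scored as weighted sums of standardized
   measures, `factor = sign · Σ w_m (x_m − mean_m)/sd_m`, with reference
   means/SDs calibrated on a reference sample (`calibrate_reference`).
   The Semantic and Fluency factors are multiplied by −1 so that higher
   always means better performance. Loadings are configuration: the
   default uses equal-magnitude weights within each factor with signs
   encoding raw direction (the raw semantic composite rises with pronoun
   use and verb percentage, falls with noun percentage). Whether published
   factor scores of this kind are regression-based estimates or weighted
   sums is generally not recoverable from reports; the weighted-sum
   contract is the documented choice here, and calibrated loadings can be
   swapped in via YAML. A missing constituent measure propagates to a
   missing factor score; remaining weights are never silently
   re-normalized, because that would change the construct.

4. **Longitudinal models** (`models`). Factor trajectories are modeled by
   a linear mixed model with a subject-specific random intercept and no
   random slopes: `y_ij = x_ij'β + b_i + e_ij`, `b_i ~ N(0, τ²)`,
   `e_ij ~ N(0, σ²)`, fit by REML. Time is age at visit, rounded to two
   decimals and centered at 63 years. The base fixed effects are
   intercept, centered age, sex (male = 1), literacy (a reading standard
   score, z-scored over the analysis sample by default) and diagnosis
   (eMCI = 1). `select_final_model` tests each diagnosis interaction
   (with age, sex, literacy) one at a time at α = 0.05, keeps the
   significant ones, refits by REML, and optionally reports a secondary
   refit with depressive symptoms, anxiety and sleep quality as extra
   fixed effects. No multiplicity adjustment is applied by default (a
   Bonferroni option exists). Baseline group contrasts use ANCOVA
   (`adjusted_group_means`: OLS on group + covariates, means evaluated at
   covariate grand means), and associations with neuropsychological
   scores use Spearman rank correlations with pairwise-complete handling.

## Numerical choices

The REML fit exploits the model's structure: with a single intercept
variance the covariance is `σ²(I + λ Z Z')`, `λ = τ²/σ²`, and for fixed λ
the GLS coefficients and profiled `σ̂²` are closed-form through a
per-subject Woodbury identity. The restricted likelihood is then a
function of λ alone, minimized by bounded scalar search on log λ over
e^[−15, 8], with the τ² = 0 boundary checked explicitly and preferred
whenever it is not genuinely worse (the criterion is flat in λ when every
subject has one observation, and the fit then equals OLS). This makes one
fit ~1–2 ms and is exact; the tests verify agreement with two independent
general-purpose REML implementations (statsmodels `MixedLM`, lme4) to
1e-4–1e-5 on fixed effects. A solution at the boundary sets a `boundary`
flag rather than failing. Exactly-fitting (noise-free) data is handled by
clamping the profiled variance away from zero; fixed effects are
unaffected. Rank-deficient designs raise an error naming the collinear
terms (QR diagnostic).

Wald inference uses t statistics with residual degrees of freedom
(`n − p`) by default; the normal approximation is available via
`df_method="normal"`. With 264 subjects × 2 visits the two are
indistinguishable. Reported intervals are 95% Wald CIs. The
degrees-of-freedom method behind published mixed-model p-values is often
unstated; residual df is a deliberate, documented convention.

Inter-rater percent agreement aligns two token sequences by global
minimum-edit-distance with unit costs; among minimum-cost alignments the
one with the most matched columns is used, and agreement is
100·matches/alignment-length (matches + substitutions + gaps). At the
`semantic_coding` level the aligned sequences are the content-unit codes
each transcript triggers, in order of first mention. Published agreement
figures rarely state the alignment level; token-level alignment is the
documented assumption here.

## The synthetic-data generators

**Transcripts.** A `TranscriptPlan` fixes, per C-unit, the non-maze word
count by POS class, the number of embedding relations, a maze-event
schedule, and the content units to mention; plus a transcript-wide
unique-word target and duration. The generator realizes the plan with
per-POS vocabulary pools that are disjoint across classes and filtered
against the content-unit checklist's trigger words, drawing distinct words
until the unique target is met and then reusing words within their class —
so type-token ratio is controlled exactly. Content units are mentioned via
single-word triggers occupying noun slots. Every feature value is
therefore computable from the plan in closed form
(`TranscriptPlan.feature_vector`), giving the extraction pipeline an exact
oracle: write → parse → tally → derive must reproduce the plan's values to
the last bit, which is the first acceptance test (100 random plans). The
generated text is not natural language and is not meant to be; what
passing proves is the counting and coding arithmetic, not linguistic
realism of the tagger or parser on real speech.

**Cohorts.** `simulate_cohort_scores` draws a two-visit cohort of 264
subjects (200 cognitively healthy, 64 eMCI) whose four factor scores
follow the random-intercept model above with independent intercepts and
residuals per factor. Fixed-effect vectors default to the published final
models per factor (e.g. Fluency: age 0.01, male 0.57, literacy −0.70,
eMCI −0.23, age×eMCI −0.03; Syntax literacy 0.75). Covariate
distributions mirror the study sample and preserve its confounding: eMCI
subjects are older at baseline (64.2 ± 5.9 vs 61.1 ± 6.5 years) and more
often male (44% vs 30%); literacy is 106.7 ± 9.3 in both groups and
enters the linear predictor z-scored over the generated records — the
same convention the analysis side uses, so generating and refit
coefficients share one scale. Visit gaps are 2.0 ± 1.5 years truncated
at 0.5. Intercept SD τ = 0.7 and residual SD σ = 0.5 are not published
quantities; they were chosen so that (i) the implied visit-to-visit
intraclass correlation (≈0.66) is consistent with factor scores reported
as stable across visits in unimpaired adults, and (ii) the implied
precision of between-subject effects matches the published SEs (≈0.11
for the sex and diagnosis effects). Depression, anxiety and sleep are
generated as opaque covariates with zero true coefficients.

**What recovery does and does not show.** The recovery studies
(`langsample.recovery`, `scripts/acceptance.py`) generate 200 replicate
cohorts per factor and refit the generating model by REML; mean estimates
recover every generating coefficient (REML fixed effects are unbiased
here). This validates the inference machinery under the model's own
assumptions — Gaussian intercepts and residuals, correct mean structure,
no measurement error — and says nothing about robustness to real-data
violations (skewed scores, informative dropout, diagnosis instability
across visits, length-dependent type-token ratio).

One power fact worth stating: with these variance components the
age-by-diagnosis interaction has SE ≈ 0.017, so an interaction of −0.04
is detected (retained at α = 0.05) in roughly 64% of replicates and one
of −0.03 in roughly 44%. Detection of effects this small in a 264-subject
two-visit design is intrinsically near the 50% knife-edge — even a
design matching the published interaction SE of ≈0.015 would have ≈52%
power for −0.03 — so the screening procedure should be expected to keep
such a term in only about half of replicated studies.

## Problem sizes used

Simulation studies default to 200 replicates per recovery target
(Monte-Carlo SE ≈ 0.001 on the interaction coefficient) and 500
replicates for the false-retention rate of the screening procedure. In
the test suite the recovery tolerance is the 200-replicate protocol's
two-Monte-Carlo-SE band; because an unbiased estimator crosses such a
band in about 5% of batches, a first-batch miss triggers a precise
re-estimation of the recovered mean (10000 pooled replicates) judged
against the same band. These sizes keep the full suite and the
acceptance script to a few minutes on one CPU.

## Known limitations

- The CHAT dialect is a subset; nested retraces, fillers inside retrace
  groups, overlapping maze spans, and the full CHAT header/code inventory
  are rejected rather than interpreted.
- The fallback POS tagger is a closed-class lookup intended only to keep
  untiered documents parseable.
- The default factor loadings are equal-weight placeholders; substantive
  use requires calibrated loadings supplied as configuration.
- Satterthwaite/Kenward-Roger degrees of freedom are not implemented;
  with ≥ 2 observations per subject and hundreds of subjects the residual
  df convention is adequate, but small-sample p-values will be
  anticonservative.
- The cohort generator simulates factor scores directly; it does not
  synthesize transcripts whose extracted features yield those scores.
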