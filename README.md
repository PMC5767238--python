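# langsample

Connected-language analysis of picture-description samples, for research on
speech as a digital biomarker of very early cognitive decline.

Everyday spoken language changes measurably in Alzheimer's-type decline
well before clinical dementia. `langsample` implements an end-to-end,
tested pipeline for studying this in a longitudinal cohort: it parses
C-unit-segmented transcripts of a picture-description task (the "Cookie
Theft" scene) in a documented CHAT-style dialect with maze (disfluency)
coding, extracts the standard discourse measures, combines them into four
latent factor scores — Semantic, Syntax, Lexical, Fluency — and relates
factor trajectories to an early-MCI diagnosis with random-intercept linear
mixed models. Because raw cohort recordings of this kind are not public,
the package also ships first-class synthetic-data generators: transcripts
with fully known composition (an exact oracle for the feature layer) and
simulated cohorts whose factor scores follow the mixed model with known
coefficients (recoverable ground truth for the inference layer).

## The model

For factor score `y_ij` of subject `i` at visit `j`:

    y_ij = x_ij' β + b_i + e_ij,   b_i ~ N(0, τ²),   e_ij ~ N(0, σ²)

fit by REML. Time is age at visit centered at 63 years; the fixed effects
are intercept, centered age, sex (male = 1), literacy (reading standard
score, z-scored), diagnosis (eMCI = 1), and — when retained by screening
at α = 0.05 — diagnosis interactions with age, sex, or literacy. Factor
scores are weighted sums of standardized discourse measures, with the
Semantic and Fluency factors sign-flipped so that higher always means
better performance. See `docs/methods.md` for the measure definitions,
conventions, and numerical details.

## Worked example

Generate three planned transcripts, extract features, and fit the Fluency
model to a simulated cohort:

```
$ langsample sim transcripts --n 3 --out samples --seed 7
$ langsample extract --transcripts samples --out features.csv
$ head -c 300 samples/sim0000.cha
```

A generated main line looks like CHAT with maze coding — here a repetition
retrace (`[/]`) whose material is excluded from the morphology tier:

```
*PAR:	table [/] table big near big water beside stand a hm [/] .
%mor:	noun|table adjective|big preposition|near adjective|big noun|water ...
```

The extracted table (`features.csv`) contains the ten factor measures and
five descriptive measures per sample; for the three samples above:

```
participant_id  total_words  type_token_ratio  maze_index   mlu  semantic_unit_count
       sim0000         70.0             0.671        1.750  8.75                 10.0
       sim0001         50.0             0.300        1.600 10.00                  3.0
       sim0002         58.0             0.448        1.333  9.67                  8.0
```

`total_words` counts non-maze words only; `maze_index` is disfluencies per
C-unit; `semantic_unit_count` is how many distinct scene content units
(boy, stool, overflowing water, ...) the sample mentions.

Simulate a 264-subject cohort from the published Fluency model and refit
it with interaction screening:

```
$ langsample sim cohort --out records.csv --seed 5
$ langsample fit --records records.csv --outcome fluency --select
retained interactions: ['age_centered:dx']
                 estimate      se  ci_low  ci_high       p
term
intercept          0.0598  0.0621 -0.0622   0.1818  0.3357
age_centered       0.0134  0.0079 -0.0021   0.0288  0.0892
sex                0.5620  0.0977  0.3700   0.7540  0.0000
literacy          -0.6789  0.0462 -0.7698  -0.5881  0.0000
dx                -0.2734  0.1117 -0.4928  -0.0539  0.0147
age_centered:dx   -0.0428  0.0163 -0.0749  -0.0107  0.0091
tau^2 = 0.4176, sigma^2 = 0.2867, subjects = 264, observations = 528
```

The screening kept the age-by-diagnosis interaction (the generating model
contains it at −0.03): eMCI subjects decline faster in speech fluency with
age, on top of a lower overall level (`dx` = −0.27) and a higher average
score in men (`sex` = 0.56). Estimates sit within sampling error of the
generating coefficients (0.57, −0.70, −0.23, −0.03).

The library mirrors the CLI: `parse_chat` / `write_chat` /
`percent_agreement`, `extract_features` / `feature_table`,
`calibrate_reference` / `score_factors`, `fit_random_intercept_lmm` /
`select_final_model` / `adjusted_group_means` / `correlation_matrix`, and
`simulate_transcripts` / `simulate_cohort_scores`.

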