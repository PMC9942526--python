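# gamblefit

Computational modelling toolkit for a risky/ambiguous gambling task:
prospect-theory decision rules crossed with value-learning rules, a
synthetic cohort generator, Bayesian-flavored fitting with WAIC model
comparison and stacking weights, behavioral measures with subject
exclusion filters, and full model/parameter recovery pipelines.

## What it implements

- **Task** (`gamblefit.task`): an 8-condition design mixing risk
  (50/50 gambles vs sure options), valence (gains 10..90, losses
  -90..-10, zero), and ambiguity (hidden magnitudes revealed through a
  running score). Schedules have 138 trials in 7 blocks; trial values
  are shared across subjects with per-subject within-block shuffling.
- **Decision models** (`gamblefit.decision`): subjective utility with
  curvature `rho`, loss aversion `lam`, and four multiplicative
  ambiguity weights (risky/sure x gain/loss), tied according to five
  variants (from "all fixed at 1" to "all four free"); softmax choice
  with inverse temperature `gamma`.
- **Learning models** (`gamblefit.learning`): the implied value of
  ambiguous options is either a no-learning baseline (mean unambiguous
  magnitude per valence), a Rescorla-Wagner rule (single or asymmetric
  learning rates), or a Bayesian mean tracker with an adaptive learning
  rate; each learning family supports fixed, shared-estimated, or
  separately-estimated starting values. 5 x 10 = 50 candidate models
  (`gamblefit.modelspace`).
- **Simulation** (`gamblefit.simulate`): cohorts generated from any
  model with parameters drawn from support-matched population
  distributions; fully seeded and reproducible.
- **Inference** (`gamblefit.inference`): per-subject MAP with Laplace
  posterior draws, or empirical-Bayes hierarchical fitting; WAIC
  (deviance scale), stacking weights over WAIC-penalized pointwise
  predictive densities, Efron's pseudo-R2, calibration tables, mean
  learning rates, learning bias, and aversion-coded parameter scores.
- **Behavior** (`gamblefit.behavior`): six aversion-coded gamble
  proportion measures, the no-ambiguous-choice exclusion flag, the
  Mahalanobis/chi-square questionnaire outlier filter, and group-level
  bias t-tests.
- **Recovery** (`gamblefit.recovery`): simulate-and-refit confusion
  matrices (stacking weights) and true-vs-recovered parameter
  correlation tables.

## CLI

```bash
gamblefit simulate-schedule --seed 1 --subjects 10 --out schedules.tsv
gamblefit simulate-cohort --model D5-BMT3 --n 479 --seed 7 --out choices.tsv
gamblefit fit --model D5-BMT3 --data choices.tsv --mode map --seed 0
gamblefit compare --models D1-none,D5-BMT3 --data choices.tsv --out waic.tsv
gamblefit measures --data choices.tsv --out measures.tsv
gamblefit recover --recovery-mode parameter --models D5-BMT3 --n 200 --seed 11
```

Model ids combine a decision variant (`D1`..`D5`) with a learning
variant (`none`, `RW1`..`RW6`, `BMT1`..`BMT3`), e.g. `D5-BMT3`.

## Data formats

All I/O is delimited text (TSV). Choice data carry one row per trial:
subject, block, trial, condition, option magnitudes (empty — never 0 —
for ambiguous slots, with explicit ambiguity flags), latent true
values, the binary choice (1 = gamble/ambiguous option), outcome,
running score, and the reveal valence when an ambiguous slot paid out.
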