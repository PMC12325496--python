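# rulexgaze

Judgment researchers have long proposed that people infer an unknown numeric
criterion (how suitable is this applicant? how valuable is this object?) by
mixing two cognitive processes: retrieving similar, previously learned
**exemplars**, and applying an abstracted linear **rule** over the object's
cues. The two processes are hard to tell apart from responses alone — but
they make different *process* predictions: exemplar retrieval is memory
retrieval, and memory retrieval shows up in eye movements as
**looking-at-nothing (LAN)**, fixations to the now-blank screen locations
where exemplars were encoded.

`rulexgaze` implements the complete analysis pipeline for testing that link
in a multiple-cue judgment task:

- the **task environment**: a 4×4 cue grid with criterion
  `c = round(5/3·x1·x2 + 2)` on a 1–30 scale, a constraint-derived exemplar
  set {21, 14, 32, 43}, reversed-cue distractors, blocked trial schedules,
  and the 4-down-1-up presentation-time staircase;
- the **RulEx-J mixture model**,
  `ĉ = α·ĉ_sim + (1−α)·ĉ_rule`, with an exponential similarity kernel over
  attention-weighted city-block distance, a linear rule `β0 + β1x1 + β2x2`,
  and Gaussian response noise σ — α ∈ [0, 1] measures reliance on
  similarity over rules;
- **fitting**: per-participant maximum likelihood under 16-fold
  leave-one-stimulus-out cross-validation, fold-mean parameters, out-of-sample
  comparison against pure-rule (α = 0) and pure-similarity (α = 1) variants,
  rule/similarity-user classification and single-cue screening;
- **gaze analysis**: AOI geometry and fixation assignment, LAN duration and
  LAN strength, five-bin within-trial time courses, exemplar-location
  counts, and stimulus-wise split-half reliability;
- a **synthetic cohort generator** (judgments from the response model
  itself; gaze from a minimal α-coupled two-process mixture) so the whole
  pipeline runs and is stress-tested without any recorded data;
- the **statistical layer**: Kendall τ-b associations, Wilcoxon–Mann–Whitney
  group tests, Fisher-z sensitivity power analysis, and an end-to-end
  association report.

See `docs/methods.md` for model details and design decisions.

## Worked example

The numbered scripts under `analysis/` run the study pipeline on a synthetic
cohort and write their tables to `results/`:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_fit_judgments.py  --seed 1
python analysis/03_gaze_metrics.py
python analysis/04_association_report.py
python analysis/05_parameter_recovery.py --seed 1
```

Step 02 fits every participant and checks estimates against the generator:

```
fitted 48 participants (mean alpha 0.548, SD 0.282)
  similarity_user: 27
  rule_user: 21
rank correlation of estimated vs generating alpha: 0.859
```

Step 03 computes the gaze metrics — about 41% of trials contain exemplar
gaze, concentrated in the fourth fifth of the trial:

```
  trials with any exemplar gaze: 41.1%
  mean LAN duration: 0.079
  LAN by time bin: 0.000, 0.000, 0.153, 0.411, 0.000
```

Step 04 ties them together. With the generator's default α-to-gaze coupling,
participants fitted with a larger mixture weight α look more at the blank
exemplar locations, and the classified groups diverge on the critical
extrapolation stimuli (similarity users overestimate 11 and 12, which lie
below the exemplar criterion range, and underestimate 34 and 44, which lie
above it):

```
headline association: tau(alpha, LAN duration) = 0.628 (p = 0.0000)

| group           |   n | lan_duration | error_11 | error_12 | error_34 | error_44 |
|:----------------|----:|-------------:|---------:|---------:|---------:|---------:|
| rule_user       |  21 |         0.05 |    -1.57 |    -0.68 |    -4.36 |    -6.45 |
| similarity_user |  27 |         0.10 |    +1.96 |    +2.17 |    -7.33 |   -10.31 |
```

Step 05 quantifies how well α is recoverable at all (the precondition for
correlating it with anything): rank correlation between generating and
refitted α per noise level σ:

```
 sigma_level   alpha_rank_corr  alpha_bias  alpha_rmse
         0.5             0.971       0.003       0.040
         2.0             0.625       0.013       0.180
         4.0             0.389      -0.019       0.322
```

The same functionality is exposed as a CLI for external data
(`rulexgaze simulate|fit|recover|report --help`); fixation tables are plain
CSVs with columns `participant, trial, onset_ms, duration_ms, x_px, y_px`.

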