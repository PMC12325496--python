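# Methods

This note documents the models, procedures, and design choices implemented
in `rulexgaze`, and what the synthetic-data experiments can and cannot show.

## Task environment

Stimuli carry two integer cues `x1, x2 ∈ {1..4}`; the judged criterion lies
on a 1–30 scale. The multiplicative environment defines the criterion as

    c = round(5/3 · x1 · x2 + 2),

which spans 4 (at stimulus 11) to 29 (at 44). Rounding is to the nearest
integer with halves away from zero; no point on the 16-cell grid lands on an
exact half, so the half-rule is inert there and only matters for arbitrary
inputs (e.g., user-supplied additive coefficients). An additive environment
`c = round(a0 + a1·x1 + a2·x2)` is supported generically; its default
coefficients `(2, 5/3, 5/3)` are an arbitrary convention chosen to span a
comparable criterion range and carry no empirical content.

Four stimuli serve as exemplars. The default set {21, 14, 32, 43} (criteria
5, 9, 12, 22) is the unique 4-set that contains 21, takes each cue value
exactly once per cue, contains no symmetric stimulus (each exemplar must
have a distinct cue-reversed distractor), and leaves the extreme stimuli 11
and 44 outside the exemplar criterion range so that they require
extrapolation. The set is overridable in config.

Trial schedules are blocked with seeded random order within blocks: location
training presents the 4 exemplars plus their 4 reversed distractors per
block; criterion training the 4 exemplars; the test phase all 16 stimuli
(8 blocks = 128 trials by default). Training termination rules are schedule
metadata, not simulated learning. The presentation-time staircase implements
the 4-down-1-up arithmetic (−336.60 ms after four consecutive correct
responses, +400 ms after an error) with a 1 ms floor — the floor is our
addition to keep durations positive; no empirical floor is claimed.

## Judgment model

The mixture model predicts the judgment for stimulus *i* as

    ĉ_i = α · ĉ_i^sim + (1 − α) · ĉ_i^rule,   0 ≤ α ≤ 1,

with a similarity-based exemplar component and a rule-based linear
component. The rule component is `ĉ^rule = β0 + β1·x1 + β2·x2`. The
similarity component is the normalized-similarity-weighted mean of the
exemplars' criterion values with an exponential-decay kernel over
attention-weighted city-block distance (generalized-context-model form):

    S(s, e_j) = exp(−h · [w1·|x1−e_j1| + w2·|x2−e_j2|]),
    ĉ^sim     = Σ_j S(s, e_j)·c_j / Σ_j S(s, e_j).

Free parameters are `α, β0, β1, β2, σ` (Gaussian response noise SD). Two
derived/fixed quantities deserve comment:

- **Attention weights** are not free: `w_m = |β_m| / (|β1| + |β2|)`.
  Absolute values guard against negative fitted cue weights; if both betas
  are exactly zero the weights are undefined and an equal-weight fallback
  (.5, .5) is used with a logged warning.
- **Sensitivity `h`** is a fixed constant (default 1.0, configurable), not
  fitted: the model has exactly five free parameters. At `h → 0` the
  similarity prediction tends to the plain exemplar mean; large `h`
  concentrates it on the nearest exemplar.

Two structural facts drive everything downstream: the similarity component
is a convex combination of exemplar criteria and therefore can never leave
the exemplar criterion range [5, 22], while the rule component extrapolates
freely (the least-squares rule on the default exemplars predicts ≈ 24.8 at
stimulus 44, above the exemplar maximum of 22). The extreme stimuli 11, 12,
34, 44 are hence "critical": the two processes disagree there most.

The response likelihood is a plain (untruncated, unrounded) Gaussian around
ĉ_i. Truncation to the 1–30 scale exists behind a flag, off by default.

## Estimation

Per participant, parameters are estimated by maximum likelihood under
16-fold cross-validation with one fold per distinct stimulus: all trials of
the held-out stimulus leave the training set, so held-out scores measure
generalization to an unseen cue combination (a blockwise fold scheme is
available in config). Per-fold estimates are averaged (mean) per
participant; medians of β1, β2 are kept as well because the gaze analyses
weight cue distances by median cue weights.

The optimizer is L-BFGS-B over `(α, β0, β1, β2)` with α bounded to [0, 1]
and betas unbounded; σ is profiled out in closed form (its conditional MLE
is the RMS residual), which removes one dimension and any need for a
positivity transform. Each fit restarts from 10 start points — one
least-squares heuristic (OLS betas, α = .5) plus 9 seeded-random draws —
and keeps the best; convergence tolerance 1e-8 on the objective.
Restricted models clamp α via degenerate bounds (pure rule: α = 0; pure
similarity: α = 1) and use 4 restarts, their objectives being much better
behaved. Non-convergence of all restarts is flagged in the result, not
raised. Fits are deterministic given the data and the restart seed.

Classification follows the fold-mean α: rule user below .5, similarity user
above, `unclassified` exactly at the boundary (the boundary case is kept
explicit rather than silently binned). A single-cue strategy is flagged when
α > .9 and the smaller attention weight is below .05; participants whose
fitted betas are both negative (a response pattern opposite to the
environment) are flagged for exclusion.

A note on identifiability: because the rule component is unbounded, inflated
betas at larger α can mimic much of a lower-α mean function; α is identified
mainly by the magnitude of the similarity component's nonlinearity
(saturation at the extreme stimuli). The recovery study quantifies the
resulting estimation noise; no bias correction is applied to the known
tendency of noisy data to pull α toward the rule end.

## Parameter recovery

The recovery study simulates cohorts with α uniform on [0, 1], betas
jittered (SD 0.5) around the least-squares-on-exemplars values, and a fixed
σ per level, then refits each simulated participant with the full
cross-validated pipeline and reports the rank correlation, bias, and RMSE of
α per σ level. Defaults: 30 participants × 128 trials, σ levels bracketing
the scale of fitted σ on a 1–30 response range.

Simulated responses are, by default, rounded to integers and clipped to the
scale — what a participant could actually enter — while the likelihood
treats them as continuous, mirroring the fitting model's own approximation.
One consequence is that exactly at σ = 0 the quantization residue is a
systematic pattern that α can partly absorb, so recovery is *not* perfect
there (α RMSE ≈ 0.1) and is best slightly above zero noise. The generator
therefore has a `round_responses` switch; with continuous noise-free
responses the estimator returns the generating α to optimizer precision
(RMSE < .01), which is the estimator-correctness oracle the test suite uses.
Both behaviors are tested.

## Gaze model and metrics

AOI geometry: a 1920×1080 screen, stimulus footprint 320×180 px, AOIs
inflated by a 0.1 margin per side to 384×216 px; exemplar AOI centers at
(±415, ±235) px from screen center (477 px eccentricity), plus one central
AOI at the test-stimulus location. AOIs must be pairwise disjoint (checked).
The corner-to-exemplar assignment is a fixed default (randomized across
participants in a live experiment; all metrics are invariant to it).
Visual-angle statements assume a 700 mm viewing distance; all computation is
in pixels. Fixations shorter than 80 ms are dropped, matching typical event
detector settings; event detection itself (velocity thresholding) is out of
scope — the input is an event table.

Metrics, per trial with test stimulus *s*:

- **LAN duration** = exemplar-AOI gaze / (exemplar + center AOI gaze);
  undefined (excluded, counted) when neither AOI received gaze.
- **Most-similar exemplar** = argmin of attention-weighted city-block
  distance from *s*, using each participant's median fitted cue weights
  normalized to sum to 1. Ties break deterministically: smaller unweighted
  city-block distance first, then lexicographically smaller (x1, x2).
- **LAN strength** = gaze on the most-similar exemplar's AOI / total
  exemplar gaze; undefined without exemplar gaze.
- **Time course**: the removal-to-click interval is cut into five equal
  bins; fixations straddling a bin edge are split pro-rata (an
  assign-to-onset-bin rule is available in config). Bins with no
  exemplar-or-center gaze contribute 0, not NaN, so per-bin curves average
  over all trials. Pro-rata splitting conserves summed gaze time exactly.
- **Trial-level counts**: share of trials with any exemplar gaze, the
  distribution of distinct exemplar locations per trial, the share of
  single-location trials targeting the most-similar exemplar, and the
  dominant-location share in multi-location trials.
- **Split-half reliability**: per stimulus, mean LAN duration over odd vs.
  even presentations, correlated (Pearson) across stimuli; stimuli with
  fewer than two presentations are dropped with a warning.

## Synthetic cohort

The generator exists to make every downstream metric exercisable and the
headline association recoverable; it is deliberately minimal and all its
constants are synthetic conventions, not estimates.

Judgments: each of 48 participants draws α ~ U(0, 1), betas jittered around
the least-squares values, σ ~ U(1.5, 3.0) (bracketing plausible response
noise on a 1–30 scale), and answers a full 128-trial schedule with
`round(clip(N(ĉ, σ), 1, 30))`.

Gaze: every trial gets an early central fixation (40% of the trial — the
just-removed stimulus) and a late re-centering fixation (12% — reaching for
the response scale). With probability `clip(.10 + .60·α, 0, 1)` the trial
also contains one (or, with probability .35, two) exemplar-AOI fixations of
200–600 ms placed inside the fourth fifth of the trial, targeted at the
most-similar exemplar with probability .75 (else one of the other three).
Coordinates are uniform inside the target AOI. Trial lengths are lognormal
with median 3.76 s. The linear α-coupling is the generative stand-in for
the hypothesis that similarity-based judgment relies on exemplar retrieval.

What the generator does *not* emulate: learning-phase dynamics, fixation
sequences within the center (single long fixations stand in for several),
saccade kinematics, drift or calibration error, participant-specific corner
assignments, old/new stimulus effects on gaze, and any nonlinearity or
saturation in the α–gaze link. Passing round-trip tests therefore show that
the metric code recovers the structure this generator puts in — not that
real gaze data have that structure.

## Statistics

Associations use Kendall's τ-b (tie-corrected, asymptotic p) since LAN
proportions and α estimates are generally non-normal; normality is screened
with Shapiro–Wilk and reported alongside. Group contrasts use the
tie-corrected asymptotic Wilcoxon–Mann–Whitney test without continuity
correction; trial-level proportions pool trials across participants into a
2×2 chi-square (df = 1, continuity correction off). The sensitivity power
analysis for a bivariate correlation uses the Fisher-z approximation,
ρ = tanh((z_{1−a/2} + z_{power}) / √(n−3)), and is invertible for the
required n; at n = 48, two-sided .05, power .95 it gives ρ ≈ .49. The
"weakly committed" subgroup window (.1 < α < .9) is a config default and
admittedly arbitrary. The exemplar-accuracy proxy is the share of exact
criterion hits on exemplar trials, averaged with location accuracy when one
is supplied (the synthetic cohort has none).

## Problem sizes and numerics

Default analysis sizes — 48 participants × 128 trials, 16 folds × 10
restarts per fit, recovery at 30 participants per σ level — run in a few
minutes on a single core; the vectorized likelihood evaluates all trials of
a participant in one pass over the 16 distinct stimuli. Degenerate inputs
are handled explicitly: empty judgment tables, non-finite responses,
missing stimuli (fewer folds, warning), both-betas-zero attention weights
(equal-weight fallback), zero-gaze trials and bins (NaN-excluded or
zero-filled as documented), and constant vectors in correlations (flagged
NaN). Profiled σ is floored at 1e-6 (1e-12 inside the objective) so exact
interpolation cannot produce infinities.

## Known limitations

- α is weakly identified for participants whose similarity component is
  nearly linear over the grid; estimates are noisy even at moderate σ.
- The likelihood ignores response rounding and scale truncation; both are
  second-order at σ ≳ 1 but visible in the σ → 0 limit.
- The gaze generator's α-coupling is linear and trial-independent; the
  report machinery (subgroup windows, single-cue screens) is therefore
  exercised but cannot be validated against realistic nonlinearities.
- Exact reproduction of empirical estimates from the original eye-tracking
  study would require its recorded dataset, which this package does not
  ship; all reported numbers here are computed from synthetic cohorts or
  closed-form design arithmetic.
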