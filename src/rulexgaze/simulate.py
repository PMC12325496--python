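"""Synthetic cohort generator.

Produces judgment and fixation tables with the statistical structure the
analysis pipeline assumes, so that the whole pipeline can run and be stress
tested without any recorded data:

* judgments follow the RulEx-J response model itself — each simulated
  participant has their own (alpha, beta0, beta1, beta2, sigma), responses
  are Gaussian around the blended prediction, rounded to integers and
  clipped to the 1-30 scale;
* gaze follows a minimal two-process mixture: every trial has center
  fixations (the just-removed test stimulus), and with a probability that
  increases linearly in the participant's alpha the trial also contains
  exemplar-AOI fixations, directed at the most-similar exemplar with a
  configurable bias and timed so that exemplar gaze peaks in the fourth
  fifth of the trial.

The alpha-to-gaze coupling is the generator's stand-in for the hypothesis
that similarity-based judgment relies on exemplar retrieval; its constants
are synthetic conventions, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .environment import Environment, Stimulus, make_schedule
from .gaze import AOISet, Rect, build_aois, most_similar_exemplar
from .model import TrialDesign, mixture_mean_vector

# Least-squares cue weights on the default exemplar set anchor the generating
# betas; per-participant jitter is added around them.
def _ols_on_exemplars(env: Environment) -> np.ndarray:
    X = np.array([[1.0, e.x1, e.x2] for e in env.exemplar_list])
    y = np.array([env.exemplars[e] for e in env.exemplar_list], dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


@dataclass(frozen=True)
class CohortSpec:
    """Generating distributions and gaze-coupling constants for a cohort."""

    n_participants: int = 48
    n_blocks: int = 8                      # test phase: 16 stimuli x 8 = 128 trials
    seed: int = 0
    # judgment model
    alpha_range: tuple[float, float] = (0.0, 1.0)   # alpha ~ uniform
    beta_jitter_sd: float = 0.5            # around least-squares-on-exemplars betas
    sigma_range: tuple[float, float] = (1.5, 3.0)   # response noise SD, scale units
    fixed_alpha: float | None = None       # overrides alpha_range when set
    fixed_sigma: float | None = None
    round_responses: bool = True           # integer responses on the 1-30 scale
    # gaze coupling
    lan_base: float = 0.10                 # exemplar-gaze probability at alpha = 0
    lan_slope: float = 0.60                # added probability per unit alpha
    most_similar_bias: float = 0.75        # P(exemplar fixation targets most similar)
    p_second_fixation: float = 0.35        # chance of a second exemplar fixation
    exemplar_fix_ms: tuple[float, float] = (200.0, 600.0)  # uniform duration range
    # trial timing (ms): lognormal removal-to-click time, median ~3.8 s
    trial_len_median_ms: float = 3760.0
    trial_len_log_sd: float = 0.55
    early_center_frac: float = 0.40        # early center fixation, fraction of trial
    late_center_frac: float = 0.12         # re-centering before the response click
    exemplar_window: tuple[float, float] = (0.60, 0.80)  # bin-4 window

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_blocks < 1:
            raise ValueError("participant and block counts must be positive")
        for p in (self.lan_base, self.most_similar_bias, self.p_second_fixation):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.trial_len_median_ms <= 0 or self.exemplar_fix_ms[0] <= 0:
            raise ValueError("durations must be positive")


def sample_cohort_params(spec: CohortSpec, env: Environment, rng=None) -> pd.DataFrame:
    """Draw each participant's generating parameters (the 'truth' table)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ols = _ols_on_exemplars(env)
    n = spec.n_participants
    alpha = (
        np.full(n, spec.fixed_alpha)
        if spec.fixed_alpha is not None
        else rng.uniform(*spec.alpha_range, size=n)
    )
    sigma = (
        np.full(n, spec.fixed_sigma)
        if spec.fixed_sigma is not None
        else rng.uniform(*spec.sigma_range, size=n)
    )
    betas = ols[None, :] + rng.normal(0.0, spec.beta_jitter_sd, size=(n, 3))
    return pd.DataFrame(
        {
            "participant": np.arange(1, n + 1),
            "alpha": alpha,
            "beta0": betas[:, 0],
            "beta1": betas[:, 1],
            "beta2": betas[:, 2],
            "sigma": sigma,
        }
    )


def generate_judgments(
    spec: CohortSpec, env: Environment, truth: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test-phase judgment table for a synthetic cohort.

    Each participant gets a full blocked test schedule (16 stimuli x
    ``n_blocks``); responses are round(clip(Normal(c_mix, sigma), 1, 30)).
    Returns (judgments, truth); identical spec and seed give identical
    tables.
    """
    master = np.random.default_rng(spec.seed)
    if truth is None:
        truth = sample_cohort_params(spec, env, master)
    frames = []
    for row in truth.itertuples(index=False):
        pid = int(row.participant)
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed % (2**31), 1, pid])
        )
        sched = make_schedule(
            "test", env, spec.n_blocks, seed=int(rng.integers(2**31))
        ).trials
        df = sched.drop(columns=["role"]).copy()
        df["response"] = 0.0  # placeholder so TrialDesign can be built
        design = TrialDesign.from_data(df, env)
        mu = mixture_mean_vector(
            design, row.alpha, row.beta0, row.beta1, row.beta2
        )[design.trial_idx]
        raw = mu if row.sigma == 0 else rng.normal(mu, row.sigma)
        if spec.round_responses:
            df["response"] = np.clip(
                np.rint(raw), env.scale_min, env.scale_max
            ).astype(int)
        else:
            df["response"] = np.clip(raw, env.scale_min, env.scale_max)
        df.insert(0, "participant", pid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True), truth


def _uniform_in(rect: Rect, rng) -> tuple[float, float]:
    return rng.uniform(rect.x0, rect.x1), rng.uniform(rect.y0, rect.y1)


def generate_fixations(
    spec: CohortSpec,
    env: Environment,
    judgments: pd.DataFrame,
    truth: pd.DataFrame,
    aois: AOISet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fixation and trial tables matched to a judgment table.

    Per trial: an early center fixation, a late re-centering fixation, and —
    with probability clip(lan_base + lan_slope * alpha, 0, 1) — one or two
    exemplar-AOI fixations inside the fourth fifth of the trial, aimed at
    the most-similar exemplar with probability ``most_similar_bias`` (else a
    uniformly random other exemplar).  Fixation coordinates are uniform
    inside the target AOI.  Returns (fixations, trials) where trials carries
    (participant, trial, x1, x2, trial_len_ms).
    """
    if aois is None:
        aois = build_aois(env)
    alpha_by_pid = truth.set_index("participant")["alpha"]
    exemplars = env.exemplar_list
    fix_rows, trial_rows = [], []
    for pid, sub in judgments.groupby("participant"):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed % (2**31), 2, int(pid)])
        )
        p_lan = float(np.clip(spec.lan_base + spec.lan_slope * alpha_by_pid[pid], 0, 1))
        for t in sub.itertuples(index=False):
            s = Stimulus(int(t.x1), int(t.x2))
            T = spec.trial_len_median_ms * np.exp(
                rng.normal(0.0, spec.trial_len_log_sd)
            )
            trial_rows.append((pid, int(t.trial), s.x1, s.x2, T))
            # early center gaze on the just-removed stimulus location
            x, y = _uniform_in(aois.center, rng)
            fix_rows.append((pid, int(t.trial), 0.0, spec.early_center_frac * T, x, y))
            # late re-centering before the mouse click
            late_dur = spec.late_center_frac * T
            x, y = _uniform_in(aois.center, rng)
            fix_rows.append((pid, int(t.trial), T - late_dur, late_dur, x, y))
            if rng.uniform() >= p_lan:
                continue
            lo, hi = spec.exemplar_window
            window = (hi - lo) * T
            n_fix = 1 + (rng.uniform() < spec.p_second_fixation)
            onset = lo * T
            for _ in range(n_fix):
                dur = rng.uniform(*spec.exemplar_fix_ms)
                dur = min(dur, lo * T + window - onset)
                if dur < 1.0:
                    break
                ms = most_similar_exemplar(s, env)
                if rng.uniform() < spec.most_similar_bias:
                    target = ms
                else:
                    others = [e for e in exemplars if e != ms]
                    target = others[rng.integers(len(others))]
                x, y = _uniform_in(aois.exemplar_aois[target], rng)
                fix_rows.append((pid, int(t.trial), onset, dur, x, y))
                onset += dur + rng.uniform(20.0, 80.0)
    fixations = pd.DataFrame(
        fix_rows,
        columns=["participant", "trial", "onset_ms", "duration_ms", "x_px", "y_px"],
    )
    trials = pd.DataFrame(
        trial_rows, columns=["participant", "trial", "x1", "x2", "trial_len_ms"]
    )
    return fixations, trials


def simulate_cohort(
    spec: CohortSpec = CohortSpec(), env: Environment | None = None
) -> dict[str, pd.DataFrame]:
    """Full synthetic dataset: judgments, fixations, trials, and the
    generating-parameter truth table."""
    if env is None:
        env = Environment.multiplicative()
    judgments, truth = generate_judgments(spec, env)
    fixations, trials = generate_fixations(spec, env, judgments, truth)
    return {
        "judgments": judgments,
        "fixations": fixations,
        "trials": trials,
        "truth": truth,
    }
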