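"""Maximum-likelihood estimation of RulEx-J per participant.

Fitting follows the study pipeline: parameters are estimated by maximum
likelihood from each participant's test-phase judgments under a 16-fold
cross-validation (one fold per distinct stimulus, held out in full), the
per-fold estimates are averaged by participant, and the blended model is
compared out of sample against its two restricted variants — a pure rule
model (alpha clamped to 0) and a pure similarity model (alpha clamped to 1).
Participants are classified as rule users (fold-mean alpha < .5) or
similarity users (alpha > .5).

The optimizer is bounded quasi-Newton (L-BFGS-B) over
(alpha, beta0, beta1, beta2) with the Gaussian sigma profiled out in closed
form, restarted from ten seeded start points (one least-squares heuristic
plus nine random); the best restart wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize

from .environment import Environment, Stimulus
from .model import (
    DEFAULT_H,
    ModelParams,
    TrialDesign,
    log_likelihood,
    mixture_mean_vector,
    negative_log_likelihood_profiled,
    profiled_sigma,
)

RULE_USER = "rule_user"
SIMILARITY_USER = "similarity_user"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and cross-validation settings."""

    n_restarts: int = 10
    seed: int = 0
    h: float = DEFAULT_H
    fold_scheme: str = "stimulus"  # or "block"
    n_restarts_restricted: int = 4
    ftol: float = 1e-8
    alpha_threshold: float = 0.5
    single_cue_alpha: float = 0.9
    single_cue_weight: float = 0.05


@dataclass
class FitResult:
    """Per-participant cross-validated fit."""

    fold_params: pd.DataFrame       # fold, alpha, beta0, beta1, beta2, sigma
    mean_params: ModelParams        # fold means
    median_betas: tuple[float, float]
    heldout: pd.DataFrame           # fold, model, loglik, rmse, n_test
    converged: bool
    classification: str = ""
    single_cue: bool = False

    @property
    def heldout_totals(self) -> pd.DataFrame:
        """Held-out log-likelihood and RMSE summed/pooled over folds."""
        g = self.heldout.groupby("model")
        out = g["loglik"].sum().to_frame("loglik")
        out["rmse"] = np.sqrt(
            g.apply(lambda d: np.sum(d["rmse"] ** 2 * d["n_test"]), include_groups=False)
            / g["n_test"].sum()
        )
        return out


def _ols_start(design: TrialDesign) -> np.ndarray:
    """Least-squares linear fit as a deterministic optimizer start."""
    X = np.column_stack(
        [
            np.ones(design.n_trials),
            design.x1[design.trial_idx],
            design.x2[design.trial_idx],
        ]
    )
    coef, *_ = np.linalg.lstsq(X, design.response, rcond=None)
    return np.array([0.5, coef[0], coef[1], coef[2]])


def _start_points(design: TrialDesign, config: FitConfig, fixed_alpha: float | None,
                  n_restarts: int) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    starts = [_ols_start(design)]
    for _ in range(n_restarts - 1):
        starts.append(
            np.array(
                [
                    rng.uniform(0.0, 1.0),
                    rng.uniform(-5.0, 10.0),
                    rng.uniform(-2.0, 8.0),
                    rng.uniform(-2.0, 8.0),
                ]
            )
        )
    starts = np.asarray(starts)
    if fixed_alpha is not None:
        starts[:, 0] = fixed_alpha
    return starts


def fit_mle(
    data: pd.DataFrame,
    env: Environment,
    config: FitConfig = FitConfig(),
    fixed_alpha: float | None = None,
) -> tuple[ModelParams, dict]:
    """Maximum-likelihood parameters for one participant's judgments.

    ``fixed_alpha`` clamps the mixture weight (0 for the pure rule model, 1
    for the pure similarity model).  Non-convergence of every restart is
    reported in the diagnostics, not raised.
    """
    if data[["x1", "x2"]].drop_duplicates().shape[0] < 2:
        raise ValueError("need at least two distinct stimuli to fit")
    design = TrialDesign.from_data(data, env)
    n_restarts = (
        config.n_restarts if fixed_alpha is None else config.n_restarts_restricted
    )
    if fixed_alpha is None:
        bounds = [(0.0, 1.0), (None, None), (None, None), (None, None)]
    else:
        bounds = [(fixed_alpha, fixed_alpha), (None, None), (None, None), (None, None)]
    best = None
    any_converged = False
    for x0 in _start_points(design, config, fixed_alpha, n_restarts):
        res = optimize.minimize(
            negative_log_likelihood_profiled,
            x0,
            args=(design, config.h),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": config.ftol, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta0, beta1, beta2 = best.x
    sigma = profiled_sigma(best.x, design, h=config.h)
    params = ModelParams(
        alpha=float(np.clip(alpha, 0.0, 1.0)),
        beta0=float(beta0),
        beta1=float(beta1),
        beta2=float(beta2),
        sigma=sigma,
        h=config.h,
    )
    diagnostics = {
        "converged": any_converged,
        "n_restarts": int(n_restarts),
        "neg_loglik": float(best.fun),
        "loglik": -float(best.fun),
    }
    return params, diagnostics


def crossval_folds(
    data: pd.DataFrame, scheme: str = "stimulus"
) -> list[tuple[pd.DataFrame, pd.DataFrame, str]]:
    """Cross-validation partitions: one fold per distinct stimulus (default,
    all trials of that stimulus held out) or per block.

    With all 16 stimuli present and 8 blocks, the stimulus scheme yields 16
    folds of 8 held-out trials each.  Missing stimuli shrink the fold count
    with a warning.
    """
    if scheme == "stimulus":
        keys = sorted(
            {Stimulus(int(a), int(b)) for a, b in zip(data["x1"], data["x2"])}
        )
        if len(keys) < 16:
            warnings.warn(
                f"only {len(keys)} distinct stimuli present; "
                f"cross-validation uses {len(keys)} folds"
            )
        folds = []
        for s in keys:
            mask = (data["x1"] == s.x1) & (data["x2"] == s.x2)
            folds.append((data[~mask], data[mask], str(s)))
        return folds
    if scheme == "block":
        folds = []
        for b in sorted(data["block"].unique()):
            mask = data["block"] == b
            folds.append((data[~mask], data[mask], f"block{b}"))
        return folds
    raise ValueError(f"unknown fold scheme {scheme!r}")


def aggregate_params(fold_params: Iterable[ModelParams]) -> tuple[ModelParams, tuple[float, float]]:
    """Fold-mean parameters plus the per-participant median cue weights.

    The mean is component-wise; the medians of beta1/beta2 are also returned
    because the gaze analyses weight cue distances by median cue weights.
    """
    fold_params = list(fold_params)
    if not fold_params:
        raise ValueError("no fold parameters to aggregate")
    arr = np.array(
        [[p.alpha, p.beta0, p.beta1, p.beta2, p.sigma] for p in fold_params]
    )
    mean = arr.mean(axis=0)
    med = np.median(arr[:, 2:4], axis=0)
    params = ModelParams(
        alpha=float(np.clip(mean[0], 0.0, 1.0)),
        beta0=float(mean[1]),
        beta1=float(mean[2]),
        beta2=float(mean[3]),
        sigma=float(max(mean[4], 1e-6)),
        h=fold_params[0].h,
    )
    return params, (float(med[0]), float(med[1]))


def _heldout_scores(
    params: ModelParams, test: pd.DataFrame, env: Environment
) -> tuple[float, float]:
    ll = log_likelihood(test, env, params)
    design = TrialDesign.from_data(test, env)
    mu = mixture_mean_vector(
        design, params.alpha, params.beta0, params.beta1, params.beta2, h=params.h
    )[design.trial_idx]
    rmse = float(np.sqrt(np.mean((design.response - mu) ** 2)))
    return ll, rmse


MODELS = {"rulexj": None, "rule_only": 0.0, "similarity_only": 1.0}


def fit_crossval(
    data: pd.DataFrame,
    env: Environment,
    config: FitConfig = FitConfig(),
    compare: bool = True,
) -> FitResult:
    """Cross-validated fit for one participant.

    Fits RulEx-J (and, when ``compare`` is set, the alpha-clamped pure rule
    and pure similarity models) on every training fold, scores each on its
    held-out trials, and averages the RulEx-J fold parameters.
    """
    models = MODELS if compare else {"rulexj": None}
    fold_rows, heldout_rows = [], []
    rulexj_folds: list[ModelParams] = []
    all_converged = True
    for train, test, label in crossval_folds(data, config.fold_scheme):
        for model, clamp in models.items():
            params, diag = fit_mle(train, env, config, fixed_alpha=clamp)
            if model == "rulexj":
                rulexj_folds.append(params)
                all_converged = all_converged and diag["converged"]
                fold_rows.append(
                    {
                        "fold": label,
                        "alpha": params.alpha,
                        "beta0": params.beta0,
                        "beta1": params.beta1,
                        "beta2": params.beta2,
                        "sigma": params.sigma,
                    }
                )
            ll, rmse = _heldout_scores(params, test, env)
            heldout_rows.append(
                {
                    "fold": label,
                    "model": model,
                    "loglik": ll,
                    "rmse": rmse,
                    "n_test": len(test),
                }
            )
    mean_params, median_betas = aggregate_params(rulexj_folds)
    result = FitResult(
        fold_params=pd.DataFrame(fold_rows),
        mean_params=mean_params,
        median_betas=median_betas,
        heldout=pd.DataFrame(heldout_rows),
        converged=all_converged,
    )
    result.classification = classify_user(mean_params.alpha, config.alpha_threshold)
    result.single_cue = detect_single_cue(
        mean_params, config.single_cue_alpha, config.single_cue_weight
    )
    return result


def compare_models(
    data: pd.DataFrame, env: Environment, config: FitConfig = FitConfig()
) -> pd.DataFrame:
    """Out-of-sample comparison of RulEx-J vs. its restricted variants:
    held-out log-likelihood (summed) and RMSE (pooled) per model."""
    return fit_crossval(data, env, config, compare=True).heldout_totals


def classify_user(alpha: float, threshold: float = 0.5) -> str:
    """Rule user (alpha < threshold), similarity user (alpha > threshold),
    or unclassified exactly at the boundary."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if alpha < threshold:
        return RULE_USER
    if alpha > threshold:
        return SIMILARITY_USER
    return UNCLASSIFIED


def detect_single_cue(
    params: ModelParams, alpha_thresh: float = 0.9, weight_thresh: float = 0.05
) -> bool:
    """Single-cue strategy flag: near-maximal similarity reliance with the
    attention weight of one cue approaching zero."""
    w = params.attention_weights
    return params.alpha > alpha_thresh and min(w) < weight_thresh


def screen_incompatible(params: ModelParams) -> bool:
    """Data-screening flag for a response pattern opposite to the environment
    (both fitted cue weights negative); such participants are excluded."""
    return params.beta1 < 0 and params.beta2 < 0


def fit_cohort(
    judgments: pd.DataFrame,
    env: Environment,
    config: FitConfig = FitConfig(),
    compare: bool = False,
) -> tuple[pd.DataFrame, dict[int, FitResult]]:
    """Cross-validated fits for every participant in a judgment table.

    Returns a tidy per-participant summary (fold-mean parameters, median cue
    weights, classification, flags) and the full per-participant results.
    """
    rows, results = [], {}
    for pid, sub in judgments.groupby("participant"):
        res = fit_crossval(sub, env, config, compare=compare)
        results[pid] = res
        p = res.mean_params
        rows.append(
            {
                "participant": pid,
                "alpha": p.alpha,
                "beta0": p.beta0,
                "beta1": p.beta1,
                "beta2": p.beta2,
                "sigma": p.sigma,
                "beta1_median": res.median_betas[0],
                "beta2_median": res.median_betas[1],
                "classification": res.classification,
                "single_cue": res.single_cue,
                "excluded": screen_incompatible(p),
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows), results


def fold_params_table(results: dict[int, FitResult]) -> pd.DataFrame:
    """Tidy per-fold parameter table across participants (for export)."""
    frames = []
    for pid, res in results.items():
        df = res.fold_params.copy()
        df.insert(0, "participant", pid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
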