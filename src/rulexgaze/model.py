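"""RulEx-J judgment model.

The model blends two judgment processes for a stimulus ``i``:

* a similarity-based exemplar process, which predicts the criterion as the
  similarity-weighted mean of the stored exemplars' criterion values, with
  similarity an exponentially decaying function of attention-weighted
  city-block distance in cue space (generalized-context-model form);
* a rule-based linear process, ``beta0 + beta1*x1 + beta2*x2``.

The blended prediction is ``c_mix = alpha * c_sim + (1 - alpha) * c_rule``
with mixture weight ``alpha`` in [0, 1] measuring relative reliance on
similarity over the rule.  Observed responses are modeled as Gaussian around
``c_mix`` with standard deviation ``sigma``.  The five free parameters are
``alpha, beta0, beta1, beta2, sigma``; the similarity sensitivity ``h`` is a
fixed constant, and the attention weights of the similarity process are
derived from the absolute cue weights, ``w_m = |beta_m| / (|beta1| + |beta2|)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .environment import Environment, Stimulus, _check_stimulus

logger = logging.getLogger(__name__)

DEFAULT_H = 1.0


@dataclass(frozen=True)
class ModelParams:
    """RulEx-J parameters; ``h`` is a fixed constant, not a free parameter."""

    alpha: float
    beta0: float
    beta1: float
    beta2: float
    sigma: float
    h: float = DEFAULT_H

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.h <= 0:
            raise ValueError("h must be positive")

    @property
    def attention_weights(self) -> tuple[float, float]:
        """Normalized absolute cue weights (w1, w2); equal-weight fallback
        when both betas are zero."""
        return attention_weights(self.beta1, self.beta2)

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "sigma": self.sigma,
            "h": self.h,
        }


class Prediction(NamedTuple):
    c_sim: float
    c_rule: float
    c_mix: float


def attention_weights(beta1: float, beta2: float) -> tuple[float, float]:
    """Attention weights |beta_m| / (|beta1| + |beta2|).

    Absolute values guard against negative fitted cue weights.  When both
    betas are exactly zero the weights are undefined; equal weights (.5, .5)
    are substituted and a warning is logged.
    """
    a1, a2 = abs(beta1), abs(beta2)
    total = a1 + a2
    if total == 0.0:
        logger.warning(
            "both cue weights are zero; falling back to equal attention weights"
        )
        return 0.5, 0.5
    return a1 / total, a2 / total


def weighted_cityblock(
    s: Stimulus, e: Stimulus, w: Sequence[float] = (0.5, 0.5)
) -> float:
    """Attention-weighted city-block distance w1*|dx1| + w2*|dx2|."""
    w1, w2 = float(w[0]), float(w[1])
    if w1 < 0 or w2 < 0:
        raise ValueError("attention weights must be non-negative")
    if not math.isclose(w1 + w2, 1.0, abs_tol=1e-9):
        raise ValueError("attention weights must sum to 1")
    s, e = Stimulus(*s), Stimulus(*e)
    return w1 * abs(s.x1 - e.x1) + w2 * abs(s.x2 - e.x2)


def similarity_prediction(s: Stimulus, env: Environment, params: ModelParams) -> float:
    """Similarity-based prediction: normalized-similarity-weighted mean of
    the exemplars' criterion values.

    Similarity to exemplar j is exp(-h * d_j) with d_j the attention-weighted
    city-block distance; similarities are strictly positive, so the weighted
    mean always exists and lies within the exemplar criterion range (the
    similarity process never extrapolates).
    """
    s = _check_stimulus(s)
    w = params.attention_weights
    sims = []
    crits = []
    for e, c in env.exemplars.items():
        sims.append(math.exp(-params.h * weighted_cityblock(s, e, w)))
        crits.append(c)
    sims = np.asarray(sims)
    return float(sims @ np.asarray(crits, dtype=float) / sims.sum())


def rule_prediction(s: Stimulus, params: ModelParams) -> float:
    """Rule-based linear prediction beta0 + beta1*x1 + beta2*x2."""
    s = _check_stimulus(s)
    return params.beta0 + params.beta1 * s.x1 + params.beta2 * s.x2


def mixture_prediction(s: Stimulus, env: Environment, params: ModelParams) -> Prediction:
    """Blend of the two processes: alpha * c_sim + (1 - alpha) * c_rule."""
    c_sim = similarity_prediction(s, env, params)
    c_rule = rule_prediction(s, params)
    c_mix = params.alpha * c_sim + (1.0 - params.alpha) * c_rule
    return Prediction(c_sim=c_sim, c_rule=c_rule, c_mix=c_mix)


def log_likelihood(
    data: pd.DataFrame,
    env: Environment,
    params: ModelParams,
    truncated: bool = False,
) -> float:
    """Gaussian response log-likelihood for one participant's judgments.

    ``data`` needs columns x1, x2, response.  Each response contributes the
    log density of N(c_mix, sigma) at the observed value; trial order is
    irrelevant.  With ``truncated=True`` the Gaussian is truncated to the
    response scale (off by default; the plain Gaussian is the fitting model).
    """
    if len(data) == 0:
        raise ValueError("empty judgment table")
    resp = np.asarray(data["response"], dtype=float)
    if not np.all(np.isfinite(resp)):
        raise ValueError("non-finite response values")
    # predictions vary only over the distinct stimuli, not over trials
    mix = {
        s: mixture_prediction(s, env, params).c_mix
        for s in {Stimulus(int(a), int(b)) for a, b in zip(data["x1"], data["x2"])}
    }
    mu = np.array(
        [mix[Stimulus(int(a), int(b))] for a, b in zip(data["x1"], data["x2"])]
    )
    if truncated:
        a = (env.scale_min - mu) / params.sigma
        b = (env.scale_max - mu) / params.sigma
        return float(
            stats.truncnorm.logpdf(resp, a, b, loc=mu, scale=params.sigma).sum()
        )
    return float(stats.norm.logpdf(resp, loc=mu, scale=params.sigma).sum())


def predict_grid(env: Environment, params: ModelParams) -> pd.DataFrame:
    """Per-stimulus predictions over the full 16-stimulus grid
    (x1, x2, c_true, c_sim, c_rule, c_mix) for export."""
    from .environment import full_grid

    rows = []
    for s in full_grid():
        p = mixture_prediction(s, env, params)
        rows.append((s.x1, s.x2, env.criterion(s), p.c_sim, p.c_rule, p.c_mix))
    return pd.DataFrame(rows, columns=["x1", "x2", "c_true", "c_sim", "c_rule", "c_mix"])


# ---------------------------------------------------------------------------
# Vectorized evaluation over a fixed trial design (used by the optimizer and
# the simulators; must agree with the scalar path above, which the test suite
# checks against brute-force oracles)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialDesign:
    """Precomputed arrays for fast repeated likelihood evaluation.

    ``d1``/``d2`` are |x_m - e_m| distance components from each distinct
    stimulus (rows) to each exemplar (columns); ``trial_idx`` maps each trial
    to its row in the distinct-stimulus arrays.
    """

    x1: np.ndarray          # (U,) distinct-stimulus cue 1
    x2: np.ndarray          # (U,)
    d1: np.ndarray          # (U, J)
    d2: np.ndarray          # (U, J)
    c_ex: np.ndarray        # (J,) exemplar criterion values
    trial_idx: np.ndarray   # (N,) row index per trial
    response: np.ndarray    # (N,)

    @property
    def n_trials(self) -> int:
        return self.response.size

    @classmethod
    def from_data(cls, data: pd.DataFrame, env: Environment) -> "TrialDesign":
        xy = np.column_stack(
            [np.asarray(data["x1"], dtype=int), np.asarray(data["x2"], dtype=int)]
        )
        uniq, trial_idx = np.unique(xy, axis=0, return_inverse=True)
        ex = np.array([[e.x1, e.x2] for e in env.exemplar_list], dtype=float)
        c_ex = np.array([env.exemplars[e] for e in env.exemplar_list], dtype=float)
        d1 = np.abs(uniq[:, :1].astype(float) - ex[:, 0][None, :])
        d2 = np.abs(uniq[:, 1:2].astype(float) - ex[:, 1][None, :])
        return cls(
            x1=uniq[:, 0].astype(float),
            x2=uniq[:, 1].astype(float),
            d1=d1,
            d2=d2,
            c_ex=c_ex,
            trial_idx=trial_idx.astype(np.intp),
            response=np.asarray(data["response"], dtype=float),
        )


def mixture_mean_vector(
    design: TrialDesign,
    alpha: float,
    beta0: float,
    beta1: float,
    beta2: float,
    h: float = DEFAULT_H,
) -> np.ndarray:
    """c_mix per distinct stimulus in ``design`` (vectorized)."""
    w1, w2 = attention_weights(beta1, beta2) if (beta1 or beta2) else (0.5, 0.5)
    sim = np.exp(-h * (w1 * design.d1 + w2 * design.d2))
    c_sim = sim @ design.c_ex / sim.sum(axis=1)
    c_rule = beta0 + beta1 * design.x1 + beta2 * design.x2
    return alpha * c_sim + (1.0 - alpha) * c_rule


def negative_log_likelihood_profiled(
    theta: np.ndarray, design: TrialDesign, h: float = DEFAULT_H
) -> float:
    """Negative log-likelihood with sigma profiled out at its MLE.

    ``theta = (alpha, beta0, beta1, beta2)``; the Gaussian scale has the
    closed-form maximizer sigma^2 = mean squared residual, so the optimizer
    works in four dimensions.  Returns n/2 * (log(2*pi*sigma^2) + 1).
    """
    alpha, beta0, beta1, beta2 = theta
    mu = mixture_mean_vector(design, alpha, beta0, beta1, beta2, h=h)
    resid = design.response - mu[design.trial_idx]
    sigma2 = max(float(resid @ resid) / resid.size, 1e-12)
    return 0.5 * resid.size * (math.log(2.0 * math.pi * sigma2) + 1.0)


def profiled_sigma(theta: np.ndarray, design: TrialDesign, h: float = DEFAULT_H) -> float:
    """The profiled sigma MLE at ``theta`` (floored at 1e-6)."""
    alpha, beta0, beta1, beta2 = theta
    mu = mixture_mean_vector(design, alpha, beta0, beta1, beta2, h=h)
    resid = design.response - mu[design.trial_idx]
    return max(math.sqrt(float(resid @ resid) / resid.size), 1e-6)
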