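"""Statistical layer tying modeling and gaze together.

Rank correlations use Kendall's tau-b (tie-corrected, asymptotic p) because
LAN proportions and alpha estimates are typically non-normal; normality is
screened with Shapiro-Wilk.  Group comparisons use the tie-corrected
asymptotic Wilcoxon-Mann-Whitney test, trial-level proportions a 2x2
chi-square on pooled trials (no continuity correction), and the design's
sensitivity power analysis the Fisher-z approximation for a bivariate
correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .environment import Environment, Stimulus

CRITICAL_STIMULI = (Stimulus(1, 1), Stimulus(1, 2), Stimulus(3, 4), Stimulus(4, 4))


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b with asymptotic two-sided p.

    Undefined (NaN, NaN) when either vector is constant; pairs with missing
    values are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Kendall's tau is undefined")
        return float("nan"), float("nan")
    res = sps.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def group_compare(values, labels, alternative: str = "two-sided") -> tuple[float, float]:
    """Tie-corrected asymptotic Wilcoxon-Mann-Whitney test between the two
    groups defined by ``labels``; returns (U statistic of group 1, p)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {len(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if min(a.size, b.size) == 1:
        warnings.warn("one group is a singleton; the test has little power")
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def sensitivity_power_correlation(
    n: int, alpha_level: float = 0.05, power: float = 0.95, sides: int = 2
) -> float:
    """Smallest correlation detectable at the given error rates (Fisher z).

    rho = tanh((z_{1-alpha/sides} + z_{power}) / sqrt(n - 3)).
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    if not (0 < alpha_level < 1 and 0 < power < 1):
        raise ValueError("alpha_level and power must lie in (0, 1)")
    z_a = sps.norm.ppf(1 - alpha_level / sides)
    z_b = sps.norm.ppf(power)
    return float(np.tanh((z_a + z_b) / math.sqrt(n - 3)))


def required_n_for_correlation(
    rho: float, alpha_level: float = 0.05, power: float = 0.95, sides: int = 2
) -> int:
    """Inverse of :func:`sensitivity_power_correlation`: smallest n whose
    detectable correlation does not exceed ``rho``."""
    if not (0 < abs(rho) < 1):
        raise ValueError("rho must lie in (0, 1)")
    z_a = sps.norm.ppf(1 - alpha_level / sides)
    z_b = sps.norm.ppf(power)
    n = ((z_a + z_b) / np.arctanh(abs(rho))) ** 2 + 3
    return int(math.ceil(n - 1e-9))


def shapiro_screen(x) -> tuple[float, float]:
    """Shapiro-Wilk normality screen; returns (W, p)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def proportion_chi2(success_a: int, n_a: int, success_b: int, n_b: int) -> tuple[float, float]:
    """2x2 chi-square (df = 1, no continuity correction) comparing two
    trial-level proportions pooled across participants."""
    table = np.array(
        [[success_a, n_a - success_a], [success_b, n_b - success_b]], dtype=float
    )
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def exemplar_accuracy(
    judgments: pd.DataFrame,
    env: Environment,
    location_accuracy: pd.Series | None = None,
) -> pd.Series:
    """Per-participant exemplar accuracy proxy.

    Criterion accuracy is the share of test-phase trials on exemplar stimuli
    whose response exactly equals the true criterion.  When a per-participant
    location accuracy is supplied, the proxy is the mean of the two measures;
    otherwise criterion accuracy alone is returned.
    """
    ex = set(env.exemplar_list)
    mask = [Stimulus(int(a), int(b)) in ex for a, b in zip(judgments["x1"], judgments["x2"])]
    sub = judgments[np.asarray(mask)].copy()
    truth = {e: c for e, c in env.exemplars.items()}
    correct = np.array(
        [
            int(r) == truth[Stimulus(int(a), int(b))]
            for a, b, r in zip(sub["x1"], sub["x2"], sub["response"])
        ]
    )
    acc = sub.assign(correct=correct).groupby("participant")["correct"].mean()
    acc.name = "exemplar_accuracy"
    if location_accuracy is not None:
        acc = (acc + location_accuracy.reindex(acc.index)) / 2.0
        acc.name = "exemplar_accuracy"
    return acc


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

REPORT_VARIABLES = ("exemplar_accuracy", "lan_duration", "lan_strength", "alpha")


@dataclass
class AssociationReport:
    """End-to-end association report between modeling and gaze."""

    participants: pd.DataFrame          # one row per participant
    correlations: pd.DataFrame          # tau below diagonal, p above
    normality: pd.DataFrame             # M, Mdn, SD, W, p per variable
    group_summary: pd.DataFrame         # rule vs similarity users
    subgroup: dict = field(default_factory=dict)
    group_tests: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def _correlation_matrix(df: pd.DataFrame, variables) -> pd.DataFrame:
    k = len(variables)
    mat = pd.DataFrame(np.full((k, k), np.nan), index=variables, columns=variables)
    for i, vi in enumerate(variables):
        for j, vj in enumerate(variables):
            if i <= j:
                continue
            try:
                tau, p = kendall_tau(df[vi], df[vj])
            except ValueError:
                tau, p = float("nan"), float("nan")
            mat.iloc[i, j] = tau   # tau below the diagonal
            mat.iloc[j, i] = p     # p above the diagonal
    return mat


def critical_stimuli_summary(
    judgments: pd.DataFrame, env: Environment, classification: pd.Series
) -> pd.DataFrame:
    """Mean responses to the extreme ('critical') stimuli per user group,
    with signed errors against the true criterion values.

    The critical stimuli (1,1), (1,2), (3,4), (4,4) are where rule- and
    similarity-based processes diverge most: similarity predictions cannot
    leave the exemplar criterion range, rules extrapolate past it.
    """
    df = judgments.merge(
        classification.rename("classification"), left_on="participant", right_index=True
    )
    rows = []
    for group, sub in df.groupby("classification"):
        rec = {"group": group, "n": sub["participant"].nunique()}
        for s in CRITICAL_STIMULI:
            m = sub[(sub["x1"] == s.x1) & (sub["x2"] == s.x2)]["response"].mean()
            rec[f"mean_{s}"] = m
            rec[f"error_{s}"] = m - env.criterion(s)
        rows.append(rec)
    return pd.DataFrame(rows)


def build_report(
    fit_table: pd.DataFrame,
    gaze_table: pd.DataFrame,
    judgments: pd.DataFrame,
    env: Environment,
    alpha_window: tuple[float, float] = (0.1, 0.9),
) -> AssociationReport:
    """Assemble the association report from per-participant fits and gaze.

    ``fit_table`` needs (participant, alpha, classification, single_cue);
    ``gaze_table`` (participant, lan_duration, lan_strength, prop_lan_trials).
    Participant IDs must align; offenders are listed in the raised error.
    """
    fit_ids = set(fit_table["participant"])
    gaze_ids = set(gaze_table["participant"])
    if fit_ids != gaze_ids:
        raise ValueError(
            "participant IDs differ between fits and gaze: "
            f"only-fits={sorted(fit_ids - gaze_ids)}, "
            f"only-gaze={sorted(gaze_ids - fit_ids)}"
        )
    acc = exemplar_accuracy(judgments, env)
    participants = (
        fit_table.merge(gaze_table, on="participant")
        .merge(acc.reset_index(), on="participant", how="left")
    )
    flags = []
    if len(participants) < 3:
        flags.append("fewer than 3 participants: correlations undefined")
    variables = [v for v in REPORT_VARIABLES if v in participants.columns]
    if len(participants) >= 3:
        correlations = _correlation_matrix(participants, variables)
    else:
        correlations = pd.DataFrame(index=variables, columns=variables, dtype=float)
    norm_rows = []
    for v in variables:
        vals = participants[v].dropna()
        if len(vals) >= 3 and vals.nunique() > 1:
            W, p = shapiro_screen(vals)
        else:
            W, p = float("nan"), float("nan")
        norm_rows.append(
            {"variable": v, "M": vals.mean(), "Mdn": vals.median(),
             "SD": vals.std(), "W": W, "p": p}
        )
    normality = pd.DataFrame(norm_rows)

    cls = participants.set_index("participant")["classification"]
    crit = critical_stimuli_summary(judgments, env, cls)
    gaze_means = participants.groupby("classification").agg(
        n=("participant", "size"),
        lan_duration=("lan_duration", "mean"),
        lan_strength=("lan_strength", "mean"),
    )
    group_summary = gaze_means.reset_index().rename(
        columns={"classification": "group"}
    ).merge(crit.drop(columns="n"), on="group", how="left")

    subgroup = {}
    lo, hi = alpha_window
    window = participants[(participants["alpha"] > lo) & (participants["alpha"] < hi)]
    if len(window) >= 3:
        tau, p = kendall_tau(window["alpha"], window["lan_duration"])
        subgroup = {"window": (lo, hi), "n": len(window), "tau": tau, "p": p}
    group_tests = {}
    two = participants[participants["classification"].isin(
        ["rule_user", "similarity_user"])]
    if two["classification"].nunique() == 2:
        W, p = group_compare(two["lan_duration"], two["classification"])
        group_tests["lan_duration"] = {"W": W, "p": p}
        W, p = group_compare(two["lan_strength"], two["classification"])
        group_tests["lan_strength"] = {"W": W, "p": p}
    if participants["alpha"].nunique() > 1:
        t, p = sps.ttest_1samp(participants["alpha"], 0.5)
        group_tests["alpha_vs_half"] = {"t": float(t), "p": float(p)}

    return AssociationReport(
        participants=participants,
        correlations=correlations,
        normality=normality,
        group_summary=group_summary,
        subgroup=subgroup,
        group_tests=group_tests,
        flags=flags,
    )


def render_report(report: AssociationReport) -> str:
    """Plain-markdown rendering of the association report."""
    lines = ["# Judgment-model / looking-at-nothing association report", ""]
    n = len(report.participants)
    lines.append(f"Participants: {n}")
    if report.flags:
        lines += ["", "Flags:"] + [f"- {f}" for f in report.flags]
    lines += ["", "## Variable distributions and normality", "",
              report.normality.round(3).to_markdown(index=False)]
    lines += ["", "## Kendall correlations (tau below diagonal, p above)", "",
              report.correlations.round(3).to_markdown()]
    lines += ["", "## Rule vs. similarity users", "",
              report.group_summary.round(2).to_markdown(index=False)]
    if report.subgroup:
        s = report.subgroup
        lines += ["", f"Subgroup {s['window'][0]} < alpha < {s['window'][1]} "
                      f"(n={s['n']}): tau = {s['tau']:.3f}, p = {s['p']:.4f}"]
    for name, t in report.group_tests.items():
        stat = ", ".join(f"{k} = {v:.3f}" for k, v in t.items())
        lines.append(f"- {name}: {stat}")
    return "\n".join(lines) + "\n"


def write_report(report: AssociationReport, outdir) -> None:
    """Write the report tables as CSV plus a markdown summary (byte-stable
    for identical inputs)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.participants.to_csv(out / "participants.csv", index=False)
    report.correlations.to_csv(out / "correlation_matrix.csv")
    report.normality.to_csv(out / "normality.csv", index=False)
    report.group_summary.to_csv(out / "group_summary.csv", index=False)
    (out / "report.md").write_text(render_report(report))
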