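"""Looking-at-nothing (LAN) gaze metrics.

After the briefly presented test stimulus disappears, the four exemplar
screen locations remain marked only by gray rectangles; fixations to those
now-empty areas of interest (AOIs) are the looking-at-nothing signature of
exemplar retrieval.  This module builds the AOI geometry, labels fixations,
and computes the trial- and participant-level metrics:

* LAN duration — exemplar-AOI gaze time / (exemplar + center AOI gaze time);
* LAN strength — gaze time on the most-similar exemplar's AOI / total
  exemplar-AOI gaze time, where "most similar" minimizes the
  attention-weighted city-block distance;
* within-trial time course over five equal-length bins (fixations straddling
  a bin edge are split pro-rata);
* trial-level counts (share of trials with any exemplar gaze, number of
  distinct exemplar locations visited, dominant-location share);
* stimulus-wise split-half reliability between odd and even presentations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .environment import Environment, Stimulus
from .model import weighted_cityblock

OUTSIDE = "outside"
CENTER = "center"

DEFAULT_SCREEN = (1920, 1080)
DEFAULT_STIMULUS_SIZE = (320, 180)
DEFAULT_OFFSETS = (415, 235)
DEFAULT_MARGIN = 0.1
MIN_FIXATION_MS = 80.0


@dataclass(frozen=True)
class Rect:
    """Axis-aligned screen rectangle, pixel coordinates, y growing downward."""

    cx: float
    cy: float
    width: float
    height: float

    @property
    def x0(self) -> float:
        return self.cx - self.width / 2

    @property
    def x1(self) -> float:
        return self.cx + self.width / 2

    @property
    def y0(self) -> float:
        return self.cy - self.height / 2

    @property
    def y1(self) -> float:
        return self.cy + self.height / 2

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )


@dataclass(frozen=True)
class AOISet:
    """Five AOIs: one per exemplar corner plus the central stimulus area."""

    exemplar_aois: dict[Stimulus, Rect]
    center: Rect
    screen: tuple[int, int] = DEFAULT_SCREEN

    def __post_init__(self) -> None:
        rects = [*self.exemplar_aois.values(), self.center]
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                if rects[i].overlaps(rects[j]):
                    raise ValueError("AOIs must be pairwise disjoint")

    @property
    def exemplar_labels(self) -> list[str]:
        return [str(e) for e in sorted(self.exemplar_aois)]

    def label_point(self, x: float, y: float) -> str:
        if self.center.contains(x, y):
            return CENTER
        for e, r in self.exemplar_aois.items():
            if r.contains(x, y):
                return str(e)
        return OUTSIDE

    def to_dict(self) -> dict:
        def rec(r: Rect) -> dict:
            return {"cx": r.cx, "cy": r.cy, "width": r.width, "height": r.height}

        return {
            "screen": list(self.screen),
            "center": rec(self.center),
            "exemplars": {str(e): rec(r) for e, r in sorted(self.exemplar_aois.items())},
        }


def build_aois(
    env: Environment | None = None,
    screen: tuple[int, int] = DEFAULT_SCREEN,
    stimulus_size: tuple[float, float] = DEFAULT_STIMULUS_SIZE,
    offsets: tuple[float, float] = DEFAULT_OFFSETS,
    margin: float = DEFAULT_MARGIN,
    corner_map: Mapping[str, Stimulus] | None = None,
) -> AOISet:
    """AOI geometry for the default display.

    Each AOI is the stimulus footprint inflated by ``margin`` per side
    (320x180 px stimuli with margin 0.1 give 384x216 px AOIs).  Exemplar AOI
    centers sit at the four screen-corner offsets (+-415, +-235) px from the
    screen center — 477 px of eccentricity; the fifth AOI covers the central
    test-stimulus location.  ``corner_map`` assigns exemplars to the corners
    ``ul, ur, ll, lr``; the default maps exemplars in (x1, x2) order.  (In
    the experiment the assignment was randomized per participant; the metrics
    are invariant to it.)
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    w = stimulus_size[0] * (1 + 2 * margin)
    h = stimulus_size[1] * (1 + 2 * margin)
    cx, cy = screen[0] / 2, screen[1] / 2
    dx, dy = offsets
    corners = {
        "ul": (cx - dx, cy - dy),
        "ur": (cx + dx, cy - dy),
        "ll": (cx - dx, cy + dy),
        "lr": (cx + dx, cy + dy),
    }
    if env is None:
        env = Environment.multiplicative()
    if corner_map is None:
        corner_map = dict(zip(["ul", "ur", "ll", "lr"], env.exemplar_list))
    exemplar_aois = {
        Stimulus(*corner_map[c]): Rect(corners[c][0], corners[c][1], w, h)
        for c in corner_map
    }
    center = Rect(cx, cy, w, h)
    return AOISet(exemplar_aois=exemplar_aois, center=center, screen=screen)


# ---------------------------------------------------------------------------
# Fixation labeling and per-trial aggregation
# ---------------------------------------------------------------------------

FIXATION_COLUMNS = ("participant", "trial", "onset_ms", "duration_ms", "x_px", "y_px")


def assign_fixations(
    fixations: pd.DataFrame,
    aois: AOISet,
    min_duration_ms: float = MIN_FIXATION_MS,
) -> pd.DataFrame:
    """Label each fixation with its containing AOI (or "outside").

    Fixations shorter than ``min_duration_ms`` are dropped (the event
    detector's minimum fixation duration); out-of-AOI fixations are kept and
    labelled, never discarded.
    """
    df = fixations[fixations["duration_ms"] >= min_duration_ms].copy()
    df["aoi"] = [
        aois.label_point(x, y) for x, y in zip(df["x_px"], df["y_px"])
    ]
    return df


def trial_gaze_table(
    labeled: pd.DataFrame,
    aois: AOISet,
    trials: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-trial summed gaze durations per AOI.

    ``trials`` (participant, trial, x1, x2[, trial_len_ms]) supplies the test
    stimulus and the removal-to-click trial length; without it the trial
    length is inferred as the last fixation offset.  Output columns: one
    ``ms_<label>`` per exemplar AOI plus ``ms_center``, ``ms_outside``,
    ``ms_exemplar_total`` and ``trial_len_ms``.
    """
    labels = aois.exemplar_labels
    pivot = (
        labeled.pivot_table(
            index=["participant", "trial"],
            columns="aoi",
            values="duration_ms",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=labels + [CENTER, OUTSIDE], fill_value=0.0)
    )
    pivot.columns = [f"ms_{c}" for c in pivot.columns]
    end = labeled.assign(end=labeled["onset_ms"] + labeled["duration_ms"]).groupby(
        ["participant", "trial"]
    )["end"].max()
    out = pivot.reset_index()
    out["ms_exemplar_total"] = out[[f"ms_{l}" for l in labels]].sum(axis=1)
    if trials is not None:
        out = trials.merge(out, on=["participant", "trial"], how="left")
        ms_cols = [c for c in out.columns if c.startswith("ms_")]
        out[ms_cols] = out[ms_cols].fillna(0.0)
        if "trial_len_ms" not in out.columns:
            out = out.merge(
                end.rename("trial_len_ms").reset_index(),
                on=["participant", "trial"],
                how="left",
            )
    else:
        out = out.merge(
            end.rename("trial_len_ms").reset_index(), on=["participant", "trial"]
        )
    return out


def lan_duration(row: Mapping[str, float]) -> float:
    """LAN duration: exemplar gaze / (exemplar + center gaze); NaN when no
    gaze landed in either (such trials are excluded from aggregation)."""
    denom = row["ms_exemplar_total"] + row["ms_center"]
    if denom <= 0:
        return float("nan")
    return float(row["ms_exemplar_total"] / denom)


def most_similar_exemplar(
    s: Stimulus, env: Environment, w: Sequence[float] = (0.5, 0.5)
) -> Stimulus:
    """Exemplar minimizing the attention-weighted city-block distance.

    Ties are broken deterministically: lowest unweighted city-block distance
    first, then lexicographically lowest (x1, x2).
    """
    s = Stimulus(*s)

    def key(e: Stimulus):
        return (
            round(weighted_cityblock(s, e, w), 12),
            abs(s.x1 - e.x1) + abs(s.x2 - e.x2),
            e.x1,
            e.x2,
        )

    return min(env.exemplar_list, key=key)


def lan_strength(row: Mapping[str, float], most_similar: Stimulus) -> float:
    """LAN strength: gaze on the most-similar exemplar's AOI / total exemplar
    gaze; NaN when there was no exemplar gaze at all."""
    total = row["ms_exemplar_total"]
    if total <= 0:
        return float("nan")
    return float(row[f"ms_{Stimulus(*most_similar)}"] / total)


def add_trial_metrics(
    trial_gaze: pd.DataFrame,
    env: Environment,
    weights: Mapping[int, Sequence[float]] | Sequence[float] = (0.5, 0.5),
) -> pd.DataFrame:
    """Attach lan_duration, most-similar exemplar, and lan_strength per trial.

    ``weights`` is either one (w1, w2) pair or a per-participant mapping
    (e.g., median fitted cue weights normalized to sum to 1).
    """
    df = trial_gaze.copy()
    def w_for(pid):
        if isinstance(weights, Mapping):
            return weights.get(pid, (0.5, 0.5))
        return weights

    ms_lookup: dict[tuple, Stimulus] = {}
    most_sim, strength, duration = [], [], []
    for row in df.itertuples(index=False):
        rowd = row._asdict()
        key = (rowd["participant"], int(rowd["x1"]), int(rowd["x2"]))
        if key not in ms_lookup:
            ms_lookup[key] = most_similar_exemplar(
                Stimulus(key[1], key[2]), env, w_for(key[0])
            )
        ms = ms_lookup[key]
        most_sim.append(str(ms))
        duration.append(lan_duration(rowd))
        strength.append(lan_strength(rowd, ms))
    df["most_similar"] = most_sim
    df["lan_duration"] = duration
    df["lan_strength"] = strength
    return df


# ---------------------------------------------------------------------------
# Within-trial time course
# ---------------------------------------------------------------------------

def _bin_overlaps(onset: float, duration: float, edges: np.ndarray) -> np.ndarray:
    """Milliseconds of a fixation falling into each [edges[i], edges[i+1]) bin
    (pro-rata split of boundary-straddling fixations)."""
    start = np.maximum(edges[:-1], onset)
    stop = np.minimum(edges[1:], onset + duration)
    return np.maximum(stop - start, 0.0)


def binned_gaze_ms(
    trial_fixations: pd.DataFrame,
    trial_len_ms: float,
    n_bins: int = 5,
    split: str = "prorata",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin exemplar and center gaze milliseconds for one trial.

    With ``split="prorata"`` a fixation straddling a bin edge contributes to
    each bin in proportion to its overlap (gaze time is conserved across
    bins); ``split="onset"`` assigns it entirely to its onset bin.
    """
    if trial_len_ms <= 0:
        raise ValueError("trial length must be positive")
    if split not in ("prorata", "onset"):
        raise ValueError(f"unknown split rule {split!r}")
    edges = np.linspace(0.0, trial_len_ms, n_bins + 1)
    ex_ms = np.zeros(n_bins)
    center_ms = np.zeros(n_bins)
    for row in trial_fixations.itertuples(index=False):
        aoi = row.aoi
        if aoi == OUTSIDE:
            continue
        if split == "prorata":
            contrib = _bin_overlaps(row.onset_ms, row.duration_ms, edges)
        else:
            b = min(int(row.onset_ms / trial_len_ms * n_bins), n_bins - 1)
            contrib = np.zeros(n_bins)
            contrib[b] = row.duration_ms
        if aoi == CENTER:
            center_ms += contrib
        else:
            ex_ms += contrib
    return ex_ms, center_ms


def time_binned_lan(
    trial_fixations: pd.DataFrame,
    trial_len_ms: float,
    n_bins: int = 5,
    split: str = "prorata",
) -> np.ndarray:
    """Per-bin LAN duration for one trial.

    The trial time from stimulus removal to the response click is cut into
    ``n_bins`` equal intervals; per bin, LAN duration is exemplar gaze over
    exemplar-plus-center gaze.  Bins with no exemplar or center gaze
    contribute 0 (not NaN), so per-bin curves can be averaged over all
    trials.
    """
    ex_ms, center_ms = binned_gaze_ms(trial_fixations, trial_len_ms, n_bins, split)
    denom = ex_ms + center_ms
    return np.where(denom > 0, ex_ms / np.where(denom > 0, denom, 1.0), 0.0)


def binned_lan_by_participant(
    labeled: pd.DataFrame,
    trial_gaze: pd.DataFrame,
    n_bins: int = 5,
    split: str = "prorata",
) -> pd.DataFrame:
    """Mean per-bin LAN duration per participant (rows) over all trials."""
    lens = trial_gaze.set_index(["participant", "trial"])["trial_len_ms"]
    out = {}
    for (pid, trial), sub in labeled.groupby(["participant", "trial"]):
        length = lens.get((pid, trial), np.nan)
        if not np.isfinite(length) or length <= 0:
            continue
        out.setdefault(pid, []).append(
            time_binned_lan(sub, length, n_bins=n_bins, split=split)
        )
    rows = {pid: np.mean(np.vstack(v), axis=0) for pid, v in out.items()}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"bin{i + 1}" for i in range(n_bins)]
    ).rename_axis("participant")


# ---------------------------------------------------------------------------
# Trial-level summaries and reliability
# ---------------------------------------------------------------------------

def trial_level_stats(trial_metrics: pd.DataFrame, exemplar_labels: Sequence[str]) -> pd.DataFrame:
    """Per-participant trial-level LAN summary.

    Columns: ``prop_lan_trials`` (share of trials with any exemplar-AOI
    gaze); ``n_locations_p0..p4`` (distribution of the number of distinct
    exemplar locations per trial); ``single_aoi_share`` (share of LAN trials
    visiting exactly one location); ``single_most_similar_share`` (share of
    those whose location is the most-similar exemplar); ``dominant_share``
    (mean share of exemplar gaze on the dominant location in multi-location
    trials) and ``dominant_most_similar_share``.
    """
    ms_cols = [f"ms_{l}" for l in exemplar_labels]
    rows = []
    for pid, sub in trial_metrics.groupby("participant"):
        gaze = sub[ms_cols].to_numpy(dtype=float)
        n_loc = (gaze > 0).sum(axis=1)
        lan_trials = n_loc > 0
        counts = np.bincount(n_loc, minlength=5)[:5] / len(sub)
        rec = {"participant": pid, "prop_lan_trials": float(lan_trials.mean())}
        rec.update({f"n_locations_p{k}": float(counts[k]) for k in range(5)})
        single = n_loc == 1
        multi = n_loc > 1
        ms_idx = sub["most_similar"].map(
            {l: i for i, l in enumerate(exemplar_labels)}
        ).to_numpy()
        looked_idx = gaze.argmax(axis=1)
        if single.any():
            rec["single_aoi_share"] = float(single.sum() / lan_trials.sum())
            rec["single_most_similar_share"] = float(
                (looked_idx[single] == ms_idx[single]).mean()
            )
        else:
            rec["single_aoi_share"] = float("nan")
            rec["single_most_similar_share"] = float("nan")
        if multi.any():
            rec["dominant_share"] = float(
                (gaze[multi].max(axis=1) / gaze[multi].sum(axis=1)).mean()
            )
            rec["dominant_most_similar_share"] = float(
                (looked_idx[multi] == ms_idx[multi]).mean()
            )
        else:
            rec["dominant_share"] = float("nan")
            rec["dominant_most_similar_share"] = float("nan")
        rows.append(rec)
    return pd.DataFrame(rows)


def split_half_reliability(trial_metrics: pd.DataFrame, min_presentations: int = 2) -> float:
    """Stimulus-wise split-half correlation of LAN duration.

    For each stimulus, trials are ordered by trial index and split into odd
    and even presentations; the two per-stimulus means are then correlated
    (Pearson) across stimuli.  Stimuli with fewer than ``min_presentations``
    trials are dropped with a warning.
    """
    odd_means, even_means = [], []
    for (x1, x2), sub in trial_metrics.groupby(["x1", "x2"]):
        sub = sub.sort_values("trial")
        if len(sub) < min_presentations:
            warnings.warn(f"stimulus ({x1},{x2}) has fewer than "
                          f"{min_presentations} presentations; dropped")
            continue
        vals = sub["lan_duration"].to_numpy()
        odd_means.append(np.nanmean(vals[0::2]))
        even_means.append(np.nanmean(vals[1::2]))
    odd = np.asarray(odd_means)
    even = np.asarray(even_means)
    ok = np.isfinite(odd) & np.isfinite(even)
    if ok.sum() < 3:
        return float("nan")
    return float(np.corrcoef(odd[ok], even[ok])[0, 1])


def participant_gaze_summary(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    env: Environment,
    aois: AOISet | None = None,
    weights: Mapping[int, Sequence[float]] | Sequence[float] = (0.5, 0.5),
    n_bins: int = 5,
) -> pd.DataFrame:
    """End-to-end per-participant gaze summary.

    Labels fixations, aggregates per trial, and returns one row per
    participant with mean LAN duration and strength, trial-level stats,
    per-bin means, and split-half reliability.
    """
    if aois is None:
        aois = build_aois(env)
    labeled = assign_fixations(fixations, aois)
    tg = trial_gaze_table(labeled, aois, trials=trials)
    tm = add_trial_metrics(tg, env, weights=weights)
    base = tm.groupby("participant").agg(
        lan_duration=("lan_duration", "mean"),
        lan_strength=("lan_strength", "mean"),
        n_trials=("trial", "size"),
    )
    stats_df = trial_level_stats(tm, aois.exemplar_labels).set_index("participant")
    bins = binned_lan_by_participant(labeled, tg, n_bins=n_bins)
    rel = tm.groupby("participant").apply(
        split_half_reliability, include_groups=False
    ).rename("split_half_r")
    out = base.join([stats_df, bins, rel]).reset_index()
    return out
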