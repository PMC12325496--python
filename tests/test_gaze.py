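"""AOI geometry, fixation assignment, and looking-at-nothing metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from rulexgaze.environment import Stimulus
from rulexgaze.gaze import (
    assign_fixations,
    binned_gaze_ms,
    build_aois,
    lan_duration,
    lan_strength,
    most_similar_exemplar,
    split_half_reliability,
    time_binned_lan,
    trial_gaze_table,
    trial_level_stats,
)


class TestGeometry:
    def test_aoi_size_from_stimulus_and_margin(self, aois):
        r = aois.center
        assert (r.width, r.height) == (384, 216)

    def test_exemplar_eccentricity(self, aois):
        cx, cy = 960, 540
        for r in aois.exemplar_aois.values():
            assert round(math.hypot(r.cx - cx, r.cy - cy)) == 477
            assert (abs(r.cx - cx), abs(r.cy - cy)) == (415, 235)

    def test_zero_margin_equals_footprint(self, env):
        a = build_aois(env, margin=0.0)
        assert (a.center.width, a.center.height) == (320, 180)

    def test_overlapping_aois_rejected(self, env):
        with pytest.raises(ValueError):
            build_aois(env, offsets=(100, 50))

    def test_point_labeling(self, aois):
        assert aois.label_point(960, 540) == "center"
        assert aois.label_point(10, 10) == "outside"
        e = sorted(aois.exemplar_aois)[0]
        r = aois.exemplar_aois[e]
        assert aois.label_point(r.cx, r.cy) == str(e)


def fixation_df(rows):
    return pd.DataFrame(
        rows, columns=["participant", "trial", "onset_ms", "duration_ms", "x_px", "y_px"]
    )


class TestAssignment:
    def test_short_fixations_filtered(self, aois):
        fx = fixation_df([(1, 1, 0, 79, 960, 540), (1, 1, 100, 80, 960, 540)])
        labeled = assign_fixations(fx, aois)
        assert len(labeled) == 1

    def test_same_aoi_durations_add(self, env, aois):
        e = env.exemplar_list[0]
        r = aois.exemplar_aois[e]
        fx = fixation_df(
            [(1, 1, 0, 100, r.cx, r.cy), (1, 1, 200, 100, r.cx + 5, r.cy - 5)]
        )
        tg = trial_gaze_table(assign_fixations(fx, aois), aois)
        assert tg.loc[0, f"ms_{e}"] == pytest.approx(200.0)
        assert tg.loc[0, "ms_exemplar_total"] == pytest.approx(200.0)


class TestLanMetrics:
    def row(self, env, ex_ms, center_ms):
        labels = [str(e) for e in env.exemplar_list]
        rec = {f"ms_{l}": v for l, v in zip(labels, ex_ms)}
        rec["ms_center"] = center_ms
        rec["ms_exemplar_total"] = sum(ex_ms)
        return rec

    def test_lan_duration_arithmetic(self, env):
        assert lan_duration(self.row(env, [300, 0, 0, 0], 700)) == pytest.approx(0.30)
        assert lan_duration(self.row(env, [0, 0, 0, 0], 500)) == 0.0
        assert lan_duration(self.row(env, [100, 50, 0, 0], 0)) == 1.0

    def test_lan_duration_undefined_without_gaze(self, env):
        assert math.isnan(lan_duration(self.row(env, [0, 0, 0, 0], 0)))

    def test_lan_strength(self, env):
        ms = env.exemplar_list[0]
        r = self.row(env, [400, 0, 0, 0], 0)
        assert lan_strength(r, ms) == 1.0
        r = self.row(env, [100, 100, 100, 100], 0)
        assert lan_strength(r, ms) == pytest.approx(0.25)
        assert math.isnan(lan_strength(self.row(env, [0, 0, 0, 0], 100), ms))

    def test_split_invariance(self, env, aois):
        """Splitting a fixation into contiguous sub-fixations leaves the
        trial metrics unchanged."""
        e = env.exemplar_list[1]
        r = aois.exemplar_aois[e]
        whole = fixation_df(
            [(1, 1, 0, 400, 960, 540), (1, 1, 500, 300, r.cx, r.cy)]
        )
        split = fixation_df(
            [
                (1, 1, 0, 150, 960, 540),
                (1, 1, 150, 250, 960, 540),
                (1, 1, 500, 120, r.cx, r.cy),
                (1, 1, 620, 180, r.cx, r.cy),
            ]
        )
        tws = [
            trial_gaze_table(assign_fixations(f, aois), aois) for f in (whole, split)
        ]
        for col in ("ms_center", "ms_exemplar_total"):
            assert tws[0].loc[0, col] == pytest.approx(tws[1].loc[0, col])


class TestMostSimilar:
    def test_zero_distance_wins(self, env):
        assert most_similar_exemplar(Stimulus(3, 2), env) == Stimulus(3, 2)

    def test_hand_computed_distances(self, env):
        # distances from (1,1) with equal weights: .5, 1.5, 1.5, 2.5
        assert most_similar_exemplar(Stimulus(1, 1), env, (0.5, 0.5)) == Stimulus(2, 1)

    def test_tie_break_is_documented_rule(self, env):
        # (2,3) is weighted-distance 1 from all four exemplars and unweighted
        # distance 2 from all of them: lexicographic order decides
        assert most_similar_exemplar(Stimulus(2, 3), env, (0.5, 0.5)) == Stimulus(1, 4)

    def test_old_stimuli_map_to_themselves(self, env):
        for e in env.exemplar_list:
            assert most_similar_exemplar(e, env, (0.7, 0.3)) == e


class TestTimeBins:
    def center_fix(self, onset, dur):
        return {"onset_ms": onset, "duration_ms": dur, "aoi": "center"}

    def ex_fix(self, onset, dur, label):
        return {"onset_ms": onset, "duration_ms": dur, "aoi": label}

    def test_single_center_fixation_zero_lan_everywhere(self):
        fx = pd.DataFrame([self.center_fix(0, 1000)])
        lan = time_binned_lan(fx, 1000.0)
        assert lan.tolist() == [0.0] * 5

    def test_exemplar_fixation_inside_one_bin(self, env):
        label = str(env.exemplar_list[0])
        fx = pd.DataFrame([self.ex_fix(650, 100, label)])
        lan = time_binned_lan(fx, 1000.0)
        assert lan.tolist() == [0.0, 0.0, 0.0, 1.0, 0.0]

    def test_prorata_split_conserves_duration(self, env, rng):
        label = str(env.exemplar_list[0])
        rows = []
        for _ in range(20):
            onset = rng.uniform(0, 900)
            dur = rng.uniform(10, 1000 - onset)
            kind = rng.choice(["center", label])
            rows.append({"onset_ms": onset, "duration_ms": dur, "aoi": kind})
        fx = pd.DataFrame(rows)
        ex_ms, center_ms = binned_gaze_ms(fx, 1000.0, n_bins=5)
        tot_ex = fx[fx.aoi == label]["duration_ms"].sum()
        tot_c = fx[fx.aoi == "center"]["duration_ms"].sum()
        assert ex_ms.sum() == pytest.approx(tot_ex, abs=1e-9)
        assert center_ms.sum() == pytest.approx(tot_c, abs=1e-9)

    def test_onset_rule_assigns_whole_fixation(self, env):
        label = str(env.exemplar_list[0])
        fx = pd.DataFrame([self.ex_fix(190, 300, label)])
        ex_ms, _ = binned_gaze_ms(fx, 1000.0, split="onset")
        assert ex_ms.tolist() == [300.0, 0.0, 0.0, 0.0, 0.0]

    def test_invalid_trial_length(self):
        with pytest.raises(ValueError):
            time_binned_lan(pd.DataFrame([self.center_fix(0, 10)]), 0.0)


class TestTrialLevelStats:
    def make_metrics(self, env, per_trial_counts):
        labels = [str(e) for e in env.exemplar_list]
        rows = []
        for t, k in enumerate(per_trial_counts, start=1):
            rec = {"participant": 1, "trial": t, "most_similar": labels[0]}
            for i, l in enumerate(labels):
                rec[f"ms_{l}"] = 100.0 if i < k else 0.0
            rows.append(rec)
        return pd.DataFrame(rows), labels

    def test_count_distribution(self, env):
        tm, labels = self.make_metrics(env, [0, 1, 1, 2])
        out = trial_level_stats(tm, labels)
        assert out.loc[0, "prop_lan_trials"] == pytest.approx(0.75)
        assert out.loc[0, "n_locations_p0"] == pytest.approx(0.25)
        assert out.loc[0, "n_locations_p1"] == pytest.approx(0.50)
        assert out.loc[0, "n_locations_p2"] == pytest.approx(0.25)

    def test_all_single_most_similar(self, env):
        tm, labels = self.make_metrics(env, [1, 1, 1])
        out = trial_level_stats(tm, labels)
        assert out.loc[0, "prop_lan_trials"] == 1.0
        assert out.loc[0, "single_aoi_share"] == 1.0
        assert out.loc[0, "single_most_similar_share"] == 1.0

    def test_no_exemplar_gaze_anywhere(self, env):
        tm, labels = self.make_metrics(env, [0, 0])
        out = trial_level_stats(tm, labels)
        assert out.loc[0, "prop_lan_trials"] == 0.0
        assert out.loc[0, "n_locations_p0"] == 1.0


class TestSplitHalf:
    def metrics_from_values(self, values_by_stim):
        rows = []
        trial = 0
        for (x1, x2), vals in values_by_stim.items():
            for v in vals:
                trial += 1
                rows.append(
                    {"participant": 1, "trial": trial, "x1": x1, "x2": x2,
                     "lan_duration": v}
                )
        return pd.DataFrame(rows)

    def test_identical_halves(self):
        vals = {(a, b): [0.1 * (a + b)] * 4 for a in (1, 2) for b in (1, 2)}
        tm = self.metrics_from_values(vals)
        assert split_half_reliability(tm) == pytest.approx(1.0)

    def test_anti_pattern(self):
        # odd means increase across stimuli while even means decrease
        vals = {
            (1, 1): [0.1, 0.9],
            (1, 2): [0.2, 0.8],
            (2, 1): [0.3, 0.7],
            (2, 2): [0.4, 0.6],
        }
        tm = self.metrics_from_values(vals)
        assert split_half_reliability(tm) == pytest.approx(-1.0)

    def test_matches_hand_rolled_pairing_oracle(self, rng):
        vals = {}
        for a in (1, 2, 3, 4):
            for b in (1, 2):
                vals[(a, b)] = list(rng.uniform(0, 1, size=6))
        tm = self.metrics_from_values(vals)
        odd = [np.mean(v[0::2]) for v in vals.values()]
        even = [np.mean(v[1::2]) for v in vals.values()]
        expected = np.corrcoef(odd, even)[0, 1]
        assert split_half_reliability(tm) == pytest.approx(expected, abs=1e-12)

    def test_sparse_stimulus_dropped(self):
        vals = {(1, 1): [0.1, 0.2], (1, 2): [0.4, 0.1], (2, 1): [0.3, 0.6],
                (2, 2): [0.5]}
        tm = self.metrics_from_values(vals)
        with pytest.warns(UserWarning, match="fewer"):
            split_half_reliability(tm)
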