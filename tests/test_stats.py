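"""Statistical layer: rank correlation, group tests, power analysis, report."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rulexgaze.environment import Stimulus
from rulexgaze.simulate import CohortSpec, generate_judgments
from rulexgaze.stats import (
    build_report,
    exemplar_accuracy,
    group_compare,
    kendall_tau,
    proportion_chi2,
    render_report,
    required_n_for_correlation,
    sensitivity_power_correlation,
    shapiro_screen,
)


def tau_b_oracle(x, y):
    """O(n^2) concordant/discordant pair counting with tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[i] - x[j])
            dy = np.sign(y[i] - y[j])
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / math.sqrt((n0 - tx) * (n0 - ty))


class TestKendallTau:
    def test_perfectly_concordant(self):
        tau, _ = kendall_tau([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert tau == pytest.approx(1.0)

    def test_perfectly_discordant(self):
        tau, _ = kendall_tau([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_tied_fixture_matches_pair_counting_oracle(self):
        x = [1, 1, 2, 3, 3, 4, 5, 5]
        y = [2, 1, 1, 3, 4, 4, 4, 6]
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(tau_b_oracle(x, y), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_random_fixtures_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=12).astype(float)
        y = rng.integers(0, 6, size=12).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(tau_b_oracle(x, y), abs=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            tau, p = kendall_tau([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(tau)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2, 3])


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        vals = [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        labels = ["a"] * 5 + ["b"] * 5
        _, p = group_compare(vals, labels)
        assert p > 0.9

    def test_fully_separated_matches_enumeration_oracle(self):
        a = [10.0, 11, 12, 13, 14]
        b = [1.0, 2, 3, 4, 5]
        stat, p = group_compare(a + b, ["a"] * 5 + ["b"] * 5)
        # exhaustive count of (a_i, b_j) pairs with a_i > b_j
        oracle_u = sum(ai > bj for ai, bj in itertools.product(a, b))
        assert stat == pytest.approx(oracle_u)
        assert oracle_u == 25
        assert p < 0.01

    def test_singleton_group_warns_but_works(self):
        with pytest.warns(UserWarning, match="singleton"):
            stat, p = group_compare([1, 2, 3, 9], ["a", "a", "a", "b"])
        assert np.isfinite(p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1, 2, 3], ["a", "a", "a"])


class TestPowerAnalysis:
    def test_design_sensitivity(self):
        rho = sensitivity_power_correlation(48, 0.05, 0.95, sides=2)
        assert round(rho, 2) == 0.49

    def test_large_n_limit(self):
        assert sensitivity_power_correlation(10**6) < 0.01

    def test_round_trip_n(self):
        rho = sensitivity_power_correlation(48)
        assert required_n_for_correlation(rho) == 48

    @given(st.integers(5, 5000))
    @settings(deadline=None, max_examples=30)
    def test_mutual_inverses(self, n):
        rho = sensitivity_power_correlation(n)
        back = sensitivity_power_correlation(required_n_for_correlation(rho))
        assert abs(back - rho) < 1e-6 or required_n_for_correlation(rho) == n

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            sensitivity_power_correlation(3)


class TestSmallUtilities:
    def test_proportion_chi2_symmetric(self):
        chi2, p = proportion_chi2(30, 100, 30, 100)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_shapiro_screen_flags_uniform_tail(self, rng):
        W, p = shapiro_screen(rng.normal(size=200))
        assert 0.9 < W <= 1.0

    def test_exemplar_accuracy_counts_exact_matches(self, env):
        e1, e2 = env.exemplar_list[0], env.exemplar_list[1]
        df = pd.DataFrame(
            {
                "participant": [1, 1, 1, 1],
                "x1": [e1.x1, e1.x1, e2.x1, 3],
                "x2": [e1.x2, e1.x2, e2.x2, 3],
                "response": [env.exemplars[e1], env.exemplars[e1] + 1,
                             env.exemplars[e2], 17],
            }
        )
        acc = exemplar_accuracy(df, env)
        assert acc.loc[1] == pytest.approx(2 / 3)


class TestReport:
    def gaze_table(self, pids, rng):
        return pd.DataFrame(
            {
                "participant": pids,
                "lan_duration": rng.uniform(0, 0.5, len(pids)),
                "lan_strength": rng.uniform(0, 1, len(pids)),
                "prop_lan_trials": rng.uniform(0, 1, len(pids)),
            }
        )

    def fit_table(self, pids, alphas):
        return pd.DataFrame(
            {
                "participant": pids,
                "alpha": alphas,
                "classification": [
                    "rule_user" if a < 0.5 else "similarity_user" for a in alphas
                ],
                "single_cue": [False] * len(pids),
            }
        )

    def test_id_mismatch_lists_offenders(self, env, rng):
        fits = self.fit_table([1, 2, 3], [0.2, 0.4, 0.8])
        gaze = self.gaze_table([1, 2, 4], rng)
        judgments, _ = generate_judgments(CohortSpec(n_participants=3, seed=0), env)
        with pytest.raises(ValueError, match=r"only-fits=\[3\].*only-gaze=\[4\]"):
            build_report(fits, gaze, judgments, env)

    def test_single_participant_renders_with_flags(self, env, rng):
        fits = self.fit_table([1], [0.3])
        gaze = self.gaze_table([1], rng)
        judgments, _ = generate_judgments(CohortSpec(n_participants=1, seed=0), env)
        rep = build_report(fits, gaze, judgments, env)
        assert rep.flags
        text = render_report(rep)
        assert "Participants: 1" in text

    def test_noiseless_rule_cohort_critical_errors_closed_form(self, env):
        """For a zero-noise pure-rule cohort with unjittered least-squares
        betas, the group's signed error on each critical stimulus equals the
        rounded least-squares prediction minus the true criterion."""
        spec = CohortSpec(
            n_participants=4, seed=0, fixed_alpha=0.0, fixed_sigma=0.0,
            beta_jitter_sd=0.0,
        )
        judgments, truth = generate_judgments(spec, env)
        rng = np.random.default_rng(0)
        fits = self.fit_table(truth["participant"], truth["alpha"])
        gaze = self.gaze_table(list(truth["participant"]), rng)
        rep = build_report(fits, gaze, judgments, env)
        # the unjittered generating betas are the normal-equations solution
        X = np.array([[1.0, e.x1, e.x2] for e in env.exemplar_list])
        y = np.array([float(env.exemplars[e]) for e in env.exemplar_list])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        b = truth.iloc[0]
        assert np.allclose([b.beta0, b.beta1, b.beta2], coef, atol=1e-9)
        row = rep.group_summary.set_index("group").loc["rule_user"]
        for s in (Stimulus(1, 1), Stimulus(1, 2), Stimulus(3, 4), Stimulus(4, 4)):
            pred = np.clip(
                np.rint(b.beta0 + b.beta1 * s.x1 + b.beta2 * s.x2),
                env.scale_min,
                env.scale_max,
            )
            assert row[f"error_{s}"] == pytest.approx(pred - env.criterion(s))

    def test_strong_coupling_yields_positive_tau(self, env, rng):
        pids = list(range(1, 13))
        alphas = np.linspace(0.05, 0.95, 12)
        fits = self.fit_table(pids, alphas)
        gaze = self.gaze_table(pids, rng)
        gaze["lan_duration"] = 0.05 + 0.4 * alphas + rng.normal(0, 0.02, 12)
        judgments, _ = generate_judgments(CohortSpec(n_participants=12, seed=0), env)
        rep = build_report(fits, gaze, judgments, env)
        tau = rep.correlations.loc["alpha", "lan_duration"]
        assert tau > 0.2

    def test_report_is_pure(self, env, rng, tmp_path):
        from rulexgaze.stats import write_report

        pids = [1, 2, 3, 4]
        fits = self.fit_table(pids, [0.1, 0.3, 0.6, 0.9])
        gaze = self.gaze_table(pids, np.random.default_rng(5))
        judgments, _ = generate_judgments(CohortSpec(n_participants=4, seed=0), env)
        rep1 = build_report(fits, gaze, judgments, env)
        rep2 = build_report(fits, gaze, judgments, env)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_report(rep1, d1)
        write_report(rep2, d2)
        for f in ("participants.csv", "correlation_matrix.csv", "report.md"):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()
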