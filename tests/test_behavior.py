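import numpy as np
import pandas as pd
import pytest

import imprintlab as il
from imprintlab.behavior import assign_zones, best_fit_gradient, trial_zone_times


def make_frames(xs, likelihoods=None, trial_id="t0", fps=10.0):
    n = len(xs)
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "time_s": np.arange(n) / fps,
            "x_cm": np.asarray(xs, dtype=float),
            "y_cm": 30.0,
            "likelihood": 1.0 if likelihoods is None else np.asarray(likelihoods),
        }
    )


class TestFilterFrames:
    def test_all_kept(self):
        kept, frac = il.filter_frames(make_frames([10.0] * 5))
        assert len(kept) == 5 and frac == 1.0

    def test_boundary_likelihood_kept(self):
        kept, frac = il.filter_frames(make_frames([10.0, 20.0], likelihoods=[0.9, 0.8999]))
        assert len(kept) == 1 and kept["likelihood"].iloc[0] == 0.9

    def test_retained_fraction(self):
        lik = [1.0] * 8 + [0.5, 0.1]
        _, frac = il.filter_frames(make_frames([10.0] * 10, likelihoods=lik))
        assert frac == pytest.approx(0.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            il.filter_frames(make_frames([]))


class TestAssignZone:
    def test_near_familiar_monitor(self):
        assert il.assign_zone(5.0, il.ArenaConfig(), "left") == "familiar"
        assert il.assign_zone(5.0, il.ArenaConfig(), "right") == "unfamiliar"

    def test_center(self):
        assert il.assign_zone(45.0, il.ArenaConfig(), "left") == "center"

    def test_boundary_belongs_to_monitor_zone(self):
        arena = il.ArenaConfig()
        assert il.assign_zone(20.0, arena, "left") == "familiar"
        assert il.assign_zone(70.0, arena, "left") == "unfamiliar"

    def test_invalid_side(self):
        with pytest.raises(ValueError):
            il.assign_zone(5.0, il.ArenaConfig(), "top")

    def test_partition_and_dwell_sums(self, rng):
        """Every in-bounds frame lands in exactly one zone and zone times
        sum to the retained dwell time."""
        arena = il.ArenaConfig()
        xs = rng.uniform(0.0, arena.length_cm, size=500)
        zones = assign_zones(xs, arena, "left")
        assert set(zones) <= {"familiar", "center", "unfamiliar"}
        frames = make_frames(xs)
        times = trial_zone_times(frames, arena, "left", frame_interval_s=0.1)
        assert sum(times.values()) == pytest.approx(500 * 0.1)


class TestPreferenceIndex:
    def test_values(self):
        assert il.preference_index(60.0, 60.0) == 50.0
        assert il.preference_index(73.0, 27.0) == 73.0

    def test_excluded_when_no_choice_time(self):
        assert np.isnan(il.preference_index(0.0, 0.0))

    def test_scale_invariance(self):
        assert il.preference_index(30.0, 10.0) == il.preference_index(3.0, 1.0)


class TestOneSampleT:
    def test_symmetric_values_give_zero_t(self):
        t, df, p = il.one_sample_t([45.0, 55.0, 45.0, 55.0])
        assert t == pytest.approx(0.0)
        assert df == 3

    def test_textbook_oracle(self):
        """mean 55, sd 7.9057: t = 5/(7.9057/sqrt(5)) = 1.4142, df 4, p = 0.2302."""
        t, df, p = il.one_sample_t([55.0, 60.0, 50.0, 65.0, 45.0])
        assert t == pytest.approx(np.sqrt(2.0), rel=1e-6)
        assert df == 4
        assert p == pytest.approx(0.23019, abs=1e-4)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            il.one_sample_t([50.0, 50.0, 50.0])


class TestHolmAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(il.holm_adjust([0.03]), [0.03])

    def test_step_down_arithmetic(self):
        np.testing.assert_allclose(il.holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_all_ones(self):
        np.testing.assert_allclose(il.holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_never_below_raw_never_above_one(self, rng):
        p = rng.uniform(0.0, 1.0, size=12)
        adj = il.holm_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            il.holm_adjust([0.5, 1.2])


class TestBestFitGradient:
    positions = np.arange(8) / 7.0

    def test_exact_line_selected(self):
        kind, coeffs = best_fit_gradient(self.positions, 2.0 * self.positions + 50.0)
        assert kind == "linear"
        np.testing.assert_allclose(coeffs, [2.0, 50.0], atol=1e-8)

    def test_exact_parabola_selected(self):
        y = 80.0 - 120.0 * (self.positions - 0.5) ** 2
        kind, coeffs = best_fit_gradient(self.positions, y)
        assert kind == "quadratic"
        np.testing.assert_allclose(coeffs, [-120.0, 120.0, 50.0], atol=1e-6)

    def test_constant_selected_for_flat_curve(self):
        kind, _ = best_fit_gradient(self.positions, np.full(8, 50.0))
        assert kind == "constant"

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            best_fit_gradient([0.0, 0.5, 1.0], [50.0, 60.0, 55.0])


class TestSummarizeCurve:
    def make_observations(self, red_yellow, values_by_stim):
        rows = []
        for stim, vals in values_by_stim.items():
            for chick, v in enumerate(vals):
                rows.append({"chick_id": f"c{chick}", "stimulus": stim, "pref": v})
        return pd.DataFrame(rows)

    def test_mean_and_sem(self, red_yellow, rng):
        values = {s: [40.0, 60.0] for s in red_yellow.names}
        values["Red1"] = [50.0 + e for e in (-1.0, 1.0)]
        obs = self.make_observations(red_yellow, values)
        curve = il.summarize_curve(obs, [70.0, 72.0], red_yellow)
        row = curve.table.set_index("stimulus").loc["Red2"]
        assert row["mean"] == 50.0
        assert row["sem"] == pytest.approx(10.0)
        assert curve.rehearsal_mean == pytest.approx(71.0)
        assert np.all(curve.table["p_holm"] >= curve.table["p_raw"])

    def test_single_chick_rejected(self, red_yellow):
        values = {s: [40.0, 60.0] for s in red_yellow.names}
        values["Red2"] = [55.0]
        obs = self.make_observations(red_yellow, values)
        with pytest.raises(ValueError, match="Red2"):
            il.summarize_curve(obs, [70.0], red_yellow)


class TestCompareToModel:
    def make_curve(self, red_yellow, means):
        rng = np.random.default_rng(0)
        rows = []
        for stim, m in zip(red_yellow.names, means):
            for chick in range(3):
                rows.append({"chick_id": f"c{chick}", "stimulus": stim,
                             "pref": m + [-2.0, 0.0, 2.0][chick]})
        obs = pd.DataFrame(rows)
        return il.summarize_curve(obs, [70.0, 72.0], red_yellow)

    def test_perfect_and_null(self, red_yellow):
        means = np.linspace(52.0, 73.0, 8)
        curve = self.make_curve(red_yellow, means)
        assert il.compare_to_model(curve, means) == pytest.approx(1.0)
        assert il.compare_to_model(curve, np.full(8, means.mean())) == pytest.approx(0.0)

    def test_worked_triple_matches_r_squared(self):
        assert il.r_squared(np.array([1.0, 2.0, 4.0]), np.array([1.0, 2.0, 3.0])) == 0.5


class TestScoreTrials:
    def test_zone_times_and_pref(self):
        # 6 frames familiar side, 2 center, 2 unfamiliar at 10 fps, left familiar
        xs = [5.0] * 6 + [45.0] * 2 + [85.0] * 2
        frames = make_frames(xs)
        trials = pd.DataFrame(
            [{"trial_id": "t0", "chick_id": "c0", "phase": "test", "familiar": "Red1",
              "test": "Yellow1", "side_familiar": "left"}]
        )
        scored, retained = il.score_trials(frames, trials)
        assert retained == 1.0
        row = scored.iloc[0]
        assert row["time_familiar_s"] == pytest.approx(0.6)
        assert row["time_unfamiliar_s"] == pytest.approx(0.2)
        assert row["pref"] == pytest.approx(75.0)

    def test_all_frames_filtered_trial_excluded(self):
        frames = make_frames([5.0] * 4, likelihoods=[0.1] * 4)
        trials = pd.DataFrame(
            [{"trial_id": "t0", "chick_id": "c0", "phase": "test", "familiar": "Red1",
              "test": "Yellow1", "side_familiar": "left"}]
        )
        scored, retained = il.score_trials(frames, trials)
        assert retained == 0.0
        assert np.isnan(scored.iloc[0]["pref"])
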