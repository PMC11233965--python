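import math

import numpy as np
import pandas as pd
import pytest

import imprintlab as il
from imprintlab.synth import (
    PREDISPOSITION_STIMULUS_S,
    PREDISPOSITION_TRIALS,
    TRIAL_STIMULUS_S,
)


class TestMakeSchedule:
    def test_short_imprinting_counts(self, red_yellow):
        spec = il.DesignSpec("short_imprinting", 2, red_yellow, imprint="Red1", seed=1)
        sched = il.make_schedule(spec)
        one = sched[sched["chick_id"] == "c000"]
        assert (one["phase"] == "imprinting").sum() == 80   # 8 sessions x 10 trials
        assert (one["phase"] == "rehearsal").sum() == 16    # 8 sessions x 2
        assert (one["phase"] == "test").sum() == 64         # 8 sessions x 8
        assert (one["duration_s"] == TRIAL_STIMULUS_S).all()

    def test_long_imprinting_has_five_days(self, red_yellow):
        spec = il.DesignSpec("long_imprinting", 1, red_yellow, imprint="Yellow1", seed=1)
        sched = il.make_schedule(spec)
        assert (sched["phase"] == "imprinting").sum() == 5 * 80

    def test_each_test_stimulus_once_per_session(self, red_yellow):
        spec = il.DesignSpec("short_imprinting", 3, red_yellow, imprint="Red1", seed=7)
        sched = il.make_schedule(spec)
        tests = sched[sched["phase"] == "test"]
        for (_, _), grp in tests.groupby(["chick_id", "session"]):
            assert sorted(grp["test"]) == sorted(red_yellow.names)

    def test_predisposition_schedule(self, red_yellow):
        spec = il.DesignSpec("predisposition", 4, red_yellow, pair=("Red1", "Yellow1"), seed=1)
        sched = il.make_schedule(spec)
        one = sched[sched["chick_id"] == "c001"]
        assert len(one) == PREDISPOSITION_TRIALS
        assert one["duration_s"].sum() == PREDISPOSITION_TRIALS * PREDISPOSITION_STIMULUS_S == 7200.0
        assert (one["side_familiar"] == "left").sum() == 3  # counterbalanced 3/3

    def test_determinism_under_seed(self, red_yellow):
        spec = il.DesignSpec("short_imprinting", 2, red_yellow, imprint="Red1", seed=11)
        a = il.make_schedule(spec)
        b = il.make_schedule(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_wrong_continuum_size_rejected(self):
        small = il.build_continuum(["A", "B", "C"])
        with pytest.raises(ValueError):
            il.DesignSpec("short_imprinting", 1, small, imprint="A")


class TestSimulateTrialTimes:
    def trial(self, **kw):
        base = dict(trial_id="t0", chick_id="c0", phase="test", familiar="Red1",
                    test="Yellow1", side_familiar="left", session=0,
                    duration_s=600.0, seed=0)
        base.update(kw)
        return base

    def test_deterministic_mode_matches_choice_probability(self, init_prefs):
        truth = il.GroundTruth(prefs=init_prefs, concentration=math.inf)
        out = il.simulate_trial_times(self.trial(), truth, np.random.default_rng(0))
        pref = 100.0 * out["time_familiar_s"] / (out["time_familiar_s"] + out["time_unfamiliar_s"])
        expected = 100.0 * il.choice_probability(
            init_prefs.value_of("Red1"), init_prefs.value_of("Yellow1")
        )
        assert pref == pytest.approx(expected, abs=1e-9)

    def test_equal_preferences_give_chance(self, init_prefs):
        truth = il.GroundTruth(prefs=init_prefs, concentration=math.inf)
        out = il.simulate_trial_times(self.trial(test="Orange"), truth, np.random.default_rng(0))
        assert out["time_familiar_s"] == pytest.approx(out["time_unfamiliar_s"])

    def test_mean_converges_to_choice_probability(self, red_yellow):
        """10^4 Beta draws at choice 0.649: mean index within ±1 of 64.9."""
        values = np.ones(8)
        values[7] = 0.351 / 0.649
        truth = il.GroundTruth(prefs=il.PreferenceCurve(red_yellow, values))
        rng = np.random.default_rng(42)
        prefs = []
        for _ in range(10_000):
            out = il.simulate_trial_times(self.trial(), truth, rng)
            prefs.append(100.0 * out["time_familiar_s"]
                         / (out["time_familiar_s"] + out["time_unfamiliar_s"]))
        assert np.mean(prefs) == pytest.approx(64.9, abs=1.0)

    def test_center_time_fraction(self, init_prefs):
        truth = il.GroundTruth(prefs=init_prefs, center_fraction=0.25)
        out = il.simulate_trial_times(self.trial(), truth, np.random.default_rng(0))
        assert out["time_center_s"] == pytest.approx(150.0)


class TestSimulateFrames:
    def trial_with_times(self, tf=300.0, tc=100.0, tu=200.0, side="left"):
        return dict(trial_id="t0", chick_id="c0", phase="test", familiar="Red1",
                    test="Yellow1", side_familiar=side, session=0, duration_s=tf + tc + tu,
                    seed=0, time_familiar_s=tf, time_center_s=tc, time_unfamiliar_s=tu)

    def test_frame_count_and_dwell_recovery(self):
        trial = self.trial_with_times(300.0, 200.0, 100.0)
        frames = il.simulate_frames(trial, fps=10.0, rng=np.random.default_rng(5))
        assert len(frames) == 6000
        times = {}
        arena = il.ArenaConfig()
        zones = np.array([il.assign_zone(x, arena, "left") for x in frames["x_cm"]])
        for z in ("familiar", "center", "unfamiliar"):
            times[z] = np.sum(zones == z) * 0.1
        assert times["familiar"] == pytest.approx(300.0, abs=0.1)
        assert times["center"] == pytest.approx(200.0, abs=0.1)
        assert times["unfamiliar"] == pytest.approx(100.0, abs=0.1)

    def test_subthreshold_fraction(self, red_yellow):
        truth = il.GroundTruth(
            prefs=il.PreferenceCurve(red_yellow, np.ones(8)), subthreshold_fraction=0.02
        )
        trial = self.trial_with_times(500.0, 200.0, 300.0)
        frames = il.simulate_frames(trial, fps=10.0, truth=truth,
                                    rng=np.random.default_rng(9))
        _, retained = il.filter_frames(frames)
        assert retained == pytest.approx(0.98, abs=0.005)

    def test_frames_inside_arena(self):
        arena = il.ArenaConfig()
        frames = il.simulate_frames(self.trial_with_times(side="right"), arena=arena,
                                    fps=10.0, rng=np.random.default_rng(2))
        assert frames["x_cm"].between(0.0, arena.length_cm).all()
        assert frames["y_cm"].between(0.0, arena.width_cm).all()

    def test_bad_fps(self):
        with pytest.raises(ValueError):
            il.simulate_frames(self.trial_with_times(), fps=0.0)


class TestSpectraLibrary:
    def test_empty(self):
        assert il.generate_spectra_library(0) == []

    def test_determinism(self):
        a = il.generate_spectra_library(20, 0.2, seed=3)
        b = il.generate_spectra_library(20, 0.2, seed=3)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.values, sb.values)

    def test_red_fraction_classified_through_colorimetry(self, receptors):
        """The colorimetry + categorical-binning chain recovers the seeded
        fraction of long-wavelength reflectors."""
        spectra = il.generate_spectra_library(1000, red_fraction=0.1, seed=13)
        cats = [il.dominant_cone_category(il.catches_for_spectrum(s, receptors))
                for s in spectra]
        frac_l = np.mean([c == "l" for c in cats])
        assert frac_l == pytest.approx(0.1, abs=0.02)

    def test_nonnegative_smooth(self):
        for spec in il.generate_spectra_library(10, 0.5, seed=1):
            assert np.all(spec.values >= 0.0)


class TestRecoveryHarness:
    def test_deterministic_mode_exact(self, red_yellow, init_prefs):
        truth = il.GroundTruth(prefs=init_prefs, concentration=math.inf)
        spec = il.DesignSpec("predisposition", 2, red_yellow, pair=("Red1", "Yellow1"), seed=3)
        report = il.recovery_harness(spec, truth)
        assert report["abs_error_choice"] == pytest.approx(0.0, abs=1e-12)

    def test_choice_probability_recovery(self, red_yellow, init_prefs):
        truth = il.GroundTruth(prefs=init_prefs)
        spec = il.DesignSpec("predisposition", 48, red_yellow, pair=("Red1", "Yellow1"), seed=21)
        report = il.recovery_harness(spec, truth)
        assert report["abs_error_choice"] <= 0.03

    def test_readout_recovery(self, red_yellow, init_prefs):
        truth = il.GroundTruth(prefs=init_prefs)
        spec = il.DesignSpec("long_imprinting", 48, red_yellow, imprint="Red1", seed=21)
        report = il.recovery_harness(spec, truth, true_readout=300)
        assert report["abs_error_readout"] <= 20
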