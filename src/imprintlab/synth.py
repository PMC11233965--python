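"""Seeded synthetic data emulating the controlled-rearing study designs.

Every other module is testable without downloading the deposited raw data
because this module generates trial schedules, zone-time allocations,
tracking frames and spectra libraries with known ground truth, fully
deterministic under a seed.

Schedules mirror the study procedure exactly:

* imprinting day — 8 sessions x 10 trials of 10 min stimulus + 2 min blank
  (one day for the short design, five for the long);
* generalization test day — 8 sessions of 2 rehearsal trials (familiar
  stimulus alone) followed by 8 test trials, each of the eight test
  stimuli exactly once per session;
* predisposition test — 6 double-choice trials of 20 min + 2 min blank
  (120 min of stimulus time), sides counterbalanced 3/3.

Behaviour follows the ratio choice rule on a ground-truth preference
curve: the familiar-side share of stimulus-zone time is Beta-distributed
with mean equal to the true choice probability and a configurable
concentration (default 10, giving between-trial scatter comparable to the
reported SEMs); a fixed fraction of trial time is spent in the center
zone.  Tracking frames realize the zone times as a reflected random walk
inside the 90 x 60 cm arena, with a controllable fraction of frames
receiving sub-threshold tracking likelihood to exercise the frame filter.

Spectra libraries are smooth nonnegative curves on 300-700 nm; a seeded
fraction are "red" (reflectance concentrated above ~580 nm, the rising
long-wavelength shape characteristic of phaeomelanin), the rest carry a
single bump at shorter wavelengths or are broadband.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import ArenaConfig, score_trials
from .colorspace import Spectrum
from .continuum import PreferenceCurve, StimulusContinuum, choice_probability
from .dynamics import (
    SimulationResult,
    UpdateParams,
    fit_readout,
    predict_generalization,
    simulate_imprinting,
)

__all__ = [
    "DesignSpec",
    "GroundTruth",
    "make_schedule",
    "simulate_trial_times",
    "simulate_times",
    "simulate_frames",
    "generate_spectra_library",
    "recovery_harness",
]

DESIGNS = ("short_imprinting", "long_imprinting", "predisposition")

# procedure constants
IMPRINT_SESSIONS_PER_DAY = 8
IMPRINT_TRIALS_PER_SESSION = 10
TRIAL_STIMULUS_S = 600.0  # 10 min of stimulus presentation
TEST_SESSIONS = 8
REHEARSAL_TRIALS_PER_SESSION = 2
TEST_TRIALS_PER_SESSION = 8
PREDISPOSITION_TRIALS = 6
PREDISPOSITION_STIMULUS_S = 1200.0  # 20 min per double-choice trial


@dataclass(frozen=True)
class DesignSpec:
    """One experimental design for one cohort of chicks."""

    design: str
    n_chicks: int
    continuum: StimulusContinuum
    imprint: str | None = None          # generalization designs
    pair: tuple[str, str] | None = None  # predisposition design
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}, got {self.design!r}")
        if self.n_chicks < 1:
            raise ValueError("n_chicks must be >= 1")
        if self.design == "predisposition":
            if self.pair is None:
                raise ValueError("predisposition design needs a stimulus pair")
            for name in self.pair:
                self.continuum.index_of(name)
        else:
            if self.imprint is None:
                raise ValueError("generalization designs need an imprint stimulus")
            self.continuum.index_of(self.imprint)
            if len(self.continuum) != TEST_TRIALS_PER_SESSION:
                raise ValueError(
                    "generalization designs need a continuum of "
                    f"{TEST_TRIALS_PER_SESSION} test stimuli, got {len(self.continuum)}"
                )

    @property
    def imprint_days(self) -> int:
        return {"short_imprinting": 1, "long_imprinting": 5}.get(self.design, 0)


@dataclass
class GroundTruth:
    """Generating preferences and noise levels of a synthetic cohort.

    prefs : true preference curve used for choice probabilities (the
        predisposition curve, or the post-imprinting curve at test).
    concentration : Beta concentration of the familiar-side share of
        stimulus-zone time (``math.inf`` = deterministic).
    center_fraction : fraction of trial time spent in the center zone.
    subthreshold_fraction : fraction of frames with tracking likelihood
        below 0.9.
    rehearsal_choice : familiar-vs-blank choice probability in rehearsal
        and imprinting trials (observed baselines sit near 68-73%).
    """

    prefs: PreferenceCurve
    concentration: float = 10.0
    center_fraction: float = 0.10
    subthreshold_fraction: float = 0.02
    rehearsal_choice: float = 0.72

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError("concentration must be positive")
        for name in ("center_fraction", "subthreshold_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0.0 < self.rehearsal_choice < 1.0):
            raise ValueError("rehearsal_choice must lie in (0, 1)")


def _alternating_sides(n: int, start: int = 0) -> list[str]:
    return ["left" if (start + k) % 2 == 0 else "right" for k in range(n)]


def make_schedule(spec: DesignSpec) -> pd.DataFrame:
    """Ordered trial table for every chick of a design (times not yet set).

    Columns: ``trial_id, chick_id, phase, familiar, test, side_familiar,
    session, duration_s, seed``.  Test-stimulus order within a session is a
    seeded permutation; sides alternate so they are counterbalanced.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []

    def add(chick: int, phase: str, familiar: str, test: str | None, side: str,
            session: int, duration: float) -> None:
        rows.append(
            {
                "trial_id": f"c{chick:03d}_t{len(rows):04d}",
                "chick_id": f"c{chick:03d}",
                "phase": phase,
                "familiar": familiar,
                "test": test,
                "side_familiar": side,
                "session": session,
                "duration_s": duration,
                "seed": spec.seed,
            }
        )

    for chick in range(spec.n_chicks):
        if spec.design == "predisposition":
            a, b = spec.pair
            sides = _alternating_sides(PREDISPOSITION_TRIALS, start=chick)
            for k in range(PREDISPOSITION_TRIALS):
                add(chick, "predisposition", a, b, sides[k], 0, PREDISPOSITION_STIMULUS_S)
            continue
        session = 0
        for _day in range(spec.imprint_days):
            for _s in range(IMPRINT_SESSIONS_PER_DAY):
                sides = _alternating_sides(IMPRINT_TRIALS_PER_SESSION, start=chick + session)
                for k in range(IMPRINT_TRIALS_PER_SESSION):
                    add(chick, "imprinting", spec.imprint, None, sides[k], session,
                        TRIAL_STIMULUS_S)
                session += 1
        for _s in range(TEST_SESSIONS):
            sides = _alternating_sides(
                REHEARSAL_TRIALS_PER_SESSION + TEST_TRIALS_PER_SESSION, start=chick + session
            )
            for k in range(REHEARSAL_TRIALS_PER_SESSION):
                add(chick, "rehearsal", spec.imprint, None, sides[k], session,
                    TRIAL_STIMULUS_S)
            order = rng.permutation(spec.continuum.names)
            for k, test_stim in enumerate(order):
                add(chick, "test", spec.imprint, str(test_stim),
                    sides[REHEARSAL_TRIALS_PER_SESSION + k], session, TRIAL_STIMULUS_S)
            session += 1
    return pd.DataFrame(rows)


def _true_choice(phase: str, familiar: str, test: str | None, truth: GroundTruth) -> float:
    if phase in ("imprinting", "rehearsal"):
        return truth.rehearsal_choice
    if test is None:
        raise ValueError(f"{phase} trial without a comparison stimulus")
    return choice_probability(truth.prefs.value_of(familiar), truth.prefs.value_of(test))


def simulate_trial_times(trial: dict | pd.Series, truth: GroundTruth,
                         rng: np.random.Generator) -> dict:
    """Draw zone times for one scheduled trial.

    The familiar-side share of stimulus-zone time is Beta(c·p, c·(1−p))
    with p the true choice probability; ``concentration=inf`` collapses to
    the deterministic share p, so the preference index equals 100·p.
    """
    trial = dict(trial)
    p = _true_choice(trial["phase"], trial["familiar"], trial["test"], truth)
    if math.isinf(truth.concentration):
        share = p
    else:
        c = truth.concentration
        share = float(rng.beta(c * p, c * (1.0 - p)))
    duration = float(trial["duration_s"])
    center = truth.center_fraction * duration
    stimulus_time = duration - center
    trial["time_familiar_s"] = share * stimulus_time
    trial["time_unfamiliar_s"] = (1.0 - share) * stimulus_time
    trial["time_center_s"] = center
    return trial


def simulate_times(schedule: pd.DataFrame, truth: GroundTruth, seed: int) -> pd.DataFrame:
    """Zone times for every trial of a schedule (seeded)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame([simulate_trial_times(row, truth, rng)
                         for row in schedule.to_dict("records")])


def _walk_within(rng: np.random.Generator, n: int, low: float, high: float,
                 step_sd: float = 2.0) -> np.ndarray:
    """Reflected Gaussian random walk strictly inside (low, high)."""
    span = high - low
    x = np.empty(n)
    pos = low + span * rng.uniform(0.3, 0.7)
    steps = rng.normal(0.0, step_sd, size=n)
    for k in range(n):
        pos = pos + steps[k]
        # reflect at the walls until inside
        while pos < low or pos > high:
            if pos < low:
                pos = 2 * low - pos
            else:
                pos = 2 * high - pos
        x[k] = pos
    return x


def simulate_frames(
    trial: dict | pd.Series,
    arena: ArenaConfig | None = None,
    fps: float = 10.0,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Tracking frames realizing a trial's zone times.

    Frame counts per zone are the zone times rounded to whole frames
    (total preserved), so zone dwell recovered through ``assign_zones`` at
    the same frame interval matches the requested times to within one
    frame interval.  Positions follow a reflected random walk inside each
    zone; a ``truth.subthreshold_fraction`` of frames get likelihood below
    0.9, the rest in [0.9, 1].
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if arena is None:
        arena = ArenaConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    sub_fraction = 0.02 if truth is None else truth.subthreshold_fraction
    trial = dict(trial)
    times = np.array([trial["time_familiar_s"], trial["time_center_s"],
                      trial["time_unfamiliar_s"]], dtype=float)
    n_total = int(round(times.sum() * fps))
    counts = np.floor(times * fps).astype(int)
    remainder = times * fps - counts
    while counts.sum() < n_total:  # largest remainders absorb the rounding
        k = int(np.argmax(remainder))
        counts[k] += 1
        remainder[k] = -1.0

    eps = 0.5  # keep walks clear of the inclusive zone boundary
    depth, length = arena.zone_depth_cm, arena.length_cm
    if trial["side_familiar"] == "left":
        ranges = {"familiar": (0.0, depth - eps), "unfamiliar": (length - depth + eps, length)}
    else:
        ranges = {"familiar": (length - depth + eps, length), "unfamiliar": (0.0, depth - eps)}
    ranges["center"] = (depth + eps, length - depth - eps)

    xs = []
    for zone, n in zip(("familiar", "center", "unfamiliar"), counts):
        if n > 0:
            xs.append(_walk_within(rng, int(n), *ranges[zone]))
    x = np.concatenate(xs) if xs else np.empty(0)
    y = _walk_within(rng, n_total, 0.0, arena.width_cm)
    likelihood = np.where(
        rng.random(n_total) < sub_fraction,
        rng.uniform(0.0, 0.9, size=n_total),
        rng.uniform(0.9, 1.0, size=n_total),
    )
    return pd.DataFrame(
        {
            "trial_id": trial["trial_id"],
            "time_s": np.arange(n_total) / fps,
            "x_cm": np.round(x, 3),
            "y_cm": np.round(y, 3),
            "likelihood": np.round(likelihood, 4),
        }
    )


def generate_spectra_library(
    n: int,
    red_fraction: float = 0.1,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
    return_labels: bool = False,
):
    """Smooth synthetic reflectance library with a known "red" fraction.

    ``round(n * red_fraction)`` spectra are long-wavelength reflectors
    (sigmoidal rise around 600 nm); the remainder carry one Gaussian bump
    centred in 330-520 nm over a low broadband baseline, emulating the
    unsaturated greens, browns and greys that dominate natural objects.
    Deterministic under the seed.  With ``return_labels=True`` also
    returns the boolean red mask.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not (0.0 <= red_fraction <= 1.0):
        raise ValueError("red_fraction must lie in [0, 1]")
    if wavelengths is None:
        wavelengths = np.arange(300.0, 701.0, 5.0)
    rng = np.random.default_rng(seed)
    n_red = int(round(n * red_fraction))
    is_red = np.zeros(n, dtype=bool)
    if n:
        is_red[rng.choice(n, size=n_red, replace=False)] = True
    spectra = []
    for red in is_red:
        if red:
            midpoint = rng.uniform(585.0, 615.0)
            steepness = rng.uniform(15.0, 30.0)
            amplitude = rng.uniform(0.4, 0.9)
            vals = amplitude / (1.0 + np.exp(-(wavelengths - midpoint) / steepness))
            vals += rng.uniform(0.0, 0.03)
        else:
            center = rng.uniform(330.0, 520.0)
            width = rng.uniform(30.0, 80.0)
            amplitude = rng.uniform(0.2, 0.6)
            baseline = rng.uniform(0.02, 0.15)
            vals = baseline + amplitude * np.exp(
                -((wavelengths - center) ** 2) / (2.0 * width**2)
            )
        spectra.append(Spectrum(wavelengths.copy(), vals))
    if return_labels:
        return spectra, is_red
    return spectra


def recovery_harness(
    spec: DesignSpec,
    truth: GroundTruth,
    params: UpdateParams | None = None,
    true_readout: int | None = None,
) -> dict:
    """End-to-end consistency loop: simulate, analyse, recover the truth.

    * predisposition design — simulate the 6-trial double-choice schedule,
      average preference indices per chick and report the absolute error
      of the recovered choice probability against the ratio-rule truth;
    * generalization designs — take the ground-truth test-phase curve from
      the imprinting dynamics at ``true_readout`` (defaults to the
      design's standard read-out), simulate the test phase, aggregate
      per-stimulus means, and report the read-out step recovered by
      :func:`~imprintlab.dynamics.fit_readout`.
    """
    if params is None:
        params = UpdateParams()
    report: dict = {"design": spec.design, "seed": spec.seed, "n_chicks": spec.n_chicks}
    if spec.design == "predisposition":
        schedule = make_schedule(spec)
        scored = simulate_times(schedule, truth, seed=spec.seed + 1)
        scored["pref"] = 100.0 * scored["time_familiar_s"] / (
            scored["time_familiar_s"] + scored["time_unfamiliar_s"]
        )
        per_chick = scored.groupby("chick_id")["pref"].mean()
        recovered = float(per_chick.mean()) / 100.0
        a, b = spec.pair
        true_p = choice_probability(truth.prefs.value_of(a), truth.prefs.value_of(b))
        report.update(
            recovered_choice=recovered,
            true_choice=true_p,
            abs_error_choice=abs(recovered - true_p),
        )
        return report

    sim = simulate_imprinting(truth.prefs, spec.continuum.index_of(spec.imprint), params)
    if true_readout is None:
        true_readout = (
            params.readout_short if spec.design == "short_imprinting" else params.readout_long
        )
    test_curve = PreferenceCurve(spec.continuum, sim.curve_at(true_readout))
    test_truth = GroundTruth(
        prefs=test_curve,
        concentration=truth.concentration,
        center_fraction=truth.center_fraction,
        subthreshold_fraction=truth.subthreshold_fraction,
        rehearsal_choice=truth.rehearsal_choice,
    )
    schedule = make_schedule(spec)
    test_phase = schedule[schedule["phase"] == "test"]
    scored = simulate_times(test_phase, test_truth, seed=spec.seed + 1)
    scored["pref"] = 100.0 * scored["time_familiar_s"] / (
        scored["time_familiar_s"] + scored["time_unfamiliar_s"]
    )
    per_stim = (
        scored.groupby(["chick_id", "test"])["pref"].mean().groupby("test").mean()
    )
    observed = per_stim.reindex(spec.continuum.names).to_numpy(float)
    t_best, r2 = fit_readout(sim, observed)
    report.update(
        true_readout=int(true_readout),
        recovered_readout=int(t_best),
        abs_error_readout=abs(int(t_best) - int(true_readout)),
        r_squared=float(r2),
        observed_curve=observed.tolist(),
    )
    return report
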