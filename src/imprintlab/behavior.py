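"""From tracking frames to generalization curves.

The behavioural read-out: per-frame centroid positions from markerless
tracking are filtered by tracking likelihood (>= 0.9 kept), assigned to
arena zones (within 20 cm of either monitor, or center), accumulated into
per-trial zone times, and turned into the familiar-preference index

    pref_familiar = 100 · t_familiar / (t_familiar + t_unfamiliar)

(50 = no preference).  Per-chick indices aggregate to a generalization
curve (mean ± SEM per test stimulus), tested against chance with
one-sample t-tests under Bonferroni–Holm correction, summarized by a
best-fit polynomial gradient, and compared with model predictions by R².

Tables move through the pipeline as pandas DataFrames:

frames : ``trial_id, time_s, x_cm, y_cm, likelihood``
trials : ``trial_id, chick_id, phase, familiar, test, side_familiar``
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .continuum import StimulusContinuum
from .dynamics import r_squared

__all__ = [
    "ArenaConfig",
    "GeneralizationCurve",
    "filter_frames",
    "assign_zone",
    "assign_zones",
    "preference_index",
    "trial_zone_times",
    "score_trials",
    "summarize_curve",
    "one_sample_t",
    "holm_adjust",
    "best_fit_gradient",
    "compare_to_model",
]

ZONES = ("familiar", "center", "unfamiliar")
SIDES = ("left", "right")


@dataclass(frozen=True)
class ArenaConfig:
    """Rectangular arena with a monitor at each end of the long axis.

    Defaults: 90 x 60 cm, choice zones within 20 cm of each monitor.
    ``monitor_axis`` names the frame column that runs between monitors.
    """

    length_cm: float = 90.0
    width_cm: float = 60.0
    zone_depth_cm: float = 20.0
    monitor_axis: str = "x_cm"

    def __post_init__(self) -> None:
        if not 2 * self.zone_depth_cm < self.length_cm:
            raise ValueError("zone depth too large: no center region remains")


def filter_frames(
    frames: pd.DataFrame, min_likelihood: float = 0.9
) -> tuple[pd.DataFrame, float]:
    """Keep frames with tracking likelihood >= threshold (inclusive).

    Returns the retained frames and the retained fraction.
    """
    if len(frames) == 0:
        raise ValueError("no frames to filter")
    lik = frames["likelihood"].to_numpy(float)
    if np.any((lik < 0) | (lik > 1)):
        raise ValueError("likelihood values must lie in [0, 1]")
    keep = lik >= min_likelihood
    return frames.loc[keep], float(keep.mean())


def assign_zones(coords, arena: ArenaConfig, side_of_familiar: str) -> np.ndarray:
    """Vectorized zone labels for positions along the monitor axis.

    A coordinate exactly on the 20-cm line belongs to the monitor zone
    ("within 20 cm" read as inclusive).
    """
    if side_of_familiar not in SIDES:
        raise ValueError(f"side_of_familiar must be one of {SIDES}, got {side_of_familiar!r}")
    coords = np.asarray(coords, dtype=float)
    near_low = coords <= arena.zone_depth_cm
    near_high = coords >= arena.length_cm - arena.zone_depth_cm
    low_zone, high_zone = (
        ("familiar", "unfamiliar") if side_of_familiar == "left" else ("unfamiliar", "familiar")
    )
    out = np.where(near_low, low_zone, np.where(near_high, high_zone, "center"))
    return out


def assign_zone(x_cm: float, arena: ArenaConfig, side_of_familiar: str) -> str:
    """Zone of a single frame: familiar, center, or unfamiliar."""
    return str(assign_zones([x_cm], arena, side_of_familiar)[0])


def preference_index(time_familiar_s: float, time_unfamiliar_s: float) -> float:
    """Familiar-preference percentage; NaN when no stimulus-zone time.

    A trial with zero time in both choice zones carries no information and
    is flagged excluded by returning NaN.
    """
    if time_familiar_s < 0 or time_unfamiliar_s < 0:
        raise ValueError("zone times must be nonnegative")
    total = time_familiar_s + time_unfamiliar_s
    if total == 0:
        return float("nan")
    return 100.0 * time_familiar_s / total


def trial_zone_times(
    trial_frames: pd.DataFrame,
    arena: ArenaConfig,
    side_of_familiar: str,
    frame_interval_s: float,
) -> dict[str, float]:
    """Dwell time per zone, one frame interval per retained frame."""
    zones = assign_zones(trial_frames[arena.monitor_axis].to_numpy(), arena, side_of_familiar)
    return {z: float(np.sum(zones == z)) * frame_interval_s for z in ZONES}


def _infer_frame_interval(time_s: np.ndarray) -> float:
    diffs = np.diff(np.sort(np.unique(time_s)))
    diffs = diffs[diffs > 0]
    if diffs.size == 0:
        raise ValueError("cannot infer frame interval from a single timestamp")
    return float(np.median(diffs))


def score_trials(
    frames: pd.DataFrame,
    trials: pd.DataFrame,
    arena: ArenaConfig | None = None,
    min_likelihood: float = 0.9,
) -> tuple[pd.DataFrame, float]:
    """Per-trial zone times and preference indices.

    The frame interval is inferred per trial from the raw (pre-filter)
    timestamps, so dropped frames do not stretch the dwell of survivors.
    Returns (trial table with times and ``pref`` column, retained fraction).
    """
    if arena is None:
        arena = ArenaConfig()
    kept, retained = filter_frames(frames, min_likelihood)
    by_trial_raw = dict(tuple(frames.groupby("trial_id")))
    by_trial = dict(tuple(kept.groupby("trial_id")))
    records = []
    for trial in trials.itertuples(index=False):
        row = trial._asdict()
        tf = by_trial.get(trial.trial_id)
        if tf is None or len(tf) == 0:
            row.update(time_familiar_s=0.0, time_center_s=0.0, time_unfamiliar_s=0.0,
                       pref=float("nan"))
            records.append(row)
            continue
        dt = _infer_frame_interval(by_trial_raw[trial.trial_id]["time_s"].to_numpy(float))
        times = trial_zone_times(tf, arena, trial.side_familiar, dt)
        row.update(
            time_familiar_s=times["familiar"],
            time_center_s=times["center"],
            time_unfamiliar_s=times["unfamiliar"],
            pref=preference_index(times["familiar"], times["unfamiliar"]),
        )
        records.append(row)
    return pd.DataFrame.from_records(records), retained


@dataclass
class GeneralizationCurve:
    """Mean ± SEM familiar preference per test stimulus, with statistics.

    ``table`` columns: stimulus, position, n, mean, sem, t, df, p_raw,
    p_holm.  ``gradient`` is (kind, coefficients) of the best polynomial
    fit of mean preference against stimulus position.
    """

    table: pd.DataFrame
    rehearsal_mean: float
    gradient_kind: str
    gradient_coefficients: np.ndarray

    @property
    def means(self) -> np.ndarray:
        return self.table["mean"].to_numpy(float)


def one_sample_t(values, mu: float = 50.0) -> tuple[float, int, float]:
    """One-sample two-sided t-test of the mean against ``mu``.

    Returns (t, df, p).  Errors on n < 2 or zero sample variance.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("one-sample t-test needs n >= 2")
    if np.std(values, ddof=1) == 0:
        raise ValueError("zero sample variance: t statistic undefined")
    res = stats.ttest_1samp(values, popmean=mu)
    return float(res.statistic), int(values.size - 1), float(res.pvalue)


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni–Holm step-down adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _aicc(rss: float, n: int, n_params: int, scale: float) -> float:
    # k counts the residual variance as a fitted parameter
    k = n_params + 1
    if n - k - 1 <= 0:
        return np.inf
    floor = max(scale, 1.0) * 1e-12  # exact fits collapse to a common floor
    return n * np.log(max(rss, floor) / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


def best_fit_gradient(
    positions, means, criterion: str = "aicc"
) -> tuple[str, np.ndarray]:
    """Best polynomial gradient (constant / linear / quadratic) of a curve.

    Candidates are least-squares fits of degree 0, 1, 2 of mean preference
    against stimulus position, compared by a small-sample information
    criterion (AICc default; ``aic`` and ``adjr2`` available).  Ties go to
    the simpler model.  Returns (kind, coefficients highest degree first).
    """
    positions = np.asarray(positions, dtype=float)
    means = np.asarray(means, dtype=float)
    n = means.size
    if n < 4:
        raise ValueError("need at least 4 points to consider a quadratic gradient")
    kinds = {0: "constant", 1: "linear", 2: "quadratic"}
    scale = float(np.sum((means - means.mean()) ** 2))
    best = None
    for degree in (0, 1, 2):
        coeffs = np.polyfit(positions, means, degree)
        rss = float(np.sum((np.polyval(coeffs, positions) - means) ** 2))
        if criterion == "aicc":
            score = _aicc(rss, n, degree + 1, scale)
        elif criterion == "aic":
            score = n * np.log(max(rss, max(scale, 1.0) * 1e-12) / n) + 2 * (degree + 2)
        elif criterion == "adjr2":
            if scale == 0:
                score = 0.0 if rss == 0 else np.inf
            else:
                score = -(1 - (rss / (n - degree - 1)) / (scale / (n - 1)))
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if best is None or score < best[0] - 1e-12:
            best = (score, kinds[degree], coeffs)
    return best[1], best[2]


def summarize_curve(
    observations: pd.DataFrame,
    rehearsal_indices,
    continuum: StimulusContinuum,
    mu: float = 50.0,
    criterion: str = "aicc",
) -> GeneralizationCurve:
    """Aggregate per-chick preference indices into a generalization curve.

    ``observations`` needs columns ``chick_id, stimulus, pref`` with one
    row per chick x test stimulus (pre-averaged across sessions).  Every
    stimulus must have n >= 2 chicks.
    """
    rows = []
    for stim in continuum.names:
        vals = observations.loc[observations["stimulus"] == stim, "pref"].dropna().to_numpy(float)
        if vals.size < 2:
            raise ValueError(f"stimulus {stim!r} has n={vals.size} < 2 chicks")
        t, df, p = one_sample_t(vals, mu=mu)
        rows.append(
            {
                "stimulus": stim,
                "position": continuum.positions[continuum.index_of(stim)],
                "n": vals.size,
                "mean": vals.mean(),
                "sem": np.std(vals, ddof=1) / np.sqrt(vals.size),
                "t": t,
                "df": df,
                "p_raw": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
    kind, coeffs = best_fit_gradient(table["position"], table["mean"], criterion=criterion)
    rehearsal = np.asarray(rehearsal_indices, dtype=float)
    rehearsal = rehearsal[~np.isnan(rehearsal)]
    return GeneralizationCurve(
        table=table,
        rehearsal_mean=float(rehearsal.mean()) if rehearsal.size else float("nan"),
        gradient_kind=kind,
        gradient_coefficients=coeffs,
    )


def compare_to_model(curve: GeneralizationCurve, predicted) -> float:
    """R² of model predictions against the curve's mean preferences."""
    return r_squared(np.asarray(predicted, dtype=float), curve.means)
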