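"""Imprinting dynamics: predispositions updated by experience.

The biased model treats a chick's colour predispositions as an initial
preference curve over the stimulus continuum and filial imprinting as a
deterministic, multiplicative update of that curve.  At each exposure step
the preference for every stimulus ``i`` is multiplied by ``1 + α·w_i``,
where the update weight ``w`` is a narrow Gaussian (width σ on the
normalized axis) centred on the presented stimulus with peak 1, and the
curve is then renormalized to its maximum.  Because the update is
multiplicative and the presented stimulus is fixed, preference *ratios*
have a closed form,

    pref_i,T / pref_j,T = (pref_i,0 / pref_j,0) · ((1+α·w_i)/(1+α·w_j))^T,

which the test suite uses as an independent oracle.

Defaults follow the study conditions: α = 0.01, σ = 0.2, 400 steps, with
read-outs at t = 100 (short, 1-day imprinting) and t = 300 (long, 5-day).
Predicted familiar-preference curves come from the ratio choice rule and
are affinely scaled about the 50% chance level to the maximum observed
preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .continuum import PreferenceCurve, StimulusContinuum, choice_probability

__all__ = [
    "UpdateParams",
    "SimulationResult",
    "PairwiseChoiceEstimate",
    "update_weight",
    "step",
    "simulate_imprinting",
    "estimate_initial_prefs",
    "predict_generalization",
    "r_squared",
    "fit_readout",
]


@dataclass(frozen=True)
class UpdateParams:
    """Learning parameters of the preference-update model.

    alpha : update rate (speed of learning), dimensionless.
    sigma : Gaussian update-weight width on the normalized stimulus axis.
    n_steps : number of update iterations.
    readout_short / readout_long : default read-out steps standing for the
        short (1-day) and long (5-day) imprinting exposures.
    """

    alpha: float = 0.01
    sigma: float = 0.2
    n_steps: int = 400
    readout_short: int = 100
    readout_long: int = 300

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not (0 < self.readout_short <= self.readout_long <= self.n_steps):
            raise ValueError(
                "need 0 < readout_short <= readout_long <= n_steps, got "
                f"{self.readout_short}, {self.readout_long}, {self.n_steps}"
            )


@dataclass
class SimulationResult:
    """Trajectory of a deterministic imprinting simulation.

    ``trajectory`` has shape (n_steps+1, n_stimuli); row 0 is the
    normalized initial curve and every row has maximum exactly 1.
    """

    continuum: StimulusContinuum
    imprint_index: int
    trajectory: np.ndarray
    params: UpdateParams

    def curve_at(self, t: int) -> np.ndarray:
        if not (0 <= t < self.trajectory.shape[0]):
            raise IndexError(
                f"time step {t} out of range 0..{self.trajectory.shape[0] - 1}"
            )
        return self.trajectory[t].copy()


@dataclass(frozen=True)
class PairwiseChoiceEstimate:
    """Mean proportion of choices of stimulus_a over stimulus_b."""

    stimulus_a: str
    stimulus_b: str
    mean_choice_a: float
    n: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.mean_choice_a < 1.0):
            raise ValueError(
                "mean_choice_a must lie strictly in (0, 1) for ratio inversion"
            )
        if self.n < 1:
            raise ValueError("n must be >= 1")


def update_weight(
    continuum: StimulusContinuum, presented_index: int, sigma: float
) -> np.ndarray:
    """Gaussian update weight per stimulus, peak 1 at the presented one."""
    n = len(continuum)
    if not (0 <= presented_index < n):
        raise IndexError(f"presented_index {presented_index} out of range for n={n}")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    d = continuum.positions - continuum.positions[presented_index]
    return np.exp(-(d**2) / (2.0 * sigma**2))


def step(pref: PreferenceCurve, w: np.ndarray, alpha: float) -> PreferenceCurve:
    """One multiplicative update followed by renormalization to the maximum."""
    w = np.asarray(w, dtype=float)
    if w.shape != pref.values.shape:
        raise ValueError(f"weight shape {w.shape} != preference shape {pref.values.shape}")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    updated = pref.values * (1.0 + alpha * w)
    return PreferenceCurve(pref.continuum, updated).normalize()


def simulate_imprinting(
    initial: PreferenceCurve, imprint_index: int, params: UpdateParams | None = None
) -> SimulationResult:
    """Iterate the update with a fixed presented stimulus; store every step.

    The simulation is fully deterministic.
    """
    if params is None:
        params = UpdateParams()
    w = update_weight(initial.continuum, imprint_index, params.sigma)
    curve = initial.normalize()
    traj = np.empty((params.n_steps + 1, len(initial.continuum)))
    traj[0] = curve.values
    for t in range(1, params.n_steps + 1):
        curve = step(curve, w, params.alpha)
        traj[t] = curve.values
    return SimulationResult(initial.continuum, imprint_index, traj, params)


def estimate_initial_prefs(
    choices: list[PairwiseChoiceEstimate],
    continuum: StimulusContinuum,
    anchor: str,
) -> PreferenceCurve:
    """Initial preference curve from predisposition double-choice tests.

    The ratio rule inverts exactly: a mean choice proportion ``c`` for A
    over B implies ``pref_A / pref_B = c / (1 - c)``.  The anchor stimulus
    is fixed at preference 1 and the measured ratios are propagated through
    the pair graph; stimuli never measured are filled by piecewise-linear
    interpolation of preference against position between the nearest
    measured stimuli (constant beyond the ends).
    """
    for name in [anchor] + [c.stimulus_a for c in choices] + [c.stimulus_b for c in choices]:
        continuum.index_of(name)  # raises on unknown stimulus

    # propagate ratios over the measured-pair graph from the anchor
    prefs: dict[str, float] = {anchor: 1.0}
    edges: dict[str, list[tuple[str, float]]] = {}
    for c in choices:
        ratio = c.mean_choice_a / (1.0 - c.mean_choice_a)  # pref_a / pref_b
        edges.setdefault(c.stimulus_a, []).append((c.stimulus_b, 1.0 / ratio))
        edges.setdefault(c.stimulus_b, []).append((c.stimulus_a, ratio))
    frontier = [anchor]
    while frontier:
        node = frontier.pop()
        for other, factor in edges.get(node, []):
            if other not in prefs:
                prefs[other] = prefs[node] * factor
                frontier.append(other)
    measured = set(edges) | {anchor}
    unreached = measured - set(prefs)
    if unreached:
        raise ValueError(
            f"measured stimuli not connected to anchor {anchor!r}: {sorted(unreached)}"
        )

    pos = continuum.positions
    known_idx = sorted(continuum.index_of(name) for name in prefs)
    known_pos = pos[known_idx]
    known_val = np.array([prefs[continuum.names[i]] for i in known_idx])
    values = np.interp(pos, known_pos, known_val)  # constant beyond the ends
    return PreferenceCurve(continuum, values)


def predict_generalization(
    sim: SimulationResult, t: int, max_observed: float | None = None
) -> np.ndarray:
    """Predicted familiar-preference percentage per test stimulus at step t.

    Raw prediction for test stimulus j is the ratio choice of the imprinted
    stimulus: ``100 · pref_imp / (pref_imp + pref_j)`` (50% when j is the
    imprinted stimulus itself).  With ``max_observed`` given (in (50, 100]),
    the curve is affinely rescaled about the 50% anchor so its largest
    deviation from chance maps to ``max_observed``; deviations below 50
    (novelty preference) keep their sign.  With ``max_observed=None`` the
    raw percentages are returned.
    """
    curve = sim.curve_at(t)
    p_imp = curve[sim.imprint_index]
    raw = 100.0 * p_imp / (p_imp + curve)
    if max_observed is None:
        return raw
    if not (50.0 < max_observed <= 100.0):
        raise ValueError("max_observed must lie in (50, 100]")
    dev = raw - 50.0
    extreme = np.abs(dev).max()
    if extreme == 0.0:
        return np.full_like(raw, 50.0)
    return 50.0 + dev * (max_observed - 50.0) / extreme


def r_squared(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (can be negative)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be 1-D arrays of equal length")
    if predicted.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values are all identical (zero total sum of squares)")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_readout(
    sim: SimulationResult,
    observed_curve: np.ndarray,
    t_grid: np.ndarray | list[int] | None = None,
    max_observed: float | None = None,
) -> tuple[int, float]:
    """Grid-search the read-out step best matching an observed curve.

    Returns ``(t_best, r_squared)``, ties broken toward the smallest t.
    ``max_observed`` defaults to the observed maximum.
    """
    observed_curve = np.asarray(observed_curve, dtype=float)
    if t_grid is None:
        t_grid = np.arange(0, sim.params.n_steps + 1)
    t_grid = np.asarray(t_grid, dtype=int)
    if t_grid.size == 0:
        raise ValueError("t_grid must be nonempty")
    if max_observed is None:
        max_observed = float(observed_curve.max())
    best_t, best_r2 = None, -np.inf
    for t in t_grid:
        r2 = r_squared(predict_generalization(sim, int(t), max_observed), observed_curve)
        if r2 > best_r2:
            best_t, best_r2 = int(t), r2
    return best_t, best_r2
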