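"""Unbiased generalization: the null model from the universal law.

Under Shepard's universal law of generalization, the probability that a
response learned to one stimulus transfers to another decays with the
perceptual distance between them — exponentially in the classical form, or
as a Gaussian in later variants. An animal with no colour biases that has
imprinted on one stimulus should therefore show a *symmetric, monotone*
generalization curve: chance preference (50%) when the familiar stimulus is
paired with itself, growing preference for the familiar stimulus as the
comparison colour gets more distant, and identical predictions for stimuli
equidistant on either side.

To turn similarity into a binary-choice prediction we use the same ratio
choice rule as the biased (imprinting-dynamics) model: the familiar
stimulus has value 1 and a comparison stimulus at distance ``d`` has value
``similarity(d)``, so the raw familiar preference is ``1/(1+similarity)``.
One choice mechanism across models keeps the comparison about the
preference structure, not the decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .continuum import StimulusContinuum

__all__ = ["UnbiasedModel", "similarity", "predict_unbiased_curve", "fit_kernel_scale"]

_KERNELS = ("exponential", "gaussian")


@dataclass(frozen=True)
class UnbiasedModel:
    """Generalization kernel: ``exponential`` exp(-d/λ) or ``gaussian``
    exp(-d²/(2τ²)), with positive scale (λ or τ)."""

    kernel: str = "exponential"
    scale: float = 0.3

    def __post_init__(self) -> None:
        if self.kernel not in _KERNELS:
            raise ValueError(f"kernel must be one of {_KERNELS}, got {self.kernel!r}")
        if not self.scale > 0:
            raise ValueError("kernel scale must be positive")


def similarity(d, model: UnbiasedModel):
    """Similarity in (0, 1] at perceptual distance ``d`` (scalar or array)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    if model.kernel == "exponential":
        out = np.exp(-d / model.scale)
    else:
        out = np.exp(-(d**2) / (2.0 * model.scale**2))
    return out if out.ndim else float(out)


def predict_unbiased_curve(
    continuum: StimulusContinuum,
    imprint_index: int,
    model: UnbiasedModel,
    max_pref: float,
) -> np.ndarray:
    """Predicted familiar-preference percentage per test stimulus.

    The raw choice for the familiar stimulus against a comparison at
    distance ``d`` is ``1/(1 + similarity(d))`` (in [0.5, 1)).  The raw
    curve is affinely rescaled about the 50% chance anchor so that its
    maximum equals ``max_pref`` — calibrating the null prediction to the
    strongest preference actually observed.

    Returns one percentage per continuum stimulus; the familiar stimulus
    itself maps to exactly 50%.
    """
    if not (50.0 < max_pref <= 100.0):
        raise ValueError("max_pref must lie in (50, 100]")
    n = len(continuum)
    if not (0 <= imprint_index < n):
        raise IndexError(f"imprint_index {imprint_index} out of range for n={n}")
    d = np.abs(continuum.positions - continuum.positions[imprint_index])
    raw = 100.0 / (1.0 + similarity(d, model))
    span = raw.max() - 50.0  # > 0: the most distant stimulus is at d >= 1/(n-1)
    return 50.0 + (raw - 50.0) * (max_pref - 50.0) / span


def fit_kernel_scale(
    continuum: StimulusContinuum,
    imprint_index: int,
    observed: np.ndarray,
    kernel: str = "exponential",
    max_pref: float | None = None,
    grid: np.ndarray | None = None,
) -> UnbiasedModel:
    """1-D grid search for the kernel scale minimizing squared error.

    A convenience for drawing a calibrated null curve next to data; the
    null model is qualitative and no serious fitting machinery is wanted.
    ``max_pref`` defaults to the observed maximum (must exceed 50).
    """
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (len(continuum),):
        raise ValueError("observed must have one value per continuum stimulus")
    if max_pref is None:
        max_pref = float(observed.max())
    if grid is None:
        grid = np.geomspace(0.02, 3.0, 60)
    best, best_sse = None, np.inf
    for scale in grid:
        model = UnbiasedModel(kernel=kernel, scale=float(scale))
        sse = float(np.sum((predict_unbiased_curve(continuum, imprint_index, model, max_pref) - observed) ** 2))
        if sse < best_sse:
            best, best_sse = model, sse
    return best
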