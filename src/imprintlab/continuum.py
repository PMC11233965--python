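"""Ordered one-dimensional colour continua and the ratio choice rule.

The experimental stimuli form two ordered colour series (red-to-yellow and
blue-to-green) in which only the order and the symmetry of distances are
assumed: the distance between two stimuli is the same in both directions.
The continuum lives on a normalized axis in [0, 1]; by default stimuli are
equally spaced, but positions are user-settable when a perceptual scaling
is available.

The ratio choice rule — an animal divides its approach between two stimuli
in proportion to the value it assigns to each — is shared by every model in
the package, so it lives here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stimulus",
    "StimulusContinuum",
    "PreferenceCurve",
    "build_continuum",
    "perceptual_distance",
    "choice_probability",
    "red_yellow_continuum",
    "blue_green_continuum",
    "read_continuum",
    "write_continuum",
]


@dataclass(frozen=True)
class Stimulus:
    """A single colour stimulus on an ordered continuum.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"Red1"``; unique within a continuum.
    index : int
        0-based position in the continuum ordering.
    position : float
        Location on the normalized perceptual axis, in [0, 1].
    wavelength_nm : float, optional
        Approximate dominant wavelength; metadata only.
    rgb : tuple of int, optional
        Display triple; metadata only, never enters computation.
    """

    name: str
    index: int
    position: float
    wavelength_nm: float | None = None
    rgb: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.position <= 1.0):
            raise ValueError(
                f"stimulus {self.name!r}: position {self.position} outside [0, 1]"
            )


class StimulusContinuum:
    """An ordered series of >=2 stimuli with strictly increasing positions.

    The first stimulus sits at position 0 and the last at position 1
    (normalized axis), so the most distant pair is at distance 1.
    """

    def __init__(self, stimuli: Sequence[Stimulus]):
        stimuli = list(stimuli)
        if len(stimuli) < 2:
            raise ValueError("a continuum needs at least 2 stimuli")
        names = [s.name for s in stimuli]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate stimulus names: {names}")
        pos = np.asarray([s.position for s in stimuli], dtype=float)
        if not np.all(np.diff(pos) > 0):
            raise ValueError("stimulus positions must be strictly increasing")
        if pos[0] != 0.0 or pos[-1] != 1.0:
            raise ValueError("continuum must span the normalized axis [0, 1]")
        self.stimuli: list[Stimulus] = stimuli
        self._positions = pos
        self._index = {s.name: s.index for s in stimuli}

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    def __repr__(self) -> str:
        return f"StimulusContinuum({self.names})"

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.stimuli]

    @property
    def positions(self) -> np.ndarray:
        """Positions on the normalized axis, shape (n,)."""
        return self._positions.copy()

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown stimulus {name!r}; have {self.names}") from None

    def distance(self, i: int, j: int) -> float:
        return perceptual_distance(self, i, j)


def build_continuum(
    names: Iterable[str],
    positions: Sequence[float] | None = None,
    wavelengths_nm: Sequence[float] | None = None,
    rgbs: Sequence[tuple[int, int, int]] | None = None,
) -> StimulusContinuum:
    """Build a :class:`StimulusContinuum` from ordered labels.

    When ``positions`` is omitted the stimuli are equally spaced:
    ``position_k = k / (n - 1)``.
    """
    names = list(names)
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 stimulus names")
    if positions is None:
        positions = np.linspace(0.0, 1.0, n)
    else:
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (n,):
            raise ValueError("positions must match the number of names")
    stimuli = []
    for k, name in enumerate(names):
        stimuli.append(
            Stimulus(
                name=name,
                index=k,
                position=float(positions[k]),
                wavelength_nm=None if wavelengths_nm is None else wavelengths_nm[k],
                rgb=None if rgbs is None else tuple(rgbs[k]),
            )
        )
    return StimulusContinuum(stimuli)


def perceptual_distance(continuum: StimulusContinuum, i: int, j: int) -> float:
    """Symmetric distance |position_i - position_j| along the continuum."""
    n = len(continuum)
    for k in (i, j):
        if not (0 <= k < n):
            raise IndexError(f"stimulus index {k} out of range for n={n}")
    return float(abs(continuum.positions[i] - continuum.positions[j]))


def choice_probability(pref_i: float, pref_j: float) -> float:
    """Probability of choosing stimulus i over j under the ratio rule.

    ``choice(i, j) = pref_i / (pref_i + pref_j)``: approach is divided in
    proportion to the evaluated value of each option.
    """
    if pref_i < 0 or pref_j < 0:
        raise ValueError("preference values must be nonnegative")
    total = pref_i + pref_j
    if total == 0:
        raise ValueError("choice undefined when both preferences are zero")
    return float(pref_i / total)


@dataclass
class PreferenceCurve:
    """A strictly positive preference value per stimulus of a continuum."""

    continuum: StimulusContinuum
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.continuum),):
            raise ValueError(
                f"expected {len(self.continuum)} preference values, "
                f"got shape {self.values.shape}"
            )
        if not np.all(self.values > 0):
            raise ValueError("preference values must be strictly positive")
        if self.normalized and self.values.max() != 1.0:
            raise ValueError("normalized curve must have max exactly 1")

    def normalize(self) -> "PreferenceCurve":
        """Return a copy rescaled so that the maximum value is exactly 1."""
        v = self.values / self.values.max()
        # guard against rounding leaving max at 1-eps
        v[np.argmax(v)] = 1.0
        return PreferenceCurve(self.continuum, v, normalized=True)

    def value_of(self, name: str) -> float:
        return float(self.values[self.continuum.index_of(name)])


# The two stimulus series used throughout: eight colours each, ordered from
# the saturated end (Red1 / Blue1) to the opposite end (Yellow1 / Green1),
# with the intermediate colour (Orange / Turquoise) at index 4.
_RED_YELLOW = ["Red1", "Red2", "Red3", "Red4", "Orange", "Yellow3", "Yellow2", "Yellow1"]
_BLUE_GREEN = ["Blue1", "Blue2", "Blue3", "Blue4", "Turquoise", "Green3", "Green2", "Green1"]


def red_yellow_continuum() -> StimulusContinuum:
    """The 8-stimulus red-to-yellow series, equally spaced."""
    return build_continuum(_RED_YELLOW)


def blue_green_continuum() -> StimulusContinuum:
    """The 8-stimulus blue-to-green series, equally spaced."""
    return build_continuum(_BLUE_GREEN)


def read_continuum(path: str | Path) -> StimulusContinuum:
    """Read a continuum definition table.

    Plain-text table (comma or tab separated, one header row) with columns
    ``name`` and optionally ``position``, ``wavelength_nm``, ``r``, ``g``, ``b``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "name" not in df.columns:
        raise ValueError(f"{path}: missing required column 'name'")
    positions = df["position"].to_numpy(float) if "position" in df.columns else None
    wl = df["wavelength_nm"].tolist() if "wavelength_nm" in df.columns else None
    rgbs = None
    if {"r", "g", "b"}.issubset(df.columns):
        rgbs = list(zip(df["r"].astype(int), df["g"].astype(int), df["b"].astype(int)))
    return build_continuum(df["name"].astype(str).tolist(), positions, wl, rgbs)


def write_continuum(continuum: StimulusContinuum, path: str | Path) -> None:
    rows = []
    for s in continuum:
        row = {"name": s.name, "position": s.position}
        if s.wavelength_nm is not None:
            row["wavelength_nm"] = s.wavelength_nm
        if s.rgb is not None:
            row["r"], row["g"], row["b"] = s.rgb
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
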