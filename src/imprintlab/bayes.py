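"""Ideal Bayesian observer for colour predispositions.

A newly hatched chick must decide whether an object it sees is its
imprinting target (the mother hen).  Scoring a colour as evidence is a
Bayes computation:

    P(target | colour) = P(colour|target)·P(target) /
        (P(colour|target)·P(target) + P(colour|not_target)·(1 − P(target)))

The interest an ideal observer should take in a colour rises with the
probability that the target displays it and falls with its prevalence
among other objects in the environment.  Hens carry reddish areas while
saturated reds are rare among natural backgrounds (vegetation, soil,
rocks), so the likelihood ratio for red exceeds that for the common
yellow-green hues — the direction this module lets you compute from colour
frequency tables.

Frequency tables are built from colour loci (relative cone catches or
tetrahedral coordinates) under a binning rule; the default is a coarse
categorical rule — dominant cone class, with an achromatic category when
no relative catch stands out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

from .colorspace import CONE_LABELS, RelativeCatches, TetraLocus

__all__ = [
    "ColorEvidence",
    "ColorFrequencyTable",
    "posterior_target_given_color",
    "likelihood_ratio",
    "dominant_cone_category",
    "GridBinning",
    "color_frequency_from_loci",
    "evidence_from_frequencies",
]

ACHROMATIC = "achromatic"


@dataclass(frozen=True)
class ColorEvidence:
    """Likelihoods and prior entering the Bayes computation."""

    p_color_given_target: float
    p_color_given_not_target: float
    p_target: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_color_given_target", "p_color_given_not_target"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.p_target < 1.0):
            raise ValueError("p_target must lie strictly in (0, 1)")
        if self.p_color_given_target == 0.0 and self.p_color_given_not_target == 0.0:
            raise ValueError("both likelihoods zero: the colour never occurs")


class ColorFrequencyTable:
    """Relative frequency of colour categories; frequencies sum to 1."""

    def __init__(self, frequencies: Mapping[str, float]):
        if not frequencies:
            raise ValueError("empty frequency table")
        if any(f < 0 for f in frequencies.values()):
            raise ValueError("frequencies must be nonnegative")
        total = sum(frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {total}")
        self._freq = dict(frequencies)

    def __getitem__(self, bin_label: str) -> float:
        if bin_label not in self._freq:
            raise KeyError(f"bin {bin_label!r} not in table; have {sorted(self._freq)}")
        return self._freq[bin_label]

    def __contains__(self, bin_label: str) -> bool:
        return bin_label in self._freq

    def get(self, bin_label: str, default: float = 0.0) -> float:
        return self._freq.get(bin_label, default)

    @property
    def bins(self) -> list[str]:
        return sorted(self._freq)

    def as_dict(self) -> dict[str, float]:
        return dict(self._freq)


def posterior_target_given_color(e: ColorEvidence) -> float:
    """P(target | colour) by Bayes' theorem."""
    num = e.p_color_given_target * e.p_target
    den = num + e.p_color_given_not_target * (1.0 - e.p_target)
    return num / den


def likelihood_ratio(e: ColorEvidence) -> float:
    """P(colour|target) / P(colour|not_target); ``inf`` for exclusive evidence."""
    if e.p_color_given_not_target == 0.0:
        return math.inf
    return e.p_color_given_target / e.p_color_given_not_target


def dominant_cone_category(rc: RelativeCatches, achromatic_below: float = 0.35) -> str:
    """Coarse colour category of a relative-catch quadruple.

    Returns the label of the dominant cone class (``vs``/``s``/``m``/``l``)
    or ``"achromatic"`` when the largest relative catch falls below
    ``achromatic_below`` (no cone stands out; equal stimulation is 0.25).
    """
    arr = rc.as_array()
    if arr.max() < achromatic_below:
        return ACHROMATIC
    return CONE_LABELS[int(arr.argmax())]


@dataclass(frozen=True)
class GridBinning:
    """Cubic-cell binning of tetrahedral loci, labels ``"i,j,k"``.

    The tetrahedral simplex fits inside [-0.75, 0.75]^3; loci outside the
    grid extent raise.
    """

    n_cells: int = 4
    extent: float = 0.75

    def __call__(self, locus: TetraLocus) -> str:
        idx = []
        width = 2.0 * self.extent / self.n_cells
        for coord in (locus.x, locus.y, locus.z):
            if not (-self.extent <= coord <= self.extent):
                raise ValueError(f"locus coordinate {coord} outside grid extent ±{self.extent}")
            i = min(int((coord + self.extent) / width), self.n_cells - 1)
            idx.append(i)
        return ",".join(map(str, idx))


def color_frequency_from_loci(
    loci: Iterable,
    binning: Callable[[object], str] | None = None,
) -> ColorFrequencyTable:
    """Bin colour loci and return their relative frequencies.

    ``loci`` may be plain category labels (used as-is), RelativeCatches
    (default binning: :func:`dominant_cone_category`), or TetraLocus values
    (require an explicit binning, e.g. :class:`GridBinning`).
    """
    counts: dict[str, int] = {}
    n = 0
    for locus in loci:
        if isinstance(locus, str):
            label = locus
        elif binning is not None:
            label = binning(locus)
        elif isinstance(locus, RelativeCatches):
            label = dominant_cone_category(locus)
        else:
            raise TypeError(
                f"no binning rule for locus of type {type(locus).__name__}; pass binning="
            )
        counts[label] = counts.get(label, 0) + 1
        n += 1
    if n == 0:
        raise ValueError("empty loci")
    return ColorFrequencyTable({k: v / n for k, v in counts.items()})


def evidence_from_frequencies(
    target_table: ColorFrequencyTable,
    environment_table: ColorFrequencyTable,
    bin_label: str,
    p_target: float = 0.5,
) -> ColorEvidence:
    """Build :class:`ColorEvidence` for one colour bin from two tables.

    The target table supplies P(colour|target) and the environment table
    P(colour|not_target).  The bin must be present in both tables.
    """
    for table, which in ((target_table, "target"), (environment_table, "environment")):
        if bin_label not in table:
            raise KeyError(f"bin {bin_label!r} missing from the {which} table")
    return ColorEvidence(
        p_color_given_target=target_table[bin_label],
        p_color_given_not_target=environment_table[bin_label],
        p_target=p_target,
    )
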