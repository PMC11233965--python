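"""Avian colorimetry: quantum catches and the tetrahedral colour space.

Birds have four single-cone classes — very-short/UV (vs), short (s),
medium (m) and long (l) wavelength sensitive.  The quantum catch of cone
``i`` viewing a surface is

    QC_i = ∫ R(λ) · S_i(λ) · I(λ) dλ   over 300–700 nm,

with R the reflectance, S_i the cone's spectral sensitivity and I the
illuminant photon flux (unit by default).  Catches normalized to sum to 1
give relative catches {vs s m l}, which project into the tetrahedral
colour space of birds via

    x = ((1 − 2s − m − u) / 2) · √(3/2)
    y = (−1 + 3m + u) / (2√2)
    z = u − 1/4            (u ≡ vs)

A colour stimulating one cone class only lands on the corresponding vertex
(all four vertices at distance 0.75 from the origin); equal stimulation of
all four cones — achromatic — lands at the origin.

Integration uses the trapezoidal rule on a 1-nm grid over [300, 700] nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "ReceptorSet",
    "RelativeCatches",
    "TetraLocus",
    "DEFAULT_GRID",
    "resample",
    "quantum_catch",
    "relative_catches",
    "tetra_project",
    "catches_for_spectrum",
    "load_spectra",
    "write_spectra",
    "synthetic_uvs_receptors",
]

DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)

CONE_LABELS = ("vs", "s", "m", "l")


@dataclass
class Spectrum:
    """Wavelength-indexed nonnegative function (reflectance or sensitivity)."""

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.size < 2:
            raise ValueError("a spectrum needs at least 2 wavelength samples")
        if self.values.shape != self.wavelengths_nm.shape:
            raise ValueError("wavelengths and values must have the same length")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(self.values < 0):
            raise ValueError("spectral values must be nonnegative")


@dataclass
class ReceptorSet:
    """The four single-cone sensitivity spectra of a UV-sensitive bird."""

    vs: Spectrum
    s: Spectrum
    m: Spectrum
    l: Spectrum

    def __post_init__(self) -> None:
        for label in CONE_LABELS:
            spec = getattr(self, label)
            area = np.trapezoid(resample(spec, DEFAULT_GRID).values, DEFAULT_GRID)
            if not area > 0:
                raise ValueError(f"receptor {label!r} has zero area on [300, 700] nm")

    def __iter__(self):
        return iter((self.vs, self.s, self.m, self.l))


@dataclass(frozen=True)
class RelativeCatches:
    """Four cone catches normalized to sum to 1 ({vs s m l})."""

    u: float  # vs cone; 'u' is the symbol used in the projection equations
    s: float
    m: float
    l: float

    def __post_init__(self) -> None:
        vals = (self.u, self.s, self.m, self.l)
        if any(v < 0 for v in vals):
            raise ValueError("relative catches must be nonnegative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"relative catches must sum to 1, got {sum(vals)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.s, self.m, self.l])


@dataclass(frozen=True)
class TetraLocus:
    """Cartesian coordinates in the tetrahedral colour space."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    def norm(self) -> float:
        return float(np.sqrt(self.x**2 + self.y**2 + self.z**2))


def resample(spec: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``grid``; zero outside the measured range."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("resampling grid is empty")
    values = np.interp(grid, spec.wavelengths_nm, spec.values, left=0.0, right=0.0)
    return Spectrum(grid, values)


def quantum_catch(
    reflectance: Spectrum,
    sensitivity: Spectrum,
    illuminant: Spectrum | None = None,
    grid: np.ndarray = DEFAULT_GRID,
) -> float:
    """Trapezoidal ∫ R(λ)·S(λ)·I(λ) dλ over the grid (default 300–700 nm, 1 nm).

    With ``illuminant=None`` the photon flux is taken as 1 at every
    wavelength.  Linear in the reflectance.
    """
    r = resample(reflectance, grid).values
    s = resample(sensitivity, grid).values
    product = r * s
    if illuminant is not None:
        product = product * resample(illuminant, grid).values
    return float(np.trapezoid(product, grid))


def relative_catches(qc_vs: float, qc_s: float, qc_m: float, qc_l: float) -> RelativeCatches:
    """Normalize four nonnegative catches to sum to 1."""
    vals = np.array([qc_vs, qc_s, qc_m, qc_l], dtype=float)
    if np.any(vals < 0):
        raise ValueError("quantum catches must be nonnegative")
    total = vals.sum()
    if total == 0:
        raise ValueError("cannot normalize all-zero quantum catches")
    u, s, m, l = vals / total
    return RelativeCatches(float(u), float(s), float(m), float(l))


def tetra_project(rc: RelativeCatches) -> TetraLocus:
    """Project relative catches {vs s m l} into the tetrahedral colour space."""
    u, s, m = rc.u, rc.s, rc.m
    x = ((1.0 - 2.0 * s - m - u) / 2.0) * np.sqrt(1.5)
    y = (-1.0 + 3.0 * m + u) / (2.0 * np.sqrt(2.0))
    z = u - 0.25
    return TetraLocus(float(x), float(y), float(z))


def catches_for_spectrum(
    reflectance: Spectrum,
    receptors: ReceptorSet,
    illuminant: Spectrum | None = None,
) -> RelativeCatches:
    """Relative cone catches of a reflectance under a receptor set."""
    qcs = [quantum_catch(reflectance, sens, illuminant) for sens in receptors]
    return relative_catches(*qcs)


def load_spectra(path: str | Path) -> list[tuple[str, Spectrum]]:
    """Read a spectra table: first column ``wavelength_nm``, one column per
    sample, one header row; comma or tab separated."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be 'wavelength_nm', got {df.columns[0]!r}")
    wl = df["wavelength_nm"].to_numpy(float)
    out = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(float)
        if np.any(vals < 0):
            row = int(np.argmax(vals < 0))
            raise ValueError(f"{path}: negative reflectance at row {row} column {col!r}")
        out.append((str(col), Spectrum(wl, vals)))
    return out


def write_spectra(spectra: list[tuple[str, Spectrum]], path: str | Path) -> None:
    """Write spectra sharing one wavelength grid to a tab-separated table."""
    if not spectra:
        raise ValueError("nothing to write")
    wl = spectra[0][1].wavelengths_nm
    for name, spec in spectra:
        if not np.array_equal(spec.wavelengths_nm, wl):
            raise ValueError(f"spectrum {name!r} is on a different wavelength grid")
    df = pd.DataFrame({"wavelength_nm": wl})
    for name, spec in spectra:
        df[name] = spec.values
    df.to_csv(path, sep="\t", index=False)


def synthetic_uvs_receptors(grid: np.ndarray = DEFAULT_GRID) -> ReceptorSet:
    """SYNTHETIC receptor sensitivities for testing and examples.

    Smooth unimodal (Gaussian) curves peaking near 370 / 445 / 508 / 565 nm,
    qualitatively shaped like the single-cone sensitivities of a
    UV-sensitive bird.  These are synthetic stand-ins constructed by this
    package — not measured or published sensitivity functions — and are
    meant for exercising the machinery; analyses of real spectra should
    supply measured sensitivities via :func:`load_spectra`.
    """
    peaks = {"vs": 370.0, "s": 445.0, "m": 508.0, "l": 565.0}
    widths = {"vs": 25.0, "s": 28.0, "m": 32.0, "l": 35.0}
    specs = {}
    for label, peak in peaks.items():
        vals = np.exp(-((grid - peak) ** 2) / (2.0 * widths[label] ** 2))
        specs[label] = Spectrum(grid.copy(), vals)
    return ReceptorSet(**specs)
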