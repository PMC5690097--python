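"""Effective-parameter fits and the absolute-dose calibration factor.

Three procedures anchor the simulation to measurement:

* effective ROI-filter thickness — the thickness of a pure Gd2O2S slab whose
  broad-spectrum transmission matches a measured composite filter;
* effective patient-table density — the density of a pure-carbon slab of
  assumed thickness matching measured table transmissions (only the areal
  density, density x thickness, is physically identified);
* the calibration factor CF converting simulated dose per source primary
  into absolute dose per mAs, anchored by a free-in-air kerma measurement.

Both fits are bracketed root searches on strictly monotone transmission
curves, so the solutions are unique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .materials import Material
from .spectra import EnergySpectrum, FilterStack, kerma_weighted_transmission

__all__ = [
    "TransmissionMeasurement",
    "CalibrationFactor",
    "fit_effective_thickness",
    "average_effective_thickness",
    "fit_effective_density",
    "calibration_factor",
    "TABLE_TRANSMISSIONS",
    "FILTER_EFFECTIVE_THICKNESSES_MM",
    "TABLE_SLAB_THICKNESS_MM",
]

#: Measured air-kerma transmission of the patient-table headrest at the five
#: adjustable CT tube voltages (kVp -> transmission), 2.5 mm added Al.
TABLE_TRANSMISSIONS: dict[float, float] = {
    70: 0.683, 81: 0.687, 90: 0.695, 96: 0.701, 102: 0.709,
}

#: Published per-voltage effective Gd2O2S thicknesses (mm) for 1-4 layers of
#: the composite screen filter: (layer count, kVp, fitted thickness).
FILTER_EFFECTIVE_THICKNESSES_MM: tuple[tuple[int, float, float], ...] = (
    (1, 80, 0.107), (1, 90, 0.105), (1, 100, 0.104),
    (2, 80, 0.208), (2, 90, 0.204), (2, 100, 0.203),
    (3, 80, 0.306), (3, 90, 0.309), (3, 100, 0.298),
    (4, 80, 0.399), (4, 90, 0.391), (4, 100, 0.391),
)

#: Assumed headrest slab thickness (mm).  Transmission identifies only the
#: areal density; this scale convention puts the reported effective densities
#: on the published per-voltage density scale (mean 0.484 g/cm^3) and is a
#: plausible physical headrest thickness.  See docs/methods.md.
TABLE_SLAB_THICKNESS_MM = 35.8168


@dataclass(frozen=True)
class TransmissionMeasurement:
    """One broad-beam transmission reading of an attenuator."""

    kvp: float
    transmission: float
    spectrum: EnergySpectrum  # beam (incl. prefiltration) the reading was taken with

    def __post_init__(self) -> None:
        if not (0.0 < self.transmission <= 1.0):
            raise ValueError(f"transmission {self.transmission} outside (0, 1]")


@dataclass(frozen=True)
class CalibrationFactor:
    """CF = (D_air per mAs, measured) / (D_air per primary, simulated)."""

    measured_dair_per_mas: float   # Gy/mAs
    simulated_dair_per_primary: float  # Gy per source primary
    kvp: float

    def __post_init__(self) -> None:
        if self.measured_dair_per_mas <= 0 or self.simulated_dair_per_primary <= 0:
            raise ValueError("calibration inputs must be positive")

    @property
    def cf(self) -> float:
        return self.measured_dair_per_mas / self.simulated_dair_per_primary


def _slab(material: Material, thickness_mm: float) -> FilterStack:
    return FilterStack(((material, thickness_mm),))


def _bracket_and_solve(f, x0: float = 1.0, tol: float = 1e-9) -> float:
    """Root of monotone-decreasing f with f(0) >= 0: double the bracket
    until the sign changes, then Brent."""
    if f(0.0) < 0:
        raise ValueError(
            "target transmission exceeds the zero-thickness transmission"
        )
    hi = x0
    for _ in range(80):
        if f(hi) < 0:
            return brentq(f, 0.0, hi, xtol=tol)
        hi *= 2.0
    raise ValueError("could not bracket the transmission target")


def fit_effective_thickness(
    target_transmission: float,
    material: Material,
    spectrum: EnergySpectrum,
    weighting: str = "air_kerma",
) -> float:
    """Slab thickness (mm) whose kerma-weighted transmission matches the target.

    Transmission is strictly decreasing in thickness, so the bracketed root
    is unique; the solve is tight enough that the transmission residual is
    below 1e-6.
    """
    if not (0.0 < target_transmission <= 1.0):
        raise ValueError("target transmission must lie in (0, 1]")
    if target_transmission == 1.0:
        return 0.0

    def f(t_mm: float) -> float:
        return (
            kerma_weighted_transmission(spectrum, _slab(material, t_mm), weighting)
            - target_transmission
        )

    return _bracket_and_solve(f, x0=0.1)


@dataclass(frozen=True)
class ThicknessSummary:
    per_layer_mean_mm: float
    per_layer_two_sigma_mm: float
    #: layer count -> (row-average thickness, row 2-sigma), mm
    rows: dict[int, tuple[float, float]]


def average_effective_thickness(
    per_layer_results=FILTER_EFFECTIVE_THICKNESSES_MM,
) -> ThicknessSummary:
    """Pool per-voltage fitted thicknesses into one thickness per layer.

    Each fitted thickness is divided by its layer count; the mean and twice
    the sample standard deviation of these per-layer values are reported, and
    the per-row (n-layer) average is n times the per-layer mean.
    """
    results = list(per_layer_results)
    if not results:
        raise ValueError("no fitted thicknesses given")
    per_layer = np.array([t / n for n, _, t in results], dtype=float)
    mean = float(per_layer.mean())
    two_sigma = float(2.0 * per_layer.std(ddof=1)) if len(per_layer) > 1 else 0.0
    counts = sorted({n for n, _, _ in results})
    rows = {n: (n * mean, n * two_sigma) for n in counts}
    return ThicknessSummary(mean, two_sigma, rows)


@dataclass(frozen=True)
class DensityFit:
    per_kvp_density: dict[float, float]    # g/cm^3 at the assumed thickness
    mean_density: float                    # g/cm^3
    deviation_percent: dict[float, float]  # |mean - value| / mean * 100
    slab_thickness_mm: float

    @property
    def mean_areal_density(self) -> float:
        """g/cm^2 — the thickness-invariant physical quantity."""
        return self.mean_density * self.slab_thickness_mm / 10.0


def fit_effective_density(
    measurements: list[TransmissionMeasurement],
    material: Material,
    slab_thickness_mm: float = TABLE_SLAB_THICKNESS_MM,
    weighting: str = "air_kerma",
) -> DensityFit:
    """Per-voltage effective density of a slab of assumed thickness.

    The root search runs on density at fixed thickness; reported densities
    scale exactly inversely with the assumed thickness (areal density is the
    invariant).
    """
    if not measurements:
        raise ValueError("no transmission measurements given")
    if slab_thickness_mm <= 0:
        raise ValueError("slab thickness must be positive")
    per_kvp: dict[float, float] = {}
    for m in measurements:
        if m.transmission >= 1.0:
            raise ValueError(f"{m.kvp} kVp: transmission must be < 1 to fit density")

        def f(rho: float) -> float:
            mat = Material(material.name, material.composition, max(rho, 1e-12))
            return (
                kerma_weighted_transmission(
                    m.spectrum, _slab(mat, slab_thickness_mm), weighting
                )
                - m.transmission
            )

        per_kvp[m.kvp] = _bracket_and_solve(f, x0=0.5)
    mean = float(np.mean(list(per_kvp.values())))
    dev = {k: abs(mean - v) / mean * 100.0 for k, v in per_kvp.items()}
    return DensityFit(per_kvp, mean, dev, slab_thickness_mm)


def calibration_factor(
    measured_dair_per_mas: float,
    simulated_dair_per_primary: float,
    kvp: float,
) -> CalibrationFactor:
    """One CF per tube voltage; plain measured/simulated ratio."""
    return CalibrationFactor(measured_dair_per_mas, simulated_dair_per_primary, kvp)
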