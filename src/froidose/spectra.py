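"""X-ray tube spectra, slab filtration, and kerma-weighted transmission.

The tube model is a semi-empirical thick-target tungsten bremsstrahlung
spectrum (Birch-Marshall style): Kramers emission per electron energy step,
target self-attenuation through the anode at the takeoff angle via a
Thomson-Whiddington depth-energy relation, plus tungsten K characteristic
lines above the K edge.  Spectra are binned at 1 keV from 1 keV to the tube
voltage, and are relative fluence: every downstream quantity of this package
is a ratio, so normalization is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import Material, get_table, predefined

__all__ = [
    "EnergySpectrum",
    "FilterStack",
    "generate_spectrum",
    "attenuate",
    "kerma_weighted_transmission",
    "monoenergetic",
]

# Thomson-Whiddington constant for tungsten, keV^2 cm^2/g: electron depth
# x(E) = (E0^2 - E^2) / C_TW.  Standard literature magnitude.
_C_TW = 7.0e5

# Tungsten K lines: energy (keV), relative intensity within the K series.
_K_LINES = ((59.318, 1.00), (57.982, 0.58), (67.244, 0.22), (69.067, 0.08))
_K_EDGE = 69.525


@dataclass(frozen=True)
class FilterStack:
    """Ordered attenuating layers of (material, thickness in mm)."""

    layers: tuple[tuple[Material, float], ...] = ()

    def __post_init__(self) -> None:
        layers = tuple((m, float(t)) for m, t in self.layers)
        object.__setattr__(self, "layers", layers)
        for mat, t in layers:
            if t < 0:
                raise ValueError(f"negative thickness {t} mm for {mat.name}")

    def __add__(self, other: "FilterStack") -> "FilterStack":
        return FilterStack(self.layers + other.layers)

    def optical_depth(self, energy_kev) -> np.ndarray:
        """Sum of mu(E) * rho * t over layers (dimensionless)."""
        e = np.asarray(energy_kev, dtype=float)
        od = np.zeros_like(e)
        for mat, t_mm in self.layers:
            od = od + mat.mu(e) * mat.density * (t_mm / 10.0)
        return od

    @staticmethod
    def of(*layers: tuple[str | Material, float]) -> "FilterStack":
        mats = predefined()
        resolved = tuple(
            (mats[m] if isinstance(m, str) else m, t) for m, t in layers
        )
        return FilterStack(resolved)


@dataclass(frozen=True)
class EnergySpectrum:
    """Binned relative photon fluence vs energy for one tube voltage."""

    kvp: float
    energies: np.ndarray  # bin centers, keV
    weights: np.ndarray   # relative photons per bin, >= 0

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)
        if e.shape != w.shape or e.ndim != 1:
            raise ValueError("energies and weights must be 1-D and congruent")
        if np.any(w < 0):
            raise ValueError("negative fluence weight")
        if not np.any(w > 0):
            raise ValueError("spectrum has no positive weight")
        if np.any(w[e > self.kvp] > 0):
            raise ValueError("fluence above the Duane-Hunt limit")

    def mean_energy(self) -> float:
        """Fluence-weighted mean energy, keV."""
        return float(np.sum(self.energies * self.weights) / np.sum(self.weights))

    def rebin(self, width_kev: float) -> "EnergySpectrum":
        """Coarsen to bins of ``width_kev``, conserving fluence per bin.

        New bin centers are fluence-weighted means within each group, so a
        monoenergetic spectrum is preserved exactly.
        """
        if width_kev <= 1.0:
            return self
        edges = np.arange(0.0, self.energies.max() + width_kev, width_kev)
        idx = np.digitize(self.energies, edges) - 1
        n = idx.max() + 1
        w = np.bincount(idx, weights=self.weights, minlength=n)
        ew = np.bincount(idx, weights=self.weights * self.energies, minlength=n)
        keep = w > 0
        return EnergySpectrum(self.kvp, ew[keep] / w[keep], w[keep])


def monoenergetic(energy_kev: float, weight: float = 1.0) -> EnergySpectrum:
    """Single-line spectrum, handy for closed-form tests."""
    return EnergySpectrum(energy_kev, np.array([energy_kev]), np.array([weight]))


def generate_spectrum(
    kvp: float,
    anode_angle_deg: float = 12.0,
    inherent_filtration: FilterStack | None = None,
) -> EnergySpectrum:
    """Tungsten-anode spectrum at ``kvp`` in 1 keV bins, 1 keV..kvp.

    ``inherent_filtration`` is applied on top of the bare-target spectrum;
    pass the unit's prefilter here (e.g. 0.3 mm Cu + 2.6 mm Al).
    """
    if not (40.0 <= kvp <= 150.0):
        raise ValueError(f"kvp {kvp} outside supported range 40-150 kV")
    e = np.arange(1.0, np.floor(kvp) + 1.0)  # bin centers, keV
    w_tab = get_table("W")
    mu_w = w_tab(e) * 19.30  # 1/cm
    sin_t = np.sin(np.radians(anode_angle_deg))

    # Integrate Kramers emission over electron energy, attenuating each
    # contribution through the anode depth at which it was produced.
    n_sub = 64
    weights = np.zeros_like(e)
    for i, ph in enumerate(e):
        if ph >= kvp:
            continue
        ee = np.linspace(ph, kvp, n_sub)
        depth_cm = (kvp**2 - ee**2) / _C_TW / 19.30  # g/cm^2 -> cm
        self_att = np.exp(-mu_w[i] * depth_cm / sin_t)
        emission = (ee / ph - 1.0)
        weights[i] = np.trapezoid(emission * self_att, ee)

    # K characteristic lines: fraction of total fluence grows with overvoltage.
    if kvp > _K_EDGE:
        u = kvp / _K_EDGE
        frac = 0.07 * (u - 1.0) ** 1.3  # ~4-7% of fluence at 90-110 kV
        total = weights.sum()
        line_sum = sum(s for _, s in _K_LINES)
        for le, ls in _K_LINES:
            weights[int(round(le)) - 1] += frac * total * ls / line_sum
    spec = EnergySpectrum(float(kvp), e, weights)
    if inherent_filtration is not None:
        spec = attenuate(spec, inherent_filtration)
    return spec


def attenuate(spectrum: EnergySpectrum, stack: FilterStack) -> EnergySpectrum:
    """Beer-Lambert filtration of every bin; scatter in filters not modeled."""
    w = spectrum.weights * np.exp(-stack.optical_depth(spectrum.energies))
    return EnergySpectrum(spectrum.kvp, spectrum.energies, w)


def air_kerma_weights(energy_kev) -> np.ndarray:
    """Relative air-kerma response weight E * (mu_en/rho)_air(E)."""
    e = np.asarray(energy_kev, dtype=float)
    return e * get_table("Air")(e, "energy_absorption")


def kerma_weighted_transmission(
    spectrum: EnergySpectrum,
    slab: FilterStack,
    weighting: str = "air_kerma",
) -> float:
    """Broad-spectrum transmission of a slab as an air-kerma dosimeter sees it.

    Ratio of air-kerma-weighted integrals of the filtered to the unfiltered
    spectrum; ``weighting="fluence"`` gives the plain fluence ratio instead.
    """
    if weighting == "air_kerma":
        resp = air_kerma_weights(spectrum.energies)
    elif weighting == "fluence":
        resp = np.ones_like(spectrum.energies)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    num = spectrum.weights * resp
    denom = num.sum()
    if denom <= 0:
        raise ValueError("spectrum carries no response-weighted fluence")
    t = np.exp(-slab.optical_depth(spectrum.energies))
    return float(np.sum(num * t) / denom)
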