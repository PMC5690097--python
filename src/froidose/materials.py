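"""Materials and photon interaction coefficients.

Coefficients (mass attenuation mu/rho and mass energy-absorption mu_en/rho,
both cm^2/g) are bundled as a CSV on a fixed energy grid covering 1-150 keV
and log-log interpolated in energy.  Table keys are either chemical elements
(H, C, ..., Gd, W) or compiled compounds (Air, Water, SoftTissue,
CorticalBone) whose coefficients come straight from standard compilations;
a :class:`Material` mixes table entries by mass fraction.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "Material",
    "CoefficientTable",
    "get_table",
    "mixture_mu",
    "predefined",
    "GD2O2S_DENSITY",
]

#: Handbook density of gadolinium oxysulfide (g/cm^3).
GD2O2S_DENSITY = 7.32

_EMIN, _EMAX = 1.0, 150.0


@dataclass(frozen=True)
class CoefficientTable:
    """Photon coefficients for one table entry on an increasing keV grid."""

    symbol: str
    energies: np.ndarray          # keV, strictly increasing
    mu_over_rho: np.ndarray       # cm^2/g
    mu_en_over_rho: np.ndarray    # cm^2/g
    z_over_a: float               # mean Z/A (electrons per atomic mass unit)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or not np.all(np.diff(e) > 0):
            raise ValueError(f"{self.symbol}: energy grid must be strictly increasing")
        if e[0] > _EMIN or e[-1] < _EMAX:
            raise ValueError(f"{self.symbol}: grid must cover {_EMIN}-{_EMAX} keV")
        for name in ("mu_over_rho", "mu_en_over_rho"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != e.shape or np.any(v <= 0):
                raise ValueError(f"{self.symbol}: {name} must be positive on the grid")

    def __call__(self, energy_kev, kind: str = "attenuation") -> np.ndarray:
        """Log-log interpolated coefficient at ``energy_kev`` (scalar or array)."""
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < _EMIN) or np.any(e > _EMAX):
            raise ValueError(
                f"energy out of table range [{_EMIN}, {_EMAX}] keV for {self.symbol}"
            )
        if kind == "attenuation":
            vals = self.mu_over_rho
        elif kind == "energy_absorption":
            vals = self.mu_en_over_rho
        else:
            raise ValueError(f"unknown coefficient kind {kind!r}")
        out = np.exp(
            np.interp(np.log(e), np.log(self.energies), np.log(vals))
        )
        return out if out.ndim else float(out)


def _load_tables() -> dict[str, CoefficientTable]:
    pkg = resources.files("froidose") / "data"
    za = json.loads((pkg / "z_over_a.json").read_text())
    raw: dict[str, list[tuple[float, float, float]]] = {}
    with (pkg / "photon_coefficients.csv").open() as fh:
        for row in csv.DictReader(fh):
            raw.setdefault(row["symbol"], []).append(
                (float(row["energy_kev"]), float(row["mu_over_rho"]),
                 float(row["mu_en_over_rho"]))
            )
    tables = {}
    for sym, rows in raw.items():
        rows.sort()
        arr = np.array(rows)
        tables[sym] = CoefficientTable(
            sym, arr[:, 0], arr[:, 1], arr[:, 2], za[sym]
        )
    return tables


_TABLES: dict[str, CoefficientTable] | None = None


def get_table(symbol: str) -> CoefficientTable:
    global _TABLES
    if _TABLES is None:
        _TABLES = _load_tables()
    try:
        return _TABLES[symbol]
    except KeyError:
        raise KeyError(
            f"no bundled coefficient table for {symbol!r}; "
            f"available: {sorted(_TABLES)}"
        ) from None


@dataclass(frozen=True)
class Material:
    """A homogeneous material: mass-fraction composition plus bulk density.

    ``composition`` entries reference bundled coefficient-table keys; mass
    fractions must be strictly positive and sum to one.
    """

    name: str
    composition: tuple[tuple[str, float], ...]
    density: float  # g/cm^3

    def __post_init__(self) -> None:
        comp = tuple((str(s), float(f)) for s, f in self.composition)
        object.__setattr__(self, "composition", comp)
        if not comp:
            raise ValueError(f"{self.name}: empty composition")
        fracs = np.array([f for _, f in comp])
        if np.any(fracs <= 0):
            raise ValueError(f"{self.name}: mass fractions must be positive")
        if abs(fracs.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.name}: mass fractions sum to {fracs.sum():.8f}, not 1"
            )
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        for sym, _ in comp:
            get_table(sym)  # fail early on unknown components

    @property
    def z_over_a(self) -> float:
        return sum(f * get_table(s).z_over_a for s, f in self.composition)

    def mu(self, energy_kev, kind: str = "attenuation"):
        return mixture_mu(self, energy_kev, kind)


def mixture_mu(material: Material, energy_kev, kind: str = "attenuation"):
    """Mass-fraction-weighted mixture coefficient (cm^2/g).

    Each component is log-log interpolated at ``energy_kev`` and the results
    are combined linearly by mass fraction (the standard mixture rule; valid
    because photon cross sections are per-atom additive).
    """
    e = np.asarray(energy_kev, dtype=float)
    out = np.zeros_like(e, dtype=float)
    for sym, frac in material.composition:
        out = out + frac * get_table(sym)(e, kind)
    return out if out.ndim else float(out)


def _gd2o2s_fractions() -> tuple[tuple[str, float], ...]:
    m_gd, m_o, m_s = 157.25, 15.999, 32.06
    total = 2 * m_gd + 2 * m_o + m_s
    return (("Gd", 2 * m_gd / total), ("O", 2 * m_o / total), ("S", m_s / total))


def predefined() -> dict[str, Material]:
    """The stock materials used throughout the package."""
    soft = (("SoftTissue", 1.0),)
    return {
        "air": Material("air", (("Air", 1.0),), 1.2047e-3),
        "water": Material("water", (("Water", 1.0),), 1.0),
        "carbon": Material("carbon", (("C", 1.0),), 1.70),
        "aluminum": Material("aluminum", (("Al", 1.0),), 2.699),
        "copper": Material("copper", (("Cu", 1.0),), 8.96),
        "tungsten": Material("tungsten", (("W", 1.0),), 19.30),
        "gadolinium_oxysulfide": Material(
            "gadolinium_oxysulfide", _gd2o2s_fractions(), GD2O2S_DENSITY
        ),
        "soft_tissue": Material("soft_tissue", soft, 1.05),
        "brain": Material("brain", soft, 1.05),
        "skin": Material("skin", soft, 1.09),
        "eye_lens": Material("eye_lens", soft, 1.07),
        "salivary_gland": Material("salivary_gland", soft, 1.03),
        "spinal_cord": Material("spinal_cord", soft, 1.04),
        "cortical_bone": Material("cortical_bone", (("CorticalBone", 1.0),), 1.92),
    }
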