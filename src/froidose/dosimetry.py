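"""Organ equivalent dose, effective dose, and comparative dose metrics.

Organ equivalent dose is the radiation-weighted, mass-weighted mean voxel
dose over the organ (w_r = 1 for photons):

    H_T = w_r * sum_i D_i rho_i v_i / sum_i rho_i v_i

Effective dose is the tissue-weighted sum E = sum_T w_T H_T with the
ICRP 103 tissue weighting factors; tissues absent from the phantom
contribute zero and are reported, so E from a head phantom is explicitly a
partial-body effective dose.  Remainder tissues use the ICRP 103
arithmetic-mean rule over whichever remainder organs exist.  The eye lens
is radiosensitive but by definition never contributes to E and is reported
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationFactor
from .geometry import ScanProtocol
from .phantom import VoxelPhantom
from .transport import DoseGrid

__all__ = [
    "TISSUE_WEIGHTS",
    "REMAINDER_ORGANS",
    "OrganDoseReport",
    "EffectiveDoseReport",
    "absolute_voxel_dose",
    "organ_dose",
    "effective_dose",
    "phantom_dose_report",
    "PhantomDoseReport",
    "dose_reduction",
    "theoretical_reduction",
]

#: ICRP Publication 103 tissue weighting factors (sum to 1).
TISSUE_WEIGHTS: dict[str, float] = {
    "red_bone_marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "breast": 0.12,
    "remainder": 0.12,
    "gonads": 0.08,
    "bladder": 0.04,
    "oesophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone_surface": 0.01,
    "brain": 0.01,
    "salivary_glands": 0.01,
    "skin": 0.01,
}

#: ICRP 103 remainder tissues (shared w_T = 0.12, arithmetic mean rule).
REMAINDER_ORGANS: tuple[str, ...] = (
    "adrenals", "extrathoracic_region", "gall_bladder", "heart", "kidneys",
    "lymphatic_nodes", "muscle", "oral_mucosa", "pancreas",
    "prostate_or_uterus", "small_intestine", "spleen", "thymus",
)

#: phantom organ label name -> ICRP tissue (or remainder organ).
DEFAULT_TISSUE_MAP: dict[str, str] = {
    "brain": "brain",
    "skin": "skin",
    "skull": "bone_surface",  # bone shell proxies the bone-surface tissue
    "salivary_gland_left": "salivary_glands",
    "salivary_gland_right": "salivary_glands",
    "soft_tissue": "muscle",  # generic head soft tissue -> remainder muscle
}

#: organs reported but never entering E (lens by ICRP rule; cord and table
#: are not ICRP 103 tissues).
EXCLUDED_FROM_E: tuple[str, ...] = (
    "eye_lens_left", "eye_lens_right", "spinal_cord", "table", "air",
)


@dataclass(frozen=True)
class OrganDoseReport:
    organ: str
    h_t: float                 # equivalent dose, units of the input grid
    w_r: float
    voxels: int
    mass_g: float
    engine: str
    rel_uncertainty: float | None = None  # type-A, MC only

    def __post_init__(self) -> None:
        if self.h_t < 0:
            raise ValueError("negative equivalent dose")


@dataclass(frozen=True)
class EffectiveDoseReport:
    effective: float
    terms: dict[str, tuple[float, float]]   # tissue -> (w_T, H_T)
    present: tuple[str, ...]
    absent: tuple[str, ...]
    excluded: tuple[str, ...]
    partial_body: bool = True


def absolute_voxel_dose(
    grid: DoseGrid, cf: CalibrationFactor, protocol: ScanProtocol
) -> DoseGrid:
    """Absolute dose in Gy: every voxel scaled by CF times the per-frame mAs.

    The engines normalize to one primary per frame, so the matching
    current-time product is the per-frame I * t, not the scan total.
    """
    if abs(cf.kvp - protocol.kvp) > 1e-9:
        raise ValueError(
            f"calibration factor is for {cf.kvp} kVp, protocol runs {protocol.kvp} kVp"
        )
    if grid.provenance.get("calibrated"):
        raise ValueError("dose grid is already calibrated")
    out = grid.scaled(cf.cf * protocol.mas_per_frame, note="CF*I*t")
    out.provenance["calibrated"] = True
    out.provenance["cf"] = cf.cf
    out.provenance["mas_per_frame"] = protocol.mas_per_frame
    return out


def organ_dose(
    grid: DoseGrid, phantom: VoxelPhantom, organ: str, w_r: float = 1.0
) -> OrganDoseReport:
    """Mass-weighted mean organ dose times the radiation weighting factor."""
    lab = phantom.label_of(organ)
    mask = phantom.labels == lab
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"organ {organ!r} has no voxels")
    rho = phantom.density_grid()[mask]  # voxel volume is uniform and cancels
    h_t = w_r * float(np.sum(grid.dose[mask] * rho) / rho.sum())
    rel = None
    if grid.batches is not None:
        bm = grid.batches[:, mask].mean(axis=1)
        nb = bm.shape[0]
        if nb > 1 and bm.mean() > 0:
            rel = float(bm.std(ddof=1) / np.sqrt(nb) / bm.mean())
    return OrganDoseReport(
        organ, h_t, w_r, n,
        phantom.organ_mass_g(organ),
        grid.provenance.get("engine", "unknown"),
        rel,
    )


def _canonical_tissue(name: str) -> tuple[str | None, str | None]:
    """(tissue, remainder-organ) classification of a report name."""
    if name in EXCLUDED_FROM_E:
        return None, None
    if name in TISSUE_WEIGHTS and name != "remainder":
        return name, None
    if name in REMAINDER_ORGANS:
        return "remainder", name
    if name in DEFAULT_TISSUE_MAP:
        target = DEFAULT_TISSUE_MAP[name]
        if target in REMAINDER_ORGANS:
            return "remainder", target
        return target, None
    raise KeyError(f"unknown organ name {name!r}")


def effective_dose(reports: list[OrganDoseReport]) -> EffectiveDoseReport:
    """E = sum_T w_T H_T over the tissues present.

    Multiple reports mapping to one tissue (left/right salivary glands) are
    combined mass-weighted; remainder organs enter through the ICRP 103
    arithmetic-mean rule.  Each phantom organ may appear at most once.
    """
    seen: set[str] = set()
    tissue_acc: dict[str, list[tuple[float, float]]] = {}
    remainder_acc: dict[str, float] = {}
    excluded = []
    for rep in reports:
        if rep.organ in seen:
            raise ValueError(f"duplicate organ {rep.organ!r}")
        seen.add(rep.organ)
        tissue, rem_organ = _canonical_tissue(rep.organ)
        if tissue is None:
            excluded.append(rep.organ)
            continue
        if rem_organ is not None:
            if rem_organ in remainder_acc:
                raise ValueError(f"duplicate remainder organ {rem_organ!r}")
            remainder_acc[rem_organ] = rep.h_t
        else:
            tissue_acc.setdefault(tissue, []).append((rep.h_t, rep.mass_g))

    terms: dict[str, tuple[float, float]] = {}
    for tissue, entries in tissue_acc.items():
        masses = sum(m for _, m in entries)
        h = (
            sum(h * m for h, m in entries) / masses
            if masses > 0
            else float(np.mean([h for h, _ in entries]))
        )
        terms[tissue] = (TISSUE_WEIGHTS[tissue], h)
    if remainder_acc:
        terms["remainder"] = (
            TISSUE_WEIGHTS["remainder"],
            float(np.mean(list(remainder_acc.values()))),
        )
    e = float(sum(w * h for w, h in terms.values()))
    present = tuple(sorted(terms))
    absent = tuple(sorted(set(TISSUE_WEIGHTS) - set(terms)))
    return EffectiveDoseReport(
        e, terms, present, absent, tuple(excluded), partial_body=bool(absent)
    )


@dataclass(frozen=True)
class PhantomDoseReport:
    """All organ doses of one simulation plus the effective dose."""

    organs: dict[str, OrganDoseReport]
    effective: EffectiveDoseReport
    unit: str  # "Gy/primary" (uncalibrated) or "Gy" / "mSv"


def phantom_dose_report(
    grid: DoseGrid, phantom: VoxelPhantom, unit: str = "Gy/primary"
) -> PhantomDoseReport:
    organs = {
        name: organ_dose(grid, phantom, name)
        for name in phantom.organ_names()
    }
    eff = effective_dose(list(organs.values()))
    return PhantomDoseReport(organs, eff, unit)


def dose_reduction(
    filtered: PhantomDoseReport, unfiltered: PhantomDoseReport
) -> dict[str, float]:
    """Relative reduction 1 - H_T(filtered)/H_T(unfiltered) per organ and
    for E (key ``"effective"``).

    Calibration and mAs cancel in the ratio, so uncalibrated grids are fine
    as long as both runs share phantom and protocol.
    """
    if set(filtered.organs) != set(unfiltered.organs):
        raise ValueError("reports cover different organ sets")
    out = {}
    for name, rep in filtered.organs.items():
        base = unfiltered.organs[name].h_t
        if base <= 0:
            raise ValueError(f"unfiltered dose is zero for {name!r}")
        out[name] = 1.0 - rep.h_t / base
    if unfiltered.effective.effective <= 0:
        raise ValueError("unfiltered effective dose is zero")
    out["effective"] = 1.0 - filtered.effective.effective / unfiltered.effective.effective
    return out


def theoretical_reduction(transmission: float, aperture_fraction: float) -> float:
    """Dose-area-product reduction of an ideal ROI filter.

    The filter attenuates the beam area outside the aperture to
    ``transmission``, so the DAP fraction removed is
    (1 - aperture_fraction) * (1 - transmission).  A geometric benchmark
    that ignores anatomy and scatter.
    """
    if not (0.0 <= transmission <= 1.0 and 0.0 <= aperture_fraction <= 1.0):
        raise ValueError("transmission and aperture fraction must lie in [0, 1]")
    return (1.0 - aperture_fraction) * (1.0 - transmission)
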