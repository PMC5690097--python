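"""Photon dose engines under the kerma approximation.

Two engines share one normalization ("per simulated primary": every frame
emits one photon isotropically at its source position, and doses are summed
over all frames of the scan, i.e. Gy per frame-primary):

* ``primary_kerma_dose`` — deterministic: exact Siddon line integrals of the
  primary fluence through the voxel grid, collision-kerma deposition at the
  voxel center, inverse-square and filter/prefilter attenuation.  No scatter.
* ``mc_photon_dose`` — analog Monte Carlo photon transport (Woodcock
  tracking, photoelectric / Klein-Nishina Compton / Rayleigh), secondary
  electrons not transported: energy transferred is deposited locally.

ROI filters enter both engines as per-ray attenuation weights (the weighted
attenuation rule); scatter generated inside the filters is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import ROIFilterSpec, ScanProtocol, _frame
from .instruments import carm_spectrum
from .materials import get_table
from .phantom import AIR_LABEL, IsocenterPlacement, VoxelPhantom
from .spectra import EnergySpectrum

__all__ = [
    "DoseGrid",
    "siddon_trace",
    "primary_kerma_dose",
    "mc_photon_dose",
    "air_kerma_at_isocenter",
]

GY_PER_KEV_PER_G = 1.602176634e-13

_N_FINE = 150  # 1-keV cross-section grid for the MC engine


@dataclass
class DoseGrid:
    """Per-voxel dose in Gy per simulated primary, with provenance."""

    dose: np.ndarray
    provenance: dict
    rel_uncertainty: np.ndarray | None = None
    batches: np.ndarray | None = None  # (n_batches, nx, ny, nz), MC only

    def __post_init__(self) -> None:
        if np.any(self.dose < 0):
            raise ValueError("negative dose")
        if (self.rel_uncertainty is None) != (self.batches is None):
            pass
        if self.provenance.get("engine") == "mc" and self.rel_uncertainty is None:
            raise ValueError("MC dose grids must carry uncertainties")

    def scaled(self, factor: float, note: str | None = None) -> "DoseGrid":
        prov = dict(self.provenance)
        if note:
            prov["scaling"] = note
        return DoseGrid(
            self.dose * factor, prov, self.rel_uncertainty,
            None if self.batches is None else self.batches * factor,
        )


def siddon_trace(phantom: VoxelPhantom, p0_mm, p1_mm):
    """Exact (voxel index, intersection length mm) list for segment p0->p1.

    Lengths sum to the in-grid chord length; the list is empty if the
    segment misses the grid.
    """
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("degenerate segment: p0 == p1")
    shape = np.array(phantom.shape, dtype=np.int64)
    nmax = int(shape.sum() + 4)
    idx = np.empty(nmax, dtype=np.int64)
    lens = np.empty(nmax)
    n = _kernels.traverse(
        p0, p1, np.asarray(phantom.origin), np.asarray(phantom.spacing),
        shape, idx, lens,
    )
    out = []
    for s in range(n):
        fl = int(idx[s])
        k = fl % phantom.shape[2]
        j = (fl // phantom.shape[2]) % phantom.shape[1]
        i = fl // (phantom.shape[1] * phantom.shape[2])
        out.append(((i, j, k), float(lens[s])))
    return out


def _label_arrays(phantom: VoxelPhantom, energies: np.ndarray, deposition: str):
    nlab = int(phantom.labels.max()) + 1
    rho = np.zeros(nlab)
    mu = np.zeros((nlab, energies.size))
    dep = np.zeros((nlab, energies.size))
    kind = "energy_absorption" if deposition == "kerma" else "attenuation"
    for lab, (_, mat) in phantom.label_map.items():
        if lab >= nlab:
            continue
        rho[lab] = phantom.densities.get(lab, mat.density)
        mu[lab] = mat.mu(energies)
        dep[lab] = mat.mu(energies, kind)
    return rho, mu, dep


def _projection_frames(protocol: ScanProtocol, iso: np.ndarray):
    nproj = protocol.projections
    sources = np.empty((nproj, 3))
    axes = np.empty((nproj, 3))
    us = np.empty((nproj, 3))
    vs = np.empty((nproj, 3))
    for p, ang in enumerate(protocol.angles_deg()):
        s, a, u, v = _frame(float(ang), iso, protocol)
        sources[p], axes[p], us[p], vs[p] = s, a, u, v
    return sources, axes, us, vs


def _filter_arrays(roi_filter: ROIFilterSpec | None, protocol: ScanProtocol,
                   energies: np.ndarray):
    if roi_filter is None:
        return -1.0, 0.0, 0.0, 0.0, np.zeros(energies.size)
    r_ap = roi_filter.aperture_radius_cm(protocol.fov_cm) * 10.0
    cx, cy = (10.0 * c for c in roi_filter.aperture_center_cm)
    od_per_mm = roi_filter.material.mu(energies) * roi_filter.material.density / 10.0
    return r_ap, cx, cy, roi_filter.thickness_mm, od_per_mm


def _resolve_spectrum(protocol: ScanProtocol, spectrum: EnergySpectrum | None,
                      rebin_kev: float) -> EnergySpectrum:
    if spectrum is None:
        spectrum = carm_spectrum(protocol.kvp)
    return spectrum.rebin(rebin_kev)


def primary_kerma_dose(
    phantom: VoxelPhantom,
    protocol: ScanProtocol,
    isocenter: IsocenterPlacement,
    roi_filter: ROIFilterSpec | None = None,
    spectrum: EnergySpectrum | None = None,
    deposition: str = "kerma",
    energy_rebin_kev: float = 2.0,
) -> DoseGrid:
    """Deterministic primary-fluence collision-kerma dose, Gy per primary.

    ``deposition="kerma"`` deposits E * mu_en/rho (collision kerma);
    ``"total"`` deposits E * mu/rho, the absorbed energy if every interaction
    were locally absorbing — the quantity the scatter-free MC mode estimates.
    """
    iso = isocenter.as_array()
    if not phantom.contains(iso):
        raise ValueError("isocenter lies outside the phantom bounding box")
    if deposition not in ("kerma", "total"):
        raise ValueError("deposition must be 'kerma' or 'total'")
    spec = _resolve_spectrum(protocol, spectrum, energy_rebin_kev)
    energies = spec.energies
    weights = spec.weights / spec.weights.sum()
    rho, mu, dep = _label_arrays(phantom, energies, deposition)
    sources, axes, us, vs = _projection_frames(protocol, iso)
    r_ap, cx, cy, th, od_mm = _filter_arrays(roi_filter, protocol, energies)
    compute = np.argwhere(phantom.labels != AIR_LABEL).astype(np.int64)
    dose = np.zeros(phantom.shape)
    if protocol.projections > 0 and compute.size:
        _kernels.primary_dose_kernel(
            phantom.labels, compute, rho, mu, dep,
            energies.astype(float), weights.astype(float),
            np.asarray(phantom.origin, dtype=float),
            np.asarray(phantom.spacing, dtype=float),
            sources, axes, us, vs,
            protocol.source_imager_cm * 10.0,
            protocol.fov_cm[0] * 10.0 / 2.0, protocol.fov_cm[1] * 10.0 / 2.0,
            r_ap, cx, cy, th, od_mm,
            dose,
        )
    dose *= GY_PER_KEV_PER_G
    prov = {
        "engine": "primary_kerma",
        "deposition": deposition,
        "kvp": spec.kvp,
        "projections": protocol.projections,
        "roi_filter": None if roi_filter is None else {
            "material": roi_filter.material.name,
            "thickness_mm": roi_filter.thickness_mm,
            "aperture_fraction": roi_filter.aperture_fraction,
        },
        "energy_rebin_kev": energy_rebin_kev,
    }
    return DoseGrid(dose, prov)


def _mc_cross_sections(phantom: VoxelPhantom):
    """Per-label 1-keV-grid linear attenuation and interaction fractions."""
    e = np.arange(1.0, _N_FINE + 1.0)
    nlab = int(phantom.labels.max()) + 1
    mu_lin = np.zeros((nlab, _N_FINE))
    p_ray = np.zeros((nlab, _N_FINE))
    p_comp = np.zeros((nlab, _N_FINE))
    k = e / 511.0
    re2 = 7.9407877e-26  # classical electron radius squared, cm^2
    NA = 6.02214076e23
    sig_kn = 2.0 * np.pi * re2 * (
        (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log(1 + 2 * k) / k)
        + np.log(1 + 2 * k) / (2 * k)
        - (1 + 3 * k) / (1 + 2 * k) ** 2
    )
    for lab, (_, mat) in phantom.label_map.items():
        if lab >= nlab:
            continue
        rho = phantom.densities.get(lab, mat.density)
        mu_mass = mat.mu(e)
        mu_lin[lab] = mu_mass * rho
        kn_mass = sig_kn * NA * mat.z_over_a
        comp = np.clip(kn_mass / mu_mass, 0.0, 1.0)
        # crude coherent fraction; only redirects photons, fidelity limit
        ray = np.minimum(0.05 * (30.0 / e) ** 1.5, 0.9 * (1.0 - comp))
        p_comp[lab] = comp
        p_ray[lab] = np.clip(ray, 0.0, 1.0)
    return mu_lin, p_ray, p_comp


def _rect_solid_angle(half_u: float, half_v: float, dist: float) -> float:
    a, b = 2 * half_u, 2 * half_v
    return 4.0 * np.arctan(a * b / (2 * dist * np.sqrt(4 * dist**2 + a**2 + b**2)))


def mc_photon_dose(
    phantom: VoxelPhantom,
    protocol: ScanProtocol,
    isocenter: IsocenterPlacement,
    roi_filter: ROIFilterSpec | None = None,
    spectrum: EnergySpectrum | None = None,
    histories: int = 1_000_000,
    seed: int = 0,
    n_batches: int = 10,
    force_photoelectric: bool = False,
) -> DoseGrid:
    """Analog MC photon dose, Gy per primary, with type-A uncertainties.

    Uncertainties are batch estimates: histories are split into
    ``n_batches`` independent runs and the per-voxel standard error of the
    batch means is reported; organ-level errors should be recomputed from
    ``batches`` (voxel errors are correlated within a history).
    """
    if histories < 1:
        raise ValueError("histories must be >= 1")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    iso = isocenter.as_array()
    if not phantom.contains(iso):
        raise ValueError("isocenter lies outside the phantom bounding box")
    spec = _resolve_spectrum(protocol, spectrum, 1.0)
    # emission CDF on the fine grid
    pdf = np.zeros(_N_FINE)
    for e_val, w in zip(spec.energies, spec.weights):
        idx = min(max(int(round(e_val)) - 1, 0), _N_FINE - 1)
        pdf[idx] += w
    cdf = np.cumsum(pdf) / pdf.sum()

    mu_lin, p_ray, p_comp = _mc_cross_sections(phantom)
    mu_max = mu_lin.max(axis=0)
    sources, axes, us, vs = _projection_frames(protocol, iso)
    e_fine = np.arange(1.0, _N_FINE + 1.0)
    r_ap, cx, cy, th, od_mm = _filter_arrays(roi_filter, protocol, e_fine)

    sid = protocol.source_imager_cm * 10.0
    half_u = protocol.fov_cm[0] * 10.0 / 2.0
    half_v = protocol.fov_cm[1] * 10.0 / 2.0
    half_diag = np.sqrt(half_u**2 + half_v**2)
    cos_max = sid / np.sqrt(sid**2 + half_diag**2)
    omega_frac = _rect_solid_angle(half_u, half_v, sid) / (4.0 * np.pi)

    rho_grid = phantom.density_grid()
    mass_g = rho_grid * phantom.voxel_volume_cm3
    mass_g[mass_g == 0] = np.inf  # no mass, no dose

    n_batches = max(1, min(n_batches, histories))
    per_batch = histories // n_batches
    seeds = np.random.SeedSequence(seed).generate_state(n_batches) % (2**31)
    batch_doses = np.zeros((n_batches,) + phantom.shape, dtype=np.float32)
    emitted = 0.0
    deposited = 0.0
    rho_lab = np.zeros(int(phantom.labels.max()) + 1)
    for lab, (_, mat) in phantom.label_map.items():
        rho_lab[lab] = phantom.densities.get(lab, mat.density)
    for b in range(n_batches):
        nh = per_batch + (histories % n_batches if b == n_batches - 1 else 0)
        edep = np.zeros(phantom.shape)
        emitted += _kernels.mc_photon_kernel(
            phantom.labels, rho_lab, mu_lin, p_ray, p_comp, mu_max, cdf,
            np.asarray(phantom.origin, dtype=float),
            np.asarray(phantom.spacing, dtype=float),
            sources, axes, us, vs,
            sid, half_u, half_v, cos_max, omega_frac,
            r_ap, cx, cy, th, od_mm,
            nh, int(seeds[b]), force_photoelectric, edep,
        )
        deposited += edep.sum()
        # histories are spread over the frames: scale to one primary per frame
        batch_doses[b] = (
            edep / nh * protocol.projections / mass_g * GY_PER_KEV_PER_G
        ).astype(np.float32)
    dose = batch_doses.mean(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = batch_doses.std(axis=0, ddof=1) / np.sqrt(n_batches) if n_batches > 1 \
            else np.zeros(phantom.shape, dtype=np.float32)
        rel = np.where(dose > 0, sem / np.maximum(dose, 1e-300), 0.0)
    prov = {
        "engine": "mc",
        "kvp": spec.kvp,
        "projections": protocol.projections,
        "histories": histories,
        "seed": seed,
        "n_batches": n_batches,
        "emitted_kev_per_history": emitted / histories,
        "deposited_kev_per_history": deposited / histories,
        "force_photoelectric": force_photoelectric,
        "roi_filter": None if roi_filter is None else {
            "material": roi_filter.material.name,
            "thickness_mm": roi_filter.thickness_mm,
            "aperture_fraction": roi_filter.aperture_fraction,
        },
    }
    return DoseGrid(dose, prov, rel_uncertainty=np.asarray(rel, dtype=float),
                    batches=batch_doses)


def air_kerma_at_isocenter(
    protocol: ScanProtocol,
    roi_filter: ROIFilterSpec | None = None,
    spectrum: EnergySpectrum | None = None,
    energy_rebin_kev: float = 1.0,
) -> float:
    """Free-in-air kerma at the isocenter, Gy per simulated primary.

    No phantom and no table: the calibration-simulation geometry, summed
    over all projections of the protocol (doubling the number of frames
    doubles the result).
    """
    spec = _resolve_spectrum(protocol, spectrum, energy_rebin_kev)
    w = spec.weights / spec.weights.sum()
    muen_air = get_table("Air")(spec.energies, "energy_absorption")
    r_cm = protocol.source_isocenter_cm
    per_proj_unfiltered = float(
        np.sum(w * spec.energies * muen_air) / (4.0 * np.pi * r_cm**2)
    )
    total = 0.0
    for _ in range(protocol.projections):
        contrib = per_proj_unfiltered
        if roi_filter is not None:
            # central ray: inside the aperture unless the aperture is off-center
            cx, cy = roi_filter.aperture_center_cm
            r_ap = roi_filter.aperture_radius_cm(protocol.fov_cm)
            if cx * cx + cy * cy > r_ap * r_ap:
                t = np.exp(
                    -roi_filter.material.mu(spec.energies)
                    * roi_filter.material.density
                    * roi_filter.thickness_mm / 10.0
                )
                contrib = float(
                    np.sum(w * spec.energies * muen_air * t)
                    / (4.0 * np.pi * r_cm**2)
                )
        total += contrib
    return total * GY_PER_KEV_PER_G
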