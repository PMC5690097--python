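"""Experiment driver: dose pipeline over a parameter grid.

Produces a tidy long-format table over (tube voltage, filter thickness,
aperture, isocenter, table) with one row per organ plus one for the
effective dose, including relative reductions against the matching
unfiltered baseline and the theoretical dose-area-product benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import TABLE_SLAB_THICKNESS_MM
from .dosimetry import (
    PhantomDoseReport,
    dose_reduction,
    phantom_dose_report,
    theoretical_reduction,
)
from .geometry import ROIFilterSpec, ScanProtocol
from .instruments import carm_spectrum
from .phantom import IsocenterPlacement, VoxelPhantom, attach_table
from .spectra import FilterStack, kerma_weighted_transmission
from .transport import mc_photon_dose, primary_kerma_dose

__all__ = ["SweepGrid", "run_sweep", "check_sweep"]

#: published effective Gd2O2S thicknesses for 1-4 screen layers, mm
DEFAULT_THICKNESSES = (0.0, 0.102, 0.204, 0.306, 0.408)


@dataclass(frozen=True)
class SweepGrid:
    kvps: tuple[float, ...] = (80.0, 90.0, 100.0)
    thicknesses_mm: tuple[float, ...] = DEFAULT_THICKNESSES
    apertures: tuple[float | None, ...] = (0.2, 0.4, None)
    isocenter_zs_mm: tuple[float, ...] = (1580.0, 1550.0)
    table: tuple[bool, ...] = (False, True)
    isocenter_xy_mm: tuple[float, float] = (265.0, 90.0)


def _single_run(
    phantom, protocol, iso, roi, engine, histories, seed, energy_rebin_kev
) -> PhantomDoseReport:
    if engine == "primary_kerma":
        grid = primary_kerma_dose(
            phantom, protocol, iso, roi_filter=roi,
            energy_rebin_kev=energy_rebin_kev,
        )
    elif engine == "mc":
        grid = mc_photon_dose(
            phantom, protocol, iso, roi_filter=roi,
            histories=histories, seed=seed,
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return phantom_dose_report(grid, phantom)


def run_sweep(
    phantom: VoxelPhantom,
    grid: SweepGrid = SweepGrid(),
    protocol: ScanProtocol = ScanProtocol(),
    table_density: float = 0.484,
    table_thickness_mm: float = TABLE_SLAB_THICKNESS_MM,
    engine: str = "primary_kerma",
    histories: int = 1_000_000,
    seed: int = 0,
    energy_rebin_kev: float = 2.0,
) -> pd.DataFrame:
    """Run the dose pipeline over the Cartesian grid and tidy the results.

    A cell with thickness 0 or aperture None is the unfiltered baseline;
    reductions are computed within each (kvp, isocenter, table) block
    against its baseline.
    """
    phantoms = {False: phantom}
    rows = []
    for with_table in grid.table:
        if with_table and True not in phantoms:
            phantoms[True] = attach_table(
                phantom, table_density, table_thickness_mm
            )
        ph = phantoms[with_table]
        for kvp in grid.kvps:
            proto = ScanProtocol(
                kvp=kvp, tube_current_ma=protocol.tube_current_ma,
                exposure_time_ms=protocol.exposure_time_ms,
                projections=protocol.projections,
                angular_spacing_deg=protocol.angular_spacing_deg,
                start_angle_deg=protocol.start_angle_deg,
                source_isocenter_cm=protocol.source_isocenter_cm,
                source_imager_cm=protocol.source_imager_cm,
                fov_cm=protocol.fov_cm,
            )
            spec = carm_spectrum(kvp)
            for iso_z in grid.isocenter_zs_mm:
                iso = IsocenterPlacement(*grid.isocenter_xy_mm, iso_z)
                baseline = _single_run(
                    ph, proto, iso, None, engine, histories, seed,
                    energy_rebin_kev,
                )
                cells = [(0.0, None, baseline)]
                for th in grid.thicknesses_mm:
                    if th == 0.0:
                        continue
                    for ap in grid.apertures:
                        if ap is None:
                            continue
                        roi = ROIFilterSpec.gadolinium(th, ap)
                        rep = _single_run(
                            ph, proto, iso, roi, engine, histories, seed,
                            energy_rebin_kev,
                        )
                        cells.append((th, ap, rep))
                for th, ap, rep in cells:
                    red = dose_reduction(rep, baseline)
                    if ap is not None and th > 0:
                        trans = kerma_weighted_transmission(
                            spec,
                            ROIFilterSpec.gadolinium(th, ap).slab(),
                        )
                        theo = theoretical_reduction(trans, ap)
                    else:
                        theo = 0.0
                    entries = [
                        (name, r.h_t, red[name]) for name, r in rep.organs.items()
                    ] + [("effective", rep.effective.effective, red["effective"])]
                    for organ, h, r in entries:
                        rows.append({
                            "kvp": kvp,
                            "thickness_mm": th,
                            "aperture": np.nan if ap is None else ap,
                            "isocenter_z_mm": iso_z,
                            "table": with_table,
                            "organ": organ,
                            "dose_per_primary": h,
                            "reduction": r,
                            "theoretical_reduction": theo,
                            "engine": engine,
                        })
    return pd.DataFrame(rows)


def check_sweep(df: pd.DataFrame) -> list[str]:
    """Consistency checks on a sweep table; returns violation messages.

    Checks that every organ's reduction is non-decreasing in filter
    thickness at fixed aperture, and that the smaller aperture never yields
    a lower effective-dose reduction than the larger one at equal thickness.
    """
    problems = []
    tol = 1e-9
    block_keys = ["kvp", "isocenter_z_mm", "table", "organ"]
    filt = df[df["aperture"].notna() & (df["thickness_mm"] > 0)]
    for key, sub in filt.groupby(block_keys + ["aperture"]):
        sub = sub.sort_values("thickness_mm")
        red = sub["reduction"].to_numpy()
        if np.any(np.diff(red) < -tol):
            problems.append(f"reduction not monotone in thickness at {key}")
    eff = filt[filt["organ"] == "effective"]
    for key, sub in eff.groupby(["kvp", "isocenter_z_mm", "table", "thickness_mm"]):
        by_ap = sub.set_index("aperture")["reduction"]
        small, large = by_ap.index.min(), by_ap.index.max()
        if small != large and by_ap[small] < by_ap[large] - tol:
            problems.append(
                f"aperture dominance violated at {key}: "
                f"{small:.2f} gives {by_ap[small]:.4f} < {by_ap[large]:.4f}"
            )
    return problems
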