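"""Cone-beam source orbit, ROI-filter aperture projection, per-ray paths.

Angle convention: source angles are measured in the axial (X-Y) plane and
increase clockwise when viewed from cranial, with the source at patient
left for angle 0 and anterior (+Y) for angle 90.  The published 106-318
frame-angle range conflicts with its own protocol arithmetic
(106 + 105 x 2 = 316); the protocol arithmetic wins.  Under this convention
the 212-degree arc is centered anterior to a supine patient, so the source
clears the posterior head-rest for most of the rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import Material, predefined
from .spectra import FilterStack

__all__ = ["ScanProtocol", "ROIFilterSpec", "source_positions", "filter_path_length"]


@dataclass(frozen=True)
class ScanProtocol:
    """Rotational acquisition protocol (published defaults)."""

    kvp: float = 100.0
    tube_current_ma: float = 250.0
    exposure_time_ms: float = 6.3
    projections: int = 106
    angular_spacing_deg: float = 2.0
    start_angle_deg: float = 106.0
    source_isocenter_cm: float = 70.0
    source_imager_cm: float = 110.0
    fov_cm: tuple[float, float] = (20.0, 20.0)

    def __post_init__(self) -> None:
        if self.projections < 1:
            raise ValueError("need at least one projection")
        if self.angular_spacing_deg <= 0:
            raise ValueError("angular spacing must be positive")
        if self.source_isocenter_cm <= 0 or self.source_imager_cm <= 0:
            raise ValueError("distances must be positive")

    @property
    def mas_per_frame(self) -> float:
        return self.tube_current_ma * self.exposure_time_ms / 1000.0

    @property
    def total_mas(self) -> float:
        return self.mas_per_frame * self.projections

    def angles_deg(self) -> np.ndarray:
        return self.start_angle_deg + self.angular_spacing_deg * np.arange(
            self.projections
        )


@dataclass(frozen=True)
class ROIFilterSpec:
    """Attenuating sheet with a circular aperture, characterized by its
    detector-plane projection.

    ``aperture_fraction`` is by default the aperture AREA as a fraction of
    the detector field of view (``interpretation="area"``); the alternative
    ``"linear"`` reads it as a diameter fraction of the FOV side.
    """

    material: Material
    thickness_mm: float
    aperture_fraction: float
    interpretation: str = "area"
    aperture_center_cm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.aperture_fraction < 1.0):
            raise ValueError("aperture fraction must lie strictly in (0, 1)")
        if self.thickness_mm < 0:
            raise ValueError("thickness must be non-negative")
        if self.interpretation not in ("area", "linear"):
            raise ValueError("interpretation must be 'area' or 'linear'")

    def aperture_radius_cm(self, fov_cm: tuple[float, float]) -> float:
        ax, ay = fov_cm
        if self.interpretation == "area":
            return float(np.sqrt(self.aperture_fraction * ax * ay / np.pi))
        return float(self.aperture_fraction * min(ax, ay) / 2.0)

    @staticmethod
    def gadolinium(thickness_mm: float, aperture_fraction: float, **kw) -> "ROIFilterSpec":
        return ROIFilterSpec(
            predefined()["gadolinium_oxysulfide"], thickness_mm, aperture_fraction, **kw
        )

    def slab(self) -> FilterStack:
        """The closed (outside-aperture) part of the filter as a slab."""
        return FilterStack(((self.material, self.thickness_mm),))


def _frame(angle_deg: float, isocenter_mm: np.ndarray, protocol: ScanProtocol):
    """Source point (mm), beam axis, and detector in-plane axes u, v."""
    phi = np.radians(angle_deg)
    radial = np.array([np.cos(phi), -np.sin(phi), 0.0])
    source = isocenter_mm + protocol.source_isocenter_cm * 10.0 * radial
    axis = -radial
    u = np.cross(axis, np.array([0.0, 0.0, 1.0]))
    u /= np.linalg.norm(u)
    v = np.cross(u, axis)
    return source, axis, u, v


def source_positions(
    protocol: ScanProtocol, isocenter_mm
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """(angle deg, source point mm, unit beam axis) for every projection."""
    iso = np.asarray(isocenter_mm, dtype=float)
    out = []
    for ang in protocol.angles_deg():
        source, axis, _, _ = _frame(ang, iso, protocol)
        out.append((float(ang), source, axis))
    return out


def filter_path_length(
    roi_filter: ROIFilterSpec,
    source_mm,
    direction,
    protocol: ScanProtocol,
    angle_deg: float,
    isocenter_mm,
) -> float:
    """mm of filter material traversed by the ray, 0 through the aperture.

    The filter is mounted near the source with its normal along the beam
    axis; a ray is inside the aperture iff its detector-plane intersection
    falls inside the projected aperture circle, and otherwise crosses the
    slab with path thickness / cos(obliquity).
    """
    iso = np.asarray(isocenter_mm, dtype=float)
    src, axis, u, v = _frame(angle_deg, iso, protocol)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ca = float(np.dot(d, axis))
    if ca <= 1e-12:
        raise ValueError("ray parallel to (or away from) the detector plane")
    sid_mm = protocol.source_imager_cm * 10.0
    hit = np.asarray(source_mm, dtype=float) + d * (sid_mm / ca)
    center = src + axis * sid_mm
    acx, acy = (10.0 * c for c in roi_filter.aperture_center_cm)
    du = float(np.dot(hit - center, u)) - acx
    dv = float(np.dot(hit - center, v)) - acy
    r_ap = roi_filter.aperture_radius_cm(protocol.fov_cm) * 10.0
    if du * du + dv * dv <= r_ap * r_ap:
        return 0.0
    return roi_filter.thickness_mm / ca
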