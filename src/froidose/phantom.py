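"""Labeled voxel head phantom: data model, synthetic generator, table, I/O.

The synthetic head stands in for a reference anthropomorphic phantom that is
not redistributable: an ellipsoidal head and cylindrical neck of soft tissue
with a skin shell, a cranial bone shell enclosing the brain, anterior eye
lenses, infero-lateral salivary glands, and a posterior spinal cord.  The
grid axes are X (left-right), Y (anterior-posterior, +Y anterior) and
Z (caudo-cranial); world position of voxel (i,j,k) center is
origin + (index + 0.5) * spacing.

Storage is MetaImage (MHD header + RAW grid) written through SimpleITK with
a JSON sidecar for the label map, materials and per-label densities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .materials import Material, predefined

__all__ = [
    "VoxelPhantom",
    "IsocenterPlacement",
    "make_synthetic_head",
    "attach_table",
    "read_phantom",
    "write_phantom",
    "AIR_LABEL",
    "TABLE_LABEL",
]

AIR_LABEL = 0
TABLE_LABEL = 10

_MIRROR_PAIRS = (
    ("eye_lens_left", "eye_lens_right"),
    ("salivary_gland_left", "salivary_gland_right"),
)


@dataclass(frozen=True)
class IsocenterPlacement:
    """Isocenter in phantom world coordinates, mm."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class VoxelPhantom:
    labels: np.ndarray                       # int16, shape (nx, ny, nz)
    spacing: tuple[float, float, float]      # mm
    origin: tuple[float, float, float]       # mm, corner of voxel (0,0,0)
    label_map: dict[int, tuple[str, Material]]
    densities: dict[int, float]              # g/cm^3 per label
    metadata: dict = field(default_factory=dict)
    #: optional per-voxel density override (g/cm^3); the transport engines
    #: use per-label densities, but dosimetry honors this when present
    density_array: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label map")
        for lab in present:
            if lab != AIR_LABEL and self.densities.get(lab, 0.0) <= 0:
                raise ValueError(f"non-air label {lab} needs a positive density")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + np.asarray(self.spacing) * np.asarray(self.labels.shape)
        return lo, hi

    def contains(self, point_mm) -> bool:
        lo, hi = self.bounding_box()
        p = np.asarray(point_mm, dtype=float)
        return bool(np.all(p >= lo) and np.all(p <= hi))

    # -- organs -------------------------------------------------------------
    def label_of(self, organ: str) -> int:
        for lab, (name, _) in self.label_map.items():
            if name == organ:
                return lab
        raise KeyError(f"no organ named {organ!r}")

    def organ_names(self, include_air: bool = False) -> list[str]:
        return [
            name
            for lab, (name, _) in sorted(self.label_map.items())
            if include_air or lab != AIR_LABEL
        ]

    def organ_mask(self, organ: str) -> np.ndarray:
        return self.labels == self.label_of(organ)

    def organ_volume_cm3(self, organ: str) -> float:
        return float(self.organ_mask(organ).sum()) * self.voxel_volume_cm3

    def organ_mass_g(self, organ: str) -> float:
        mask = self.organ_mask(organ)
        return float(self.density_grid()[mask].sum()) * self.voxel_volume_cm3

    def density_grid(self) -> np.ndarray:
        if self.density_array is not None:
            return np.asarray(self.density_array, dtype=np.float64)
        rho = np.zeros(self.labels.shape, dtype=np.float64)
        for lab in np.unique(self.labels):
            rho[self.labels == lab] = self.densities.get(int(lab), 0.0)
        return rho

    def total_mass_g(self) -> float:
        return sum(self.organ_mass_g(n) for n in self.organ_names())

    def mirror_x(self) -> "VoxelPhantom":
        """Mirror in X, swapping left/right organ labels."""
        flipped = self.labels[::-1, :, :].copy()
        swap = {}
        for left, right in _MIRROR_PAIRS:
            try:
                swap[self.label_of(left)] = self.label_of(right)
                swap[self.label_of(right)] = self.label_of(left)
            except KeyError:
                continue
        out = flipped.copy()
        for src, dst in swap.items():
            out[flipped == src] = dst
        return VoxelPhantom(
            out, self.spacing, self.origin, dict(self.label_map),
            dict(self.densities), dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# synthetic head generator


def _default_anatomy() -> dict:
    """Anatomical sizes (mm) of the synthetic head; all configurable."""
    return {
        "head_center": (265.0, 90.0, 1600.0),
        "head_semi_axes": (78.0, 92.0, 108.0),
        "skin_thickness": 4.0,
        "skull_center": (265.0, 88.0, 1612.0),
        "skull_outer_semi_axes": (68.0, 80.0, 88.0),
        "skull_thickness": 6.0,
        "neck_center_xy": (265.0, 80.0),
        "neck_radius": 52.0,
        "neck_top_z": 1540.0,
        "eye_lens_radius": 4.5,
        "eye_lens_dx": 31.0,
        "eye_lens_y": 160.0,
        "eye_lens_z": 1580.0,
        "salivary_semi_axes": (13.0, 16.0, 20.0),
        "salivary_dx": 45.0,
        "salivary_y": 70.0,
        "salivary_z": 1535.0,
        "cord_radius": 5.0,
        "cord_xy": (265.0, 55.0),
        "cord_top_z": 1565.0,
        "extent_lo": (170.0, -12.0, 1440.0),
        "extent_hi": (360.0, 196.0, 1720.0),
    }


def _ellipsoid(xc, yc, zc, a, b, c, X, Y, Z):
    return ((X - xc) / a) ** 2 + ((Y - yc) / b) ** 2 + ((Z - zc) / c) ** 2 <= 1.0


def make_synthetic_head(
    voxel_mm: float = 2.5,
    seed: int = 0,
    jitter_frac: float = 0.0,
    params: dict | None = None,
) -> VoxelPhantom:
    """Deterministic labeled head-and-neck phantom.

    ``jitter_frac`` optionally perturbs the anatomical sizes by a uniform
    relative amount drawn from ``seed`` (0 reproduces the reference anatomy,
    which is mirror-symmetric in X).  Organ volumes and centers are returned
    in ``metadata``.
    """
    if not (1.0 <= voxel_mm <= 5.0):
        raise ValueError("voxel size must lie in [1, 5] mm")
    p = _default_anatomy()
    if params:
        p.update(params)

    rng = np.random.default_rng(seed)
    if jitter_frac:
        scale = lambda: 1.0 + rng.uniform(-jitter_frac, jitter_frac)  # noqa: E731
        for key in ("head_semi_axes", "skull_outer_semi_axes", "salivary_semi_axes"):
            p[key] = tuple(v * scale() for v in p[key])
        for key in ("eye_lens_radius", "neck_radius", "cord_radius"):
            p[key] = p[key] * scale()

    lo = np.asarray(p["extent_lo"], dtype=float)
    hi = np.asarray(p["extent_hi"], dtype=float)
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel_mm)) for i in range(3))
    hc, hs = np.asarray(p["head_center"]), np.asarray(p["head_semi_axes"])
    if np.any(hc - hs < lo) or np.any(hc + hs > hi):
        raise ValueError("voxel grid too small to contain the head")

    xs = lo[0] + (np.arange(shape[0]) + 0.5) * voxel_mm
    ys = lo[1] + (np.arange(shape[1]) + 0.5) * voxel_mm
    zs = lo[2] + (np.arange(shape[2]) + 0.5) * voxel_mm
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    labels = np.zeros(shape, dtype=np.int16)

    head = _ellipsoid(*hc, *hs, X, Y, Z)
    nx0, ny0 = p["neck_center_xy"]
    neck = (
        ((X - nx0) ** 2 + (Y - ny0) ** 2 <= p["neck_radius"] ** 2)
        & (Z <= p["neck_top_z"])
    )
    body = head | neck
    labels[body] = 1  # soft tissue

    t = p["skin_thickness"]
    head_inner = _ellipsoid(*hc, *(hs - t), X, Y, Z)
    neck_inner = (
        ((X - nx0) ** 2 + (Y - ny0) ** 2 <= (p["neck_radius"] - t) ** 2)
        & (Z <= p["neck_top_z"])
    )
    labels[body & ~(head_inner | neck_inner)] = 2  # skin

    sc, ss = np.asarray(p["skull_center"]), np.asarray(p["skull_outer_semi_axes"])
    skull = _ellipsoid(*sc, *ss, X, Y, Z)
    brain = _ellipsoid(*sc, *(ss - p["skull_thickness"]), X, Y, Z)
    labels[skull & body] = 3
    labels[brain & body] = 4

    cx, cy = p["cord_xy"]
    cord = ((X - cx) ** 2 + (Y - cy) ** 2 <= p["cord_radius"] ** 2) & (
        Z <= p["cord_top_z"]
    )
    labels[cord & body] = 9

    ga, gb, gc_ = p["salivary_semi_axes"]
    for sign, lab in ((+1, 7), (-1, 8)):
        gx = 265.0 + sign * p["salivary_dx"]
        gland = _ellipsoid(gx, p["salivary_y"], p["salivary_z"], ga, gb, gc_, X, Y, Z)
        labels[gland & body] = lab

    r = p["eye_lens_radius"]
    for sign, lab in ((+1, 5), (-1, 6)):
        ex = 265.0 + sign * p["eye_lens_dx"]
        lens = (
            (X - ex) ** 2 + (Y - p["eye_lens_y"]) ** 2 + (Z - p["eye_lens_z"]) ** 2
            <= r**2
        )
        labels[lens & body] = lab

    mats = predefined()
    label_map = {
        AIR_LABEL: ("air", mats["air"]),
        1: ("soft_tissue", mats["soft_tissue"]),
        2: ("skin", mats["skin"]),
        3: ("skull", mats["cortical_bone"]),
        4: ("brain", mats["brain"]),
        5: ("eye_lens_left", mats["eye_lens"]),
        6: ("eye_lens_right", mats["eye_lens"]),
        7: ("salivary_gland_left", mats["salivary_gland"]),
        8: ("salivary_gland_right", mats["salivary_gland"]),
        9: ("spinal_cord", mats["spinal_cord"]),
    }
    densities = {lab: mat.density for lab, (_, mat) in label_map.items()}

    for lab, (name, _) in label_map.items():
        if lab != AIR_LABEL and not np.any(labels == lab):
            raise ValueError(f"organ {name!r} empty: grid or anatomy inconsistent")

    vox_vol = voxel_mm**3 / 1000.0
    meta = {"seed": int(seed), "voxel_mm": float(voxel_mm), "organs": {}}
    for lab, (name, _) in label_map.items():
        if lab == AIR_LABEL:
            continue
        mask = labels == lab
        idx = np.argwhere(mask)
        center = lo + (idx.mean(axis=0) + 0.5) * voxel_mm
        meta["organs"][name] = {
            "volume_cm3": float(mask.sum() * vox_vol),
            "center_mm": [float(v) for v in center],
        }

    return VoxelPhantom(
        labels, (voxel_mm,) * 3, tuple(lo), label_map, densities, meta
    )


def attach_table(
    phantom: VoxelPhantom,
    density: float,
    thickness_mm: float,
    gap_mm: float = 10.0,
) -> VoxelPhantom:
    """Extend the grid posteriorly (-Y) with a rectangular carbon slab.

    The slab spans the X-Z footprint of the non-air content, separated from
    the posterior surface by ``gap_mm`` of air; original labels are untouched.
    """
    if thickness_mm < 0 or gap_mm < 0:
        raise ValueError("thickness and gap must be non-negative")
    if thickness_mm == 0:
        return phantom
    sx, sy, sz = phantom.spacing
    n_gap = int(np.ceil(gap_mm / sy))
    n_slab = max(1, int(round(thickness_mm / sy)))
    nx, ny, nz = phantom.labels.shape
    new = np.zeros((nx, ny + n_gap + n_slab, nz), dtype=np.int16)
    new[:, n_gap + n_slab :, :] = phantom.labels

    body = phantom.labels != AIR_LABEL
    xs = np.any(body, axis=(1, 2))
    zs = np.any(body, axis=(0, 1))
    if not xs.any():
        raise ValueError("phantom contains no material to put on a table")
    x0, x1 = np.flatnonzero(xs)[[0, -1]]
    z0, z1 = np.flatnonzero(zs)[[0, -1]]
    new[x0 : x1 + 1, :n_slab, z0 : z1 + 1] = TABLE_LABEL

    mats = predefined()
    carbon = Material("table_carbon", (("C", 1.0),), density)
    label_map = dict(phantom.label_map)
    label_map[TABLE_LABEL] = ("table", carbon)
    densities = dict(phantom.densities)
    densities[TABLE_LABEL] = density
    origin = (
        phantom.origin[0],
        phantom.origin[1] - (n_gap + n_slab) * sy,
        phantom.origin[2],
    )
    meta = dict(phantom.metadata)
    meta["table"] = {
        "density_g_cm3": float(density),
        "thickness_mm": float(n_slab * sy),
        "gap_mm": float(n_gap * sy),
    }
    return VoxelPhantom(new, phantom.spacing, origin, label_map, densities, meta)


# ---------------------------------------------------------------------------
# I/O: MetaImage + JSON sidecar


def write_phantom(phantom: VoxelPhantom, path: str | Path) -> None:
    path = Path(path)
    if path.suffix != ".mhd":
        raise ValueError("phantom path must end in .mhd")
    img = sitk.GetImageFromArray(np.transpose(phantom.labels, (2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in phantom.spacing))
    # ITK origin is the center of voxel (0,0,0)
    img.SetOrigin(tuple(o + 0.5 * s for o, s in zip(phantom.origin, phantom.spacing)))
    sitk.WriteImage(img, str(path))
    sidecar = {
        "labels": {
            str(lab): {
                "organ": name,
                "material": {
                    "name": mat.name,
                    "composition": list(map(list, mat.composition)),
                    "density": mat.density,
                },
                "density": phantom.densities.get(lab),
            }
            for lab, (name, mat) in phantom.label_map.items()
        },
        "metadata": phantom.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_phantom(path: str | Path) -> VoxelPhantom:
    path = Path(path)
    img = sitk.ReadImage(str(path))
    labels = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(np.int16)
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = tuple(
        float(o) - 0.5 * s for o, s in zip(img.GetOrigin(), spacing)
    )
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing phantom sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    label_map: dict[int, tuple[str, Material]] = {}
    densities: dict[int, float] = {}
    for key, entry in sidecar["labels"].items():
        lab = int(key)
        m = entry["material"]
        mat = Material(m["name"], tuple((s, f) for s, f in m["composition"]), m["density"])
        label_map[lab] = (entry["organ"], mat)
        if entry.get("density") is not None:
            densities[lab] = float(entry["density"])
    present = set(int(v) for v in np.unique(labels))
    unmapped = present - set(label_map)
    if unmapped:
        raise ValueError(f"phantom file contains unmapped labels {sorted(unmapped)}")
    return VoxelPhantom(
        labels, spacing, origin, label_map, densities, sidecar.get("metadata", {})
    )
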