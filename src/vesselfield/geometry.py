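"""Physical coordinate model for cone-beam angiographic acquisition.

The reconstruction volume is a regular voxel grid centered on the C-arm
isocenter.  A projection view is described by the source-to-detector distance
(DSD), source-to-isocenter distance (DSO) and two gantry angles: the primary
angle (LAO/RAO, rotation about the patient head-foot axis) and the secondary
angle (cranial/caudal, rotation about the patient left-right axis).  All
lengths are millimetres, all angles degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "VolumeSpec",
    "DetectorSpec",
    "ConeBeamGeometry",
    "normalize_coordinates",
    "voxel_center_grid",
    "pose_from_angles",
    "sample_projection_pair",
    "orthogonal_pair",
    "save_geometry_sidecar",
    "load_geometry_sidecar",
]


@dataclass(frozen=True)
class VolumeSpec:
    """Voxel grid: number of voxels and voxel spacing (mm) per axis."""

    size: tuple[int, int, int]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.size) != 3 or len(self.spacing) != 3:
            raise ValueError("size and spacing must be length-3")
        if any(int(n) < 1 or int(n) != n for n in self.size):
            raise ValueError(f"voxel counts must be positive integers, got {self.size}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")
        object.__setattr__(self, "size", tuple(int(n) for n in self.size))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical edge lengths n*s of the volume in mm."""
        return tuple(n * s for n, s in zip(self.size, self.spacing))

    @property
    def num_voxels(self) -> int:
        return int(np.prod(self.size))

    @classmethod
    def isotropic(cls, n: int, spacing: float) -> "VolumeSpec":
        return cls((n, n, n), (spacing, spacing, spacing))


@dataclass(frozen=True)
class DetectorSpec:
    """Flat-panel detector: pixel counts and pixel pitch (mm)."""

    size: tuple[int, int]
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        if any(int(n) < 1 or int(n) != n for n in self.size):
            raise ValueError(f"detector size must be positive integers, got {self.size}")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        object.__setattr__(self, "size", tuple(int(n) for n in self.size))
        object.__setattr__(self, "pixel_spacing", tuple(float(s) for s in self.pixel_spacing))

    @property
    def num_pixels(self) -> int:
        return self.size[0] * self.size[1]


@dataclass(frozen=True)
class ConeBeamGeometry:
    """One cone-beam view: distances, gantry angles and the detector."""

    dsd: float
    dso: float
    primary_angle: float
    secondary_angle: float
    detector: DetectorSpec = field(
        default_factory=lambda: DetectorSpec((512, 512), (0.2779, 0.2779))
    )

    def __post_init__(self) -> None:
        if not (self.dsd > self.dso > 0):
            raise ValueError(
                f"require dsd > dso > 0, got dsd={self.dsd}, dso={self.dso}"
            )


def normalize_coordinates(
    index: tuple[int, int, int] | np.ndarray, vol: VolumeSpec
) -> np.ndarray:
    """Map 1-based voxel indices to centered physical coordinates in mm.

    The voxel centers form a grid symmetric about the origin (the isocenter):
    ``x'_i = (index_i - 1) * s_i - (n_i * s_i - s_i) / 2``.  Adjacent centers
    differ by exactly one voxel spacing.

    Parameters
    ----------
    index : integer triple or (..., 3) array, 1-based
    vol : VolumeSpec

    Returns
    -------
    (..., 3) float array of coordinates in mm.
    """
    idx = np.asarray(index, dtype=float)
    if idx.shape[-1] != 3:
        raise ValueError("index must have a trailing dimension of 3")
    n = np.asarray(vol.size, dtype=float)
    s = np.asarray(vol.spacing, dtype=float)
    if np.any(idx < 1) or np.any(idx > n):
        raise ValueError(f"voxel index out of range [1, {vol.size}]")
    return (idx - 1.0) * s - (n * s - s) / 2.0


def voxel_center_grid(vol: VolumeSpec, dtype=np.float64) -> np.ndarray:
    """All voxel-center coordinates, shape (num_voxels, 3), C-order, in mm."""
    axes = [
        (np.arange(n, dtype=dtype)) * s - (n * s - s) / 2.0
        for n, s in zip(vol.size, vol.spacing)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def pose_from_angles(geom: ConeBeamGeometry):
    """Realize the C-arm pose for a view.

    At zero angles the source sits at (0, -dso, 0) and the detector center at
    (0, dsd - dso, 0); the primary angle rotates the arm about +z (patient
    head-foot axis), the secondary angle about +x (patient left-right axis),
    composed primary first.

    Returns
    -------
    source : (3,) mm
    detector_center : (3,) mm
    u_axis, v_axis : (3,) unit vectors spanning the detector plane
        (columns / rows of the detector image, orthogonal to the beam axis)
    """
    rot = _rot_x(geom.secondary_angle) @ _rot_z(geom.primary_angle)
    source = rot @ np.array([0.0, -geom.dso, 0.0])
    det_center = rot @ np.array([0.0, geom.dsd - geom.dso, 0.0])
    u_axis = rot @ np.array([1.0, 0.0, 0.0])
    v_axis = rot @ np.array([0.0, 0.0, 1.0])
    return source, det_center, u_axis, v_axis


def beam_axis(geom: ConeBeamGeometry) -> np.ndarray:
    """Unit vector from source to isocenter."""
    source, _, _, _ = pose_from_angles(geom)
    return -source / np.linalg.norm(source)


# Clinically motivated acquisition ranges for the two view planes, per artery.
# Each entry: (plane-1 range, plane-2 rule).  Plane-2 rules are either an
# absolute range or an offset relative to plane 1.
_PLANE_RANGES = {
    "RCA": {
        "dsd": ((970.0, 1010.0), ("abs", 1050.0, 1070.0)),
        "dso": ((745.0, 785.0), ("rel", -3.0, 3.0)),
        "primary": ((18.0, 42.0), ("abs", -8.0, 8.0)),
        "secondary": ((-8.0, 8.0), ("abs", 18.0, 42.0)),
    },
    "LAD": {
        "dsd": ((1030.0, 1090.0), ("rel", 70.0, 70.0)),
        "dso": ((740.0, 760.0), ("rel", 3.0, 3.0)),
        "primary": ((-8.0, 8.0), ("abs", -47.0, -23.0)),
        "secondary": ((18.0, 42.0), ("abs", 21.0, 45.0)),
    },
}

_DETECTOR_SPACING_RANGE = (0.2769, 0.2789)


def sample_projection_pair(
    artery: str,
    rng_seed: int,
    detector: DetectorSpec | None = None,
) -> tuple[ConeBeamGeometry, ConeBeamGeometry]:
    """Draw a clinically plausible pair of acquisition geometries.

    Parameters are sampled uniformly and independently inside per-artery
    ranges; the second plane's DSD/DSO are tied to the first where clinical
    protocols tie them (LAD plane 2: DSD +70 mm, DSO +3 mm; RCA plane 2:
    DSO within +-3 mm of plane 1).

    Parameters
    ----------
    artery : {"RCA", "LAD"}
    rng_seed : int
    detector : optional DetectorSpec; when omitted a 512x512 panel with pixel
        pitch drawn from the clinical range is used.
    """
    key = artery.upper()
    if key not in _PLANE_RANGES:
        raise ValueError(f"artery must be 'RCA' or 'LAD', got {artery!r}")
    rng = np.random.default_rng(rng_seed)
    ranges = _PLANE_RANGES[key]

    if detector is None:
        pitch = float(rng.uniform(*_DETECTOR_SPACING_RANGE))
        detector = DetectorSpec((512, 512), (pitch, pitch))

    def draw(name: str) -> tuple[float, float]:
        (lo1, hi1), rule = ranges[name]
        v1 = float(rng.uniform(lo1, hi1))
        kind, lo2, hi2 = rule
        if kind == "abs":
            v2 = float(rng.uniform(lo2, hi2))
        else:  # offset relative to plane 1
            v2 = v1 + (lo2 if lo2 == hi2 else float(rng.uniform(lo2, hi2)))
        return v1, v2

    dsd1, dsd2 = draw("dsd")
    dso1, dso2 = draw("dso")
    pa1, pa2 = draw("primary")
    sa1, sa2 = draw("secondary")
    g1 = ConeBeamGeometry(dsd1, dso1, pa1, sa1, detector)
    g2 = ConeBeamGeometry(dsd2, dso2, pa2, sa2, detector)
    return g1, g2


def orthogonal_pair(
    base: ConeBeamGeometry,
) -> tuple[ConeBeamGeometry, ConeBeamGeometry]:
    """Pair the base view with a second view at 90 degrees to it.

    The second view's source-isocenter axis is horizontal (zero secondary
    angle) and perpendicular to the base axis; distances and detector are
    copied from the base.
    """
    a1 = beam_axis(base)
    # horizontal direction perpendicular to the base axis: z_hat x a1
    h = np.array([-a1[1], a1[0], 0.0])
    norm = np.linalg.norm(h)
    if norm < 1e-12:
        raise ValueError("base beam axis is vertical; orthogonal view undefined")
    h /= norm
    # beam axis at secondary 0 is (-sin p, cos p, 0)  =>  p = atan2(-h_x, h_y)
    primary2 = float(np.rad2deg(np.arctan2(-h[0], h[1])))
    second = replace(base, primary_angle=primary2, secondary_angle=0.0)
    return base, second


def _geometry_to_dict(geom: ConeBeamGeometry) -> dict:
    return {
        "dsd_mm": geom.dsd,
        "dso_mm": geom.dso,
        "primary_deg": geom.primary_angle,
        "secondary_deg": geom.secondary_angle,
        "detector_size": list(geom.detector.size),
        "detector_spacing_mm": list(geom.detector.pixel_spacing),
    }


def _geometry_from_dict(d: dict) -> ConeBeamGeometry:
    det = DetectorSpec(tuple(d["detector_size"]), tuple(d["detector_spacing_mm"]))
    return ConeBeamGeometry(
        d["dsd_mm"], d["dso_mm"], d["primary_deg"], d["secondary_deg"], det
    )


def save_geometry_sidecar(
    path: str | Path,
    geometries: list[ConeBeamGeometry],
    vol: VolumeSpec,
) -> None:
    """Write acquisition geometry as a JSON sidecar (units mm / degrees)."""
    payload = {
        "volume_size": list(vol.size),
        "volume_spacing_mm": list(vol.spacing),
        "views": [_geometry_to_dict(g) for g in geometries],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_geometry_sidecar(path: str | Path) -> tuple[list[ConeBeamGeometry], VolumeSpec]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"geometry sidecar not found: {p}")
    payload = json.loads(p.read_text())
    vol = VolumeSpec(tuple(payload["volume_size"]), tuple(payload["volume_spacing_mm"]))
    geoms = [_geometry_from_dict(d) for d in payload["views"]]
    return geoms, vol
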