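"""Forward projection and glandular-fraction maps via Siddon ray tracing.

Geometry follows the mammographic half-cone convention: the point source
sits 35.46 cm above the phantom's top surface, over the chest-wall edge
(y = 0) and laterally centered; the detector plane lies at the phantom's
bottom surface, pixels on a grid matched 1:1 to the voxel columns.  The
detector is ideal (photon-counting transmission fraction, 1 = no
attenuation; no blur, noise, or scatter — the projector is primary-only
Beer–Lambert).

The per-pixel glandular fraction is the fibroglandular path length along
the pixel's ray divided by the compressed breast thickness, so
GF × thickness recovers the fibroglandular path budget each
reconstruction ray must satisfy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .materials import get_table
from .phantom import (LABEL_ADIPOSE, LABEL_FG, LABEL_SKIN, LABELS,
                      VoxelPhantom)
from .spectrum import EnergySpectrum

__all__ = [
    "ProjectionGeometry",
    "RayPath",
    "ProjectionImage",
    "GFMap",
    "default_geometry",
    "trace_ray",
    "forward_project",
    "compute_gf_map",
    "save_image",
    "load_image",
    "save_gf_map",
    "load_gf_map",
]

SOURCE_HEIGHT_MM = 354.6  # source above the phantom top surface


@dataclass(frozen=True)
class ProjectionGeometry:
    """Cone-beam geometry tying a detector pixel grid to a voxel grid.

    ``source`` is in phantom coordinates (mm); the detector plane is
    z = ``det_z`` with pixel (i, j) centered at ((i+0.5)p, (j+0.5)p).
    """

    source: tuple  # (x, y, z) mm
    det_z: float  # mm
    pixel_pitch: float  # mm
    npix: tuple  # (nx, ny)

    def __post_init__(self):
        if self.source[2] >= 0:
            raise ValueError("source must lie above the phantom top surface (z < 0)")
        if self.det_z <= 0:
            raise ValueError("detector plane must lie below the phantom (z > 0)")

    def pixel_center(self, i: int, j: int) -> tuple:
        p = self.pixel_pitch
        return ((i + 0.5) * p, (j + 0.5) * p, self.det_z)

    def to_dict(self) -> dict:
        return {"source": list(self.source), "det_z": self.det_z,
                "pixel_pitch": self.pixel_pitch, "npix": list(self.npix)}

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionGeometry":
        return cls(tuple(d["source"]), d["det_z"], d["pixel_pitch"], tuple(d["npix"]))


def default_geometry(phantom: VoxelPhantom) -> ProjectionGeometry:
    """Source over the chest-wall edge, detector at the phantom bottom,
    pixels 1:1 with voxel columns."""
    nx, ny, nz = phantom.shape
    p = phantom.voxel_pitch
    return ProjectionGeometry(
        source=(nx * p / 2.0, 0.0, -SOURCE_HEIGHT_MM),
        det_z=nz * p,
        pixel_pitch=p,
        npix=(nx, ny),
    )


@dataclass
class RayPath:
    """Ordered voxel intersections of one ray, from source to detector."""

    indices: np.ndarray  # (n, 3) voxel indices
    lengths: np.ndarray  # (n,) mm

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


def trace_ray(geom: ProjectionGeometry, phantom: VoxelPhantom, pixel: tuple) -> RayPath:
    """Siddon traversal for the ray of detector ``pixel`` = (i, j).

    A ray missing the grid yields an empty path.
    """
    i, j = pixel
    if not (0 <= i < geom.npix[0] and 0 <= j < geom.npix[1]):
        raise ValueError(f"pixel {pixel} outside the detector extent {geom.npix}")
    nx, ny, nz = phantom.shape
    cap = nx + ny + nz + 4
    idx = np.empty((cap, 3), dtype=np.int64)
    seg = np.empty(cap, dtype=np.float64)
    px, py, pz = geom.pixel_center(i, j)
    n = _kernels.siddon(geom.source[0], geom.source[1], geom.source[2],
                        px, py, pz, phantom.voxel_pitch, nx, ny, nz, idx, seg)
    return RayPath(idx[:n].copy(), seg[:n].copy())


@dataclass
class ProjectionImage:
    """Detected transmission fraction per pixel (spectrum-weighted)."""

    values: np.ndarray  # (npx, npy)
    pixel_pitch: float
    geometry: ProjectionGeometry = field(repr=False, default=None)


@dataclass
class GFMap:
    """Per-pixel glandular fraction (FG path / compressed thickness).

    ``support`` marks pixels whose ray intersects any tissue (the breast
    shadow); values are zero outside it.  ``tissue_path_mm`` records the
    total tissue chord per pixel, which lets downstream consumers
    separate solidly shadowed pixels from edge rays that merely clip the
    voxelized surface.
    """

    values: np.ndarray  # (npx, npy)
    support: np.ndarray  # bool (npx, npy)
    pixel_pitch: float
    thickness_mm: float
    geometry: ProjectionGeometry = field(repr=False, default=None)
    tissue_path_mm: np.ndarray | None = field(repr=False, default=None)

    def solid_support(self, fraction: float = 0.5) -> np.ndarray:
        """Pixels whose tissue chord reaches ``fraction`` of the
        compressed thickness (all of ``support`` if chords are unknown)."""
        if self.tissue_path_mm is None:
            return self.support.copy()
        return self.support & (self.tissue_path_mm >= fraction * self.thickness_mm)


def _material_path_lengths(phantom: VoxelPhantom, geom: ProjectionGeometry) -> np.ndarray:
    out = np.zeros((geom.npix[0], geom.npix[1], len(LABELS)))
    _kernels.project_paths(phantom.labels, phantom.voxel_pitch,
                           geom.source[0], geom.source[1], geom.source[2],
                           geom.det_z, geom.pixel_pitch,
                           geom.npix[0], geom.npix[1], out)
    return out


def forward_project(phantom: VoxelPhantom, spectrum: EnergySpectrum,
                    geom: ProjectionGeometry | None = None) -> ProjectionImage:
    """Primary-beam projection: per pixel,
    signal = Σ_E W_E exp(−Σ_materials μ(E) · path)."""
    geom = geom or default_geometry(phantom)
    L = _material_path_lengths(phantom, geom)  # mm
    mu = np.empty((len(LABELS), spectrum.energies.size))  # 1/mm
    for lab, mat in LABELS.items():
        t = get_table(mat)
        loge = np.log(t.energies)
        mu[lab] = t.density * np.exp(
            np.interp(np.log(spectrum.energies), loge, np.log(t.total))) / 10.0
    att = np.einsum("abm,me->abe", L, mu)
    signal = np.einsum("abe,e->ab", np.exp(-att), spectrum.weights)
    return ProjectionImage(signal, geom.pixel_pitch, geom)


def compute_gf_map(phantom: VoxelPhantom, geom: ProjectionGeometry | None = None) -> GFMap:
    """Glandular-fraction map of a phantom: FG path length over
    compressed thickness, zero outside the breast shadow."""
    geom = geom or default_geometry(phantom)
    L = _material_path_lengths(phantom, geom)
    tissue = L[:, :, LABEL_ADIPOSE] + L[:, :, LABEL_FG] + L[:, :, LABEL_SKIN]
    thickness = phantom.thickness_mm
    values = L[:, :, LABEL_FG] / thickness
    support = tissue > 0.0
    values[~support] = 0.0
    return GFMap(values, support, geom.pixel_pitch, thickness, geom, tissue)


def _save_f32_tiff(values: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(str(path), values.astype(np.float32))


def save_image(image: ProjectionImage, path) -> None:
    """32-bit float TIFF plus a JSON geometry sidecar (path + '.json')."""
    _save_f32_tiff(image.values, path)
    with open(str(path) + ".json", "w") as fh:
        json.dump({"kind": "projection", "pixel_pitch": image.pixel_pitch,
                   "geometry": image.geometry.to_dict()}, fh, indent=1)


def load_image(path) -> ProjectionImage:
    import tifffile

    values = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    geom = ProjectionGeometry.from_dict(meta["geometry"])
    return ProjectionImage(values, meta["pixel_pitch"], geom)


def save_gf_map(gf_map: GFMap, path) -> None:
    """32-bit float TIFF plus a JSON sidecar carrying geometry,
    compressed thickness and the support mask."""
    _save_f32_tiff(gf_map.values, path)
    meta = {"kind": "gf_map", "pixel_pitch": gf_map.pixel_pitch,
            "thickness_mm": gf_map.thickness_mm,
            "geometry": gf_map.geometry.to_dict(),
            "support": gf_map.support.astype(int).tolist()}
    if gf_map.tissue_path_mm is not None:
        meta["tissue_path_mm"] = np.round(gf_map.tissue_path_mm, 4).tolist()
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh)


def load_gf_map(path) -> GFMap:
    import tifffile

    values = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    geom = ProjectionGeometry.from_dict(meta["geometry"])
    support = np.asarray(meta["support"], dtype=bool)
    tissue = meta.get("tissue_path_mm")
    tissue = np.asarray(tissue, dtype=float) if tissue is not None else None
    return GFMap(values, support, meta["pixel_pitch"], meta["thickness_mm"], geom,
                 tissue)
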