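"""Voxelized compressed-breast phantoms.

A phantom is a uint8 label grid (air / adipose / fibroglandular / skin)
on an isotropic voxel lattice.  The compressed breast is a half-elliptic
prism: its footprint in the detector plane is the half-ellipse with
lateral semi-axis ``diameter/2`` and chest-wall-to-nipple extent
``cw_nipple``, flat at the chest-wall plane y = 0, with uniform
compressed thickness (flat top and bottom, as under compression
paddles).  A rounded half-ellipsoid profile is available behind the
``shape`` flag for sensitivity studies.

Axes: x lateral, y chest wall → nipple, z depth from the top (source
side, z = 0) to the bottom (detector side).  Voxel centers sit at
``origin + (index + 0.5) * pitch``.

Fibroglandular tissue occupies a depth-contiguous slab of interior
voxels — hugging the top skin, the bottom skin, or centered on
mid-depth — whose extent is chosen so the interior volume fraction
matches the requested glandular fraction as closely as voxelization
allows (the boundary slice is filled partially, in fixed raster order).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .materials import Material, get_table

__all__ = [
    "Placement",
    "BreastSpec",
    "VoxelPhantom",
    "build_breast",
    "achieved_gf",
    "table1_presets",
    "save_phantom",
    "load_phantom",
    "LABELS",
]

LABEL_AIR, LABEL_ADIPOSE, LABEL_FG, LABEL_SKIN = 0, 1, 2, 3
LABELS = {
    LABEL_AIR: Material.AIR,
    LABEL_ADIPOSE: Material.ADIPOSE,
    LABEL_FG: Material.FIBROGLANDULAR,
    LABEL_SKIN: Material.SKIN,
}
_LEGEND = "0=air,1=adipose,2=fibroglandular,3=skin"


class Placement(str, enum.Enum):
    TOP = "top"  # source side
    CENTER = "center"
    BOTTOM = "bottom"  # detector side


@dataclass(frozen=True)
class BreastSpec:
    """Geometry and composition of one compressed breast.

    Linear dimensions include the skin layer.  ``diameter`` is the full
    lateral extent, ``thickness`` the compressed thickness and
    ``cw_nipple`` the chest-wall-to-nipple distance, all in cm;
    ``skin_thickness`` and ``voxel_pitch`` are in mm.
    """

    diameter: float
    thickness: float
    cw_nipple: float
    glandular_fraction: float
    placement: Placement = Placement.CENTER
    skin_thickness: float = 1.45
    voxel_pitch: float = 1.0

    def __post_init__(self):
        for name in ("diameter", "thickness", "cw_nipple"):
            if getattr(self, name) * 10.0 <= 2.0 * self.skin_thickness:
                raise ValueError(f"{name} must exceed twice the skin thickness")
        if not 0.0 <= self.glandular_fraction <= 1.0:
            raise ValueError("glandular_fraction must lie in [0, 1]")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")
        object.__setattr__(self, "placement", Placement(self.placement))


@dataclass
class VoxelPhantom:
    """A 3-D material-label grid with physical coordinates."""

    labels: np.ndarray  # uint8, shape (nx, ny, nz)
    voxel_pitch: float  # mm
    origin: tuple = (0.0, 0.0, 0.0)  # mm, corner of voxel (0, 0, 0)
    spec: BreastSpec | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def thickness_mm(self) -> float:
        """Compressed thickness as represented on the grid."""
        return self.labels.shape[2] * self.voxel_pitch

    def voxel_volume_cm3(self) -> float:
        return (self.voxel_pitch / 10.0) ** 3

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    def fg_mass_g(self) -> float:
        rho = get_table(Material.FIBROGLANDULAR).density
        return self.count(LABEL_FG) * self.voxel_volume_cm3() * rho


def _breast_mask(spec: BreastSpec, shape: str) -> np.ndarray:
    p = spec.voxel_pitch
    a = spec.diameter * 10.0 / 2.0
    b = spec.cw_nipple * 10.0
    t = spec.thickness * 10.0
    nx = int(np.ceil(spec.diameter * 10.0 / p))
    ny = int(np.ceil(b / p))
    nz = int(np.ceil(t / p))
    cx = nx * p / 2.0
    x = (np.arange(nx) + 0.5) * p
    y = (np.arange(ny) + 0.5) * p
    z = (np.arange(nz) + 0.5) * p
    r2 = ((x[:, None] - cx) / a) ** 2 + (y[None, :] / b) ** 2
    if shape == "prism":
        mask = (r2 <= 1.0)[:, :, None] & np.ones(nz, dtype=bool)[None, None, :]
    elif shape == "half_ellipsoid":
        zc = nz * p / 2.0
        zr2 = ((z - zc) / (nz * p / 2.0)) ** 2
        mask = r2[:, :, None] + zr2[None, None, :] <= 1.0
    else:
        raise ValueError(f"unknown breast shape {shape!r}")
    return mask


def _skin_shell(mask: np.ndarray, n_layers: int) -> np.ndarray:
    """Outermost ``n_layers`` voxels of the support (6-connectivity).

    The chest-wall face (y = 0) carries no skin: the support is extended
    across that plane before erosion.
    """
    padded = np.concatenate([np.repeat(mask[:, :1, :], n_layers, axis=1), mask], axis=1)
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(padded, structure=struct, iterations=n_layers,
                                      border_value=0)[:, n_layers:, :]
    return mask & ~interior


def _slice_order(z_lo: int, z_hi: int, placement: Placement) -> list[int]:
    """Depth slices in fill priority order for a contiguous slab."""
    zs = list(range(z_lo, z_hi + 1))
    if placement is Placement.TOP:
        return zs
    if placement is Placement.BOTTOM:
        return zs[::-1]
    mid = (z_lo + z_hi) // 2
    order, step = [mid], 1
    while len(order) < len(zs):
        for cand in (mid - step, mid + step):  # one voxel up, then one down
            if z_lo <= cand <= z_hi:
                order.append(cand)
        step += 1
    return order


def build_breast(spec: BreastSpec, shape: str = "prism") -> VoxelPhantom:
    """Construct the voxel phantom described by ``spec``.

    The requested glandular fraction is achieved to within one voxel by
    filling whole depth slices of the interior and topping up the
    boundary slice partially, in fixed raster order.
    """
    mask = _breast_mask(spec, shape)
    n_layers = max(1, int(round(spec.skin_thickness / spec.voxel_pitch)))
    skin = _skin_shell(mask, n_layers)
    interior = mask & ~skin
    n_interior = int(interior.sum())
    if n_interior == 0:
        raise ValueError("breast geometry has no interior voxels inside the skin shell")

    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[interior] = LABEL_ADIPOSE
    labels[skin] = LABEL_SKIN

    target = int(round(spec.glandular_fraction * n_interior))
    if target > 0:
        if spec.placement is Placement.BOTTOM:
            # exact mirror image of the top placement through mid-depth
            top = build_breast(
                BreastSpec(spec.diameter, spec.thickness, spec.cw_nipple,
                           spec.glandular_fraction, Placement.TOP,
                           spec.skin_thickness, spec.voxel_pitch),
                shape,
            )
            labels = top.labels[:, :, ::-1].copy()
            return VoxelPhantom(labels, spec.voxel_pitch, spec=spec)
        z_any = np.flatnonzero(interior.any(axis=(0, 1)))
        z_lo, z_hi = int(z_any[0]), int(z_any[-1])
        remaining = target
        for z in _slice_order(z_lo, z_hi, spec.placement):
            idx = np.argwhere(interior[:, :, z])
            if remaining >= len(idx):
                labels[interior[:, :, z], z] = LABEL_FG
                remaining -= len(idx)
            else:
                sel = idx[:remaining]
                labels[sel[:, 0], sel[:, 1], z] = LABEL_FG
                remaining = 0
            if remaining == 0:
                break
    return VoxelPhantom(labels, spec.voxel_pitch, spec=spec)


def achieved_gf(phantom: VoxelPhantom) -> float:
    """Fibroglandular voxel count over interior (non-skin tissue) count."""
    n_fg = phantom.count(LABEL_FG)
    n_ad = phantom.count(LABEL_ADIPOSE)
    if n_fg + n_ad == 0:
        raise ValueError("phantom has no interior tissue voxels")
    return n_fg / (n_fg + n_ad)


_BASE_SIZES = [
    # (diameter, thickness, chest-wall-to-nipple), cm, skin included
    (11.29, 3.29, 5.645),
    (12.29, 4.29, 6.145),
    (13.29, 5.29, 6.645),
    (14.29, 6.29, 7.145),
]


def table1_presets() -> list[BreastSpec]:
    """The 18 baseline breast specifications: four sizes at 20%
    glandular fraction plus the 12.29 cm size at 30% and 50%, each with
    top / center / bottom fibroglandular placement."""
    combos = [(s, 0.20) for s in _BASE_SIZES]
    combos += [(_BASE_SIZES[1], 0.30), (_BASE_SIZES[1], 0.50)]
    return [
        BreastSpec(d, t, c, gf, placement)
        for (d, t, c), gf in combos
        for placement in (Placement.TOP, Placement.CENTER, Placement.BOTTOM)
    ]


def save_phantom(phantom: VoxelPhantom, path) -> None:
    """Write a phantom as MetaImage (.mha / .mhd), uint8 labels."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(phantom.labels.T))  # (z, y, x)
    img.SetSpacing((phantom.voxel_pitch,) * 3)
    img.SetOrigin(tuple(float(v) for v in phantom.origin))
    img.SetMetaData("label_legend", _LEGEND)
    sitk.WriteImage(img, str(path))


def load_phantom(path) -> VoxelPhantom:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    labels = sitk.GetArrayFromImage(img).T.astype(np.uint8)  # back to (x, y, z)
    return VoxelPhantom(labels, float(img.GetSpacing()[0]), tuple(img.GetOrigin()))
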