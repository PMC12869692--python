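"""Photon interaction data for the materials of a compressed-breast model.

Five materials are supported — air, adipose, fibroglandular, skin, and
CsI — over the mammographic band 10–30 keV.  Mass attenuation is stored
split into photoelectric, Compton (incoherent) and Rayleigh (coherent)
components, alongside the mass energy-absorption coefficient, on a
0.5 keV grid shipped as CSV package data (see
``scripts/build_material_tables.py`` for provenance).  Interpolation
between grid energies is log–log linear, the standard convention for
near-power-law photon cross sections.

Units: energies keV, mass coefficients cm²/g, densities g/cm³, linear
attenuation 1/cm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "Material",
    "MaterialTable",
    "get_table",
    "mu_over_rho",
    "mu_en_over_rho",
    "linear_mu",
    "interaction_fractions",
    "density",
    "E_MIN",
    "E_MAX",
]

E_MIN = 10.0
E_MAX = 30.0


class Material(str, enum.Enum):
    """Material labels used throughout the package."""

    AIR = "air"
    ADIPOSE = "adipose"
    FIBROGLANDULAR = "fibroglandular"
    SKIN = "skin"
    CSI = "csi"


@dataclass(frozen=True)
class MaterialTable:
    """Tabulated photon cross sections for one material.

    ``total`` is by construction the exact sum of the three interaction
    components at every grid energy.
    """

    material: Material
    energies: np.ndarray  # keV, strictly increasing
    pe: np.ndarray  # photoelectric mass attenuation, cm^2/g
    compton: np.ndarray  # incoherent, cm^2/g
    rayleigh: np.ndarray  # coherent, cm^2/g
    mu_en: np.ndarray  # mass energy-absorption, cm^2/g
    density: float  # g/cm^3

    @property
    def total(self) -> np.ndarray:
        return self.pe + self.compton + self.rayleigh


def _read_table(name: str, material: Material | None) -> MaterialTable:
    ref = resources.files("dgnrange.data").joinpath(f"{name}.csv")
    density = None
    with ref.open("r") as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("# density_g_cm3:"):
            density = float(line.split(":")[1])
    if density is None:
        raise ValueError(f"material table {name!r} lacks a density header")
    rows = [line for line in lines if line[0].isdigit()]
    data = np.array([[float(v) for v in r.split(",")] for r in rows])
    return MaterialTable(
        material=material,
        energies=data[:, 0],
        pe=data[:, 1],
        compton=data[:, 2],
        rayleigh=data[:, 3],
        mu_en=data[:, 4],
        density=density,
    )


_CACHE: dict[str, MaterialTable] = {}


def get_table(material: Material | str | MaterialTable) -> MaterialTable:
    """Return the cross-section table for ``material``.

    A :class:`MaterialTable` passes through unchanged, which lets tests
    substitute synthetic tables.
    """
    if isinstance(material, MaterialTable):
        return material
    name = Material(material).value
    if name not in _CACHE:
        _CACHE[name] = _read_table(name, Material(name))
    return _CACHE[name]


def _aluminum_table() -> MaterialTable:
    # internal to the spectrum module's filtration model; not a Material
    if "aluminum" not in _CACHE:
        _CACHE["aluminum"] = _read_table("aluminum", None)
    return _CACHE["aluminum"]


def _check_range(material, E) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if np.any(E < E_MIN) or np.any(E > E_MAX):
        bad = E[(E < E_MIN) | (E > E_MAX)]
        name = material.material if isinstance(material, MaterialTable) else material
        raise ValueError(
            f"energy {np.atleast_1d(bad)[0]:g} keV outside the tabulated "
            f"range [{E_MIN:g}, {E_MAX:g}] keV for material {name!r}"
        )
    return E


def _loglog_interp(E, grid, values) -> np.ndarray:
    """Log–log linear interpolation; an identically-zero column stays zero."""
    if np.all(values == 0.0):
        return np.zeros_like(np.asarray(E, dtype=float))
    return np.exp(np.interp(np.log(E), np.log(grid), np.log(values)))


def mu_over_rho(material: Material | str | MaterialTable, E) -> float | np.ndarray:
    """Total mass attenuation coefficient, cm²/g (log–log interpolated)."""
    E = _check_range(material, E)
    t = get_table(material)
    out = _loglog_interp(E, t.energies, t.total)
    return float(out) if out.ndim == 0 else out


def mu_en_over_rho(material: Material | str | MaterialTable, E) -> float | np.ndarray:
    """Mass energy-absorption coefficient, cm²/g."""
    E = _check_range(material, E)
    t = get_table(material)
    out = _loglog_interp(E, t.energies, t.mu_en)
    return float(out) if out.ndim == 0 else out


def linear_mu(material: Material | str | MaterialTable, E) -> float | np.ndarray:
    """Linear attenuation coefficient, 1/cm."""
    t = get_table(material)
    return t.density * mu_over_rho(t, E)


def interaction_fractions(material: Material | str | MaterialTable, E):
    """Probabilities (photoelectric, Compton, Rayleigh) of each
    interaction type at energy ``E``, normalized to sum to one.

    Components are interpolated independently and normalized by their sum.
    """
    E = _check_range(material, E)
    t = get_table(material)
    pe = _loglog_interp(E, t.energies, t.pe)
    co = _loglog_interp(E, t.energies, t.compton)
    ra = _loglog_interp(E, t.energies, t.rayleigh)
    tot = pe + co + ra
    if np.ndim(E) == 0:
        return float(pe / tot), float(co / tot), float(ra / tot)
    return pe / tot, co / tot, ra / tot


def density(material: Material | str | MaterialTable) -> float:
    """Bulk density, g/cm³."""
    return get_table(material).density
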