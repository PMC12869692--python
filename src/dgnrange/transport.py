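"""Photon Monte Carlo for fibroglandular dose and entrance air kerma.

The engine transports photons per energy bin through a voxel phantom
under the kerma approximation (the CSDA range of sub-30 keV electrons in
tissue is below 0.02 mm, far smaller than a voxel, so recoil/photo-
electron energy is deposited at the interaction site).  Photoelectric
events absorb the photon; Compton scatter is sampled from the
Klein–Nishina distribution on free electrons; Rayleigh scatter redirects
with a Thomson angular law and deposits nothing.  Nothing but the
phantom is transported: the entrance-kerma plane tallies photons on
their way in, before any material.

Entrance surface air kerma per energy is computed from the photon count
N through a 3 cm × 3 cm scoring region above the phantom::

    K_E = 1.602e-10 * E * 1e-3 * (mu_en/rho)_air(E) * N / 9 cm^2

i.e. fluence N/9 cm² × E × air mass energy-absorption (the leading
constants convert keV/g to Gy).

Results are bit-reproducible for a fixed seed (single-threaded,
deterministic kernels; bin ``i`` uses seed ``rng_seed + i``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .materials import Material, get_table
from .phantom import LABEL_FG, LABELS, VoxelPhantom
from .projector import ProjectionGeometry, default_geometry
from .spectrum import EnergySpectrum

__all__ = [
    "TransportConfig",
    "DoseResult",
    "run_monte_carlo",
    "primary_dose_oracle",
    "tally_entrance_kerma",
    "kerma_from_photon_count",
]

KEV_TO_J = 1.602176634e-16
KERMA_PLANE_CM = 3.0  # side of the square entrance scoring region


@dataclass(frozen=True)
class TransportConfig:
    """Monte Carlo run parameters.

    ``photons_per_bin`` defaults to 1e5, a desk-scale count; standard
    errors are estimated from ``n_batches`` interleaved batches.
    """

    photons_per_bin: int = 100_000
    rng_seed: int = 12345
    rayleigh_enabled: bool = True
    scatter_enabled: bool = True
    n_batches: int = 10

    def __post_init__(self):
        if self.photons_per_bin < 1:
            raise ValueError("photons_per_bin must be >= 1")
        if self.n_batches < 2 or self.photons_per_bin < self.n_batches:
            raise ValueError("need at least 2 batches and >= 1 photon per batch")


@dataclass
class DoseResult:
    """Per-energy dose and kerma tallies for one phantom.

    ``D_E`` is the mean fibroglandular dose (Gy) delivered by the
    ``photons`` simulated in each bin; ``N`` the entrance-plane photon
    counts; ``K_E`` the entrance air kerma (Gy) from the printed-formula
    tally.  ``edep_fg_batch`` (n_bins, n_batches) supports standard-error
    estimates; ``deposited``/``escaped`` (keV) are the exact energy
    ledger per bin: deposited + escaped = photons * E.
    """

    energies: np.ndarray
    D_E: np.ndarray
    N: np.ndarray
    K_E: np.ndarray
    photons: int
    edep_fg_batch: np.ndarray
    deposited: np.ndarray
    escaped: np.ndarray
    fg_mass_g: float
    seed: int | None = None
    config: TransportConfig | None = field(default=None, repr=False)

    def dose_stderr(self) -> np.ndarray:
        """Per-energy 1σ standard error of D_E (Gy), from batch spread."""
        n_b = self.edep_fg_batch.shape[1]
        batch_dose = self.edep_fg_batch * n_b * KEV_TO_J / (self.fg_mass_g * 1e-3)
        return batch_dose.std(axis=1, ddof=1) / np.sqrt(n_b)


def _energy_grid(step: float = 0.1):
    from .materials import E_MAX, E_MIN

    return np.arange(E_MIN, E_MAX + 1e-9, step)


def _lookup_tables(pitch_mm: float):
    """Linear attenuation (1/mm) and cumulative interaction-type
    probabilities for the four phantom labels on a fine energy grid."""
    egrid = _energy_grid()
    n_lab = len(LABELS)
    mu_mm = np.empty((n_lab, egrid.size))
    cum_pe = np.empty_like(mu_mm)
    cum_pec = np.empty_like(mu_mm)
    for lab, mat in LABELS.items():
        t = get_table(mat)
        loge = np.log(t.energies)
        pe = np.exp(np.interp(np.log(egrid), loge, np.log(t.pe)))
        co = np.exp(np.interp(np.log(egrid), loge, np.log(t.compton)))
        ra = np.exp(np.interp(np.log(egrid), loge, np.log(t.rayleigh)))
        tot = pe + co + ra
        mu_mm[lab] = t.density * tot / 10.0  # cm^2/g * g/cm^3 -> 1/cm -> 1/mm
        cum_pe[lab] = pe / tot
        cum_pec[lab] = (pe + co) / tot
    return egrid, mu_mm, cum_pe, cum_pec


def run_monte_carlo(phantom: VoxelPhantom, spectrum: EnergySpectrum,
                    geom: ProjectionGeometry | None = None,
                    config: TransportConfig | None = None) -> DoseResult:
    """Simulate every spectrum bin and tally fibroglandular dose and
    entrance-kerma photons."""
    config = config or TransportConfig()
    geom = geom or default_geometry(phantom)
    fg_mass = phantom.fg_mass_g()
    if fg_mass <= 0:
        raise ValueError("phantom contains no fibroglandular tissue to score dose in")
    egrid, mu_mm, cum_pe, cum_pec = _lookup_tables(phantom.voxel_pitch)
    kx0, kx1, ky0, ky1 = _kerma_region(geom)
    n_bins = spectrum.energies.size
    edep_fg = np.zeros((n_bins, config.n_batches))
    N = np.zeros(n_bins, dtype=np.int64)
    deposited = np.zeros(n_bins)
    escaped = np.zeros(n_bins)
    for ib, E0 in enumerate(spectrum.energies):
        n_k, dep, esc = _kernels.mc_bin(
            phantom.labels, phantom.voxel_pitch,
            geom.source[0], geom.source[1], geom.source[2], geom.det_z,
            geom.npix[0] * geom.pixel_pitch, geom.npix[1] * geom.pixel_pitch,
            float(E0), egrid[0], float(egrid[1] - egrid[0]),
            mu_mm, cum_pe, cum_pec,
            int(config.photons_per_bin), int(config.rng_seed + ib),
            int(config.n_batches),
            config.scatter_enabled, config.rayleigh_enabled,
            kx0, kx1, ky0, ky1, LABEL_FG,
            edep_fg[ib],
        )
        N[ib] = n_k
        deposited[ib] = dep
        escaped[ib] = esc
    D_E = edep_fg.sum(axis=1) * KEV_TO_J / (fg_mass * 1e-3)
    K_E = kerma_from_photon_count(spectrum.energies, N)
    return DoseResult(spectrum.energies.copy(), D_E, N, K_E,
                      int(config.photons_per_bin), edep_fg, deposited, escaped,
                      fg_mass, seed=config.rng_seed, config=config)


def primary_dose_oracle(phantom: VoxelPhantom, spectrum: EnergySpectrum,
                        geom: ProjectionGeometry | None = None,
                        photons_per_bin: int = 100_000,
                        n_sub: int = 2) -> DoseResult:
    """Deterministic scatter-free dose: Beer–Lambert-attenuated fluence
    times E × (μ_en/μ)_FG accumulated along Siddon rays.

    Serves as the independent validation oracle for the Monte Carlo with
    ``scatter_enabled=False``; rays sample detector pixels on an
    ``n_sub``× finer subgrid.
    """
    geom = geom or default_geometry(phantom)
    fg_mass = phantom.fg_mass_g()
    if fg_mass <= 0:
        raise ValueError("phantom contains no fibroglandular tissue to score dose in")
    egrid, mu_mm, _, _ = _lookup_tables(phantom.voxel_pitch)
    fg_table = get_table(Material.FIBROGLANDULAR)
    kx0, kx1, ky0, ky1 = _kerma_region(geom)
    n_bins = spectrum.energies.size
    D_E = np.zeros(n_bins)
    N = np.zeros(n_bins, dtype=np.int64)
    deposited = np.zeros(n_bins)
    for ib, E0 in enumerate(spectrum.energies):
        # same lookup interpolation as the Monte Carlo kernel
        fe = (E0 - egrid[0]) / (egrid[1] - egrid[0])
        ie = min(max(int(fe), 0), egrid.size - 2)
        w = min(max(fe - ie, 0.0), 1.0)
        mu4 = mu_mm[:, ie] * (1 - w) + mu_mm[:, ie + 1] * w
        loge = np.log(fg_table.energies)
        muen_fg = np.exp(np.interp(np.log(E0), loge, np.log(fg_table.mu_en)))
        mu_fg_cm = mu4[LABEL_FG] * 10.0 / fg_table.density  # back to cm^2/g
        ratio = muen_fg / mu_fg_cm
        dep, cross = _kernels.primary_bin(
            phantom.labels, phantom.voxel_pitch,
            geom.source[0], geom.source[1], geom.source[2], geom.det_z,
            geom.npix[0] * geom.pixel_pitch, geom.npix[1] * geom.pixel_pitch,
            float(E0), mu4, ratio, LABEL_FG, n_sub,
            kx0, kx1, ky0, ky1,
        )
        D_E[ib] = dep * photons_per_bin * KEV_TO_J / (fg_mass * 1e-3)
        N[ib] = int(round(cross * photons_per_bin))
        deposited[ib] = dep * photons_per_bin
    K_E = kerma_from_photon_count(spectrum.energies, N)
    edep_batch = np.repeat(deposited[:, None] / 2.0, 2, axis=1)  # zero spread
    return DoseResult(spectrum.energies.copy(), D_E, N, K_E,
                      int(photons_per_bin), edep_batch, deposited,
                      photons_per_bin * spectrum.energies - deposited,
                      fg_mass, seed=None, config=None)


def _kerma_region(geom: ProjectionGeometry):
    """3 cm × 3 cm scoring square at the entrance plane, on the beam
    axis (chest-wall centered laterally, spanning y = 0–3 cm)."""
    half = KERMA_PLANE_CM * 10.0 / 2.0
    return (geom.source[0] - half, geom.source[0] + half, 0.0, 2 * half)


def kerma_from_photon_count(E_keV, N) -> np.ndarray:
    """Entrance air kerma (Gy) from photons through the 3 × 3 cm plane."""
    muen_air = _muen_air(np.asarray(E_keV, dtype=float))
    area_cm2 = KERMA_PLANE_CM * KERMA_PLANE_CM
    return 1.602e-10 * np.asarray(E_keV, dtype=float) * 1e-3 * muen_air \
        * np.asarray(N, dtype=float) / area_cm2


def _muen_air(E):
    t = get_table(Material.AIR)
    return np.exp(np.interp(np.log(E), np.log(t.energies), np.log(t.mu_en)))


def tally_entrance_kerma(result: DoseResult) -> np.ndarray:
    """Recompute K_E from a result's photon counts (the printed-formula
    tally); identical to ``result.K_E``."""
    return kerma_from_photon_count(result.energies, result.N)


def result_to_frame(result: DoseResult):
    """DoseResult as a pandas DataFrame (one row per energy bin)."""
    import pandas as pd

    return pd.DataFrame({
        "energy_keV": result.energies,
        "photons": np.full(result.energies.size, result.photons),
        "D_E_Gy": result.D_E,
        "N_kerma_plane": result.N,
        "K_E_Gy": result.K_E,
    })
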