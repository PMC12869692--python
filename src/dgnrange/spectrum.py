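"""X-ray tube spectra: a modeled W-anode bremsstrahlung beam, coarse
energy binning, and CSV round-tripping.

The default beam is a 30 kVp tungsten-anode spectrum behind 0.7 mm of
aluminum.  The bremsstrahlung shape follows the Kramers thick-target law
in the photon-count convention, N(E) ∝ (kVp − E)/E, multiplied by the
aluminum transmission exp(−(μ/ρ)_Al ρ_Al t).  Tungsten characteristic
lines lie far above these tube voltages and are omitted.  Weights are
photon-count weights (each energy bin's dose and kerma are simulated per
photon and weighted afterwards), normalized to sum to one.

Every downstream computation accepts an arbitrary :class:`EnergySpectrum`,
so a measured spectrum can be substituted via :func:`load_spectrum_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import _aluminum_table

__all__ = [
    "EnergySpectrum",
    "model_spectrum",
    "bin_spectrum",
    "load_spectrum_csv",
    "save_spectrum_csv",
]


@dataclass(frozen=True)
class EnergySpectrum:
    """Binned photon energies with normalized beam weights.

    ``energies`` are bin centers in keV, strictly increasing and uniformly
    spaced; ``weights`` are non-negative and sum to one.
    """

    energies: np.ndarray
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        E = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if E.ndim != 1 or E.shape != w.shape or E.size == 0:
            raise ValueError("energies and weights must be matching 1-D arrays")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("beam weights must be finite and non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("beam weights must not all be zero")
        if E.size > 1:
            d = np.diff(E)
            if np.any(d <= 0):
                raise ValueError("bin centers must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
                raise ValueError("bin centers must be uniformly spaced")
        object.__setattr__(self, "energies", E)
        object.__setattr__(self, "weights", w / total)

    @property
    def mean_energy(self) -> float:
        """Weight-averaged photon energy, keV."""
        return float(np.sum(self.energies * self.weights))


def _al_transmission(E: np.ndarray, al_thickness_mm: float) -> np.ndarray:
    t = _aluminum_table()
    mu_rho = np.exp(np.interp(np.log(E), np.log(t.energies), np.log(t.total)))
    return np.exp(-mu_rho * t.density * al_thickness_mm / 10.0)


def model_spectrum(kvp: float = 30.0, al_thickness_mm: float = 0.7,
                   grid_step_kev: float = 0.5) -> EnergySpectrum:
    """Model a filtered W-anode spectrum on a fine energy grid.

    Parameters
    ----------
    kvp : tube voltage, 20–49 kV (tungsten lines are outside this range)
    al_thickness_mm : aluminum filtration thickness, ≥ 0
    """
    if not (20.0 <= kvp <= 49.0):
        raise ValueError(f"tube voltage {kvp} kV outside the supported 20-49 kV range")
    if al_thickness_mm < 0:
        raise ValueError("filtration thickness must be non-negative")
    E = np.arange(5.0, kvp + 1e-9, grid_step_kev)
    w = np.clip(kvp - E, 0.0, None) / E  # Kramers, photon-count convention
    w = w * _al_transmission(E, al_thickness_mm)
    return EnergySpectrum(E, w, {"kvp": kvp, "filtration": f"{al_thickness_mm} mm Al"})


def bin_spectrum(spec: EnergySpectrum, lo: float = 13.0, hi: float = 27.0,
                 width: float = 2.0) -> EnergySpectrum:
    """Rebin a fine spectrum onto coarse bins centered at lo, lo+width, … hi.

    Fine-grid weight falling outside [lo − width/2, hi + width/2) is
    discarded; the retained weights are renormalized to sum to one.
    """
    if lo >= hi:
        raise ValueError("lo must be below hi")
    n_bins = (hi - lo) / width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {width} does not evenly divide [{lo}, {hi}]")
    centers = lo + width * np.arange(int(round(n_bins)) + 1)
    idx = np.floor((spec.energies - (lo - width / 2.0)) / width).astype(int)
    keep = (idx >= 0) & (idx < centers.size)
    w = np.bincount(idx[keep], weights=spec.weights[keep], minlength=centers.size)
    if w.sum() <= 0:
        raise ValueError("no spectrum weight falls inside the requested bins")
    meta = dict(spec.metadata)
    meta["binning"] = f"{width} keV bins, {lo}-{hi} keV"
    return EnergySpectrum(centers, w, meta)


def save_spectrum_csv(spec: EnergySpectrum, path) -> None:
    """Write a spectrum as CSV with '#' metadata header lines."""
    with open(path, "w") as fh:
        for key, value in spec.metadata.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("energy_keV,weight\n")
        for e, w in zip(spec.energies, spec.weights):
            fh.write(f"{e:.6g},{w:.12e}\n")


def load_spectrum_csv(path) -> EnergySpectrum:
    """Load a spectrum CSV (columns energy_keV, weight); weights are
    renormalized to sum to one."""
    metadata = {}
    energies, weights = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line[1:].partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            if line.lower().startswith("energy"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            try:
                e, w = float(parts[0]), float(parts[1])
            except ValueError as err:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}") from err
            if w < 0:
                raise ValueError(f"{path}: negative weight at line {lineno}")
            energies.append(e)
            weights.append(w)
    if not energies:
        raise ValueError(f"{path}: no spectrum rows found")
    return EnergySpectrum(np.array(energies), np.array(weights), metadata)
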