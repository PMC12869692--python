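"""Normalized glandular dose (DgN) and the two-slab analytic model.

DgN is the spectrum-weighted ratio of sums

    DgN = Σ_E D_E W_E  /  Σ_E K_E W_E

with D_E the fibroglandular dose and K_E the entrance air kerma per
energy bin — the ratio of weighted totals, not a weighted mean of
per-bin ratios.  It is dimensionless (Gy per Gy of entrance air kerma)
and invariant to rescaling of the beam weights.

The two-slab model is the 1-D closed form behind the placement
inequality: for a fibroglandular slab of thickness ``t_fg`` buried at
depth ``d`` under adipose, under a monoenergetic normal-incidence beam,
the mean fibroglandular collision kerma is

    D(d) ∝ exp(−μ_ad d) · (1 − exp(−μ_fg t_fg)) · (μ_en/μ)_fg / (ρ_fg t_fg)

which is strictly decreasing in ``d`` (its log-derivative is −μ_ad), so
dose is maximized with the slab at the entrance surface and minimized
with it at the exit surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .transport import DoseResult

__all__ = [
    "DgNResult",
    "DgNRange",
    "compute_dgn",
    "dgn_from_result",
    "dgn_range",
    "two_slab_dose",
]


@dataclass
class DgNResult:
    """A single DgN value with the per-energy terms that produced it."""

    dgn: float  # Gy / Gy, unitless
    stderr: float  # 1-sigma Monte Carlo standard error (0 if deterministic)
    D_E: np.ndarray
    K_E: np.ndarray
    W_E: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def dgn_mgy_per_mgy(self) -> float:
        """Display alias; DgN is a ratio so the value is unchanged."""
        return self.dgn


def compute_dgn(doses, kermas, weights, dose_batches=None,
                provenance=None) -> DgNResult:
    """Weighted-sums DgN from per-energy dose, kerma and beam weights.

    ``dose_batches`` (n_bins, n_batches), when given, yields a Monte
    Carlo standard error by recomputing DgN per interleaved batch.
    """
    D = np.asarray(doses, dtype=float)
    K = np.asarray(kermas, dtype=float)
    W = np.asarray(weights, dtype=float)
    if not (D.shape == K.shape == W.shape) or D.ndim != 1:
        raise ValueError("doses, kermas and weights must be matching 1-D arrays")
    denom = float(np.sum(K * W))
    if denom <= 0:
        raise ZeroDivisionError("weighted kerma sum is zero; DgN undefined")
    dgn = float(np.sum(D * W)) / denom
    stderr = 0.0
    if dose_batches is not None:
        # batch k carries 1/n_batches of the statistics, in dose units:
        # scale each batch to a full-run-equivalent dose, hold kerma fixed
        B = np.asarray(dose_batches, dtype=float)
        n_b = B.shape[1]
        dgn_b = (B * n_b).T @ W / denom
        stderr = float(np.std(dgn_b, ddof=1) / np.sqrt(n_b))
    return DgNResult(dgn, stderr, D, K, W, provenance or {})


def dgn_from_result(result: DoseResult, weights, provenance=None) -> DgNResult:
    """DgN of a transport result under beam weights ``weights``."""
    W = np.asarray(weights, dtype=float)
    denom = float(np.sum(result.K_E * W))
    if denom <= 0:
        raise ZeroDivisionError("weighted kerma sum is zero; DgN undefined")
    dgn = float(np.sum(result.D_E * W)) / denom
    # batch k holds 1/n_batches of the photons: scale to full-run dose
    from .transport import KEV_TO_J

    n_b = result.edep_fg_batch.shape[1]
    batch_dose = result.edep_fg_batch * n_b * KEV_TO_J / (result.fg_mass_g * 1e-3)
    dgn_b = batch_dose.T @ W / denom
    stderr = float(np.std(dgn_b, ddof=1) / np.sqrt(n_b)) if n_b > 1 else 0.0
    return DgNResult(dgn, stderr, result.D_E.copy(), result.K_E.copy(), W,
                     provenance or {})


@dataclass
class DgNRange:
    """Feasible DgN interval from the three reconstruction modes."""

    dgn_min: float
    dgn_likely: float
    dgn_max: float
    stderr_min: float = 0.0
    stderr_likely: float = 0.0
    stderr_max: float = 0.0
    ordering_consistent: bool = True

    @property
    def ratio(self) -> float:
        """max/min DgN ratio."""
        return self.dgn_max / self.dgn_min

    @property
    def width(self) -> float:
        return self.dgn_max - self.dgn_min

    def contains(self, dgn: float, n_sigma: float = 3.0,
                 stderr: float = 0.0) -> bool:
        """Whether a DgN value lies inside [min, max], padded by
        ``n_sigma`` combined standard errors at each end."""
        lo = self.dgn_min - n_sigma * (self.stderr_min + stderr)
        hi = self.dgn_max + n_sigma * (self.stderr_max + stderr)
        return lo <= dgn <= hi


def dgn_range(result_min: DgNResult, result_likely: DgNResult,
              result_max: DgNResult) -> DgNRange:
    """Assemble the [min, likely, max] DgN range.

    An ordering violation beyond 3σ is flagged (it signals a transport
    or reconstruction defect) and warned about, not silently accepted.
    """
    r = DgNRange(result_min.dgn, result_likely.dgn, result_max.dgn,
                 result_min.stderr, result_likely.stderr, result_max.stderr)
    tol_lo = 3.0 * (result_min.stderr + result_likely.stderr)
    tol_hi = 3.0 * (result_likely.stderr + result_max.stderr)
    if (r.dgn_likely < r.dgn_min - tol_lo) or (r.dgn_likely > r.dgn_max + tol_hi):
        r.ordering_consistent = False
        warnings.warn("DgN ordering min <= likely <= max violated beyond 3 sigma",
                      stacklevel=2)
    return r


def two_slab_dose(mu_fg: float, mu_en_fg: float, mu_adip: float,
                  t_fg: float, t_total: float, fg_depth: float) -> float:
    """Relative fibroglandular dose of the 1-D two-slab configuration.

    Parameters
    ----------
    mu_fg, mu_adip : linear attenuation of fibroglandular / adipose, 1/cm
    mu_en_fg : fibroglandular mass energy-absorption ratio driver; only
        the ratio ``mu_en_fg / mu_fg`` enters, so any consistent units
        (e.g. both linear, or both mass coefficients) may be passed
    t_fg : fibroglandular slab thickness, cm
    t_total : total compressed thickness, cm
    fg_depth : adipose depth above the slab, cm, in [0, t_total − t_fg]

    Returns the mean collision kerma in the slab per unit entrance
    fluence-energy, up to a density constant.
    """
    if t_fg <= 0 or t_total <= 0:
        raise ValueError("slab thicknesses must be positive")
    if not 0.0 <= fg_depth <= t_total - t_fg + 1e-12:
        raise ValueError(
            f"fg_depth {fg_depth} outside the feasible range "
            f"[0, {t_total - t_fg}]")
    return float(np.exp(-mu_adip * fg_depth)
                 * (1.0 - np.exp(-mu_fg * t_fg))
                 * (mu_en_fg / mu_fg) / t_fg)
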