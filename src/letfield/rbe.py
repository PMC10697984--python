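"""Quadratic calibration of maximum low-dose RBE against photon energy.

RBE_M — the low-dose limit of the relative biological effectiveness, here
relative to ⁶⁰Co γ rays — is markedly energy dependent for low-LET photon
beams: softer spectra produce denser ionisation and larger RBE_M.  This
module fits a degree-2 polynomial to a user-supplied calibration table
(photon energy, RBE_M, standard uncertainty), by default in the coordinate
x = log10(E/MeV) with inverse-variance weights, and predicts RBE_M at an
effective photon energy with first-order uncertainty propagation through
the coefficient covariance.

Quadratics diverge outside the calibration range, so predictions there are
clamped to the boundary value and flagged as extrapolations.

The packaged calibration table is a synthetic stand-in (see its header);
replace it with measured data for quantitative work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .materials import _data_path

__all__ = [
    "RBECalibrationPoint",
    "RBEQuadraticFit",
    "RBEPrediction",
    "load_calibration",
    "default_calibration_path",
    "fit_rbe_curve",
    "predict_rbem",
    "effective_photon_energy",
]


@dataclass(frozen=True)
class RBECalibrationPoint:
    photon_energy_mev: float
    rbe_m: float
    std_uncertainty: float = 0.0

    def __post_init__(self) -> None:
        if self.photon_energy_mev <= 0:
            raise ValueError("photon energy must be positive")
        if self.rbe_m <= 0:
            raise ValueError("RBE_M must be positive")
        if self.std_uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


@dataclass(frozen=True)
class RBEQuadraticFit:
    """Coefficients (c0, c1, c2) of RBE_M ≈ c0 + c1·x + c2·x² and their covariance.

    ``energy_scale`` selects the coordinate: x = E (linear) or x = log10(E).
    ``valid_range_mev`` spans the calibration energies; predictions are
    clamped outside it.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    energy_scale: str
    valid_range_mev: tuple
    weighted: bool

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        v = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "coefficients", c)
        object.__setattr__(self, "covariance", v)
        if c.shape != (3,) or v.shape != (3, 3):
            raise ValueError("need 3 coefficients and a 3x3 covariance")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh((v + v.T) / 2) < -1e-9 * max(1.0, np.abs(v).max())):
            raise ValueError("covariance must be positive semi-definite")
        if self.energy_scale not in ("linear", "log10"):
            raise ValueError("energy_scale must be 'linear' or 'log10'")
        if not self.valid_range_mev[0] < self.valid_range_mev[1]:
            raise ValueError("invalid energy range")

    def coordinate(self, energy_mev):
        e = np.asarray(energy_mev, dtype=float)
        return np.log10(e) if self.energy_scale == "log10" else e


@dataclass(frozen=True)
class RBEPrediction:
    value: float
    std_uncertainty: float
    photon_energy_mev: float
    extrapolated: bool = False


def default_calibration_path():
    return _data_path("synthetic_rbe_calibration.csv")


def load_calibration(path=None) -> list:
    """Read calibration points from CSV (photon_energy_MeV, rbe_m, std_u)."""
    path = path or default_calibration_path()
    df = pd.read_csv(path, comment="#")
    return [
        RBECalibrationPoint(r.photon_energy_MeV, r.rbe_m, r.std_u)
        for r in df.itertuples()
    ]


def fit_rbe_curve(
    points: Sequence[RBECalibrationPoint],
    scale: str = "log10",
    weighted: bool = True,
) -> RBEQuadraticFit:
    """Weighted least-squares quadratic fit of RBE_M vs photon energy.

    With ``weighted`` and strictly positive reported uncertainties the
    weights are 1/σ² and the returned covariance is (XᵀWX)⁻¹ (known-σ
    case).  Otherwise an unweighted fit is used and the covariance is
    scaled by the residual variance.
    """
    energies = np.array([p.photon_energy_mev for p in points], dtype=float)
    y = np.array([p.rbe_m for p in points], dtype=float)
    sig = np.array([p.std_uncertainty for p in points], dtype=float)
    if len(np.unique(energies)) < 3:
        raise ValueError("need at least 3 distinct calibration energies")
    if scale not in ("linear", "log10"):
        raise ValueError("scale must be 'linear' or 'log10'")
    x = np.log10(energies) if scale == "log10" else energies

    use_weights = weighted
    if weighted and np.any(sig <= 0):
        warnings.warn(
            "zero/absent uncertainties: falling back to an unweighted fit",
            stacklevel=2,
        )
        use_weights = False

    design = np.vander(x, 3, increasing=True)  # columns 1, x, x²
    if use_weights:
        w = 1.0 / sig
        coef, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
        cov = np.linalg.inv(design.T @ (design * (w**2)[:, None]))
    else:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        dof = max(len(y) - 3, 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(design.T @ design)
    return RBEQuadraticFit(
        coefficients=coef,
        covariance=cov,
        energy_scale=scale,
        valid_range_mev=(float(energies.min()), float(energies.max())),
        weighted=use_weights,
    )


def predict_rbem(fit: RBEQuadraticFit, energy_mev: float) -> RBEPrediction:
    """Evaluate the calibration quadratic at a photon energy.

    Outside the calibration range the boundary prediction is returned with
    ``extrapolated=True`` (the quadratic itself is never evaluated there).
    """
    if energy_mev <= 0:
        raise ValueError("photon energy must be positive")
    lo, hi = fit.valid_range_mev
    e_eval = min(max(energy_mev, lo), hi)
    extrapolated = not (lo <= energy_mev <= hi)
    x = float(fit.coordinate(e_eval))
    g = np.array([1.0, x, x * x])
    value = float(g @ fit.coefficients)
    var = float(g @ fit.covariance @ g)
    return RBEPrediction(
        value=value,
        std_uncertainty=float(np.sqrt(max(var, 0.0))),
        photon_energy_mev=energy_mev,
        extrapolated=extrapolated,
    )


def effective_photon_energy(photon_spectrum) -> float:
    """Fluence-weighted mean photon energy (MeV) of a binned spectrum.

    Accepts any object with ``bin_edges_mev`` and ``fluence_density``
    attributes.  This is the stand-in mapping from a geometry point to the
    calibration energy axis; the choice of a fluence-weighted mean is a
    documented convention, not a constraint of the calibration itself.
    """
    edges = np.asarray(photon_spectrum.bin_edges_mev, dtype=float)
    phi = np.asarray(photon_spectrum.fluence_density, dtype=float)
    widths = np.diff(edges)
    mid = np.sqrt(edges[:-1] * edges[1:])
    w = phi * widths
    tot = w.sum()
    if tot <= 0:
        raise ValueError("photon spectrum carries no fluence")
    return float((w * mid).sum() / tot)
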