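"""Track- and dose-average restricted LET of an electron fluence spectrum.

Given a binned electron fluence differential in energy Φ(E) and a stopping
power table, the two spectrum moments are

    L_Δ,D = [ ∫ L_Δ²(E) Φ(E) dE + S(Δ)² Φ(Δ) Δ ] / [ ∫ L_Δ(E) Φ(E) dE + S(Δ) Φ(Δ) Δ ]
    L_Δ,T = [ ∫ L_Δ(E) Φ(E) dE + S(Δ) Φ(Δ) Δ ] / [ ∫ Φ(E) dE + Φ(Δ) Δ ]

where the S(Δ)Φ(Δ)Δ terms are the track-end correction for electrons whose
energy falls below the cutoff Δ (they deposit the remaining Δ locally).
Integrals run from Δ to the spectrum maximum and are evaluated by the
midpoint rule on the bins, with L_Δ taken at geometric bin midpoints through
the table's log-log interpolation.

Φ(E) is treated as *particle* fluence differential in energy by default;
an energy-fluence weighting is available as a sensitivity option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np

from .geometry import GeometryPoint
from .materials import StoppingPowerTable

__all__ = [
    "FluenceSpectrum",
    "LETResult",
    "TrackEndTerms",
    "track_end_terms",
    "dose_average_let",
    "track_average_let",
    "compute_let",
    "attach_uncertainty",
    "DEFAULT_REL_U",
]

log = logging.getLogger(__name__)

#: Default relative standard uncertainty attached to LET results (k = 1).
DEFAULT_REL_U = 0.006


@dataclass(frozen=True)
class FluenceSpectrum:
    """Binned electron fluence differential in energy at one geometry point.

    ``bin_edges_mev`` has length n+1 and must start at or above the cutoff Δ;
    ``fluence_density`` (length n, arbitrary absolute scale, per MeV) is the
    mean Φ(E) on each bin.  ``track_end_fluence`` is Φ(Δ), the fluence
    density at the cutoff used by the track-end correction.
    """

    bin_edges_mev: np.ndarray
    fluence_density: np.ndarray
    delta_kev: float = 1.0
    kind: str = "TEF"
    geometry: Optional[GeometryPoint] = None
    track_end_fluence: Optional[float] = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_mev, dtype=float)
        phi = np.asarray(self.fluence_density, dtype=float)
        object.__setattr__(self, "bin_edges_mev", edges)
        object.__setattr__(self, "fluence_density", phi)
        if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if phi.shape != (len(edges) - 1,):
            raise ValueError("fluence_density must have one value per bin")
        if np.any(phi < 0):
            raise ValueError("fluence density must be non-negative")
        if self.kind not in ("TEF", "SE"):
            raise ValueError("kind must be 'TEF' or 'SE'")
        if self.delta_kev <= 0:
            raise ValueError("delta cutoff must be positive")
        if edges[0] < self.delta_kev * 1e-3 * (1 - 1e-9):
            raise ValueError("spectrum must not extend below the delta cutoff")
        if self.track_end_fluence is not None and self.track_end_fluence < 0:
            raise ValueError("track-end fluence must be non-negative")

    @property
    def midpoints_mev(self) -> np.ndarray:
        """Geometric bin midpoints, matching the log-log table interpolation."""
        return np.sqrt(self.bin_edges_mev[:-1] * self.bin_edges_mev[1:])

    @property
    def bin_widths_mev(self) -> np.ndarray:
        return np.diff(self.bin_edges_mev)

    def phi_at_delta(self) -> float:
        """Φ(Δ) for the track-end terms; falls back to the first bin."""
        if self.track_end_fluence is not None:
            return float(self.track_end_fluence)
        log.warning("track_end_fluence missing; using the first bin's density")
        return float(self.fluence_density[0])

    def mean_energy_mev(self) -> float:
        w = self.fluence_density * self.bin_widths_mev
        tot = w.sum()
        if tot <= 0:
            raise ValueError("spectrum has no fluence")
        return float((w * self.midpoints_mev).sum() / tot)

    def scaled(self, factor: float) -> "FluenceSpectrum":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        te = None if self.track_end_fluence is None else self.track_end_fluence * factor
        return replace(
            self, fluence_density=self.fluence_density * factor, track_end_fluence=te
        )


@dataclass(frozen=True)
class LETResult:
    """Track- and dose-average restricted LET with relative uncertainty."""

    track_average_kev_um: float
    dose_average_kev_um: float
    delta_kev: float
    relative_standard_uncertainty: float = DEFAULT_REL_U
    kind: str = "TEF"
    geometry: Optional[GeometryPoint] = field(default=None)

    def __post_init__(self) -> None:
        if not self.track_average_kev_um > 0:
            raise ValueError("track-average LET must be positive")
        if self.dose_average_kev_um < self.track_average_kev_um * (1 - 1e-12):
            raise ValueError("dose-average LET cannot fall below the track average")

    @property
    def absolute_uncertainties(self) -> tuple:
        u = self.relative_standard_uncertainty
        return (self.track_average_kev_um * u, self.dose_average_kev_um * u)


class TrackEndTerms(NamedTuple):
    """The three S(Δ)Φ(Δ)Δ-type correction terms.

    ``l_sq``: S(Δ)²Φ(Δ)Δ (dose-average numerator); ``l``: S(Δ)Φ(Δ)Δ
    (shared middle term); ``plain``: Φ(Δ)Δ (track-average denominator).
    """

    l_sq: float
    l: float
    plain: float


def _check_pair(spec: FluenceSpectrum, table: StoppingPowerTable) -> None:
    if abs(spec.delta_kev - table.delta_kev) > 1e-9:
        raise ValueError(
            f"cutoff mismatch: spectrum Δ={spec.delta_kev} keV, table Δ={table.delta_kev} keV"
        )
    if spec.bin_edges_mev[-1] > table.energy_grid_mev[-1] * (1 + 1e-9):
        raise ValueError("table does not cover the spectrum's energy range")


def track_end_terms(spec: FluenceSpectrum, table: StoppingPowerTable) -> TrackEndTerms:
    """Track-end correction terms, using the unrestricted S at Δ."""
    _check_pair(spec, table)
    delta_mev = spec.delta_kev * 1e-3
    phi_delta = spec.phi_at_delta()
    s_delta = table.unrestricted_at(max(delta_mev, table.energy_grid_mev[0]))
    base = phi_delta * delta_mev
    return TrackEndTerms(l_sq=s_delta**2 * base, l=s_delta * base, plain=base)


def _moment_integrals(spec: FluenceSpectrum, table: StoppingPowerTable, weighting: str):
    if weighting not in ("particle", "energy"):
        raise ValueError("weighting must be 'particle' or 'energy'")
    mid = spec.midpoints_mev
    w = spec.fluence_density * spec.bin_widths_mev
    if weighting == "energy":
        w = w * mid
    l_mid = table.restricted_at(mid)
    return float(w.sum()), float((w * l_mid).sum()), float((w * l_mid**2).sum())


def dose_average_let(
    spec: FluenceSpectrum, table: StoppingPowerTable, weighting: str = "particle"
) -> float:
    """Dose-average restricted LET (keV/μm) of a fluence spectrum."""
    _check_pair(spec, table)
    te = track_end_terms(spec, table)
    _, m1, m2 = _moment_integrals(spec, table, weighting)
    denom = m1 + te.l
    if denom <= 0:
        raise ValueError("undefined moment: spectrum carries no fluence")
    return (m2 + te.l_sq) / denom


def track_average_let(
    spec: FluenceSpectrum, table: StoppingPowerTable, weighting: str = "particle"
) -> float:
    """Track-average restricted LET (keV/μm) of a fluence spectrum."""
    _check_pair(spec, table)
    te = track_end_terms(spec, table)
    m0, m1, _ = _moment_integrals(spec, table, weighting)
    denom = m0 + te.plain
    if denom <= 0:
        raise ValueError("undefined moment: spectrum carries no fluence")
    return (m1 + te.l) / denom


def compute_let(
    spec: FluenceSpectrum,
    table: StoppingPowerTable,
    weighting: str = "particle",
    rel_u: float = DEFAULT_REL_U,
) -> LETResult:
    """Both LET moments of a spectrum as an :class:`LETResult`."""
    return LETResult(
        track_average_kev_um=track_average_let(spec, table, weighting),
        dose_average_kev_um=dose_average_let(spec, table, weighting),
        delta_kev=spec.delta_kev,
        relative_standard_uncertainty=rel_u,
        kind=spec.kind,
        geometry=spec.geometry,
    )


def attach_uncertainty(result: LETResult, rel_u: float = DEFAULT_REL_U) -> LETResult:
    """Return a copy of ``result`` carrying the given relative uncertainty."""
    if not 0 <= rel_u < 1:
        raise ValueError("relative uncertainty must lie in [0, 1)")
    return replace(result, relative_standard_uncertainty=rel_u)
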