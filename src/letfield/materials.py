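"""Electron collision stopping powers in liquid water.

Closed-form Bethe collision stopping power for electrons with the Møller
close-collision term (ICRU-37 form) and the Sternheimer density-effect
correction, plus the Δ-restricted stopping power ``L_Δ`` that counts only
energy transfers below a delta-ray cutoff Δ.  Radiative losses are excluded
throughout: LET is a collisional quantity.

All public functions return *linear* stopping powers in keV/μm (mass stopping
power in MeV·cm²/g times density times 0.1).  Energies are electron kinetic
energies in MeV; the cutoff Δ is given in keV.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MaterialSpec",
    "StoppingPowerTable",
    "load_material",
    "density_effect_delta",
    "collision_stopping_power",
    "restricted_let",
    "moller_macroscopic_dcs",
    "build_table",
    "default_energy_grid",
    "WATER",
]

ELECTRON_REST_MEV = 0.51099895
# 2π r_e² m_e c² N_A  (MeV·cm²/mol): prefactor of the Møller/Bethe terms
STOPPING_CONSTANT = 0.1535336

#: Kinetic-energy validity floor (MeV).  The Bethe formula is unreliable
#: below ~1 keV; we raise rather than extrapolate.
VALIDITY_FLOOR_MEV = 1e-3

MEVCM2G_TO_KEVUM_PER_DENSITY = 0.1  # (MeV/cm) -> keV/μm


@dataclass(frozen=True)
class MaterialSpec:
    """Medium constants needed for electron collision stopping powers.

    ``sternheimer`` holds the density-effect coefficients (a, m, x0, x1,
    Cbar, delta0) on the coordinate x = log10(p / m_e c).
    """

    name: str
    mean_excitation_energy_ev: float
    density_g_cm3: float
    z_over_a: float
    sternheimer: dict

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        if self.mean_excitation_energy_ev <= 0:
            raise ValueError("mean excitation energy must be positive")
        st = self.sternheimer
        missing = {"a", "m", "x0", "x1", "Cbar", "delta0"} - set(st)
        if missing:
            raise ValueError(f"missing Sternheimer coefficients: {sorted(missing)}")
        if not st["x0"] < st["x1"]:
            raise ValueError("Sternheimer x0 must be below x1")
        if st["a"] <= 0:
            raise ValueError("Sternheimer coefficient a must be positive")


def _data_path(fname: str) -> Path:
    return Path(str(resources.files("letfield") / "data" / fname))


def load_material(name: str = "water_liquid") -> MaterialSpec:
    """Load a material row from the packaged constants file."""
    df = pd.read_csv(_data_path("materials.csv"), comment="#")
    row = df[df["name"] == name]
    if row.empty:
        raise KeyError(f"unknown material {name!r}")
    r = row.iloc[0]
    return MaterialSpec(
        name=r["name"],
        mean_excitation_energy_ev=float(r["I_eV"]),
        density_g_cm3=float(r["density_g_cm3"]),
        z_over_a=float(r["Z_over_A"]),
        sternheimer={k: float(r[k]) for k in ("a", "m", "x0", "x1", "Cbar", "delta0")},
    )


def _check_energy(energy_mev, floor_mev: float = VALIDITY_FLOOR_MEV):
    e = np.asarray(energy_mev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("kinetic energy must be positive")
    if np.any(e < floor_mev):
        raise ValueError(
            f"kinetic energy below validity floor of {floor_mev * 1e3:g} keV; "
            "the Bethe formula is unreliable there"
        )
    return e


def density_effect_delta(energy_mev, material: MaterialSpec):
    """Sternheimer density-effect correction δ(E) for electrons.

    Zero below x0 (non-conductor, delta0 = 0), quadratic-bridge form on
    [x0, x1], asymptotic 2·ln(10)·x − Cbar above x1.
    """
    e = _check_energy(energy_mev, floor_mev=0.0)
    st = material.sternheimer
    gamma = 1.0 + e / ELECTRON_REST_MEV
    beta_gamma = np.sqrt(gamma * gamma - 1.0)
    x = np.log10(beta_gamma)
    bridge = st["a"] * np.clip(st["x1"] - x, 0.0, None) ** st["m"]
    delta = np.where(
        x >= st["x1"],
        2.0 * np.log(10.0) * x - st["Cbar"],
        2.0 * np.log(10.0) * x - st["Cbar"] + bridge,
    )
    delta = np.where(x < st["x0"], st["delta0"], delta)
    return delta if np.ndim(energy_mev) else float(delta)


def _kinematics(e):
    tau = e / ELECTRON_REST_MEV
    beta_sq = 1.0 - 1.0 / (1.0 + tau) ** 2
    return tau, beta_sq


def _log_term(tau, material):
    i_ratio = material.mean_excitation_energy_ev * 1e-6 / ELECTRON_REST_MEV
    return np.log(tau * tau * (tau + 2.0) / (2.0 * i_ratio * i_ratio))


def collision_stopping_power(energy_mev, material: MaterialSpec = None):
    """Unrestricted electron collision stopping power S(E) in keV/μm.

    Bethe soft-collision term plus the Møller close-collision term
    (ICRU-37 closed form) with the density-effect correction; radiative
    losses excluded.
    """
    material = material or WATER
    e = _check_energy(energy_mev)
    tau, beta_sq = _kinematics(e)
    inv_gamma_sq = 1.0 - beta_sq  # = 1/(τ+1)²
    f_minus = 1.0 - beta_sq + (tau * tau / 8.0 - (2.0 * tau + 1.0) * np.log(2.0)) * inv_gamma_sq
    delta = density_effect_delta(e, material)
    mass_sp = (
        STOPPING_CONSTANT
        * material.z_over_a
        / beta_sq
        * (_log_term(tau, material) + f_minus - delta)
    )
    out = mass_sp * material.density_g_cm3 * MEVCM2G_TO_KEVUM_PER_DENSITY
    return out if np.ndim(energy_mev) else float(out)


def restricted_let(energy_mev, delta_kev: float, material: MaterialSpec = None):
    """Restricted stopping power L_Δ(E) in keV/μm (transfers below Δ only).

    ICRU-37 closed form; for Δ ≥ E/2 (no delta ray can exceed half the
    kinetic energy, the two outgoing electrons being indistinguishable)
    this is exactly the unrestricted collision stopping power.
    """
    material = material or WATER
    if delta_kev <= 0:
        raise ValueError("delta cutoff must be positive")
    e = _check_energy(energy_mev)
    tau, beta_sq = _kinematics(e)
    inv_gamma_sq = 1.0 - beta_sq
    eta = np.minimum(delta_kev * 1e-3 / e, 0.5)
    g_minus = (
        -1.0
        - beta_sq
        + np.log(4.0 * (1.0 - eta) * eta)
        + 1.0 / (1.0 - eta)
        + inv_gamma_sq
        * (tau * tau * eta * eta / 2.0 + (2.0 * tau + 1.0) * np.log(1.0 - eta))
    )
    delta = density_effect_delta(e, material)
    mass_sp = (
        STOPPING_CONSTANT
        * material.z_over_a
        / beta_sq
        * (_log_term(tau, material) + g_minus - delta)
    )
    out = mass_sp * material.density_g_cm3 * MEVCM2G_TO_KEVUM_PER_DENSITY
    return out if np.ndim(energy_mev) else float(out)


def moller_macroscopic_dcs(energy_mev, transfer_mev, material: MaterialSpec = None):
    """Macroscopic Møller cross section dΣ/dW (per cm per MeV of transfer).

    Free-electron Møller scattering of an electron of kinetic energy E with
    energy transfer W to the (lower-energy) knock-on electron, W ≤ E/2.
    Returns 0 outside the kinematic range.  Units follow the keV/μm
    convention of this module: multiplying by W (MeV) and integrating over
    W ∈ [Δ, E/2] gives the hard-collision part S(E) − L_Δ(E) in keV/μm.
    """
    material = material or WATER
    e = np.asarray(energy_mev, dtype=float)
    w = np.asarray(transfer_mev, dtype=float)
    tau, beta_sq = _kinematics(e)
    inv_gamma_sq = 1.0 - beta_sq
    eps = w / e
    with np.errstate(divide="ignore", invalid="ignore"):
        shape = (
            1.0 / eps**2
            + 1.0 / (1.0 - eps) ** 2
            + (tau / (tau + 1.0)) ** 2
            - (2.0 * tau + 1.0) * inv_gamma_sq / (eps * (1.0 - eps))
        )
        dcs = (
            STOPPING_CONSTANT
            * material.z_over_a
            * material.density_g_cm3
            * MEVCM2G_TO_KEVUM_PER_DENSITY
            / (beta_sq * e * e)
            * shape
        )
    dcs = np.where((eps > 0) & (eps <= 0.5), dcs, 0.0)
    return dcs if (np.ndim(energy_mev) or np.ndim(transfer_mev)) else float(dcs)


@dataclass(frozen=True)
class StoppingPowerTable:
    """S(E) and L_Δ(E) tabulated on a strictly increasing energy grid.

    Consumers interpolate log-log linearly between grid points via
    :meth:`unrestricted_at` / :meth:`restricted_at`.
    """

    energy_grid_mev: np.ndarray
    unrestricted_kev_um: np.ndarray
    restricted_kev_um: np.ndarray
    delta_kev: float
    material_name: str = "water_liquid"

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_grid_mev, dtype=float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be 1-D and strictly increasing")
        if e[0] < self.delta_kev * 1e-3 * (1 - 1e-12):
            raise ValueError("grid must start at or above the delta cutoff")
        s = np.asarray(self.unrestricted_kev_um, dtype=float)
        l = np.asarray(self.restricted_kev_um, dtype=float)
        if s.shape != e.shape or l.shape != e.shape:
            raise ValueError("table column lengths must match the grid")
        if np.any(s <= 0) or np.any(l <= 0):
            raise ValueError("stopping powers must be positive")
        if np.any(l > s * (1 + 1e-12)):
            raise ValueError("restricted values must not exceed unrestricted ones")

    def _interp(self, energy_mev, values):
        e = np.asarray(energy_mev, dtype=float)
        grid = self.energy_grid_mev
        if np.any(e < grid[0] * (1 - 1e-9)) or np.any(e > grid[-1] * (1 + 1e-9)):
            raise ValueError("energy outside the tabulated range")
        out = np.exp(np.interp(np.log(e), np.log(grid), np.log(values)))
        return out if np.ndim(energy_mev) else float(out)

    def unrestricted_at(self, energy_mev):
        return self._interp(energy_mev, self.unrestricted_kev_um)

    def restricted_at(self, energy_mev):
        return self._interp(energy_mev, self.restricted_kev_um)

    def write_tsv(self, path) -> None:
        header = f"# energy_MeV\tS_keV_per_um\tL_delta_keV_per_um\tdelta_keV={self.delta_kev:g}\n"
        with open(path, "w") as fh:
            fh.write(header)
            for e, s, l in zip(
                self.energy_grid_mev, self.unrestricted_kev_um, self.restricted_kev_um
            ):
                fh.write(f"{e:.8e}\t{s:.8e}\t{l:.8e}\n")

    @classmethod
    def read_tsv(cls, path) -> "StoppingPowerTable":
        with open(path) as fh:
            header = fh.readline()
        if "delta_keV=" not in header:
            raise ValueError("missing delta_keV header")
        delta_kev = float(header.rsplit("delta_keV=", 1)[1])
        arr = np.loadtxt(path)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], delta_kev)


def default_energy_grid(n: int = 200, e_min_mev: float = 1e-3, e_max_mev: float = 6.5):
    """Default evaluation grid: log-spaced from 1 keV to 6.5 MeV."""
    return np.logspace(np.log10(e_min_mev), np.log10(e_max_mev), n)


def build_table(
    grid_mev, delta_kev: float = 1.0, material: MaterialSpec = None
) -> StoppingPowerTable:
    """Tabulate S(E) and L_Δ(E) on a strictly increasing grid."""
    material = material or WATER
    grid = np.asarray(grid_mev, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < delta_kev * 1e-3 * (1 - 1e-12):
        raise ValueError("grid minimum must be at or above the delta cutoff")
    return StoppingPowerTable(
        energy_grid_mev=grid,
        unrestricted_kev_um=collision_stopping_power(grid, material),
        restricted_kev_um=restricted_let(grid, delta_kev, material),
        delta_kev=delta_kev,
        material_name=material.name,
    )


WATER = load_material("water_liquid")
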