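"""Electron physics: stopping powers, CSDA ranges, condensed-history steps.

Collision stopping follows the Bethe formula for electrons with the Moller
closure, evaluated from the material's mixture-rule <Z/A> and
Bragg-additivity mean excitation energy; the density-effect correction is
omitted (< ~2% below 1 MeV).  Radiative stopping uses the compact
approximation S_rad = S_col * Z_eff * E[MeV] / 800, which captures the
Z-driven bremsstrahlung trend without a full cross-section treatment.
Multiple scattering per condensed step uses the Highland formula; no delta
rays and no energy-loss straggling (class-I condensed history).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .fixtures import ELECTRON_REST_KEV
from .materials import EffectiveParams, Material, effective_params

#: Bethe prefactor 2 pi r_e^2 m c^2 N_A (MeV cm^2 / mol)
_BETHE_K = 0.1535374
ENERGY_MIN_KEV = 1.0
ENERGY_MAX_KEV = 2000.0
DEFAULT_ELECTRON_CUTOFF_KEV = 10.0


def _collision_stopping_scalar(z_over_a: float, i_ev: float, e_kev: float) -> float:
    tau = e_kev / ELECTRON_REST_KEV
    gamma = 1.0 + tau
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    i_ratio = (i_ev / 1000.0) / ELECTRON_REST_KEV  # I in keV over m_e c^2
    arg = tau * tau * (tau + 2.0) / (2.0 * i_ratio * i_ratio)
    f_tau = 1.0 - beta2 + (tau * tau / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / (gamma * gamma)
    val = _BETHE_K * z_over_a / beta2 * (math.log(arg) + f_tau)
    return max(val, 1e-12)


def collision_stopping(material: Material, energy_kev: float) -> float:
    """Collision (ionization) mass stopping power, MeV cm^2/g."""
    if not (ENERGY_MIN_KEV <= energy_kev <= ENERGY_MAX_KEV):
        raise ValueError(
            f"electron energy {energy_kev} keV outside "
            f"[{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV"
        )
    p = effective_params(material)
    return _collision_stopping_scalar(p.z_over_a, p.i_ev, energy_kev)


def radiative_stopping(material: Material, energy_kev: float) -> float:
    """Approximate radiative (bremsstrahlung) mass stopping power, MeV cm^2/g."""
    p = effective_params(material)
    s_col = _collision_stopping_scalar(p.z_over_a, p.i_ev, max(energy_kev, ENERGY_MIN_KEV))
    return s_col * p.z_eff * (energy_kev / 1000.0) / 800.0


@dataclass
class StoppingModel:
    """Tabulated stopping powers and CSDA range for one material."""

    material: Material
    params: EffectiveParams
    energy_kev: np.ndarray       # strictly increasing grid
    s_col: np.ndarray            # MeV cm^2/g
    s_rad: np.ndarray            # MeV cm^2/g
    csda_g_cm2: np.ndarray       # cumulative range, g/cm^2
    x0_g_cm2: float

    @classmethod
    def build(cls, material: Material, n_grid: int = 512) -> "StoppingModel":
        p = effective_params(material)
        grid = np.geomspace(ENERGY_MIN_KEV, ENERGY_MAX_KEV, n_grid)
        s_col = np.array([_collision_stopping_scalar(p.z_over_a, p.i_ev, e) for e in grid])
        s_rad = s_col * p.z_eff * (grid / 1000.0) / 800.0
        # R(E) = int_0^E dE' / S_tot ; the sub-grid piece below 1 keV is
        # approximated by a linear run-in (range there is < 1e-4 g/cm^2)
        inv_s = 1.0 / (s_col + s_rad)
        csda = cumulative_trapezoid(inv_s, grid / 1000.0, initial=0.0)
        csda += (grid[0] / 1000.0) * inv_s[0]
        return cls(material, p, grid, s_col, s_rad, csda, p.x0_g_cm2)

    def stopping(self, energy_kev: float) -> tuple[float, float]:
        """(S_col, S_rad) at one energy by log-log interpolation."""
        e = float(np.clip(energy_kev, self.energy_kev[0], self.energy_kev[-1]))
        le = np.log(e)
        lg = np.log(self.energy_kev)
        sc = float(np.exp(np.interp(le, lg, np.log(self.s_col))))
        sr = float(np.exp(np.interp(le, lg, np.log(np.maximum(self.s_rad, 1e-30)))))
        return sc, sr

    def csda_range(self, energy_kev: float) -> float:
        """CSDA range in g/cm^2."""
        e = float(np.clip(energy_kev, self.energy_kev[0], self.energy_kev[-1]))
        return float(np.interp(np.log(e), np.log(self.energy_kev), self.csda_g_cm2))

    def csda_range_mm(self, energy_kev: float) -> float:
        return self.csda_range(energy_kev) / self.material.density * 10.0

    def export_text(self, path) -> None:
        """Columnar text dump (energy, S_col, S_rad, CSDA) for inspection."""
        lines = [
            f"# stopping powers and CSDA range for {self.material.name}",
            "# energy_keV\tS_col_MeV_cm2_g\tS_rad_MeV_cm2_g\tcsda_g_cm2",
        ]
        for e, sc, sr, r in zip(self.energy_kev, self.s_col, self.s_rad, self.csda_g_cm2):
            lines.append(f"{e:.6g}\t{sc:.6e}\t{sr:.6e}\t{r:.6e}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def csda_range(material: Material, energy_kev: float) -> float:
    """CSDA range in g/cm^2 (convenience wrapper building a model)."""
    return StoppingModel.build(material).csda_range(energy_kev)


@dataclass
class CondensedStepResult:
    deposited_mev: float
    new_energy_kev: float
    sigma_theta: float                 # Highland polar-deflection sigma, rad
    polar_deflection: float            # sampled deflection, rad
    brems_photon_kev: float | None     # emitted along the electron direction


def highland_sigma(
    energy_kev: float, path_g_cm2: float, x0_g_cm2: float
) -> float:
    """Highland multiple-scattering sigma_theta for one step (radians)."""
    if path_g_cm2 <= 0:
        return 0.0
    pc_mev = math.sqrt(energy_kev * (energy_kev + 2.0 * ELECTRON_REST_KEV)) / 1000.0
    beta = pc_mev * 1000.0 / (energy_kev + ELECTRON_REST_KEV)
    ratio = path_g_cm2 / x0_g_cm2
    corr = 1.0 + 0.038 * math.log(ratio)
    return 13.6 / (beta * pc_mev) * math.sqrt(ratio) * max(corr, 0.25)


def condensed_step(
    energy_kev: float,
    model: StoppingModel,
    max_ds_cm: float,
    rng: np.random.Generator,
    brems_cutoff_kev: float = 1.0,
    brems_enabled: bool = True,
) -> CondensedStepResult:
    """One class-I condensed-history step of length max_ds_cm.

    Continuous (collisional) loss S_col rho ds is deposited locally; with
    probability S_rad rho ds / E one bremsstrahlung photon with energy drawn
    proportional to 1/k on [cutoff, E_after] is emitted forward and
    subtracted from the electron's kinetic energy, so per-history energy
    conservation stays exact.
    """
    if max_ds_cm <= 0:
        raise ValueError("step length must be positive")
    rho = model.material.density
    s_col, s_rad = model.stopping(energy_kev)
    de_col = min(s_col * rho * max_ds_cm * 1000.0, energy_kev)  # keV
    e_after = energy_kev - de_col
    brems = None
    if brems_enabled and e_after > brems_cutoff_kev:
        p_brem = s_rad * rho * max_ds_cm * 1000.0 / energy_kev
        if rng.random() < p_brem:
            k = brems_cutoff_kev * (e_after / brems_cutoff_kev) ** rng.random()
            brems = float(k)
            e_after -= k
    x = rho * max_ds_cm
    sigma = highland_sigma(energy_kev, x, model.x0_g_cm2)
    theta = sigma * math.sqrt(max(-2.0 * math.log(max(rng.random(), 1e-300)), 0.0))
    return CondensedStepResult(
        deposited_mev=de_col / 1000.0,
        new_energy_kev=e_after,
        sigma_theta=sigma,
        polar_deflection=theta,
        brems_photon_kev=brems,
    )


def electron_cutoff_deposit(
    energy_kev: float, cutoff_kev: float = DEFAULT_ELECTRON_CUTOFF_KEV
) -> float:
    """Residual energy (MeV) deposited locally when E falls below cutoff."""
    if energy_kev > cutoff_kev:
        raise ValueError("electron above cutoff; keep transporting it")
    return energy_kev / 1000.0
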