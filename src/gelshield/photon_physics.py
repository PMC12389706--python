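"""Photon interaction physics: cross sections and event sampling.

Partial mass-attenuation coefficients (photoelectric, incoherent/Compton,
coherent/Rayleigh) come from the frozen per-element tables in
:mod:`gelshield.fixtures`; a material combines them with the mass-fraction
mixture rule, mu/rho(mix) = sum_i w_i mu/rho(element i).  Interpolation is
log-log on each element's own grid; K absorption edges are represented by
duplicated grid energies so interpolation never crosses an edge.

Compton scattering is sampled from the Klein-Nishina differential cross
section on free electrons with the standard composition-rejection (Kahn
style) scheme; coherent scattering keeps the photon energy and redirects it
with Thomson angles (no form factor); the photoelectric effect produces a
photoelectron and, for the filler metals above their K edge, an isotropic
K fluorescence X-ray with probability omega_K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fixtures import (
    ELECTRON_REST_KEV,
    ELEMENT_DATA,
    FLUORESCENT_ELEMENTS,
    load_element_table,
)
from .materials import Material

_ELEMENT_TABLE: dict | None = None


def element_table() -> dict:
    global _ELEMENT_TABLE
    if _ELEMENT_TABLE is None:
        _ELEMENT_TABLE = load_element_table()
    return _ELEMENT_TABLE


class EnergyOutOfRangeError(ValueError):
    pass


def _interp_loglog(energy, grid, values):
    """Log-log interpolation on a grid with possible duplicated edge points.

    A query exactly on a duplicated edge energy returns the value from the
    side being approached from below.  Queries outside the grid span raise
    (no silent extrapolation).
    """
    e = np.atleast_1d(np.asarray(energy, dtype=float))
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        bad = e[(e < grid[0]) | (e > grid[-1])][0]
        raise EnergyOutOfRangeError(
            f"energy {bad} keV outside table span [{grid[0]}, {grid[-1]}] keV"
        )
    # index of the right node of the bracketing interval
    hi = np.searchsorted(grid, e, side="left")
    hi = np.clip(hi, 1, len(grid) - 1)
    lo = hi - 1
    same = grid[hi] == grid[lo]  # duplicated edge: step over it
    lo = np.where(same, lo - 1, lo)
    lg_lo, lg_hi = np.log(grid[lo]), np.log(grid[hi])
    f = np.where(lg_hi > lg_lo, (np.log(e) - lg_lo) / np.where(lg_hi > lg_lo, lg_hi - lg_lo, 1.0), 0.0)
    out = np.exp(np.log(values[lo]) * (1.0 - f) + np.log(values[hi]) * f)
    return out if np.ndim(energy) else float(out[0])


@dataclass(frozen=True)
class PartialMu:
    """Partial mass attenuation coefficients at one energy, cm^2/g."""

    photoelectric: float
    incoherent: float
    coherent: float

    @property
    def total(self) -> float:
        return self.photoelectric + self.incoherent + self.coherent


class MaterialPhotonModel:
    """Mixture-rule photon cross-section model for one material.

    Evaluation sums per-element log-log interpolants weighted by mass
    fraction, which keeps the mixture-consistency invariant exact at grid
    nodes and within interpolation tolerance everywhere else.
    """

    def __init__(self, material: Material, coherent_enabled: bool = True):
        self.material = material
        self.coherent_enabled = coherent_enabled
        table = element_table()
        self._parts = []  # (weight, grid, pe, inc, coh) per element
        for sym, w in material.composition.items():
            if w == 0.0:
                continue
            t = table[sym]
            self._parts.append(
                (w, sym, t["energy"], t["photoelectric"], t["incoherent"], t["coherent"])
            )
        self.energy_min = max(p[2][0] for p in self._parts)
        self.energy_max = min(p[2][-1] for p in self._parts)

    def partials(self, energy_kev):
        """Vectorized (photoelectric, incoherent, coherent) in cm^2/g."""
        e = np.asarray(energy_kev, dtype=float)
        pe = np.zeros_like(e, dtype=float)
        inc = np.zeros_like(pe)
        coh = np.zeros_like(pe)
        for w, _sym, grid, tpe, tinc, tcoh in self._parts:
            pe = pe + w * _interp_loglog(e, grid, tpe)
            inc = inc + w * _interp_loglog(e, grid, tinc)
            coh = coh + w * _interp_loglog(e, grid, tcoh)
        if not self.coherent_enabled:
            coh = np.zeros_like(coh)
        return pe, inc, coh

    def photoelectric_element_fractions(self, energy_kev: float) -> dict[str, float]:
        """P(absorbing element | photoelectric event) at one energy."""
        contrib = {}
        for w, sym, grid, tpe, _i, _c in self._parts:
            contrib[sym] = w * float(_interp_loglog(energy_kev, grid, tpe))
        total = sum(contrib.values())
        return {sym: v / total for sym, v in contrib.items()}


def mu_over_rho(model: MaterialPhotonModel, energy_kev: float) -> PartialMu:
    """Partial and total mass attenuation for the model's material."""
    pe, inc, coh = model.partials(float(energy_kev))
    return PartialMu(float(pe), float(inc), float(coh))


def sample_path_length(
    model: MaterialPhotonModel, rho: float, energy_kev: float, rng: np.random.Generator
) -> float:
    """Free path (cm) to the next interaction: exponential with mean 1/mu."""
    mu = mu_over_rho(model, energy_kev).total * rho
    return float(-np.log(rng.random()) / mu)


def select_interaction(
    model: MaterialPhotonModel, energy_kev: float, rng: np.random.Generator
) -> str:
    """Draw the interaction channel proportionally to the partial mu/rho."""
    p = mu_over_rho(model, energy_kev)
    x = rng.random() * p.total
    if x < p.photoelectric:
        return "photoelectric"
    if x < p.photoelectric + p.incoherent:
        return "incoherent"
    return "coherent"


def compton_scattered_energy(energy_kev: float, cos_theta: float) -> float:
    """Compton relation E' = E / (1 + alpha (1 - cos theta))."""
    alpha = energy_kev / ELECTRON_REST_KEV
    return energy_kev / (1.0 + alpha * (1.0 - cos_theta))


@dataclass(frozen=True)
class ComptonSample:
    e_scattered_kev: float
    cos_theta_photon: float
    e_electron_kev: float
    cos_theta_electron: float


def sample_compton(energy_kev: float, rng: np.random.Generator) -> ComptonSample:
    """Klein-Nishina sample on a free electron (composition-rejection).

    Energy is conserved exactly: E_scattered + E_electron = E.
    """
    alpha = energy_kev / ELECTRON_REST_KEV
    eps_min = 1.0 / (1.0 + 2.0 * alpha)
    a1 = -np.log(eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    while True:
        if rng.random() * (a1 + a2) < a1:
            eps = float(np.exp(-a1 * rng.random()))
        else:
            eps = float(np.sqrt(eps_min * eps_min + (1.0 - eps_min * eps_min) * rng.random()))
        t = (1.0 - eps) / (alpha * eps)
        sin2 = t * (2.0 - t)
        if rng.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            break
    cos_theta = 1.0 - t
    e_sc = eps * energy_kev
    e_el = energy_kev - e_sc
    # electron angle from momentum conservation
    p_el = np.sqrt(e_el * (e_el + 2.0 * ELECTRON_REST_KEV))
    cos_el = (energy_kev - e_sc * cos_theta) / p_el if p_el > 0 else 1.0
    cos_el = float(np.clip(cos_el, -1.0, 1.0))
    return ComptonSample(e_sc, float(cos_theta), e_el, cos_el)


@dataclass(frozen=True)
class PhotoelectricResult:
    electron_energy_kev: float
    local_deposit_kev: float
    fluorescence_kev: float | None  # isotropic K X-ray, if emitted
    element: str


def photoelectric_event(
    model: MaterialPhotonModel, energy_kev: float, rng: np.random.Generator
) -> PhotoelectricResult:
    """Photoelectric absorption outcome.

    The absorbing element is drawn proportionally to w_i * mu_pe,i.  For Zn
    and Bi above their K edge an isotropic K X-ray of energy e_Kx is emitted
    with probability omega_K; the photoelectron then carries E - E_K and the
    relaxation remainder E_K - e_Kx is deposited locally.  Otherwise the
    photoelectron carries the full photon energy (binding deposited locally
    through the electron cascade).
    """
    fracs = model.photoelectric_element_fractions(energy_kev)
    symbols = list(fracs)
    probs = np.array([fracs[s] for s in symbols])
    sym = symbols[int(rng.choice(len(symbols), p=probs / probs.sum()))]
    el = ELEMENT_DATA[sym]
    if (
        sym in FLUORESCENT_ELEMENTS
        and energy_kev > el["k_edge"]
        and rng.random() < el["omega_K"]
    ):
        return PhotoelectricResult(
            electron_energy_kev=energy_kev - el["k_edge"],
            local_deposit_kev=el["k_edge"] - el["e_kx"],
            fluorescence_kev=el["e_kx"],
            element=sym,
        )
    return PhotoelectricResult(
        electron_energy_kev=energy_kev,
        local_deposit_kev=0.0,
        fluorescence_kev=None,
        element=sym,
    )


def sample_coherent_angle(energy_kev: float, rng: np.random.Generator) -> float:
    """Thomson angular sample, pdf proportional to 1 + cos^2 theta."""
    while True:
        c = 2.0 * rng.random() - 1.0
        if rng.random() <= 0.5 * (1.0 + c * c):
            return float(c)
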