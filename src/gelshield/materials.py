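"""Composite material definitions for pads, fillers and tissues.

A :class:`Material` couples a mass density with an elemental mass-fraction
:class:`Composition`.  Pads are hydrated polymer composites (80 wt% water,
20 wt% dry polymer) optionally doped with ZnO or Bi2O3 at 5/10 wt%; tissue
layers use embedded ICRP-style compositions.  Mixing follows the standard
mass-fraction mixture rule; density combines by inverse specific volume,
1/rho = sum f_k / rho_k, the usual rule for intimate composites (an explicit
density override is available for sensitivity studies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import yaml

from .fixtures import ELEMENT_DATA, TISSUE_DATA

_SUM_TOL = 1e-9

#: dry-polymer densities (g/cm^3) and formulas of the three carbohydrate
#: matrices, plus the two oxide fillers.
POLYMERS: dict[str, dict] = {
    "chitosan": {"density": 1.05, "formula": {"C": 6, "H": 11, "N": 1, "O": 4}},
    "alginate": {"density": 1.05, "formula": {"C": 6, "H": 7, "Na": 1, "O": 6}},
    "cellulose": {"density": 1.10, "formula": {"C": 6, "H": 10, "O": 5}},
}
FILLERS: dict[str, dict] = {
    "Bi2O3": {"density": 8.90, "formula": {"Bi": 2, "O": 3}},
    "ZnO": {"density": 5.60, "formula": {"Zn": 1, "O": 1}},
}
WATER_DENSITY = 1.0


class UnknownElementError(KeyError):
    pass


@dataclass(frozen=True)
class ElementRecord:
    symbol: str
    Z: int
    A: float
    I_ev: float
    k_edge_kev: float
    omega_K: float
    e_kx_kev: float

    def __post_init__(self) -> None:
        if self.Z < 1 or self.A <= 0 or self.I_ev <= 0:
            raise ValueError(f"invalid atomic data for {self.symbol}")
        if not (0.0 <= self.omega_K <= 1.0):
            raise ValueError(f"omega_K out of [0,1] for {self.symbol}")
        if not (0.0 < self.e_kx_kev <= self.k_edge_kev):
            raise ValueError(f"K X-ray energy must lie in (0, K-edge] for {self.symbol}")


def element_record(symbol: str) -> ElementRecord:
    try:
        d = ELEMENT_DATA[symbol]
    except KeyError:
        raise UnknownElementError(
            f"element {symbol!r} not in the embedded atomic-data table"
        ) from None
    return ElementRecord(symbol, d["Z"], d["A"], d["I"], d["k_edge"], d["omega_K"], d["e_kx"])


@dataclass(frozen=True)
class Composition:
    """Elemental mass fractions; must be non-negative and sum to one."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        for sym, w in self.fractions.items():
            if sym not in ELEMENT_DATA:
                raise UnknownElementError(
                    f"element {sym!r} not in the embedded atomic-data table"
                )
            if w < 0:
                raise ValueError(f"negative mass fraction for {sym}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"mass fractions sum to {total!r}, expected 1")

    def __getitem__(self, symbol: str) -> float:
        return self.fractions.get(symbol, 0.0)

    def items(self):
        return self.fractions.items()


@dataclass(frozen=True)
class Material:
    name: str
    density: float  # g/cm^3
    composition: Composition
    provenance: str = "derived-mixture"

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")

    # -- plain-text serialization ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "density": self.density,
            "mass_fractions": dict(self.composition.fractions),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Material":
        if "formula" in d:
            comp = composition_from_formula(d["formula"])
        else:
            comp = Composition(dict(d["mass_fractions"]))
        return cls(d["name"], float(d["density"]), comp, d.get("provenance", "derived-mixture"))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Material":
        return cls.from_dict(yaml.safe_load(text))


def composition_from_formula(formula: dict[str, int | float]) -> Composition:
    """Mass fractions from an element -> atom-count mapping.

    w_i = n_i A_i / sum_j n_j A_j.
    """
    if not formula:
        raise ValueError("empty formula")
    masses = {}
    for sym, n in formula.items():
        if sym not in ELEMENT_DATA:
            raise UnknownElementError(
                f"element {sym!r} not in the embedded atomic-data table"
            )
        if n <= 0:
            raise ValueError(f"non-positive atom count for {sym}")
        masses[sym] = n * ELEMENT_DATA[sym]["A"]
    total = sum(masses.values())
    return Composition({sym: m / total for sym, m in masses.items()})


def mix_by_mass(
    components: list[tuple[Material, float]],
    name: str | None = None,
    density_override: float | None = None,
) -> Material:
    """Mass-fraction mixture of materials.

    Element fractions are f-weighted sums; density follows the
    inverse-volume rule 1/rho = sum f_k/rho_k unless overridden.
    """
    fracs = [f for _, f in components]
    if any(f < 0 for f in fracs):
        raise ValueError("component fractions must be non-negative")
    total = sum(fracs)
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"component fractions sum to {total!r}, expected 1")
    elements: dict[str, float] = {}
    inv_rho = 0.0
    for mat, f in components:
        if f == 0.0:
            continue
        for sym, w in mat.composition.items():
            elements[sym] = elements.get(sym, 0.0) + f * w
        inv_rho += f / mat.density
    density = density_override if density_override is not None else 1.0 / inv_rho
    if name is None:
        name = " + ".join(f"{f:g}*{m.name}" for m, f in components if f > 0)
    return Material(name, density, Composition(elements), provenance="derived-mixture")


def water() -> Material:
    return Material("water", WATER_DENSITY, composition_from_formula({"H": 2, "O": 1}),
                    provenance="literature-table")


def dry_polymer(polymer: str) -> Material:
    try:
        d = POLYMERS[polymer]
    except KeyError:
        raise KeyError(f"unknown polymer {polymer!r}; choose from {sorted(POLYMERS)}") from None
    return Material(polymer, d["density"], composition_from_formula(d["formula"]),
                    provenance="literature-table")


def filler_material(filler: str) -> Material:
    try:
        d = FILLERS[filler]
    except KeyError:
        raise KeyError(f"unknown filler {filler!r}; choose from {sorted(FILLERS)}") from None
    return Material(filler, d["density"], composition_from_formula(d["formula"]),
                    provenance="literature-table")


def hydrated_gel(polymer: str) -> Material:
    """80 wt% water / 20 wt% dry polymer base hydrogel."""
    gel = mix_by_mass([(water(), 0.8), (dry_polymer(polymer), 0.2)],
                      name=f"{polymer} hydrogel")
    return gel


def make_pad_material(
    polymer: str,
    filler: str = "none",
    filler_wt: float = 0.0,
    density_override: float | None = None,
) -> Material:
    """Doped hydrogel pad: (1-f) hydrated gel + f oxide filler by mass."""
    if filler_wt < 0 or filler_wt > 0.5:
        raise ValueError(
            f"filler mass fraction {filler_wt} outside [0, 0.5]; heavier loadings "
            "are physically implausible for a flexible hydrogel"
        )
    gel = hydrated_gel(polymer)
    if filler == "none" or filler_wt == 0.0:
        if filler != "none" and filler_wt == 0.0:
            pass  # zero loading of a named filler is just the base gel
        if density_override is not None:
            gel = Material(gel.name, density_override, gel.composition, gel.provenance)
        return gel
    doped = mix_by_mass(
        [(gel, 1.0 - filler_wt), (filler_material(filler), filler_wt)],
        name=f"{polymer} + {filler} {100 * filler_wt:g}%",
        density_override=density_override,
    )
    return doped


def tissue_material(layer: str) -> Material:
    """Embedded ICRP-style tissue for a phantom layer name.

    Layer thicknesses belong to the geometry (transport module), not here.
    """
    try:
        d = TISSUE_DATA[layer]
    except KeyError:
        raise KeyError(
            f"unknown tissue layer {layer!r}; choose from {sorted(TISSUE_DATA)}"
        ) from None
    comp = dict(d["composition"])
    total = sum(comp.values())
    if abs(total - 1.0) > 5e-3:
        raise ValueError(f"embedded composition for {layer} sums to {total}")
    comp = {k: v / total for k, v in comp.items()}
    return Material(layer, d["density"], Composition(comp), provenance="ICRP-embedded")


@dataclass(frozen=True)
class EffectiveParams:
    """Mixture-rule effective parameters for electron physics."""

    z_over_a: float          # <Z/A>, mol electrons per gram (x N_A)
    ln_i_ev: float           # Bragg-additivity ln I, I in eV
    x0_g_cm2: float          # radiation length
    z_eff: float             # sum w Z^2/A / sum w Z/A (bremsstrahlung weighting)

    @property
    def i_ev(self) -> float:
        return math.exp(self.ln_i_ev)


def _element_x0(Z: int, A: float) -> float:
    # Tsai-style approximate radiation length, g/cm^2
    return 716.408 * A / (Z * (Z + 1) * math.log(287.0 / math.sqrt(Z)))


def effective_params(material: Material) -> EffectiveParams:
    """<Z/A>, Bragg-additivity ln I, radiation length and Z_eff."""
    z_over_a = 0.0
    ln_i_num = 0.0
    inv_x0 = 0.0
    z2_over_a = 0.0
    for sym, w in material.composition.items():
        el = ELEMENT_DATA[sym]
        za = el["Z"] / el["A"]
        z_over_a += w * za
        ln_i_num += w * za * math.log(el["I"])
        inv_x0 += w / _element_x0(el["Z"], el["A"])
        z2_over_a += w * el["Z"] ** 2 / el["A"]
    return EffectiveParams(
        z_over_a=z_over_a,
        ln_i_ev=ln_i_num / z_over_a,
        x0_g_cm2=1.0 / inv_x0,
        z_eff=z2_over_a / z_over_a,
    )
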