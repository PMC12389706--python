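"""Layered-slab geometry, beams, tallies and the analog history loop.

The phantom is the four-layer skin model used throughout: 0.1 mm epidermis,
1.0 mm dermis, 10 mm subcutaneous fat and 100 mm skeletal muscle, backed by
100 mm of water to emulate a water-tank world; an optional hydrogel pad of
2 or 10 mm sits on top, with the source abutting it in vacuum.  Depth z
increases into the phantom, the pad occupying [-t_pad, 0) mm.

`run_beam` drives the numba kernel in independent seeded batches (one
generator per batch, spawned from the master seed with
numpy SeedSequence), giving bit-reproducible tallies and a batch-based
standard error per layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .fixtures import ELEMENT_DATA
from .materials import Material, effective_params, tissue_material
from .electron_physics import _collision_stopping_scalar
from .photon_physics import MaterialPhotonModel, _interp_loglog, element_table

#: tissue layer recipe: (name, thickness mm)
TISSUE_LAYERS = (
    ("epidermis", 0.1),
    ("dermis", 1.0),
    ("subcut", 10.0),
    ("muscle", 100.0),
    ("backing", 100.0),
)

_GRID_LO_KEV = 1.0
_GRID_HI_KEV = 2000.0
_GRID_N = 1024


@dataclass(frozen=True)
class Layer:
    name: str
    material: Material
    z_min_mm: float
    z_max_mm: float

    @property
    def thickness_mm(self) -> float:
        return self.z_max_mm - self.z_min_mm


@dataclass(frozen=True)
class LayerStack:
    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.layers, self.layers[1:]):
            if not np.isclose(a.z_max_mm, b.z_min_mm):
                raise ValueError(f"layers {a.name}/{b.name} not contiguous")
            if b.z_max_mm <= b.z_min_mm:
                raise ValueError(f"layer {b.name} has non-positive thickness")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.layers)

    @property
    def boundaries_mm(self) -> np.ndarray:
        return np.array([self.layers[0].z_min_mm] + [l.z_max_mm for l in self.layers])

    def __getitem__(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)


def build_stack(pad: tuple[Material, float] | None = None) -> LayerStack:
    """Stack of (optional pad) + epidermis/dermis/subcut/muscle + water backing."""
    layers = []
    z = 0.0
    if pad is not None:
        pad_material, t_pad = pad
        if t_pad <= 0:
            raise ValueError("pad thickness must be positive")
        layers.append(Layer("pad", pad_material, -t_pad, 0.0))
    for name, thick in TISSUE_LAYERS:
        layers.append(Layer(name, tissue_material(name), z, z + thick))
        z += thick
    return LayerStack(tuple(layers))


@dataclass(frozen=True)
class BeamSpec:
    """Pencil beam at normal incidence on the stack's top surface."""

    particle: str            # "photon" | "electron"
    energy_kev: float
    n_histories: int
    seed: int

    def __post_init__(self) -> None:
        if self.particle not in ("photon", "electron"):
            raise ValueError(f"unknown particle {self.particle!r}")
        if self.energy_kev <= 0:
            raise ValueError("beam energy must be positive")
        if self.n_histories < 1:
            raise ValueError("need at least one history")


@dataclass(frozen=True)
class TransportOptions:
    photon_cutoff_kev: float = 1.0
    electron_cutoff_kev: float = 10.0
    coherent_enabled: bool = True
    brems_enabled: bool = True
    absorb_only: bool = False        # test mode: first interaction absorbs
    mu_scale: float = 1.0            # test knob: scale photon attenuation
    max_step_frac: float = 0.05      # condensed-history energy-loss fraction


@dataclass
class Tally:
    """Per-layer energy deposition, MeV per primary, with batch SE."""

    layer_names: tuple[str, ...]
    e0_mev: float
    n_histories: int
    n_batches: int
    sums_mev: np.ndarray        # (layers+2,) total deposited energy
    sumsq_mev: np.ndarray       # per-history sum of squares
    batch_means: np.ndarray     # (batches, layers+2)

    @property
    def mean_mev(self) -> np.ndarray:
        return self.sums_mev / self.n_histories

    @property
    def se_mev(self) -> np.ndarray:
        b = self.n_batches
        if b < 2:
            return np.full_like(self.sums_mev, np.nan)
        m = self.batch_means.mean(axis=0)
        return np.sqrt(((self.batch_means - m) ** 2).sum(axis=0) / (b * (b - 1)))

    @property
    def se_mev_pooled(self) -> np.ndarray:
        """SE from per-history moments (smoother than the batch estimate)."""
        n = self.n_histories
        var = self.sumsq_mev / n - self.mean_mev**2
        return np.sqrt(np.maximum(var, 0.0) / n)

    def layer_mean(self, name: str) -> float:
        return float(self.mean_mev[self.layer_names.index(name)])

    def layer_se(self, name: str) -> float:
        return float(self.se_mev[self.layer_names.index(name)])

    @property
    def escape_up_mev(self) -> float:
        return float(self.mean_mev[-2])

    @property
    def escape_down_mev(self) -> float:
        return float(self.mean_mev[-1])

    def conservation_residual(self) -> float:
        """Sum of layer means and escapes minus the beam energy (MeV)."""
        return float(self.mean_mev.sum() - self.e0_mev)

    def to_frame(self) -> pd.DataFrame:
        names = list(self.layer_names) + ["escape_up", "escape_down"]
        return pd.DataFrame(
            {
                "layer": names,
                "mean_mev_per_primary": self.mean_mev,
                "se_mev": self.se_mev,
                "n_histories": self.n_histories,
            }
        )


# --------------------------------------------------------------------------
# packed per-material physics tables for the kernel
# --------------------------------------------------------------------------
_PACK_CACHE: dict[tuple, dict] = {}


def _material_key(mat: Material) -> tuple:
    comp = tuple(sorted(mat.composition.fractions.items()))
    return (mat.name, round(mat.density, 12), comp)


def _pack_material(mat: Material) -> dict:
    key = _material_key(mat)
    pack = _PACK_CACHE.get(key)
    if pack is not None:
        return pack
    grid = np.geomspace(_GRID_LO_KEV, _GRID_HI_KEV, _GRID_N)
    model = MaterialPhotonModel(mat)
    pe, inc, coh = model.partials(grid)
    table = element_table()
    w_bi = mat.composition["Bi"]
    w_zn = mat.composition["Zn"]
    p_bi = np.zeros(_GRID_N)
    p_zn = np.zeros(_GRID_N)
    if w_bi > 0:
        t = table["Bi"]
        p_bi = w_bi * _interp_loglog(grid, t["energy"], t["photoelectric"]) / pe
    if w_zn > 0:
        t = table["Zn"]
        p_zn = w_zn * _interp_loglog(grid, t["energy"], t["photoelectric"]) / pe
    params = effective_params(mat)
    s_col = np.array(
        [_collision_stopping_scalar(params.z_over_a, params.i_ev, e) for e in grid]
    )
    s_rad = s_col * params.z_eff * (grid / 1000.0) / 800.0
    pack = {
        "ln_mu_pe": np.log(pe),
        "ln_mu_in": np.log(inc),
        "ln_mu_coh": np.log(coh),
        "p_bi": p_bi,
        "p_zn": p_zn,
        "ln_s_col": np.log(s_col),
        "ln_s_rad": np.log(np.maximum(s_rad, 1e-300)),
        "rho": mat.density,
        "inv_x0": 1.0 / params.x0_g_cm2,
    }
    _PACK_CACHE[key] = pack
    return pack


def _pack_stack(stack: LayerStack) -> dict:
    mats: list[Material] = []
    mat_idx = []
    keys: dict[tuple, int] = {}
    for layer in stack.layers:
        k = _material_key(layer.material)
        if k not in keys:
            keys[k] = len(mats)
            mats.append(layer.material)
        mat_idx.append(keys[k])
    packs = [_pack_material(m) for m in mats]
    stacked = {
        name: np.stack([p[name] for p in packs])
        for name in ("ln_mu_pe", "ln_mu_in", "ln_mu_coh", "p_bi", "p_zn",
                     "ln_s_col", "ln_s_rad")
    }
    grid = np.geomspace(_GRID_LO_KEV, _GRID_HI_KEV, _GRID_N)
    return {
        "zb_cm": stack.boundaries_mm / 10.0,
        "mat_of_layer": np.array(mat_idx, dtype=np.int64),
        "rho": np.array([p["rho"] for p in packs]),
        "inv_x0": np.array([p["inv_x0"] for p in packs]),
        "ln_e0": float(np.log(grid[0])),
        "inv_dln": float(1.0 / (np.log(grid[1]) - np.log(grid[0]))),
        **stacked,
    }


def _kernel_args(pack: dict, opts: TransportOptions) -> tuple:
    bi = ELEMENT_DATA["Bi"]
    zn = ELEMENT_DATA["Zn"]
    return (
        pack["zb_cm"], pack["mat_of_layer"], pack["rho"],
        pack["ln_mu_pe"], pack["ln_mu_in"], pack["ln_mu_coh"],
        pack["p_bi"], pack["p_zn"],
        pack["ln_s_col"], pack["ln_s_rad"], pack["inv_x0"],
        pack["ln_e0"], pack["inv_dln"], _GRID_N,
        bi["k_edge"], bi["omega_K"], bi["e_kx"],
        zn["k_edge"], zn["omega_K"], zn["e_kx"],
        opts.photon_cutoff_kev, opts.electron_cutoff_kev,
        opts.coherent_enabled, opts.absorb_only, opts.brems_enabled,
        opts.mu_scale, opts.max_step_frac,
    )


def transport_history(
    beam: BeamSpec,
    stack: LayerStack,
    rng: np.random.Generator,
    options: TransportOptions = TransportOptions(),
    n_histories: int = 1,
) -> np.ndarray:
    """Transport a few histories; returns summed deposits (MeV), length
    n_layers+2 with escape-upstream and escape-downstream accounts last."""
    pack = _pack_stack(stack)
    n_slots = len(stack.layers) + 2
    out_sum = np.zeros(n_slots)
    out_sumsq = np.zeros(n_slots)
    kind = _kernel.KIND_PHOTON if beam.particle == "photon" else _kernel.KIND_ELECTRON
    _kernel.run_batch(
        n_histories, kind, beam.energy_kev,
        *_kernel_args(pack, options), rng, out_sum, out_sumsq,
    )
    return out_sum


def run_beam(
    beam: BeamSpec,
    stack: LayerStack,
    options: TransportOptions = TransportOptions(),
    batches: int = 20,
) -> Tally:
    """Run the full beam in seeded batches and tally per-layer deposition."""
    if not (10 <= batches <= beam.n_histories):
        raise ValueError("need n_histories >= batches >= 10")
    pack = _pack_stack(stack)
    kind = _kernel.KIND_PHOTON if beam.particle == "photon" else _kernel.KIND_ELECTRON
    n_slots = len(stack.layers) + 2
    args = _kernel_args(pack, options)

    per_batch = np.full(batches, beam.n_histories // batches)
    per_batch[: beam.n_histories % batches] += 1
    children = np.random.SeedSequence(beam.seed).spawn(batches)

    sums = np.zeros(n_slots)
    sumsq = np.zeros(n_slots)
    batch_means = np.zeros((batches, n_slots))
    for b in range(batches):
        rng = np.random.Generator(np.random.PCG64(children[b]))
        bs = np.zeros(n_slots)
        bq = np.zeros(n_slots)
        _kernel.run_batch(int(per_batch[b]), kind, beam.energy_kev, *args, rng, bs, bq)
        sums += bs
        sumsq += bq
        batch_means[b] = bs / per_batch[b]
    return Tally(
        layer_names=stack.names,
        e0_mev=beam.energy_kev / 1000.0,
        n_histories=beam.n_histories,
        n_batches=batches,
        sums_mev=sums,
        sumsq_mev=sumsq,
        batch_means=batch_means,
    )
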