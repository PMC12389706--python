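"""Configuration sweeps, derived shielding metrics and heatmap reporting.

The default grid mirrors the study design: three carbohydrate polymers
(alginate, chitosan, cellulose) x five filler states (pure, ZnO 5/10 wt%,
Bi2O3 5/10 wt%) x two pad thicknesses (2, 10 mm) plus a No-Pad control,
each irradiated by monoenergetic photon and electron pencil beams at 50,
100, 300, 500 and 1000 keV.  Results are long-format records of mean
energy deposited per primary (MeV) per layer, with batch standard errors,
from which relative dose changes versus the No-Pad control are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .materials import make_pad_material
from .transport import BeamSpec, TransportOptions, build_stack, run_beam

DEFAULT_POLYMERS = ("alginate", "chitosan", "cellulose")
DEFAULT_FILLER_STATES = (
    ("none", 0.0), ("ZnO", 0.05), ("ZnO", 0.10), ("Bi2O3", 0.05), ("Bi2O3", 0.10),
)
DEFAULT_THICKNESSES_MM = (2.0, 10.0)
DEFAULT_ENERGIES_KEV = (50.0, 100.0, 300.0, 500.0, 1000.0)
NO_PAD_ID = "no-pad"


def pad_label(polymer: str | None, filler: str = "none", filler_wt: float = 0.0) -> str:
    if polymer is None:
        return NO_PAD_ID
    if filler == "none" or filler_wt == 0.0:
        return polymer
    return f"{polymer}+{filler} {100 * filler_wt:g}%"


@dataclass(frozen=True)
class RunConfig:
    """One runnable (pad state, particle, energy) cell of the sweep."""

    pad_id: str
    polymer: str | None
    filler: str
    filler_wt: float
    thickness_mm: float      # 0 for the No-Pad control
    particle: str
    energy_kev: float
    n_histories: int
    seed: int

    @property
    def has_pad(self) -> bool:
        return self.polymer is not None


@dataclass(frozen=True)
class SweepConfig:
    polymers: tuple[str, ...] = DEFAULT_POLYMERS
    fillers: tuple[tuple[str, float], ...] = DEFAULT_FILLER_STATES
    thicknesses_mm: tuple[float, ...] = DEFAULT_THICKNESSES_MM
    include_no_pad: bool = True
    particles: tuple[str, ...] = ("photon", "electron")
    energies_kev: tuple[float, ...] = DEFAULT_ENERGIES_KEV
    n_histories: int = 100_000
    seed: int = 0


def enumerate_configs(spec: SweepConfig) -> list[RunConfig]:
    """Deterministically ordered list of runnable configurations.

    Per-run seeds derive from the master seed through a generate_state
    splitting of numpy's SeedSequence, so any single run can be reproduced
    in isolation.
    """
    pad_states: list[tuple[str | None, str, float, float]] = []
    for polymer in spec.polymers:
        for filler, wt in spec.fillers:
            for t in spec.thicknesses_mm:
                pad_states.append((polymer, filler, wt, t))
    if spec.include_no_pad:
        pad_states.append((None, "none", 0.0, 0.0))

    n_runs = len(pad_states) * len(spec.particles) * len(spec.energies_kev)
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_runs) & 0x7FFFFFFF

    configs = []
    i = 0
    for polymer, filler, wt, t in pad_states:
        base = pad_label(polymer, filler, wt)
        pad_id = base if polymer is None else f"{base}@{t:g}mm"
        for particle in spec.particles:
            for e in spec.energies_kev:
                configs.append(
                    RunConfig(
                        pad_id=pad_id, polymer=polymer, filler=filler,
                        filler_wt=wt, thickness_mm=t, particle=particle,
                        energy_kev=e, n_histories=spec.n_histories,
                        seed=int(seeds[i]),
                    )
                )
                i += 1
    return configs


@dataclass
class SweepResult:
    """Long-format sweep records plus run metadata."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def get(self, pad_id: str, particle: str, energy_kev: float, layer: str):
        f = self.frame
        row = f[
            (f.pad_id == pad_id) & (f.particle == particle)
            & (f.energy_kev == energy_kev) & (f.layer == layer)
        ]
        if row.empty:
            raise KeyError(
                f"no record for ({pad_id}, {particle}, {energy_kev} keV, {layer})"
            )
        r = row.iloc[0]
        return float(r.mean_mev), float(r.se_mev)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def run_config(cfg: RunConfig, options: TransportOptions = TransportOptions(),
               batches: int = 20) -> pd.DataFrame:
    """Run one configuration and return its long-format records."""
    if cfg.has_pad:
        pad_mat = make_pad_material(cfg.polymer, cfg.filler, cfg.filler_wt)
        stack = build_stack((pad_mat, cfg.thickness_mm))
    else:
        stack = build_stack(None)
    beam = BeamSpec(cfg.particle, cfg.energy_kev, cfg.n_histories, cfg.seed)
    tally = run_beam(beam, stack, options, batches=batches)
    names = list(tally.layer_names) + ["escape_up", "escape_down"]
    return pd.DataFrame(
        {
            "pad_id": cfg.pad_id,
            "polymer": cfg.polymer if cfg.polymer else "",
            "filler": cfg.filler,
            "filler_wt": cfg.filler_wt,
            "thickness_mm": cfg.thickness_mm,
            "particle": cfg.particle,
            "energy_kev": cfg.energy_kev,
            "layer": names,
            "mean_mev": tally.mean_mev,
            "se_mev": tally.se_mev,
            "n_histories": cfg.n_histories,
        }
    )


def run_sweep(
    spec: SweepConfig,
    options: TransportOptions = TransportOptions(),
    batches: int = 20,
    progress: bool = False,
) -> SweepResult:
    frames = []
    configs = enumerate_configs(spec)
    for i, cfg in enumerate(configs):
        if progress:
            print(f"[{i + 1}/{len(configs)}] {cfg.pad_id} {cfg.particle} "
                  f"{cfg.energy_kev:g} keV")
        frames.append(run_config(cfg, options, batches))
    frame = pd.concat(frames, ignore_index=True)
    meta = {"seed": spec.seed, "n_histories": spec.n_histories, "runs": len(configs)}
    return SweepResult(frame, meta)


def relative_metric(
    result: SweepResult, pad_id: str, layer: str, energy_kev: float, particle: str
) -> tuple[float, float]:
    """Percent change of layer dose vs the No-Pad control, with propagated SE."""
    m_pad, se_pad = result.get(pad_id, particle, energy_kev, layer)
    m0, se0 = result.get(NO_PAD_ID, particle, energy_kev, layer)
    if m0 == 0:
        raise ZeroDivisionError("No-Pad control deposit is zero")
    pct = 100.0 * (m_pad - m0) / m0
    se = 100.0 * np.hypot(se_pad / m0, m_pad * se0 / m0**2)
    return pct, se


def pad_heatmap(
    result: SweepResult, particle: str, thickness_mm: float
) -> pd.DataFrame:
    """Pad-layer deposition matrix (pad composition rows x energy columns).

    Values are MeV per primary deposited inside the pad itself; the No-Pad
    control has no pad layer and is excluded.
    """
    f = result.frame
    sel = f[
        (f.particle == particle) & (f.thickness_mm == thickness_mm)
        & (f.layer == "pad") & (f.pad_id != NO_PAD_ID)
    ]
    if sel.empty:
        raise ValueError(f"sweep contains no pad-layer records at {thickness_mm} mm")
    sel = sel.assign(
        composition=[
            pad_label(r.polymer, r.filler, r.filler_wt) for r in sel.itertuples()
        ]
    )
    mat = sel.pivot_table(index="composition", columns="energy_kev", values="mean_mev")
    order = [
        pad_label(p, f_, w)
        for p in DEFAULT_POLYMERS
        for f_, w in DEFAULT_FILLER_STATES
        if pad_label(p, f_, w) in mat.index
    ]
    extra = [c for c in mat.index if c not in order]
    return mat.loc[order + extra]


def render_heatmap(matrix: pd.DataFrame, path, title: str = "") -> None:
    """Save a labeled heatmap figure (values are MeV per primary)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.45 * len(matrix.index) + 2))
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)),
                  [f"{c:g}" for c in matrix.columns])
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.set_xlabel("beam energy (keV)")
    ax.set_title(title or "pad-layer energy deposition (MeV per primary)")
    fig.colorbar(im, ax=ax, label="MeV per primary")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def attenuation_summary(result: SweepResult) -> pd.DataFrame:
    """Per-layer percent dose reduction vs No Pad for every configuration.

    Positive values mean shielding (dose lowered); negative values mean
    enhancement.  Reductions are bounded above by 100%.
    """
    f = result.frame
    controls = f[f.pad_id == NO_PAD_ID].set_index(["particle", "energy_kev", "layer"])
    rows = []
    tissue = ("epidermis", "dermis", "subcut", "muscle")
    for r in f[(f.pad_id != NO_PAD_ID) & (f.layer.isin(tissue))].itertuples():
        try:
            ctrl = controls.loc[(r.particle, r.energy_kev, r.layer)]
        except KeyError:
            continue
        m0, se0 = float(ctrl.mean_mev), float(ctrl.se_mev)
        if m0 <= 0:
            continue
        reduction = -100.0 * (r.mean_mev - m0) / m0
        se = 100.0 * np.hypot(r.se_mev / m0, r.mean_mev * se0 / m0**2)
        rows.append(
            {
                "pad_id": r.pad_id, "particle": r.particle,
                "energy_kev": r.energy_kev, "layer": r.layer,
                "reduction_percent": reduction, "se_percent": se,
            }
        )
    return pd.DataFrame(rows)
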