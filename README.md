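# gelshield

Monte Carlo dosimetry of carbohydrate-hydrogel radiotherapy pads doped with
high-Z oxide fillers (Bi₂O₃, ZnO), evaluated on a layered skin phantom.

Flexible hydrogel pads — 80 wt% water, 20 wt% alginate, chitosan or
cellulose — are candidate shielding/bolus materials for superficial
radiotherapy. Loading them with a high-atomic-number oxide raises their
photon interaction cross sections (the photoelectric cross section scales
roughly as Z³/E³), but also creates secondary photoelectrons and K
fluorescence that can *increase* the skin dose at low photon energies.
`gelshield` quantifies these trade-offs with a coupled photon–electron
transport engine:

* **Photons**: analog transport with photoelectric absorption, incoherent
  (Compton) scattering sampled from the Klein–Nishina differential cross
  section, and coherent (Rayleigh) scattering with Thomson angles.
  Per-element partial mass-attenuation tables (1 keV – 2 MeV, K edges
  duplicated) combine by the mixture rule μ/ρ = Σᵢ wᵢ (μ/ρ)ᵢ.
  Zn and Bi emit K X-rays with probability ω_K above their K edge.
* **Electrons**: class-I condensed-history transport — Bethe collision
  stopping with Bragg-additivity mean excitation energy, CSDA energy loss,
  Highland multiple scattering σ_θ = (13.6 MeV/βcp)·√(x/X₀)(1+0.038 ln x/X₀),
  and a 1/k bremsstrahlung spectrum emitted forward with probability
  S_rad·ρ·ds/E per step.
* **Geometry**: 1-D slab stack (full 3-D directions, boundaries in z):
  optional pad (2 or 10 mm) on 0.1 mm epidermis, 1.0 mm dermis, 10 mm
  subcutaneous fat, 100 mm muscle (ICRP-style compositions) and a 100 mm
  water backing. Pencil beams of 50–1000 keV photons or electrons at normal
  incidence.
* **Tallies**: energy deposited per layer in MeV per primary with a
  batch-based standard error; analog transport makes the per-history energy
  balance exact, so Σ(layer deposits) + escapes = E_beam to round-off.

The history loop is a numba kernel; all cross-section data ship as frozen
plain-text tables inside the package, so everything runs offline.

## Worked example

Epidermal dose enhancement of a 2 mm alginate + 10 wt% Bi₂O₃ pad under a
100 keV photon beam:

```python
from gelshield import BeamSpec, build_stack, make_pad_material, run_beam

bare = run_beam(BeamSpec("photon", 100.0, 200_000, seed=1), build_stack(None))
pad = make_pad_material("alginate", "Bi2O3", 0.10)
padded = run_beam(BeamSpec("photon", 100.0, 200_000, seed=2), build_stack((pad, 2.0)))

e0 = bare.layer_mean("epidermis")
e1 = padded.layer_mean("epidermis")
print(f"bare epidermis   {e0:.3e} MeV/primary")
print(f"padded epidermis {e1:.3e} MeV/primary")
print(f"enhancement      {100 * (e1 - e0) / e0:+.0f}%")
```

```
bare epidermis   4.441e-05 MeV/primary
padded epidermis 6.381e-05 MeV/primary
enhancement      +44%
```

The doped pad raises the surface dose by roughly half again (the converged
value at large N is ≈55%; at 2×10⁵ histories the thin epidermis tally still
carries several percent statistical error) — photoelectric
absorption in the bismuth produces secondary electrons and 77 keV K X-rays
just upstream of the skin. The same pad at 1 MeV leaves the muscle-layer
dose within a few percent of the bare phantom: high-energy photons are
Compton-dominated and nearly indifferent to the pad's atomic number.

The full study grid (3 polymers × 5 filler states × 2 thicknesses + a
No-Pad control, both particles, 5 energies) is available as:

```python
from gelshield import SweepConfig, run_sweep, pad_heatmap, attenuation_summary
result = run_sweep(SweepConfig(n_histories=100_000, seed=0))
summary = attenuation_summary(result)          # % dose reduction vs No Pad
matrix = pad_heatmap(result, "photon", 10.0)   # pad self-absorption heatmap
```

or from the shell via `gelshield simulate | sweep | report | validate`.

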