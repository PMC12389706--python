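# Methods

## Model overview

`gelshield` is an analog (no variance reduction) coupled photon–electron
Monte Carlo code for a one-dimensional layered geometry: an optional
hydrogel pad on a four-layer skin phantom (epidermis 0.1 mm, dermis 1.0 mm,
subcutaneous fat 10 mm, skeletal muscle 100 mm) backed by 100 mm of water
to emulate a water-tank world. Particle directions are tracked in full 3-D;
material boundaries exist only in depth z. A pencil beam enters at normal
incidence at the top surface. Every history is followed, with all its
secondaries (LIFO stack), until each particle deposits its energy in a
layer, or escapes upstream or downstream; the per-history energy balance is
therefore exact to floating-point round-off, and the conservation audit
`Σ layer deposits + escapes = E_beam` is a hard invariant rather than a
statistical one.

## Materials

Pads are built in two mixing steps: hydrated gel = 80 wt% water + 20 wt%
dry polymer (chitosan C₆H₁₁NO₄ ρ=1.05, alginate C₆H₇NaO₆ ρ=1.05, cellulose
C₆H₁₀O₅ ρ=1.10 g/cm³), then gel + filler (Bi₂O₃ ρ=8.90, ZnO ρ=5.60 g/cm³)
at 0, 5 or 10 wt%. Elemental mass fractions combine linearly; density uses
the inverse-specific-volume rule 1/ρ = Σ f_k/ρ_k, the standard rule for
intimate composites. The combined pad density is not independently
constrained by any measurement we model, so `make_pad_material` accepts a
density override for sensitivity studies. Tissue layers use embedded
ICRP-style compositions (9–13 elements) with densities 1.09 (skin), 1.03
(soft tissue), 0.92 (adipose), 1.05 (skeletal muscle) and 1.00 g/cm³
(water).

## Photon physics

Per-element partial mass-attenuation tables (photoelectric, incoherent,
coherent; 1 keV – 2 MeV) ship as a frozen text artifact and combine by the
mass-fraction mixture rule. Interpolation is log–log on each element's own
grid; the K edges of Zn (9.659 keV) and Bi (90.526 keV) appear as
duplicated grid energies so interpolation never crosses an edge. Table
provenance:

* incoherent — closed-form Klein–Nishina total cross section on free
  electrons × Z/A. Exact within the free-electron model; a few percent high
  below ~60 keV where electron binding suppresses scattering, most visibly
  for bismuth.
* photoelectric — transcribed published-anchor curves for O, Zn and Bi
  (including K-edge jumps); remaining low-Z elements scale from the O curve
  as Z⁴·⁵/A, verified against spot values for Ca, Fe and Zn to better than
  ~10%. Bi L/M-edge structure below 20 keV is smoothed through the
  transcription anchors; energies that low are reached only by
  bremsstrahlung tails and are absorbed within ~0.1 mm regardless.
* coherent — form-factor-style scaling σ(Z,E) = Z²·g(E·Z^(−1/3)) of an
  embedded O curve. Crude (tens of percent for high Z), but coherent
  scattering moves no energy and redirects mildly; its effect on layer
  tallies is second order. A configuration switch disables it entirely.

Sampling: path lengths are exponential in the local μ; the interaction
channel is drawn proportionally to the partial μ/ρ. Compton scattering uses
the standard composition–rejection (Kahn-style) sampler for the
Klein–Nishina ε = E′/E; the electron angle follows from momentum
conservation. Photoelectric events choose the absorbing element with
probability ∝ wᵢ·μ_pe,i; for Zn and Bi above their K edge a K X-ray of the
mean Kα energy (8.64 / 77.1 keV) is emitted isotropically with probability
ω_K (0.474 / 0.958), the photoelectron carries E − E_K, and the relaxation
remainder deposits locally. This applies ω_K to every photoelectric event
above the edge rather than to the ~80% K-shell fraction, a deliberate
simplification that slightly overestimates fluorescence. Photoelectrons are
emitted with the Sauter–Gavrila K-shell angular distribution
(∝ sin²θ/(1−β cos θ)⁴), strongly forward-peaked at 100 keV — this matters
for pad-born electrons crossing into the epidermis. Photons below the
1 keV cutoff deposit locally.

## Electron physics

Class-I condensed history: continuous energy loss, no δ-ray production, no
energy-loss straggling. Collision stopping power is the Bethe formula for
electrons with the Møller closure, using the mixture ⟨Z/A⟩ and
Bragg-additivity ln I; the density-effect correction is omitted (<~2%
below 1 MeV). Radiative stopping uses the compact approximation
S_rad = S_col · Z_eff · E[MeV]/800 with Z_eff = Σw Z²/A / Σw Z/A, which
captures the Z-driven bremsstrahlung trend; per step one photon with a 1/k
spectrum on [1 keV, E] is emitted *forward* with probability S_rad·ρ·ds/E
and subtracted from the electron's kinetic energy (the collisional loss
S_col·ρ·ds deposits locally, keeping conservation exact). This
probability-of-one-photon scheme underestimates the total radiative yield
by roughly the logarithm of the spectral span; bremsstrahlung carries ≲1%
of the energy budget in these materials, and quantities bounded from above
by bremsstrahlung leakage (deep doses under thick pads) are conservative.

Step length is min(5% energy-loss distance, layer thickness/5, distance to
boundary), which resolves the 0.1 mm epidermis with ≥5 steps. Each step
deflects the direction by a Highland multiple-scattering angle
σ_θ = (13.6 MeV/βcp)·√(x/X₀)·max(1+0.038 ln(x/X₀), 0.25), sampled as a
Rayleigh polar angle with uniform azimuth; lateral displacement within a
step is ignored (second order in a depth-only geometry). Radiation lengths
use the Tsai-style per-element formula combined by 1/X₀ = Σ wᵢ/X₀,ᵢ.
Electrons below the 10 keV cutoff (range < 3 μm in tissue) deposit locally;
a cutoff-insensitivity test verifies thick-absorber tallies are unchanged
between 5 and 20 keV.

Validation anchors (embedded with provenance, tested before anything else):
water μ/ρ at 100/500/1000 keV (0.1707/0.0969/0.0707 cm²/g, within 2%),
Bi μ/ρ at 100 keV (5.739 cm²/g, 15%), water collision stopping at 1 MeV
(1.849 MeV cm²/g, 5%), water CSDA range at 300 keV / 1 MeV (0.0844/0.4367
g/cm², 10%).

## Random numbers and reproducibility

Each beam runs in independent batches (default 20); batch generators are
PCG64 streams spawned from the master seed via numpy `SeedSequence`, so any
run is bit-reproducible from `(seed, N, batches)` and batches could be
dispatched in parallel without changing results. The layer standard error
comes from the scatter of batch means; a per-history moment estimator
(`Tally.se_mev_pooled`) is also kept, which is smoother for the thin,
heavy-tailed epidermis tally.

## Problem sizes

The default sweep uses 10⁵ histories per configuration; the headline
acceptance computations use 10⁵–10⁶ (and 6×10⁶ for the 100 keV epidermal
enhancement ratios, whose tally is dominated by rare ~30 keV electron
crossings of the 0.1 mm epidermis and therefore carries a few-percent
relative error per 10⁶ histories). At 10⁶ histories, bulk-layer tallies
reach 0.1–0.9% relative standard error; the epidermis sits near 2.5%.

## What the engine does and does not reproduce

The engine reproduces: exact energy balance; Beer–Lambert narrow-beam
transmission; the Klein–Nishina spectrum against quadrature; CSDA ranges
against published anchors; photoelectric dominance of Bi₂O₃-rich pads below
~100 keV and its E⁻³ decay; electron range-out under 10 mm pads; the
near-transparency of all pads to 1 MeV photons at depth; and the low-energy
surface-dose enhancement of Bi₂O₃-doped pads, for which all three polymer
matrices converge to ≈55% at 100 keV (the polymers differ only in their
20 wt% dry fraction, so larger spreads between them are not physically
resolvable).

Known fidelity gaps, accepted by design: free-electron Compton (no Doppler
broadening or binding), no Sauter–Gavrila L-shell or Auger cascades (local
deposit), no δ-rays or straggling (electron backscatter from low-Z media is
underestimated — a thick-pad electron tally reads ~0.99 rather than ~0.95
MeV/primary at 1 MeV), the compact bremsstrahlung model above, and Thomson
coherent angles. One pad observable is bounded by physics rather than
fidelity: a 10 mm pad intercepts only ~7% of a 1 MeV photon beam and
Compton electrons carry ~44% of the transferred energy, so no analog tally
of the pad-interior deposit can much exceed ~0.045 MeV/primary (direct
transfer plus backscatter albedo); the engine computes ~0.043 and reports
it as computed.
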