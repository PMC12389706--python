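"""Geometry, history transport, tallies and conservation."""

import numpy as np
import pytest

from gelshield.materials import filler_material, make_pad_material, water
from gelshield.transport import (
    BeamSpec,
    Layer,
    LayerStack,
    TransportOptions,
    build_stack,
    run_beam,
    transport_history,
)


def single_slab(material, thickness_mm: float) -> LayerStack:
    return LayerStack((Layer("slab", material, 0.0, thickness_mm),))


class TestStackConstruction:
    def test_no_pad_starts_at_epidermis(self):
        s = build_stack(None)
        assert s.layers[0].name == "epidermis"
        assert s.layers[0].z_min_mm == 0.0

    def test_pad_spans_negative_z(self):
        s = build_stack((make_pad_material("alginate"), 10.0))
        pad = s["pad"]
        assert (pad.z_min_mm, pad.z_max_mm) == (-10.0, 0.0)

    def test_boundaries_contiguous(self):
        s = build_stack((make_pad_material("cellulose", "ZnO", 0.05), 2.0))
        b = s.boundaries_mm
        assert np.all(np.diff(b) > 0)
        assert list(b) == [-2.0, 0.0, 0.1, 1.1, 11.1, 111.1, 211.1]

    def test_layer_thicknesses_match_phantom(self):
        s = build_stack(None)
        assert [l.thickness_mm for l in s.layers] == pytest.approx(
            [0.1, 1.0, 10.0, 100.0, 100.0]
        )

    def test_nonpositive_pad_rejected(self):
        with pytest.raises(ValueError):
            build_stack((make_pad_material("alginate"), -1.0))


class TestBeamSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            BeamSpec("proton", 100.0, 10, 0)
        with pytest.raises(ValueError):
            BeamSpec("photon", -5.0, 10, 0)


class TestConservation:
    def test_single_history_exact(self, rng):
        deposits = transport_history(
            BeamSpec("photon", 300.0, 1, 0), build_stack(None), rng, n_histories=50
        )
        assert deposits.sum() == pytest.approx(50 * 0.3, rel=1e-12)

    def test_beam_level_conservation(self):
        beam = BeamSpec("electron", 500.0, 5_000, 42)
        tally = run_beam(beam, build_stack((make_pad_material("chitosan"), 2.0)))
        assert abs(tally.conservation_residual()) < 1e-9

    def test_vacuum_like_medium_full_escape(self, rng):
        opts = TransportOptions(mu_scale=1e-9)
        deposits = transport_history(
            BeamSpec("photon", 100.0, 1, 0), build_stack(None), rng,
            options=opts, n_histories=200,
        )
        assert deposits[-1] == pytest.approx(200 * 0.1, rel=1e-12)  # all downstream
        assert deposits[:-1].sum() == 0.0


class TestNarrowBeamOracle:
    def test_transmission_matches_beer_lambert(self):
        """Absorb-on-first-interaction mode reproduces exp(-mu t)."""
        from gelshield.photon_physics import MaterialPhotonModel, mu_over_rho

        w = water()
        t_cm = 10.0
        stack = single_slab(w, t_cm * 10.0)
        e = 100.0
        mu = mu_over_rho(MaterialPhotonModel(w), e).total * w.density
        expected = np.exp(-mu * t_cm)
        n = 1_000_000
        tally = run_beam(
            BeamSpec("photon", e, n, 7), stack,
            TransportOptions(absorb_only=True),
        )
        transmitted = tally.escape_down_mev / (e / 1000.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert transmitted == pytest.approx(expected, abs=3 * se)


class TestElectronDepthDose:
    def test_300kev_electrons_stop_within_range(self):
        """>95% of 300 keV electron energy lands in the first 1.1 mm of skin."""
        tally = run_beam(BeamSpec("electron", 300.0, 10_000, 3), build_stack(None))
        frac = (tally.layer_mean("epidermis") + tally.layer_mean("dermis")) / 0.3
        assert frac > 0.95

    def test_range_out_blocks_direct_transmission(self):
        """A pad thicker than 1.5x CSDA passes <0.1% of beam energy
        (bremsstrahlung disabled to isolate collisional transport)."""
        pad = make_pad_material("alginate", "ZnO", 0.05)
        stack = build_stack((pad, 10.0))  # CSDA(300 keV) ~ 0.9 mm << 10 mm
        tally = run_beam(
            BeamSpec("electron", 300.0, 10_000, 4), stack,
            TransportOptions(brems_enabled=False),
        )
        beyond_pad = tally.mean_mev[1:].sum() - tally.escape_up_mev
        assert beyond_pad < 1e-3 * 0.3

    def test_backscatter_higher_from_high_z(self):
        """Energy albedo of a thick Bi2O3 slab exceeds water's at 300 keV."""
        bi_slab = single_slab(filler_material("Bi2O3"), 50.0)
        w_slab = single_slab(water(), 50.0)
        t_bi = run_beam(BeamSpec("electron", 300.0, 20_000, 5), bi_slab)
        t_w = run_beam(BeamSpec("electron", 300.0, 20_000, 6), w_slab)
        assert t_bi.escape_up_mev > t_w.escape_up_mev

    def test_cutoff_insensitivity_in_thick_absorber(self):
        slab = single_slab(water(), 50.0)
        beam = BeamSpec("electron", 300.0, 20_000, 8)
        means, ses = [], []
        for cut in (5.0, 20.0):
            t = run_beam(beam, slab, TransportOptions(electron_cutoff_kev=cut))
            means.append(t.layer_mean("slab"))
            ses.append(t.layer_se("slab"))
        assert abs(means[0] - means[1]) < 3 * np.hypot(*ses)


class TestTally:
    def test_determinism_bit_identical(self):
        beam = BeamSpec("photon", 300.0, 5_000, 99)
        stack = build_stack((make_pad_material("cellulose", "Bi2O3", 0.10), 2.0))
        a = run_beam(beam, stack)
        b = run_beam(beam, stack)
        assert np.array_equal(a.sums_mev, b.sums_mev)
        assert np.array_equal(a.batch_means, b.batch_means)

    def test_se_scales_inverse_sqrt_n(self):
        stack = build_stack(None)
        t1 = run_beam(BeamSpec("photon", 100.0, 20_000, 1), stack, batches=40)
        t4 = run_beam(BeamSpec("photon", 100.0, 80_000, 2), stack, batches=40)
        i = t1.layer_names.index("muscle")
        ratio = t1.se_mev_pooled[i] / t4.se_mev_pooled[i]
        assert ratio == pytest.approx(2.0, rel=0.35)

    def test_batch_and_pooled_se_agree(self):
        t = run_beam(BeamSpec("electron", 500.0, 20_000, 12), build_stack(None))
        i = t.layer_names.index("dermis")
        assert t.se_mev[i] == pytest.approx(t.se_mev_pooled[i], rel=0.8)

    def test_layer_precision_at_1e6(self):
        """At the study's N=1e6, layer tallies reach the ~1-2% relative
        uncertainty regime: every bulk layer is well below 2%; the 0.1 mm
        epidermis, whose deposit distribution is dominated by rare electron
        crossings, sits just above at ~2.5%."""
        t = run_beam(BeamSpec("photon", 100.0, 1_000_000, 21), build_stack(None))
        rel = t.se_mev_pooled[: len(t.layer_names)] / t.mean_mev[: len(t.layer_names)]
        for name, r in zip(t.layer_names, rel):
            limit = 0.03 if name == "epidermis" else 0.02
            assert r <= limit, (name, r)

    def test_frame_schema(self):
        t = run_beam(BeamSpec("photon", 100.0, 2_000, 0), build_stack(None))
        f = t.to_frame()
        assert list(f.columns) == [
            "layer", "mean_mev_per_primary", "se_mev", "n_histories"
        ]
        assert list(f.layer[-2:]) == ["escape_up", "escape_down"]

    def test_batch_bounds_validated(self):
        with pytest.raises(ValueError):
            run_beam(BeamSpec("photon", 100.0, 50, 0), build_stack(None), batches=5)


class TestShieldingTrends:
    def test_photon_deep_layer_monotone_in_filler(self):
        """Muscle dose at 100 keV does not rise as Bi2O3 loading grows."""
        means, ses = [], []
        for wt in (0.0, 0.05, 0.10):
            pad = make_pad_material("cellulose", "Bi2O3", wt)
            t = run_beam(BeamSpec("photon", 100.0, 60_000, 31), build_stack((pad, 10.0)))
            means.append(t.layer_mean("muscle"))
            ses.append(t.layer_se("muscle"))
        assert means[1] <= means[0] + 3 * np.hypot(ses[0], ses[1])
        assert means[2] <= means[1] + 3 * np.hypot(ses[1], ses[2])
        assert means[2] < means[0]  # 10% loading shields measurably

    def test_electron_epidermis_ordering_with_thickness(self):
        """Epidermal electron dose: No Pad >= 2 mm pad >= 10 mm pad."""
        nopad = run_beam(BeamSpec("electron", 300.0, 20_000, 32), build_stack(None))
        pad = make_pad_material("alginate", "Bi2O3", 0.10)
        t2 = run_beam(BeamSpec("electron", 300.0, 20_000, 33), build_stack((pad, 2.0)))
        t10 = run_beam(BeamSpec("electron", 300.0, 20_000, 34), build_stack((pad, 10.0)))
        e0, e2, e10 = (t.layer_mean("epidermis") for t in (nopad, t2, t10))
        tol = 3 * nopad.layer_se("epidermis")
        assert e0 + tol >= e2 >= e10 - 1e-12

    def test_no_pad_photon_surface_minimum(self):
        """Bare skin sees less surface dose than under a Bi2O3 pad, 50-300 keV."""
        pad = make_pad_material("alginate", "Bi2O3", 0.10)
        for e_kev, seed in ((50.0, 35), (300.0, 36)):
            t0 = run_beam(BeamSpec("photon", e_kev, 60_000, seed), build_stack(None))
            tp = run_beam(
                BeamSpec("photon", e_kev, 60_000, seed + 10),
                build_stack((pad, 2.0)),
            )
            assert tp.layer_mean("epidermis") > t0.layer_mean("epidermis")
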