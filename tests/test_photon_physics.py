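"""Photon cross sections, interpolation and interaction sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from gelshield.fixtures import ELECTRON_REST_KEV, ELEMENT_DATA
from gelshield.materials import Material, composition_from_formula, make_pad_material
from gelshield.photon_physics import (
    EnergyOutOfRangeError,
    MaterialPhotonModel,
    compton_scattered_energy,
    element_table,
    mu_over_rho,
    photoelectric_event,
    sample_coherent_angle,
    sample_compton,
    sample_path_length,
    select_interaction,
)


class TestMuOverRho:
    def test_grid_node_identity(self, water_model):
        """At a grid node the mixture value equals the stored weighted sum."""
        table = element_table()
        e = 100.0
        expected = sum(
            w * np.interp(e, table[s]["energy"], table[s]["photoelectric"])
            for s, w in water_model.material.composition.items()
        )
        assert mu_over_rho(water_model, e).photoelectric == pytest.approx(
            expected, rel=1e-9
        )

    def test_water_is_elementwise_sum(self, water_model):
        table = element_table()
        got = mu_over_rho(water_model, 100.0)
        for part in ("photoelectric", "incoherent", "coherent"):
            expected = 0.0
            for sym, w in water_model.material.composition.items():
                t = table[sym]
                expected += w * np.exp(
                    np.interp(np.log(100.0), np.log(t["energy"]), np.log(t[part]))
                )
            assert getattr(got, part) == pytest.approx(expected, rel=1e-9)

    def test_mixture_consistency_random_energies(self, bi_pad):
        """mu(mix) = sum_i w_i mu(element_i) at 200 random energies."""
        model = MaterialPhotonModel(bi_pad)
        rng = np.random.default_rng(7)
        energies = np.exp(rng.uniform(np.log(10.0), np.log(1999.0), 200))
        pe, inc, coh = model.partials(energies)
        table = element_table()
        for part, got in (("photoelectric", pe), ("incoherent", inc), ("coherent", coh)):
            expected = np.zeros_like(energies)
            for sym, w in bi_pad.composition.items():
                t = table[sym]
                for i, e in enumerate(energies):
                    # manual log-log interpolation honoring duplicated edges
                    g = t["energy"]
                    hi = np.searchsorted(g, e, side="left")
                    hi = min(max(hi, 1), len(g) - 1)
                    lo = hi - 1
                    if g[hi] == g[lo]:
                        lo -= 1
                    f = (np.log(e) - np.log(g[lo])) / (np.log(g[hi]) - np.log(g[lo]))
                    expected[i] += w * np.exp(
                        (1 - f) * np.log(t[part][lo]) + f * np.log(t[part][hi])
                    )
            assert got == pytest.approx(expected, rel=1e-6)

    def test_out_of_span_errors(self, water_model):
        with pytest.raises(EnergyOutOfRangeError):
            water_model.partials(0.5)
        with pytest.raises(EnergyOutOfRangeError):
            water_model.partials(3000.0)

    def test_bi_photoelectric_e3_regime(self, bismuth_metal):
        """Away from edges the photoelectric partial falls roughly as E^-3."""
        model = MaterialPhotonModel(bismuth_metal)
        lo = mu_over_rho(model, 40.0).photoelectric
        hi = mu_over_rho(model, 80.0).photoelectric
        ratio = lo / hi
        assert ratio > 1.0
        assert 8.0 / 3.0 < ratio < 8.0 * 3.0  # within factor 3 of (80/40)^3

    def test_bi_k_edge_jump(self, bismuth_metal):
        model = MaterialPhotonModel(bismuth_metal)
        below = mu_over_rho(model, 90.5).photoelectric
        above = mu_over_rho(model, 90.6).photoelectric
        assert above / below > 3.0

    def test_photoelectric_fraction_falls_with_energy(self):
        """Photoelectric share at 50 keV exceeds that at 1 MeV for every pad."""
        for polymer in ("alginate", "chitosan", "cellulose"):
            for filler, wt in (("none", 0.0), ("ZnO", 0.10), ("Bi2O3", 0.10)):
                m = MaterialPhotonModel(make_pad_material(polymer, filler, wt))
                lo, hi = mu_over_rho(m, 50.0), mu_over_rho(m, 1000.0)
                assert lo.photoelectric / lo.total > hi.photoelectric / hi.total


class TestPathLength:
    def test_mean_matches_closed_form(self, water_model, rng):
        e, rho, n = 100.0, 1.0, 20_000
        mu = mu_over_rho(water_model, e).total * rho
        samples = np.array(
            [sample_path_length(water_model, rho, e, rng) for _ in range(n)]
        )
        se = samples.std() / np.sqrt(n)
        assert samples.mean() == pytest.approx(1.0 / mu, abs=3 * se)

    def test_median_of_exponential(self, water_model, rng):
        e, rho = 50.0, 5.0  # dense medium: short paths
        mu = mu_over_rho(water_model, e).total * rho
        samples = np.array(
            [sample_path_length(water_model, rho, e, rng) for _ in range(5_000)]
        )
        assert np.median(samples) < np.log(2.0) / mu * 1.1

    def test_deterministic_stream(self, water_model):
        a = [sample_path_length(water_model, 1.0, 100.0, np.random.default_rng(5))
             for _ in range(1)]
        b = [sample_path_length(water_model, 1.0, 100.0, np.random.default_rng(5))
             for _ in range(1)]
        assert a == b


class TestSelectInteraction:
    def test_zeroed_coherent_never_selected(self, water_material, rng):
        model = MaterialPhotonModel(water_material, coherent_enabled=False)
        draws = {select_interaction(model, 60.0, rng) for _ in range(500)}
        assert "coherent" not in draws

    def test_empirical_frequencies(self, water_model, rng):
        e, n = 80.0, 30_000
        p = mu_over_rho(water_model, e)
        draws = [select_interaction(water_model, e, rng) for _ in range(n)]
        for name, expected in (
            ("photoelectric", p.photoelectric / p.total),
            ("incoherent", p.incoherent / p.total),
            ("coherent", p.coherent / p.total),
        ):
            freq = draws.count(name) / n
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(freq - expected) < 3 * se + 1e-9

    def test_bi_rich_pad_photoelectric_dominates_at_50kev(self, rng):
        model = MaterialPhotonModel(make_pad_material("alginate", "Bi2O3", 0.10))
        p = mu_over_rho(model, 50.0)
        assert p.photoelectric > p.incoherent


class TestCompton:
    def test_forward_scatter_limit(self):
        assert compton_scattered_energy(321.0, 1.0) == pytest.approx(321.0)

    def test_backscatter_closed_form_511(self):
        # E' = E / (1 + 2 E/mc^2) = 511/3 at 180 degrees
        assert compton_scattered_energy(511.0, -1.0) == pytest.approx(
            ELECTRON_REST_KEV / 3.0, rel=1e-6
        )
        assert compton_scattered_energy(511.0, -1.0) == pytest.approx(170.33, abs=0.4)

    def test_energy_conservation_exact(self, rng):
        for _ in range(200):
            s = sample_compton(150.0, rng)
            assert s.e_scattered_kev + s.e_electron_kev == pytest.approx(
                150.0, abs=1e-12
            )
            assert -1.0 <= s.cos_theta_photon <= 1.0
            assert -1.0 <= s.cos_theta_electron <= 1.0

    def test_sample_consistent_with_compton_relation(self, rng):
        for _ in range(100):
            s = sample_compton(400.0, rng)
            assert s.e_scattered_kev == pytest.approx(
                compton_scattered_energy(400.0, s.cos_theta_photon), rel=1e-9
            )

    def test_mean_scattered_fraction_matches_quadrature(self, rng):
        """Sampled <E'/E> agrees with numeric integration of the KN spectrum."""
        e = 100.0
        alpha = e / ELECTRON_REST_KEV
        eps_min = 1.0 / (1.0 + 2.0 * alpha)

        def kn_density(eps):  # unnormalized dsigma/deps
            t = (1.0 - eps) / (alpha * eps)
            sin2 = t * (2.0 - t)
            return (1.0 / eps + eps) * (1.0 - eps * sin2 / (1.0 + eps * eps))

        norm, _ = quad(kn_density, eps_min, 1.0)
        mean_eps_ref = quad(lambda x: x * kn_density(x), eps_min, 1.0)[0] / norm

        n = 200_000
        eps = np.array([sample_compton(e, rng).e_scattered_kev / e for _ in range(n)])
        se = eps.std() / np.sqrt(n)
        assert eps.mean() == pytest.approx(mean_eps_ref, abs=3 * se)

    @given(e=st.floats(5.0, 1500.0))
    @settings(max_examples=30, deadline=None)
    def test_scattered_energy_within_kinematic_bounds(self, e):
        rng = np.random.default_rng(int(e * 1000))
        s = sample_compton(e, rng)
        alpha = e / ELECTRON_REST_KEV
        assert e / (1 + 2 * alpha) - 1e-9 <= s.e_scattered_kev <= e + 1e-9


class TestPhotoelectric:
    def test_no_fluorescence_without_heavy_elements(self, water_model, rng):
        for _ in range(300):
            r = photoelectric_event(water_model, 80.0, rng)
            assert r.fluorescence_kev is None
            assert r.electron_energy_kev == 80.0

    def test_bi_fluorescence_frequency(self, bismuth_metal, rng):
        """K X-ray emission frequency ~ omega_K(Bi) above the K edge."""
        model = MaterialPhotonModel(bismuth_metal)
        n = 10_000
        omega = ELEMENT_DATA["Bi"]["omega_K"]
        hits = sum(
            photoelectric_event(model, 200.0, rng).fluorescence_kev is not None
            for _ in range(n)
        )
        se = np.sqrt(omega * (1 - omega) / n)
        assert hits / n == pytest.approx(omega, abs=4 * se)

    def test_below_edge_never_fluoresces(self, bismuth_metal, rng):
        model = MaterialPhotonModel(bismuth_metal)
        for _ in range(300):
            r = photoelectric_event(model, 80.0, rng)  # below Bi K edge 90.5
            assert r.fluorescence_kev is None

    def test_fluorescence_energy_budget(self, bismuth_metal, rng):
        model = MaterialPhotonModel(bismuth_metal)
        e = 300.0
        for _ in range(200):
            r = photoelectric_event(model, e, rng)
            if r.fluorescence_kev is not None:
                total = r.electron_energy_kev + r.local_deposit_kev + r.fluorescence_kev
                assert total == pytest.approx(e, abs=1e-9)
                assert r.fluorescence_kev == pytest.approx(77.10)
                break
        else:
            pytest.fail("no fluorescence sampled in 200 events on pure Bi")


class TestCoherent:
    def test_angles_in_range_and_symmetric(self, rng):
        c = np.array([sample_coherent_angle(100.0, rng) for _ in range(20_000)])
        assert np.all((c >= -1) & (c <= 1))
        se = c.std() / np.sqrt(len(c))
        assert abs(c.mean()) < 3 * se
        # E[c^2] under the 1+c^2 density on [-1,1] is (2/3+2/5)/(8/3) = 0.4
        assert c.var() == pytest.approx(0.4, abs=0.02)
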