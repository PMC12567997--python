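import math

import numpy as np
import pytest

from ringppg.finger import RingPlacement
from ringppg.transport import (
    TransportConfig,
    fresnel_reflectance,
    run_simulation,
    sample_free_path,
    scatter_hg,
)

from conftest import homogeneous_rod


class TestFreePath:
    def test_known_draws(self):
        assert sample_free_path(1.0, math.exp(-1)) == pytest.approx(1.0)
        assert sample_free_path(2.0, math.exp(-1)) == pytest.approx(0.5)

    def test_mean_matches_exponential(self, rng):
        draws = rng.uniform(1e-12, 1.0, size=1_000_000)
        paths = sample_free_path(1.0, draws)
        se = paths.std() / math.sqrt(len(paths))
        assert abs(paths.mean() - 1.0) < 3 * se

    def test_zero_mu_t_is_free_flight(self):
        assert sample_free_path(0.0, 0.5) == math.inf


class TestHenyeyGreenstein:
    def test_isotropic_midpoint(self):
        assert scatter_hg(0.0, 0.5) == pytest.approx(0.0)

    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_first_moment_equals_g(self, g, rng):
        u = rng.uniform(0, 1, size=1_000_000)
        cos_t = scatter_hg(g, u)
        se = cos_t.std() / math.sqrt(len(cos_t))
        assert abs(cos_t.mean() - g) < 3 * se

    def test_range(self, rng):
        cos_t = scatter_hg(0.9, rng.uniform(0, 1, size=1_000_000))
        assert np.all(cos_t >= -1.0) and np.all(cos_t <= 1.0)

    def test_phi_uniform_range(self):
        cos_t, phi = scatter_hg(0.5, 0.3, 0.25)
        assert phi == pytest.approx(math.pi / 2)

    def test_invalid_g(self):
        with pytest.raises(ValueError):
            scatter_hg(1.0, 0.5)


class TestFresnel:
    def test_normal_incidence_glass(self):
        assert fresnel_reflectance(1.0, 1.5, 1.0) == pytest.approx(0.04)

    def test_index_matched(self):
        assert fresnel_reflectance(1.4, 1.4, 0.3) == 0.0

    def test_grazing_sweep_against_direct_equations(self):
        """1-degree sweep vs a direct transcription of the Fresnel equations."""
        n1, n2 = 1.4, 1.0
        critical = math.asin(n2 / n1)
        for deg in range(90):
            theta = math.radians(deg + 0.5)
            R = fresnel_reflectance(n1, n2, math.cos(theta))
            if theta >= critical:
                assert R == 1.0
            else:
                st = n1 / n2 * math.sin(theta)
                tt = math.asin(st)
                rs = (n1 * math.cos(theta) - n2 * math.cos(tt)) / (
                    n1 * math.cos(theta) + n2 * math.cos(tt)
                )
                rp = (n1 * math.cos(tt) - n2 * math.cos(theta)) / (
                    n1 * math.cos(tt) + n2 * math.cos(theta)
                )
                assert R == pytest.approx(0.5 * (rs**2 + rp**2), rel=1e-9)


class TestRunSimulation:
    @pytest.mark.parametrize("mu_a", [0.05, 0.1, 0.5])
    def test_beer_lambert_limit(self, mu_a):
        """Non-scattering straight-through transmission matches e^(-mu_a L)."""
        model = homogeneous_rod(mu_a=mu_a)
        cfg = TransportConfig(n_photons=100_000, seed=42, launch="collimated")
        res = run_simulation(model, RingPlacement(0, 180), 550, cfg)
        expected = math.exp(-mu_a * 19.2)
        se = math.sqrt(expected * (1 - expected) / cfg.n_photons)
        assert abs(res.detection_efficiency - expected) < 3 * se

    def test_all_micro_interior_gives_fraction_one(self, scattering_rod):
        cfg = TransportConfig(n_photons=20_000, seed=7)
        res = run_simulation(scattering_rod, RingPlacement(0, 90), 550, cfg)
        assert res.detected_count > 0
        assert res.micro_fraction == 1.0

    def test_deterministic_for_fixed_seed(self, default_model):
        cfg = TransportConfig(n_photons=20_000, seed=9)
        a = run_simulation(default_model, RingPlacement(0, 60), 940, cfg)
        b = run_simulation(default_model, RingPlacement(0, 60), 940, cfg)
        assert a == b

    def test_seeds_differ(self, default_model):
        a = run_simulation(
            default_model, RingPlacement(0, 60), 940, TransportConfig(20_000, seed=1)
        )
        b = run_simulation(
            default_model, RingPlacement(0, 60), 940, TransportConfig(20_000, seed=2)
        )
        assert a.detected_weight != b.detected_weight

    @pytest.mark.parametrize("wl,placement", [(550, (0, 0)), (940, (90, 150))])
    def test_weight_conservation(self, default_model, wl, placement):
        cfg = TransportConfig(n_photons=20_000, seed=3)
        res = run_simulation(default_model, RingPlacement(*placement), wl, cfg)
        total = res.absorbed_weight + res.escaped_weight + res.detected_weight
        assert total == pytest.approx(res.launched_weight, rel=1e-6)

    def test_step_cap_fraction_negligible(self, default_model):
        res = run_simulation(
            default_model, RingPlacement(0, 60), 940, TransportConfig(20_000, seed=3)
        )
        assert res.capped_count / res.launched_weight < 1e-6

    def test_micro_fraction_bounds(self, default_model):
        res = run_simulation(
            default_model, RingPlacement(0, 30), 940, TransportConfig(20_000, seed=5)
        )
        assert 0.0 <= res.micro_fraction <= 1.0
        assert (
            res.detected_weight_through_microcirculation <= res.detected_weight
        )

    def test_no_detection_yields_nan(self):
        """A fully opaque phantom lets nothing reach the PD: NaN, not an error."""
        model = homogeneous_rod(mu_a=50.0)
        res = run_simulation(
            model, RingPlacement(0, 180), 550, TransportConfig(2_000, seed=1)
        )
        assert math.isnan(res.micro_fraction)

    def test_missing_wavelength_raises(self, default_model):
        with pytest.raises(ValueError):
            run_simulation(
                default_model, RingPlacement(0, 60), 810, TransportConfig(100, seed=1)
            )
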