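import math

import numpy as np
import pytest

from swirsr import lut
from swirsr.errors import (DomainError, LowSNRError, MonotonicityError,
                          OutOfRangeError)
from swirsr.lut import (LutEntry, RatioCurve, build_lut, check_monotonic,
                        default_grid, invert_ratio, ratio_curve,
                        ratio_curve_from_diffusion, read_lut, write_lut)


def synthetic_curve(n=20, lo=0.5, hi=10.0, a=-1.0, b=0.6):
    """Strictly decreasing analytic curve r(mu) = exp(a - b*mu^0.7)."""
    mu = np.geomspace(lo, hi, n)
    r = np.exp(a - b * mu**0.7)
    return RatioCurve(wavelength=1650, mu_a_assigned=1.0, mu_s_prime=mu, ratio=r)


class TestInvertRatio:
    def test_exact_at_every_node(self):
        curve = synthetic_curve()
        for mu, r in zip(curve.mu_s_prime, curve.ratio):
            assert invert_ratio(curve, r) == mu

    def test_geometric_midpoint_gives_arithmetic_midpoint(self):
        curve = RatioCurve(wavelength=1650, mu_a_assigned=1.0,
                           mu_s_prime=np.array([1.0, 2.0]),
                           ratio=np.array([0.10, 0.20]))
        r_mid = math.sqrt(0.10 * 0.20)
        assert invert_ratio(curve, r_mid) == pytest.approx(1.5, rel=1e-12)

    def test_nonpositive_ratio_is_low_snr(self):
        with pytest.raises(LowSNRError):
            invert_ratio(synthetic_curve(), 0.0)

    def test_out_of_range_no_extrapolation(self):
        curve = synthetic_curve()
        with pytest.raises(OutOfRangeError):
            invert_ratio(curve, curve.ratio.max() * 1.5)
        with pytest.raises(OutOfRangeError):
            invert_ratio(curve, curve.ratio.min() * 0.5)

    def test_tie_breaks_to_lower_mu(self):
        curve = RatioCurve(wavelength=1650, mu_a_assigned=1.0,
                           mu_s_prime=np.array([1.0, 2.0, 3.0]),
                           ratio=np.array([0.3, 0.2, 0.2]))
        assert invert_ratio(curve, 0.2) == 2.0

    def test_recovery_within_grid_spacing(self, rng):
        # brute-force oracle: dense grid inversion of the generating function
        coarse = synthetic_curve(n=15)
        dense = synthetic_curve(n=4001)
        for _ in range(50):
            mu_star = rng.uniform(0.6, 9.5)
            r_star = math.exp(-1.0 - 0.6 * mu_star**0.7)
            mu_hat = invert_ratio(coarse, r_star)
            mu_oracle = invert_ratio(dense, r_star)
            assert mu_oracle == pytest.approx(mu_star, abs=0.01)
            i = np.searchsorted(coarse.mu_s_prime, mu_star)
            spacing = coarse.mu_s_prime[i] - coarse.mu_s_prime[i - 1]
            assert abs(mu_hat - mu_star) < spacing


class TestRatioCurve:
    def _entries(self, p_far, p_close, starved_far=None):
        entries = []
        for i, (pf, pc) in enumerate(zip(p_far, p_close)):
            musp = 1.0 + i
            entries.append(LutEntry(1650, 0.70, 1.0, musp, pf, 10_000, 10**6,
                                    bool(starved_far and i in starved_far)))
            entries.append(LutEntry(1650, 0.45, 1.0, musp, pc, 100_000, 10**6,
                                    False))
        return entries

    def test_ratio_arithmetic(self):
        curve = ratio_curve(self._entries([1e-5], [1e-4]), 1650)
        assert curve.ratio[0] == pytest.approx(0.1, rel=1e-12)

    def test_starved_pair_dropped(self):
        curve = ratio_curve(self._entries([1e-5, 2e-5], [1e-4, 1e-4],
                                          starved_far={1}), 1650)
        assert curve.mu_s_prime.tolist() == [1.0]
        assert curve.dropped == [2.0]

    def test_scaling_invariance(self):
        e1 = self._entries([1e-5, 2e-5], [1e-4, 3e-4])
        e2 = [LutEntry(x.wavelength, x.rho, x.mu_a_assigned, x.mu_s_prime,
                       x.p_det * 7.0, x.detected_count, x.launched, x.starved)
              for x in e1]
        np.testing.assert_allclose(ratio_curve(e1, 1650).ratio,
                                   ratio_curve(e2, 1650).ratio, rtol=1e-12)

    def test_all_starved_raises(self):
        with pytest.raises(DomainError):
            ratio_curve(self._entries([1e-5], [1e-4], starved_far={0}), 1650)


class TestCheckMonotonic:
    def test_clean_curve_passes_through(self):
        curve = synthetic_curve()
        assert check_monotonic(curve) is curve

    def test_small_violation_smoothed(self):
        curve = synthetic_curve(n=10)
        r = curve.ratio.copy()
        se = 0.02 * r
        r[4] = r[3] * 1.01  # within 2 SE of monotone
        noisy = RatioCurve(1650, 1.0, curve.mu_s_prime, r, ratio_se=se)
        fixed = check_monotonic(noisy)
        assert np.all(np.diff(fixed.ratio) <= 0)

    def test_large_violation_raises(self):
        curve = synthetic_curve(n=10)
        r = curve.ratio.copy()
        r[4] = r[0] * 2.0
        noisy = RatioCurve(1650, 1.0, curve.mu_s_prime, r,
                           ratio_se=0.001 * r)
        with pytest.raises(MonotonicityError):
            check_monotonic(noisy)

    def test_noise_free_violation_raises(self):
        curve = synthetic_curve(n=10)
        r = curve.ratio.copy()
        r[4] = r[3] * 1.01
        with pytest.raises(MonotonicityError):
            check_monotonic(RatioCurve(1650, 1.0, curve.mu_s_prime, r))


class TestDiffusionBackedCurve:
    def test_monotonic_and_compressed_at_1450(self, geometry):
        grid = np.geomspace(0.5, 10.0, 30)
        c1450 = ratio_curve_from_diffusion(0.78, 1450, grid, geometry)
        c1650 = ratio_curve_from_diffusion(0.78, 1650, grid, geometry)
        assert np.all(np.diff(c1450.ratio) < 0)
        assert np.all(np.diff(c1650.ratio) < 0)
        assert c1450.dynamic_range < c1650.dynamic_range

    def test_round_trip_through_inversion(self, geometry):
        from swirsr import diffusion
        grid = np.geomspace(0.5, 10.0, 60)
        curve = ratio_curve_from_diffusion(0.83, 1650, grid, geometry)
        r_star = diffusion.model_ratio(0.83, 3.1, 1650, geometry)
        assert invert_ratio(curve, r_star) == pytest.approx(3.1, rel=2e-3)


class TestBuildLut:
    def test_entry_counting_and_mu_a_constancy(self, open_geometry, water_table):
        grid = np.array([1.0, 2.0, 4.0])
        entries = build_lut(0.78, mu_s_prime_grid=grid, geometry=open_geometry,
                            n_photons=20_000, seed=5, min_counts=10)
        assert len(entries) == 12  # 3 grid x 2 wavelengths x 2 separations
        mu_a_1450 = 0.78 * water_table.mu_a(1450)
        for e in entries:
            if e.wavelength == 1450:
                assert e.mu_a_assigned == pytest.approx(mu_a_1450, rel=1e-12)

    def test_close_exceeds_far_pointwise(self, open_geometry):
        grid = np.array([2.0, 6.0])
        entries = build_lut(0.10, mu_s_prime_grid=grid, geometry=open_geometry,
                            n_photons=100_000, seed=6, min_counts=10)
        for musp in grid:
            by_rho = {e.rho: e for e in entries
                      if e.wavelength == 1650 and e.mu_s_prime == musp}
            assert by_rho[0.45].p_det > by_rho[0.70].p_det

    def test_grid_bounds_enforced(self, open_geometry):
        with pytest.raises(DomainError):
            build_lut(0.78, mu_s_prime_grid=np.array([0.01]),
                      geometry=open_geometry, n_photons=1000, seed=1)


class TestDefaultGrid:
    def test_span_and_size(self):
        g = default_grid()
        assert g.size == 40
        assert g[0] == pytest.approx(0.05) and g[-1] == pytest.approx(30.0)

    def test_bad_bounds(self):
        with pytest.raises(DomainError):
            default_grid(lo=0.01)


class TestPersistence:
    def test_round_trip_with_sidecar(self, tmp_path):
        entries = [LutEntry(1450, 0.45, 22.58, 2.0, 1e-4, 123, 10**6, False)]
        path = write_lut(entries, tmp_path / "lut.csv", fw_nominal=0.78,
                         seed=9, config={"n_photons": 10**6})
        loaded, sidecar = read_lut(path)
        assert loaded == entries
        assert sidecar["fw_nominal"] == 0.78
        assert sidecar["seed"] == 9
        assert "config_sha256" in sidecar
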