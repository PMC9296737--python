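"""Well-transmission and detector-efficiency Monte Carlo."""

import math

import numpy as np
import pytest

from alphadosim.transport import (EnergySpectrum, SourceModel, WellGeometry,
                                  pips_geometric_efficiency,
                                  radial_fluence_profile,
                                  sample_central_arrivals,
                                  simulate_well_transmission)


def cone_fraction(r, d):
    """Closed-form solid-angle fraction of the downward hemisphere
    subtended by a coaxial disk of radius r at distance d from a point."""
    return 1.0 - math.cos(math.atan2(r, d))


class TestPipsEfficiency:
    def test_point_source_matches_cone_solid_angle(self):
        got = pips_geometric_efficiency(0.0, 9.77, 36.0, 400_000, seed=1)
        assert got == pytest.approx(cone_fraction(9.77, 36.0), abs=3e-3)

    def test_zero_detector_radius_gives_zero(self):
        assert pips_geometric_efficiency(5.9, 0.0, 36.0, 1000, seed=1) == 0.0

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            pips_geometric_efficiency(-1.0, 9.77, 36.0, 1000, seed=1)

    def test_huge_detector_captures_everything(self):
        got = pips_geometric_efficiency(5.9, 1e6, 36.0, 10_000, seed=2)
        assert got == 1.0


class TestWellTransmission:
    def test_point_source_open_well_matches_cone(self, source):
        # bottom disk at 19 mm entirely limits; rim (radius 8.1 at 2 mm
        # drop) does not clip near-axis point emission
        src = SourceModel(window_radius_mm=1e-9, spectrum=source.spectrum)
        res = simulate_well_transmission(src, WellGeometry(), 400_000, seed=3,
                                         keep_arrivals=False)
        assert res.fraction == pytest.approx(cone_fraction(8.1, 19.0), abs=3e-3)

    def test_arrival_records_respect_geometry(self, source, well):
        res = simulate_well_transmission(source, well, 200_000, seed=4)
        arr = res.arrivals
        r = np.hypot(arr.x_mm, arr.y_mm)
        assert (r <= well.inner_radius_mm + 1e-9).all()
        theta_max = math.degrees(math.atan(
            (source.window_radius_mm + well.inner_radius_mm)
            / well.source_to_bottom_mm))
        assert (arr.polar_angle_deg < theta_max + 1e-9).all()
        assert (arr.energy_MeV >= 0).all()
        assert (arr.energy_MeV <= 5.486).all()

    def test_azimuthal_symmetry_by_quadrant_counts(self, source, well):
        res = simulate_well_transmission(source, well, 400_000, seed=5)
        arr = res.arrivals
        quad = (arr.x_mm > 0).astype(int) * 2 + (arr.y_mm > 0).astype(int)
        counts = np.bincount(quad, minlength=4)
        expected = len(arr) / 4
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < 16.3  # chi-square(3) at alpha = 0.001

    def test_standard_error_scales_as_inverse_sqrt(self, source, well):
        r1 = simulate_well_transmission(source, well, 50_000, seed=6,
                                        keep_arrivals=False)
        r2 = simulate_well_transmission(source, well, 200_000, seed=6,
                                        keep_arrivals=False)
        assert r2.std_error == pytest.approx(r1.std_error / 2, rel=0.1)
        assert abs(r1.fraction - r2.fraction) < 4 * r1.std_error

    def test_zero_histories_rejected(self, source, well):
        with pytest.raises(ValueError):
            simulate_well_transmission(source, well, 0, seed=1)

    def test_source_below_rim_rejected(self):
        with pytest.raises(ValueError):
            WellGeometry(source_to_bottom_mm=10.0, wall_height_mm=17.0)


class TestRadialFluence:
    def test_disk_source_profile_is_center_weighted(self, source, well):
        res = simulate_well_transmission(source, well, 400_000, seed=7)
        prof = radial_fluence_profile(res.arrivals, 8,
                                      r_max_mm=well.inner_radius_mm)
        assert prof.fluence_per_mm2.iloc[0] >= prof.fluence_per_mm2.iloc[-1]

    def test_single_center_arrival_lands_in_innermost_annulus(self):
        import pandas as pd
        arr = pd.DataFrame({"x_mm": [0.0], "y_mm": [0.0]})
        prof = radial_fluence_profile(arr, 5, r_max_mm=5.0)
        assert prof["count"].iloc[0] == 1
        assert prof["count"].iloc[1:].sum() == 0

    def test_uniform_arrivals_give_flat_profile(self):
        import pandas as pd
        rng = np.random.default_rng(8)
        n = 200_000
        r = 5.0 * np.sqrt(rng.random(n))
        phi = rng.random(n) * 2 * math.pi
        arr = pd.DataFrame({"x_mm": r * np.cos(phi), "y_mm": r * np.sin(phi)})
        prof = radial_fluence_profile(arr, 5, r_max_mm=5.0)
        dens = n / (math.pi * 25.0)
        se = np.sqrt(prof["count"]) / (math.pi * (
            prof.r_outer_mm**2 - prof.r_inner_mm**2))
        assert np.all(np.abs(prof.fluence_per_mm2 - dens) < 4 * se)

    def test_empty_arrivals_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            radial_fluence_profile(pd.DataFrame({"x_mm": [], "y_mm": []}), 3)


class TestCentralArrivals:
    def test_rate_agrees_with_brute_force_filtering(self, source, well):
        # unrestricted simulation, filtered to the central square
        res = simulate_well_transmission(source, well, 2_000_000, seed=9)
        arr = res.arrivals
        in_sq = ((arr.x_mm.abs() <= 2.0) & (arr.y_mm.abs() <= 2.0)).sum()
        brute = in_sq / res.n_histories
        se = math.sqrt(in_sq) / res.n_histories
        ca = sample_central_arrivals(source, well, 4.0, 50_000, seed=10)
        assert abs(ca.arrivals_per_history - brute) < 2 * se

    def test_importance_sampled_angles_match_brute_force(self, source, well):
        res = simulate_well_transmission(source, well, 1_000_000, seed=11)
        arr = res.arrivals
        sel = arr[(arr.x_mm.abs() <= 2.0) & (arr.y_mm.abs() <= 2.0)]
        ca = sample_central_arrivals(source, well, 4.0, len(sel), seed=12)
        from alphadosim.rif_stats import ks_two_sample
        d, p = ks_two_sample(sel.polar_angle_deg, ca.arrivals.polar_angle_deg)
        assert p > 0.001

    def test_zero_requested_returns_normalization_only(self, source, well):
        ca = sample_central_arrivals(source, well, 4.0, 0, seed=13)
        assert len(ca.arrivals) == 0
        assert ca.arrivals_per_second > 0

    def test_region_larger_than_well_rejected(self, source, well):
        with pytest.raises(ValueError):
            sample_central_arrivals(source, well, 14.0, 10, seed=1)


class TestEnergySpectrum:
    def test_default_spectrum_bounded_by_principal_line(self):
        rng = np.random.default_rng(14)
        e = EnergySpectrum().sample(50_000, rng)
        assert e.max() <= 5.486 and e.min() > 0
        assert e.mean() == pytest.approx(4.9, abs=0.02)

    def test_tabulated_spectrum_normalizes_and_samples(self):
        sp = EnergySpectrum(energies=[1.0, 2.0], probabilities=[1.0, 3.0])
        assert sp.probabilities.sum() == pytest.approx(1.0)
        rng = np.random.default_rng(15)
        draws = sp.sample(10_000, rng)
        assert np.isin(draws, [1.0, 2.0]).all()
        assert (draws == 2.0).mean() == pytest.approx(0.75, abs=0.02)
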