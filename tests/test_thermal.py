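"""Thermal chain: radiometric CSV parsing, segmentation, reference
temperatures (percentile and energy balance) and stress indices."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urbancanopy.thermal import (
    InsufficientDataError,
    MicrometState,
    ReferenceTemperatures,
    ThermalFrame,
    ThermalParseError,
    compute_ig,
    compute_td,
    compute_twsi,
    read_thermal_csv,
    reference_temps_energy_balance,
    reference_temps_percentile,
    saturation_vp,
    segment_canopy,
    svp_slope,
    vpd,
    water_status,
    write_thermal_csv,
)


# ---------------------------------------------------------------------------
# CSV I/O

class TestThermalCsv:
    def test_small_matrix_parses(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("10,20\n30,40\n")
        f = read_thermal_csv(p)
        assert np.array_equal(f.temps, [[10.0, 20.0], [30.0, 40.0]])

    def test_header_line_auto_detected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("col1,col2\n10,20\n30,40\n")
        assert read_thermal_csv(p).temps.shape == (2, 2)

    def test_round_trip_is_value_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        f = ThermalFrame(temps=rng.normal(20, 7, (17, 23)))
        p = tmp_path / "rt.csv"
        write_thermal_csv(f, p)
        assert np.array_equal(read_thermal_csv(p).temps, f.temps)

    def test_camera_native_resolution_parses(self, tmp_path):
        # 90 x 60 px export: 5400 values
        f = ThermalFrame(temps=np.full((60, 90), 25.0))
        p = tmp_path / "cam.csv"
        write_thermal_csv(f, p)
        assert read_thermal_csv(p).temps.size == 5400

    def test_ragged_row_error_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("1,2,3\n4,5\n")
        with pytest.raises(ThermalParseError, match="row 2"):
            read_thermal_csv(p)

    def test_non_numeric_cell_error_names_row_and_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("1,2,3\n4,oops,6\n")
        with pytest.raises(ThermalParseError, match="row 2, column 2"):
            read_thermal_csv(p)


# ---------------------------------------------------------------------------
# segmentation

class TestSegmentCanopy:
    def test_cold_sky_half_is_excluded(self):
        temps = np.full((10, 10), -40.0)
        temps[:, 5:] = 25.0
        ct = segment_canopy(ThermalFrame(temps=temps))
        assert ct.valid and ct.n_pixels == 50
        assert ct.t_canopy == pytest.approx(25.0)
        assert np.array_equal(ct.mask, temps > 0)

    def test_all_sky_frame_flagged_invalid(self):
        ct = segment_canopy(ThermalFrame(temps=np.full((10, 10), -40.0)))
        assert not ct.valid and math.isnan(ct.t_canopy)

    def test_gaussian_canopy_mean_recovered(self):
        # Monte-Carlo: canopy ~ N(28, 1), sky -40; mean within 3 SE of 28
        rng = np.random.default_rng(11)
        temps = np.full((60, 90), -40.0)
        mask = rng.random((60, 90)) < 0.5
        n = int(mask.sum())
        temps[mask] = rng.normal(28.0, 1.0, n)
        ct = segment_canopy(ThermalFrame(temps=temps))
        assert ct.n_pixels == n
        assert abs(ct.t_canopy - 28.0) < 3.0 / math.sqrt(n)

    def test_median_statistic_available(self):
        temps = np.full((10, 10), 20.0)
        temps[0, 0] = 60.0  # hot outlier barely shifts the median
        ct = segment_canopy(ThermalFrame(temps=temps), statistic="median")
        assert ct.t_canopy == 20.0


# ---------------------------------------------------------------------------
# percentile references

class TestPercentileReferences:
    def test_linear_interpolation_matches_sort_and_index_oracle(self):
        # temps 1..100: index h = p/100 * (n-1) into the sorted sample,
        # linearly interpolated -> 5.95 and 95.05
        temps = np.arange(1.0, 101.0)
        ct = segment_canopy(ThermalFrame(temps=temps.reshape(10, 10)))
        refs = reference_temps_percentile(ct)
        s = np.sort(temps)

        def oracle(p):
            h = p / 100 * (len(s) - 1)
            lo = int(math.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])

        assert refs.t_wet == pytest.approx(oracle(5.0)) == pytest.approx(5.95)
        assert refs.t_dry == pytest.approx(oracle(95.0)) == pytest.approx(95.05)

    def test_constant_canopy_flagged_degenerate(self):
        ct = segment_canopy(ThermalFrame(temps=np.full((10, 10), 25.0)))
        refs = reference_temps_percentile(ct)
        assert refs.degenerate and refs.t_dry == refs.t_wet

    def test_extreme_percentiles_are_min_and_max(self):
        temps = np.arange(1.0, 101.0).reshape(10, 10)
        ct = segment_canopy(ThermalFrame(temps=temps))
        refs = reference_temps_percentile(ct, p_wet=0, p_dry=100)
        assert (refs.t_wet, refs.t_dry) == (1.0, 100.0)

    def test_too_few_pixels_raises(self):
        temps = np.full((10, 10), -40.0)
        temps[0, :6] = 25.0
        ct = segment_canopy(ThermalFrame(temps=temps), min_pixel_fraction=0.01)
        with pytest.raises(InsufficientDataError):
            reference_temps_percentile(ct)


# ---------------------------------------------------------------------------
# psychrometrics

class TestPsychrometrics:
    def test_tetens_anchor_at_zero_celsius(self):
        assert saturation_vp(0.0) == pytest.approx(610.78)

    def test_saturated_air_has_zero_vpd(self):
        assert vpd(20.0, 1.0) == 0.0

    def test_slope_matches_finite_difference(self):
        h = 1e-4
        fd = (saturation_vp(20 + h) - saturation_vp(20 - h)) / (2 * h)
        assert svp_slope(20.0) == pytest.approx(fd, rel=1e-3)

    def test_rh_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            vpd(20.0, 1.5)


# ---------------------------------------------------------------------------
# energy balance

class TestEnergyBalance:
    def test_no_radiation_saturated_air_collapses_to_t_air(self):
        met = MicrometState(t_air=25.0, rh=1.0, r_ni=0.0)
        refs = reference_temps_energy_balance(met)
        assert refs.t_dry == pytest.approx(25.0)
        assert refs.t_wet == pytest.approx(25.0)

    def test_evaporative_cooling_only(self):
        met = MicrometState(t_air=25.0, rh=0.5, r_ni=0.0)
        refs = reference_temps_energy_balance(met)
        assert refs.t_dry == pytest.approx(25.0)
        assert refs.t_wet < 25.0

    def test_direct_substitution_oracle(self):
        # frozen from an independent scalar evaluation of the dry/wet
        # reference formulas at t_air=25, rh=0.5, r_ni=300, r_aw=50,
        # r_hr=30, gamma=66, rho=1.184, cp=1005
        met = MicrometState(t_air=25.0, rh=0.5, r_ni=300.0, r_aw=50.0,
                            r_hr=30.0, gamma=66.0, rho=1.184, cp=1005.0)
        refs = reference_temps_energy_balance(met)
        assert refs.t_dry == pytest.approx(32.563533682936665, abs=1e-9)
        assert refs.t_wet == pytest.approx(22.482792868158295, abs=1e-9)
        assert refs.t_wet < 25.0 < refs.t_dry

    def test_t_dry_monotone_in_radiation(self):
        dries = [reference_temps_energy_balance(
            MicrometState(t_air=25.0, rh=0.5, r_ni=r)).t_dry
            for r in np.linspace(0, 900, 10)]
        assert all(b > a for a, b in zip(dries, dries[1:]))

    def test_t_wet_monotone_decreasing_in_vpd(self):
        wets = [reference_temps_energy_balance(
            MicrometState(t_air=25.0, rh=rh, r_ni=300.0)).t_wet
            for rh in np.linspace(1.0, 0.1, 10)]  # decreasing rh = rising vpd
        assert all(b < a for a, b in zip(wets, wets[1:]))

    def test_air_density_defaults_from_temperature(self):
        met = MicrometState(t_air=25.0, rh=0.5, r_ni=100.0)
        assert met.rho == pytest.approx(101325.0 / (287.05 * 298.15))


# ---------------------------------------------------------------------------
# indices

REFS = ReferenceTemperatures(t_wet=20.0, t_dry=30.0, method="percentile")


class TestStressIndices:
    @pytest.mark.parametrize("tc,expected", [(20.0, 0.0), (30.0, 1.0),
                                             (25.0, 0.5)])
    def test_twsi_endpoints_and_midpoint(self, tc, expected):
        twsi, clamped = compute_twsi(tc, REFS)
        assert twsi == expected and not clamped

    def test_twsi_clamps_out_of_range_with_flag(self):
        lo, cl = compute_twsi(15.0, REFS)
        hi, ch = compute_twsi(35.0, REFS)
        assert (lo, cl) == (0.0, True) and (hi, ch) == (1.0, True)

    def test_ig_closed_stomata_limit(self):
        assert compute_ig(30.0, REFS) == 0.0

    def test_ig_midpoint_is_one(self):
        assert compute_ig(25.0, REFS) == pytest.approx(1.0)

    def test_ig_degenerate_below_wet_reference(self):
        assert math.isnan(compute_ig(19.0, REFS))

    @given(st.floats(20.001, 30.0))
    @settings(max_examples=200, deadline=None)
    def test_ig_twsi_identity(self, tc):
        twsi, _ = compute_twsi(tc, REFS)
        ig = compute_ig(tc, REFS)
        assert abs(ig - (1 - twsi) / twsi) < 1e-9

    def test_td_is_signed_difference(self):
        assert compute_td(28.2, 25.0) == pytest.approx(3.2)
        assert compute_td(25.0, 25.0) == 0.0
        assert compute_td(1.0, 4.0) == -compute_td(4.0, 1.0)

    def test_water_status_bundles_flags(self):
        ws = water_status(35.0, REFS, t_air=25.0)
        assert ws.twsi == 1.0 and ws.clamped and not ws.degenerate
        assert ws.td == pytest.approx(10.0)
        bad = ReferenceTemperatures(t_wet=30.0, t_dry=20.0,
                                    method="percentile", degenerate=True)
        assert water_status(25.0, bad).degenerate
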